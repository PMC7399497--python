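"""Single-site isothermal titration calorimetry: simulation and fitting.

The model is one class of independent sites.  At every injection the cell
contents are diluted by the standard perfusion bookkeeping (the cell volume
is constant, each injected aliquot displaces an equal volume of the mixed
cell contents), the single-site mass balance is solved for the bound-complex
concentration, and the integrated heat is the enthalpy of newly formed
complex plus a constant dilution heat.

Weak binding (Wiseman c = N * M_cell / K_d below ~1) gives a hyperbolic,
featureless isotherm in which N and K_d trade off against each other; the
fitter raises an identifiability flag in that regime rather than pretending
the covariance matrix is trustworthy.

Internally everything is SI (molar, joules); reported values follow the
conventional presentation (K_d in microM, heats in microcal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "TitrationProtocol",
    "BindingParameters",
    "Isotherm",
    "FitResult",
    "simulate_titration",
    "fit_isotherm",
    "wiseman_c",
    "read_isotherm",
    "write_isotherm",
]

R_GAS = 8.31446261815324  # J/(mol K)
CAL = 4.184               # J per cal


@dataclass(frozen=True)
class TitrationProtocol:
    """Injection protocol; defaults follow a VP-ITC run of 19 x 10 uL
    injections of 5 mM ligand into 0.13 mM macromolecule at 25 C."""

    cell_concentration: float = 1.3e-4   # M (macromolecule, in cell)
    syringe_concentration: float = 5e-3  # M (ligand, in syringe)
    injection_volume: float = 1.0e-5     # L
    n_injections: int = 19
    cell_volume: float = 1.4195e-3       # L (VP-ITC active cell volume)
    temperature: float = 298.15          # K

    def __post_init__(self) -> None:
        if min(self.cell_concentration, self.syringe_concentration,
               self.injection_volume, self.cell_volume, self.temperature) <= 0:
            raise ValueError("protocol quantities must be positive")
        if self.n_injections < 1:
            raise ValueError("need at least one injection")


@dataclass
class BindingParameters:
    """Single-site parameters: K_d (M), stoichiometry N, enthalpy (J/mol)."""

    kd: float
    n: float
    dh: float
    temperature: float = 298.15
    kd_err: float | None = None
    n_err: float | None = None
    dh_err: float | None = None

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.n <= 0:
            raise ValueError("K_d and N must be positive")

    @property
    def dg(self) -> float:
        """Binding free energy, dG = RT ln K_d (J/mol; negative for K_d < 1 M)."""
        return R_GAS * self.temperature * np.log(self.kd)

    @property
    def ds(self) -> float:
        """Binding entropy from dG = dH - T dS (J/(mol K))."""
        return (self.dh - self.dg) / self.temperature

    @property
    def kd_microM(self) -> float:
        return self.kd * 1e6


@dataclass
class Isotherm:
    """Integrated per-injection heats in microcal, with the protocol."""

    heats_ucal: np.ndarray
    protocol: TitrationProtocol
    sigma_ucal: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if len(self.heats_ucal) != self.protocol.n_injections:
            raise ValueError("heat count does not match the protocol")

    def molar_ratios(self) -> np.ndarray:
        """Cumulative ligand / macromolecule molar ratio in the cell."""
        mtot, xtot = _cell_concentrations(self.protocol)
        return xtot / mtot


def _cell_concentrations(protocol: TitrationProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Total cell concentrations after each injection (perfusion recursion).

    Each aliquot dV mixes into the constant cell volume V0 and displaces an
    equal volume of the mixture: c -> c * V0/(V0+dV) for resident species,
    plus the injected ligand share.
    """
    v0, dv = protocol.cell_volume, protocol.injection_volume
    keep = v0 / (v0 + dv)
    m = np.empty(protocol.n_injections)
    x = np.empty(protocol.n_injections)
    mc, xc = protocol.cell_concentration, 0.0
    for i in range(protocol.n_injections):
        mc = mc * keep
        xc = (xc * v0 + protocol.syringe_concentration * dv) / (v0 + dv)
        m[i], x[i] = mc, xc
    return m, x


def _bound_concentration(m_sites: float, x_total: float, kd: float) -> float:
    """Single-site mass balance: [MX] from totals via the stable quadratic root."""
    b = m_sites + x_total + kd
    disc = b * b - 4.0 * m_sites * x_total
    return 0.5 * (b - np.sqrt(max(disc, 0.0)))


def _model_heats_ucal(
    kd: float, n: float, dh: float, baseline_ucal: float,
    protocol: TitrationProtocol,
) -> np.ndarray:
    """Per-injection heats (microcal) for the single-site perfusion model."""
    v0, dv = protocol.cell_volume, protocol.injection_volume
    keep = v0 / (v0 + dv)
    mtot, xtot = _cell_concentrations(protocol)
    heats = np.empty(protocol.n_injections)
    bound_prev = 0.0
    for i in range(protocol.n_injections):
        bound = _bound_concentration(n * mtot[i], xtot[i], kd)
        dq = dh * v0 * (bound - bound_prev * keep)  # J
        heats[i] = dq / CAL * 1e6 + baseline_ucal
        bound_prev = bound
    return heats


def simulate_titration(
    params: BindingParameters,
    protocol: TitrationProtocol | None = None,
    dilution_heat_ucal: float = 0.0,
    noise_fraction: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> Isotherm:
    """Simulate an isotherm; noise is Gaussian with sigma equal to
    ``noise_fraction`` of the largest ideal injection heat."""
    protocol = protocol or TitrationProtocol()
    ideal = _model_heats_ucal(params.kd, params.n, params.dh, dilution_heat_ucal, protocol)
    sigma = None
    heats = ideal
    if noise_fraction > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        scale = noise_fraction * float(np.abs(ideal).max())
        heats = ideal + rng.normal(0.0, scale, size=len(ideal))
        sigma = np.full(len(ideal), scale)
    return Isotherm(heats, protocol, sigma, label=f"sim kd={params.kd:.3g}")


@dataclass
class FitResult:
    params: BindingParameters
    baseline_ucal: float
    c_value: float
    kd_n_correlation: float
    identifiability_flag: bool
    chi2: float
    message: str = ""
    covariance: np.ndarray | None = field(default=None, repr=False)


def wiseman_c(params_or_kd, protocol: TitrationProtocol, n: float | None = None) -> float:
    """Wiseman c parameter, c = N M_cell / K_d."""
    if isinstance(params_or_kd, BindingParameters):
        kd, nn = params_or_kd.kd, params_or_kd.n
    else:
        kd, nn = float(params_or_kd), float(n if n is not None else 1.0)
    return nn * protocol.cell_concentration / kd


def fit_isotherm(
    isotherm: Isotherm,
    protocol: TitrationProtocol | None = None,
    fit_baseline: bool = True,
    baseline_ucal: float = 0.0,
    x0: tuple[float, float, float] | None = None,
) -> FitResult:
    """Weighted nonlinear least squares for (K_d, N, dH [, baseline]).

    K_d is fitted on a log scale.  The identifiability flag is raised when the
    fitted Wiseman c-value is below 1 or the K_d-N correlation exceeds 0.95,
    the regime where stoichiometry and affinity cannot be refined
    independently.
    """
    protocol = protocol or isotherm.protocol
    if protocol.n_injections < 6:
        raise ValueError("need at least six injections for a meaningful fit")
    y = isotherm.heats_ucal
    sig = isotherm.sigma_ucal
    if sig is None:
        sig = np.full(len(y), max(0.01 * float(np.abs(y).max()), 1e-9))

    # starting guesses: saturation heat scale and a mid-range affinity
    if x0 is None:
        dh0 = float(y[0] - y[-1]) * CAL * 1e-6 / max(
            protocol.injection_volume * protocol.syringe_concentration, 1e-30
        )
        dh0 = dh0 if abs(dh0) > 1e3 else -2e4
        x0 = (np.log(protocol.cell_concentration), 1.0, dh0)
    base0 = [baseline_ucal] if fit_baseline else []

    def resid(theta):
        logkd, n, dh = theta[:3]
        base = theta[3] if fit_baseline else baseline_ucal
        if n <= 0:
            return np.full(len(y), 1e6)
        model = _model_heats_ucal(np.exp(logkd), n, dh, base, protocol)
        return (model - y) / sig

    res = optimize.least_squares(
        resid, np.array([x0[0], x0[1], x0[2], *base0]),
        method="lm" if len(y) > 4 else "trf", max_nfev=20000,
    )
    if not res.success:
        raise RuntimeError(
            f"isotherm fit did not converge: {res.message}; last iterate {res.x}"
        )
    logkd, n, dh = res.x[:3]
    base = float(res.x[3]) if fit_baseline else baseline_ucal
    kd = float(np.exp(logkd))
    dof = max(len(y) - len(res.x), 1)
    s2 = float(2 * res.cost / dof)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        cov = np.full((len(res.x), len(res.x)), np.nan)
    kd_err = kd * float(np.sqrt(abs(cov[0, 0])))
    n_err = float(np.sqrt(abs(cov[1, 1])))
    dh_err = float(np.sqrt(abs(cov[2, 2])))
    denom = np.sqrt(abs(cov[0, 0]) * abs(cov[1, 1]))
    corr = float(abs(cov[0, 1]) / denom) if denom > 0 else 1.0
    c_val = wiseman_c(kd, protocol, n)
    flag = bool(c_val < 1.0 or corr > 0.95)
    params = BindingParameters(
        kd, float(n), float(dh), protocol.temperature,
        kd_err=kd_err, n_err=n_err, dh_err=dh_err,
    )
    chi2 = float(2 * res.cost / dof)
    return FitResult(params, base, c_val, corr, flag, chi2,
                     message=res.message, covariance=cov)


def write_isotherm(isotherm: Isotherm, path) -> None:
    """Two-column text: molar ratio, integrated heat (microcal)."""
    ratios = isotherm.molar_ratios()
    with open(path, "w") as fh:
        fh.write(f"# {isotherm.label}\n# molar_ratio heat_ucal\n")
        for r, h in zip(ratios, isotherm.heats_ucal):
            fh.write(f"{r:.6f} {h:.6e}\n")


def read_isotherm(path, protocol: TitrationProtocol) -> Isotherm:
    heats = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            heats.append(float(s.split()[-1]))
    return Isotherm(np.asarray(heats), protocol, label=str(path))
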