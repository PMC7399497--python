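"""Volume-fraction mixture fitting of scattering curves.

An experimental curve is modelled as a non-negative linear combination of
component curves (oligomers of n copies, alternate monomer conformers, an
optional free-ligand term) with a free overall scale:

    I_model(q) = s * sum_k f_k I_k(q),   f_k >= 0,  sum_k f_k = 1.

The solver is plain non-negative least squares on unnormalized weights
(w_k = s f_k), which makes the problem linear and deterministic; the scale is
recovered as s = sum w_k.  Reduced chi^2 uses N - 1 degrees of freedom.

Volume fractions are converted to per-monomer populations with
p_k = f_k n_k / sum_j f_j n_j: a fraction assigned to an n-mer is weighted by
its oligomer number before renormalization, so the histogram reports the
proportion of monomers living in each oligomer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .saxs_model import ScatteringCurve

__all__ = [
    "Component",
    "ComponentSet",
    "MixtureResult",
    "fit_volume_fractions",
    "populations",
    "chi2",
    "CollinearComponentsWarning",
]


class CollinearComponentsWarning(UserWarning):
    pass


@dataclass
class Component:
    label: str
    curve: ScatteringCurve
    n_copies: int = 1                  # oligomer number n_k
    population_eligible: bool = True   # False for e.g. a free-ligand term

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError("oligomer number must be >= 1")


@dataclass
class ComponentSet:
    components: list[Component]

    def __post_init__(self) -> None:
        labels = [c.label for c in self.components]
        if len(set(labels)) != len(labels):
            raise ValueError("component labels must be unique")
        if not self.components:
            raise ValueError("need at least one component")

    def __iter__(self):
        return iter(self.components)

    def __len__(self) -> int:
        return len(self.components)

    def design_matrix(self, q: np.ndarray) -> np.ndarray:
        """Component intensities interpolated onto the data grid (never the
        reverse: data sigmas must be preserved)."""
        cols = []
        for comp in self.components:
            cols.append(comp.curve.interpolated_to(q).I)
        return np.column_stack(cols)


@dataclass
class MixtureResult:
    labels: list[str]
    fractions: np.ndarray
    fraction_errors: np.ndarray
    scale: float
    chi2: float
    background: float | None = None
    condition_number: float = field(default=np.nan)

    def fraction(self, label: str) -> float:
        return float(self.fractions[self.labels.index(label)])

    def fraction_error(self, label: str) -> float:
        return float(self.fraction_errors[self.labels.index(label)])

    def report(self, components: "ComponentSet | None" = None) -> str:
        lines = [f"scale = {self.scale:.6g}   reduced chi2 = {self.chi2:.4g}"]
        if self.background is not None:
            lines.append(f"background = {self.background:.6g}")
        pops = None
        if components is not None:
            pops, pop_err = populations(self, components, with_errors=True)
        for i, lab in enumerate(self.labels):
            row = f"  {lab:>8s}  f = {self.fractions[i]:.4f} +- {self.fraction_errors[i]:.4f}"
            if pops is not None and lab in pops:
                row += f"   population = {pops[lab]:.4f} +- {pop_err[lab]:.4f}"
            lines.append(row)
        return "\n".join(lines)


def chi2(
    data: ScatteringCurve, model_I: np.ndarray, n_fitted: int | None = None
) -> float:
    """Reduced chi^2 between a curve and a model evaluated on the same grid.

    With no fitted-parameter count supplied, N - 1 degrees of freedom are
    used (the common SAXS convention).
    """
    if data.sigma is None:
        raise ValueError("chi2 requires data uncertainties")
    model_I = np.asarray(model_I, dtype=float)
    if model_I.shape != data.q.shape:
        raise ValueError("model grid does not match data grid")
    resid = (data.I - model_I) / data.sigma
    dof = len(data.q) - (1 if n_fitted is None else n_fitted)
    return float((resid**2).sum() / max(dof, 1))


def fit_volume_fractions(
    data: ScatteringCurve,
    components: ComponentSet,
    background: bool = False,
) -> MixtureResult:
    """Fit volume fractions by non-negative least squares.

    Returns fractions on the simplex (f >= 0, sum f = 1), the overall scale,
    reduced chi^2 and covariance-based fraction uncertainties.  An optional
    flat additive background term can be co-fitted.
    """
    if data.sigma is None:
        raise ValueError("mixture fitting requires data uncertainties")
    A = components.design_matrix(data.q)
    if background:
        A = np.column_stack([A, np.ones(len(data.q))])
    Aw = A / data.sigma[:, None]
    yw = data.I / data.sigma
    cond = float(np.linalg.cond(Aw))
    if cond > 1e8:
        warnings.warn(
            f"component curves nearly collinear (condition number {cond:.3g}); "
            "fractions may be poorly determined",
            CollinearComponentsWarning,
            stacklevel=2,
        )
    w, _ = nnls(Aw, yw)
    ncomp = len(components)
    bkg = float(w[-1]) if background else None
    wc = w[:ncomp]
    s = float(wc.sum())
    if s <= 0:
        raise ValueError("all component weights fitted to zero")
    fractions = wc / s
    model_I = A @ w
    n_fitted = ncomp + (1 if background else 0)
    chisq = chi2(data, model_I, n_fitted=n_fitted)
    # covariance of the unnormalized weights on the active set, then
    # first-order propagation through the normalization f_k = w_k / sum(w)
    active = w > 0
    cov_w = np.zeros((len(w), len(w)))
    if active.any():
        Aact = Aw[:, active]
        try:
            cov_act = np.linalg.inv(Aact.T @ Aact) * max(chisq, 1.0)
            cov_w[np.ix_(active, active)] = cov_act
        except np.linalg.LinAlgError:
            cov_w[:] = np.nan
    cov_c = cov_w[:ncomp, :ncomp]
    J = (np.eye(ncomp) - fractions[:, None]) / s  # d f_i / d w_j
    cov_f = J @ cov_c @ J.T
    f_err = np.sqrt(np.maximum(np.diag(cov_f), 0.0))
    return MixtureResult(
        labels=[c.label for c in components],
        fractions=fractions,
        fraction_errors=f_err,
        scale=s,
        chi2=chisq,
        background=bkg,
        condition_number=cond,
    )


def populations(
    result: MixtureResult,
    components: ComponentSet,
    with_errors: bool = False,
):
    """Per-monomer population histogram, p_k = f_k n_k / sum_j f_j n_j.

    Only population-eligible components enter (a free-ligand term is
    excluded).  Errors are first-order propagated from the fraction
    uncertainties.
    """
    eligible = [c for c in components if c.population_eligible]
    if not eligible:
        raise ValueError("no population-eligible components")
    idx = [result.labels.index(c.label) for c in eligible]
    f = result.fractions[idx]
    n = np.array([c.n_copies for c in eligible], dtype=float)
    total = float(f @ n)
    if total <= 0:
        raise ValueError("all eligible fractions are zero")
    p = f * n / total
    pops = {c.label: float(pk) for c, pk in zip(eligible, p)}
    if not with_errors:
        return pops
    ferr = result.fraction_errors[idx]
    # dp_i/df_j = n_i (delta_ij total - f_i n_j) / total^2 ; diagonal approx
    errs = {}
    for i, c in enumerate(eligible):
        grads = n * (-f[i] * n[i]) / total**2
        grads[i] += n[i] / total
        errs[c.label] = float(np.sqrt(((grads * ferr) ** 2).sum()))
    return pops, errs
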