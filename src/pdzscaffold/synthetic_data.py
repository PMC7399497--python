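"""Synthetic data generators with serialized ground truth.

Everything the analysis pipeline consumes can be generated here with known
generating parameters: a coarse-grained dumbbell monomer standing in for a
two-domain tandem construct, noisy exposure-frame series with optional
radiation-damage inflation, dilution series with a linear interparticle
interference factor, oligomer mixture curves built from the scaffolding
presets, and single-site titrations.

Every generator is a pure function of (spec, seed), and each dataset carries
a :class:`GroundTruth` record that serializes the generating parameters to
JSON so recovery tests read truth from the sidecar, never from closures.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .itc import BindingParameters, Isotherm, TitrationProtocol, simulate_titration
from .saxs_model import ScatteringCurve, debye_curve
from .saxs_reduce import DilutionSeries, FrameSeries
from .structures import CoordinateSet

__all__ = [
    "DumbbellSpec",
    "GroundTruth",
    "make_dumbbell",
    "make_frame_series",
    "make_dilution_series",
    "make_mixture_dataset",
    "make_itc_dataset",
    "noisy_curve",
]


@dataclass(frozen=True)
class DumbbellSpec:
    """Two bead-filled spherical domains joined by a short linker.

    Defaults give a radius of gyration near 22.5 A, inside the 21-25 A band
    of a two-domain tandem that samples extended conformations.
    """

    domain_radius: float = 12.0     # A
    separation: float = 40.0        # A between domain centres
    beads_per_domain: int = 60
    linker_beads: int = 4
    rg_band: tuple[float, float] = (21.0, 25.0)

    def __post_init__(self) -> None:
        if self.separation < 2 * self.domain_radius:
            raise ValueError(
                "infeasible spec: separation smaller than the sum of domain radii"
            )


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic dataset."""

    kind: str
    seed: int | None
    parameters: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=_jsonable)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["kind"], d.get("seed"), d.get("parameters", {}))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _sphere_beads(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Quasi-uniform bead fill of a sphere (rejection sampling)."""
    out = []
    while len(out) < n:
        pts = rng.uniform(-radius, radius, size=(2 * n, 3))
        pts = pts[(pts**2).sum(axis=1) <= radius**2]
        out.extend(pts.tolist())
    return np.asarray(out[:n])


def make_dumbbell(
    spec: DumbbellSpec | None = None, seed: int | None = 0, label: str = "dumbbell"
) -> CoordinateSet:
    """Deterministic dumbbell bead model along x, centred at the origin.

    Beads are uniform-weight pseudo-atoms; the first ``beads_per_domain``
    belong to domain 1 (the PDZ1-like half), the next block to domain 2, and
    the remainder to the linker.  The model's radius of gyration is checked
    against the spec band.
    """
    spec = spec or DumbbellSpec()
    rng = np.random.default_rng(seed)
    half = spec.separation / 2.0
    c1 = np.array([-half, 0.0, 0.0])
    c2 = np.array([+half, 0.0, 0.0])
    d1 = _sphere_beads(rng, spec.beads_per_domain, spec.domain_radius) + c1
    d2 = _sphere_beads(rng, spec.beads_per_domain, spec.domain_radius) + c2
    if spec.linker_beads > 0:
        ts = np.linspace(-0.3, 0.3, spec.linker_beads)
        linker = np.outer(ts, c2 - c1)
    else:
        linker = np.empty((0, 3))
    coords = np.vstack([d1, d2, linker])
    res_names = (
        ["DM1"] * len(d1) + ["DM2"] * len(d2) + ["LNK"] * len(linker)
    )
    cs = CoordinateSet.from_points(coords, weight=1.0, label=label, res_names=res_names)
    rg = float(np.sqrt(((cs.coords - cs.coords.mean(0)) ** 2).sum(1).mean()))
    lo, hi = spec.rg_band
    if not (lo <= rg <= hi):
        raise ValueError(f"generated dumbbell R_g {rg:.1f} A outside band [{lo}, {hi}]")
    return cs


def noisy_curve(
    curve: ScatteringCurve,
    noise_level: float,
    rng: np.random.Generator,
    model: str = "counting",
    floor_fraction: float = 1e-4,
) -> ScatteringCurve:
    """Add Gaussian noise to a curve.

    ``model="counting"``: sigma(q) proportional to sqrt(I), scaled so
    ``noise_level`` is the fractional error at the intensity maximum
    (sigma = noise_level * sqrt(I * I_max) plus a small floor) - the
    counting-statistics emulation used for exposure frames and dilution
    series.  ``model="relative"``: sigma = noise_level * I pointwise, the
    conventional meaning of "x% Gaussian noise" on a curve.
    """
    imax = float(curve.I.max())
    if model == "counting":
        floor = floor_fraction * imax
        sigma = noise_level * np.sqrt(np.maximum(curve.I, 0.0) * imax + floor * imax)
    elif model == "relative":
        sigma = noise_level * np.abs(curve.I)
    else:
        raise ValueError("noise model must be 'counting' or 'relative'")
    sigma = np.maximum(sigma, 1e-12 * imax)
    noisy = curve.I + rng.normal(0.0, sigma) if noise_level > 0 else curve.I.copy()
    return ScatteringCurve(curve.q, noisy, sigma, curve.concentration, curve.label)


def mixture_q_grid(q_min: float = 0.006, q_max: float = 0.48, n: int = 500) -> np.ndarray:
    """The q grid used for synthetic mixture data: the measured range and a
    beamline-like sampling density (hundreds of points to ~0.5 1/A)."""
    return np.linspace(q_min, q_max, n)


def make_frame_series(
    base: ScatteringCurve,
    n_frames: int = 6,
    noise_level: float = 0.01,
    damaged_frames: Sequence[int] = (),
    damage_lowq_factor: float = 3.0,
    seed: int | None = 0,
) -> tuple[FrameSeries, GroundTruth]:
    """Exposure frames of one sample; listed frames get low-q inflated and
    high-q deflated scattering, the radiation-damage signature."""
    rng = np.random.default_rng(seed)
    qn = base.q / base.q[-1]
    lowq_shape = np.exp(-((qn / 0.15) ** 2))
    frames = []
    for i in range(n_frames):
        ideal = base.I.copy()
        if i in damaged_frames:
            ideal = ideal * (1.0 + (damage_lowq_factor - 1.0) * lowq_shape)
            ideal = ideal * (1.0 - 0.3 * (1.0 - lowq_shape))
        frames.append(
            noisy_curve(
                ScatteringCurve(base.q, ideal, None, base.concentration,
                                f"frame{i}"),
                noise_level, rng,
            )
        )
    truth = GroundTruth(
        "frame_series", seed,
        {"n_frames": n_frames, "damaged_frames": list(damaged_frames),
         "noise_level": noise_level, "damage_lowq_factor": damage_lowq_factor},
    )
    return FrameSeries(frames), truth


def default_interference(q: np.ndarray, amplitude: float = 0.25,
                         width: float = 0.05) -> np.ndarray:
    """Default beta(q): a smooth positive low-q bump (Gaussian in q at q=0).

    At the highest concentration (c = 1) the forward intensity is suppressed
    by ``amplitude``, reproducing the qualitative low-q suppression of a
    repulsive-interference concentration series; interference is negligible
    in the high-q scaling window.
    """
    return amplitude * np.exp(-((q / width) ** 2))


def make_dilution_series(
    form_factor: ScatteringCurve,
    concentrations: Sequence[float] = (1.0, 0.5),
    beta: np.ndarray | None = None,
    noise_level: float = 0.005,
    seed: int | None = 0,
) -> tuple[DilutionSeries, GroundTruth]:
    """Concentration series under the linear interference model
    I(q, c) = c * P(q) * (1 - beta(q) * c), plus counting noise."""
    if len(concentrations) < 2:
        raise ValueError("need at least two concentrations")
    q = form_factor.q
    beta_arr = default_interference(q) if beta is None else np.asarray(beta, float)
    rng = np.random.default_rng(seed)
    curves = []
    for c in concentrations:
        ideal = form_factor.I * (1.0 - beta_arr * c)
        if np.any(ideal <= 0):
            raise ValueError("interference slope drives intensity negative")
        cur = ScatteringCurve(q, ideal, None, concentration=float(c),
                              label=f"c={c:g}")
        curves.append(noisy_curve(cur, noise_level, rng))
    truth = GroundTruth(
        "dilution_series", seed,
        {"concentrations": list(map(float, concentrations)),
         "noise_level": noise_level, "beta": beta_arr,
         "form_factor_I": form_factor.I, "q": q},
    )
    return DilutionSeries(curves), truth


def make_mixture_dataset(
    component_curves: Mapping[str, ScatteringCurve],
    fractions: Mapping[str, float],
    noise_level: float = 0.02,
    seed: int | None = 0,
    noise_model: str = "relative",
) -> tuple[ScatteringCurve, GroundTruth]:
    """Mix component curves with given volume fractions and add noise.

    ``fractions`` must be non-negative and sum to 1 over the component
    labels; components are combined on the first component's q grid.  The
    default noise model is pointwise relative ("2% Gaussian noise" means
    sigma = 0.02 I at every q).
    """
    labels = list(component_curves)
    f = np.array([fractions.get(lab, 0.0) for lab in labels], dtype=float)
    if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be >= 0 and sum to 1")
    q = component_curves[labels[0]].q
    ideal = np.zeros_like(q)
    for lab, fk in zip(labels, f):
        ideal = ideal + fk * component_curves[lab].interpolated_to(q).I
    rng = np.random.default_rng(seed)
    curve = noisy_curve(
        ScatteringCurve(q, ideal, None, label="synthetic mixture"),
        noise_level, rng, model=noise_model,
    )
    truth = GroundTruth(
        "mixture", seed,
        {"fractions": {k: float(v) for k, v in fractions.items()},
         "noise_level": noise_level, "noise_model": noise_model,
         "labels": labels},
    )
    return curve, truth


def default_q_grid(q_min: float = 0.008, q_max: float = 0.40, n: int = 120) -> np.ndarray:
    return np.linspace(q_min, q_max, n)


def oligomer_component_curves(
    q: np.ndarray | None = None,
    names: Sequence[str] = ("1e", "2e", "4e", "8e", "12e", "16e", "20e", "24e"),
    beads_per_domain: int = 30,
    seed: int = 0,
) -> dict[str, ScatteringCurve]:
    """Debye curves for the scaffolding-lattice oligomer presets.

    A dumbbell monomer is placed at the lattice reference position, expanded
    by each preset's operators, and forward-modelled; curves share one q
    grid.  Labels are the preset names.
    """
    from .scaffold import build_oligomer, reference_monomer

    if q is None:
        q = default_q_grid()
    mono = reference_monomer(beads_per_domain=beads_per_domain, seed=seed)
    out = {}
    for name in names:
        asm = build_oligomer(mono, name, graph="relations", label=name)
        curve = debye_curve(asm.combined(), q)
        curve.label = name
        out[name] = curve
    return out


def free_ligand_curve(
    q: np.ndarray | None = None, i0_fraction_of: ScatteringCurve | None = None,
    i0_fraction: float = 0.02,
) -> ScatteringCurve:
    """Scattering of a free extended hexapeptide (one bead per residue).

    A low-amplitude, smoothly varying curve.  By default its forward
    scattering is set to ``i0_fraction`` of the reference curve's I(0) so the
    component is plausible next to protein curves on the same scale.
    """
    if q is None:
        q = default_q_grid()
    beads = np.outer(np.arange(6), np.array([3.8, 0.0, 0.0]))  # extended chain
    cs = CoordinateSet.from_points(beads, weight=1.0, label="free ligand")
    curve = debye_curve(cs, q)
    if i0_fraction_of is not None:
        s = i0_fraction * float(i0_fraction_of.I[0]) / float(curve.I[0])
        curve = curve.scaled(s)
    curve.label = "ligand"
    return curve


def make_itc_dataset(
    params: BindingParameters,
    protocol: TitrationProtocol | None = None,
    dilution_heat_ucal: float = 0.0,
    noise_fraction: float = 0.02,
    seed: int | None = 0,
) -> tuple[Isotherm, GroundTruth]:
    """Simulated titration plus its ground truth."""
    protocol = protocol or TitrationProtocol()
    iso = simulate_titration(params, protocol, dilution_heat_ucal,
                             noise_fraction, seed)
    truth = GroundTruth(
        "itc", seed,
        {"kd": params.kd, "n": params.n, "dh": params.dh,
         "dilution_heat_ucal": dilution_heat_ucal,
         "noise_fraction": noise_fraction,
         "protocol": asdict(protocol)},
    )
    return iso, truth
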