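"""Reduction of SAXS frame series and concentration series.

Covers the three bookkeeping steps that precede any modelling: merging of
sequential exposure frames with exclusion of radiation-damaged ones (damage
shows as enhanced low-q scattering at the expense of high q), scaling of
curves onto a reference over a high-q window where interparticle interference
is negligible, and point-by-point linear extrapolation of a dilution series
to infinite dilution, which removes the structure-factor modulation
I(q, c) = P(q) (1 - beta(q) c) and recovers the form factor P(q).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .saxs_model import ScatteringCurve

__all__ = [
    "FrameSeries",
    "DilutionSeries",
    "MergeResult",
    "merge_frames",
    "scale_to_reference",
    "extrapolate_to_zero",
    "i0_concentration_ratio",
]

_SIGMA_FLOOR_FRACTION = 1e-6


def _common_grid(curves: list[ScatteringCurve]) -> list[ScatteringCurve]:
    """Interpolate curves onto the coarsest common q grid."""
    qmin = max(c.q[0] for c in curves)
    qmax = min(c.q[-1] for c in curves)
    if qmin >= qmax:
        raise ValueError("curves have no overlapping q range")
    coarsest = min(curves, key=lambda c: ((c.q >= qmin) & (c.q <= qmax)).sum())
    grid = coarsest.q[(coarsest.q >= qmin) & (coarsest.q <= qmax)]
    return [c.interpolated_to(grid) for c in curves]


@dataclass
class FrameSeries:
    """Sequential exposure frames on a common q grid, exposure order preserved."""

    frames: list[ScatteringCurve]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty frame series")
        q0 = self.frames[0].q
        for f in self.frames[1:]:
            if len(f.q) != len(q0) or not np.allclose(f.q, q0):
                raise ValueError("frames must share one q grid")


@dataclass
class DilutionSeries:
    """Curves at >= 2 distinct relative concentrations (highest = 1)."""

    curves: list[ScatteringCurve]

    def __post_init__(self) -> None:
        concs = [c.concentration for c in self.curves]
        if any(c is None for c in concs):
            raise ValueError("every curve needs a concentration / dilution factor")
        if len(set(concs)) < 2:
            raise ValueError("need at least two distinct concentrations")
        self.curves = _common_grid(self.curves)


@dataclass
class MergeResult:
    merged: ScatteringCurve
    kept: list[int]
    excluded: list[int]
    ratios: list[float] = field(repr=False, default_factory=list)


def _damage_ratio(curve: ScatteringCurve) -> float:
    """Mean I over the lowest q decile divided by mean I over the highest."""
    n = len(curve.q)
    k = max(n // 10, 3)
    lo = float(curve.I[:k].mean())
    hi = float(curve.I[-k:].mean())
    if hi <= 0:
        return np.inf
    return lo / hi


def merge_frames(series: FrameSeries, damage_threshold: float = 0.10) -> MergeResult:
    """Damage-aware inverse-variance merge of an exposure series.

    A frame is excluded when its low-q/high-q intensity ratio exceeds the
    first frame's ratio by more than ``damage_threshold`` (relative), the
    operational form of "enhanced scattering at low q at the expense of high
    q".  Survivors are averaged with inverse-variance weights.
    """
    frames = series.frames
    ref = _damage_ratio(frames[0])
    ratios = [_damage_ratio(f) for f in frames]
    kept = [i for i, r in enumerate(ratios) if r <= ref * (1.0 + damage_threshold)]
    excluded = [i for i in range(len(frames)) if i not in kept]
    if not kept:
        raise ValueError(
            "all frames excluded by the damage criterion; review damage_threshold"
        )
    q = frames[0].q
    Is = np.stack([frames[i].I for i in kept])
    if all(frames[i].sigma is not None for i in kept):
        sig = np.stack([frames[i].sigma for i in kept])
        wgt = 1.0 / sig**2
        mean = (wgt * Is).sum(axis=0) / wgt.sum(axis=0)
        sigma = np.sqrt(1.0 / wgt.sum(axis=0))
    else:
        mean = Is.mean(axis=0)
        sigma = Is.std(axis=0, ddof=1) / np.sqrt(len(kept)) if len(kept) > 1 else None
    merged = ScatteringCurve(
        q, mean, sigma, frames[0].concentration,
        f"merge[{len(kept)}/{len(frames)}]",
    )
    return MergeResult(merged, kept, excluded, ratios)


def scale_to_reference(
    curve: ScatteringCurve,
    reference: ScatteringCurve,
    q_range: tuple[float, float] = (0.22, 0.48),
    min_points: int = 10,
) -> tuple[ScatteringCurve, float]:
    """Least-squares scale of ``curve`` onto ``reference`` over a q window.

    Minimizes sum(((s I - I_ref)/sigma)^2) over the window and applies the
    scalar to the whole curve.
    """
    lo, hi = q_range
    mask_c = (curve.q >= lo) & (curve.q <= hi)
    if mask_c.sum() < min_points:
        raise ValueError(
            f"only {int(mask_c.sum())} points overlap the scaling range {q_range}"
        )
    ref = reference.interpolated_to(curve.q[mask_c])
    y = ref.I
    x = curve.I[mask_c]
    if ref.sigma is not None:
        w = 1.0 / ref.sigma**2
    elif curve.sigma is not None:
        w = 1.0 / curve.sigma[mask_c] ** 2
    else:
        w = np.ones_like(y)
    denom = float(w @ (x * x))
    if denom <= 0:
        raise ValueError("degenerate scaling window (zero intensity)")
    s = float(w @ (x * y)) / denom
    return curve.scaled(s, label=f"{curve.label} (x{s:.4g})"), s


def extrapolate_to_zero(
    series: DilutionSeries, weighted: bool = True
) -> ScatteringCurve:
    """Point-by-point linear projection of I(q) versus concentration to c = 0.

    At each q a (sigma-weighted by default) straight line in concentration is
    fitted and its intercept reported; the output is labelled "[0]".  Relative
    dilution factors work in place of absolute concentrations because the
    intercept of a line is invariant under a rescaling of the abscissa.
    """
    curves = series.curves
    q = curves[0].q
    concs = np.array([c.concentration for c in curves], dtype=float)
    Is = np.stack([c.I for c in curves])
    sigs = []
    for c in curves:
        if c.sigma is None or not weighted:
            sigs.append(np.ones_like(c.I))
        else:
            floor = _SIGMA_FLOOR_FRACTION * max(float(np.abs(c.I).max()), 1.0)
            sigs.append(np.maximum(c.sigma, floor))
    sigs = np.stack(sigs)
    w = 1.0 / sigs**2
    # weighted linear fit I = a + b c at each q, vectorized over q
    s0 = w.sum(axis=0)
    s1 = (w * concs[:, None]).sum(axis=0)
    s2 = (w * concs[:, None] ** 2).sum(axis=0)
    t0 = (w * Is).sum(axis=0)
    t1 = (w * concs[:, None] * Is).sum(axis=0)
    det = s0 * s2 - s1**2
    if np.any(det <= 0):
        raise ValueError("degenerate design (identical concentrations?)")
    intercept = (s2 * t0 - s1 * t1) / det
    var_intercept = s2 / det
    return ScatteringCurve(
        q, intercept, np.sqrt(var_intercept), 0.0,
        f"{curves[0].label.split(' ')[0]} [0]",
    )


def i0_concentration_ratio(curve: ScatteringCurve, i0: float) -> float:
    """I(0)/c, the quantity compared against a standard (e.g. BSA) for an
    absolute molecular-weight estimate.  Informative only; no pipeline stage
    depends on absolute scale."""
    if curve.concentration in (None, 0):
        raise ValueError("curve has no concentration")
    return float(i0) / float(curve.concentration)
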