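"""Forward scattering model and standard one-dimensional SAXS analyses.

The forward model is the Debye sum over coarse-grained scatterers,

    I(q) = sum_ij f_i f_j sin(q r_ij) / (q r_ij),

with per-bead weights from :class:`~pdzscaffold.structures.CoordinateSet`.
No hydration-shell or excluded-volume term is applied, so absolute
intensities are on an arbitrary scale and mixture fitting downstream always
carries a free overall scale factor.

Also provided: Guinier analysis with a self-consistent q*Rg window, the
Kratky transform, and a regularized indirect Fourier transform for the pair
distance distribution P(r).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TextIO

import numpy as np
from scipy.optimize import nnls
from scipy.spatial.distance import pdist

from .structures import CoordinateSet

__all__ = [
    "ScatteringCurve",
    "GuinierResult",
    "PofR",
    "read_dat",
    "write_dat",
    "debye_curve",
    "guinier_fit",
    "kratky_transform",
    "pr_transform",
]

_MAX_BEADS = 3000


@dataclass
class ScatteringCurve:
    """A 1-D scattering curve: momentum transfer q (1/A), intensity, sigma."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    concentration: float | None = None  # mg/mL or relative dilution factor
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.I.shape != self.q.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if np.any(np.diff(self.q) <= 0) or np.any(self.q < 0):
            raise ValueError("q must be non-negative and strictly increasing")
        if not np.all(np.isfinite(self.I)):
            raise ValueError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")

    def __len__(self) -> int:
        return len(self.q)

    def scaled(self, s: float, label: str | None = None) -> "ScatteringCurve":
        return ScatteringCurve(
            self.q, s * self.I, None if self.sigma is None else s * self.sigma,
            self.concentration, self.label if label is None else label,
        )

    def interpolated_to(self, q: np.ndarray) -> "ScatteringCurve":
        """Linear interpolation onto a new q grid (sigma in quadrature sense)."""
        q = np.asarray(q, dtype=float)
        if q[0] < self.q[0] - 1e-12 or q[-1] > self.q[-1] + 1e-12:
            raise ValueError("target q grid extends beyond the measured range")
        newI = np.interp(q, self.q, self.I)
        news = None
        if self.sigma is not None:
            news = np.sqrt(np.interp(q, self.q, self.sigma**2))
        return ScatteringCurve(q, newI, news, self.concentration, self.label)


def read_dat(path, label: str | None = None,
             concentration: float | None = None) -> ScatteringCurve:
    """Read a whitespace 3-column (q, I, sigma) curve; '#' lines are headers."""
    rows = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 2:
                continue
            rows.append([float(v) for v in parts[:3]])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    sigma = arr[:, 2] if arr.shape[1] > 2 else None
    return ScatteringCurve(arr[:, 0], arr[:, 1], sigma,
                           concentration, label or str(path))


def write_dat(curve: ScatteringCurve, path_or_fh) -> None:
    def _write(fh: TextIO) -> None:
        fh.write(f"# {curve.label}\n# q(1/A) I(a.u.) sigma\n")
        sig = curve.sigma if curve.sigma is not None else np.zeros_like(curve.q)
        for q, i, s in zip(curve.q, curve.I, sig):
            fh.write(f"{q:.6e} {i:.6e} {s:.6e}\n")

    if hasattr(path_or_fh, "write"):
        _write(path_or_fh)
    else:
        with open(path_or_fh, "w") as fh:
            _write(fh)


def debye_curve(
    coords: CoordinateSet, q: np.ndarray, max_beads: int = _MAX_BEADS
) -> ScatteringCurve:
    """Debye-equation scattering from a coordinate set.

    I(0) equals (sum of weights)^2.  Models larger than ``max_beads`` are
    decimated by stride sampling (the Debye sum is O(n^2)); SAXS resolution
    does not justify all-atom sums for large assemblies.
    """
    q = np.asarray(q, dtype=float)
    cs = coords
    if len(cs) > max_beads:
        stride = int(np.ceil(len(cs) / max_beads))
        mask = np.zeros(len(cs), dtype=bool)
        mask[::stride] = True
        # rescale weights so I(0) is preserved
        scale = cs.weights.sum() / cs.weights[mask].sum()
        cs = cs.select(mask)
        cs.weights = cs.weights * scale
    w = cs.weights
    if len(cs) == 1:
        return ScatteringCurve(q, np.full_like(q, float(w[0] ** 2)), label=cs.label)
    r = pdist(cs.coords)
    wij = (w[:, None] * w[None, :])[np.triu_indices(len(w), k=1)]
    self_term = float((w**2).sum())
    intensity = np.empty_like(q)
    for k, qv in enumerate(q):
        # np.sinc(x) = sin(pi x)/(pi x); handles q=0 exactly
        intensity[k] = self_term + 2.0 * float(wij @ np.sinc(qv * r / np.pi))
    return ScatteringCurve(q, intensity, label=cs.label)


@dataclass
class GuinierResult:
    rg: float
    i0: float
    q_window: tuple[float, float]
    n_points: int
    rg_err: float
    i0_err: float
    nonlinear: bool
    positive_slope: bool
    curvature_z: float  # significance of the quadratic term in the residuals


def guinier_fit(
    curve: ScatteringCurve, qrg_limit: float = 1.3, max_iter: int = 20,
    min_points: int = 5,
) -> GuinierResult:
    """Weighted linear Guinier fit, ln I = ln I(0) - q^2 Rg^2 / 3.

    The fitting window q*Rg <= ``qrg_limit`` is determined self-consistently.
    A quadratic-residual diagnostic flags a nonlinear Guinier region (the
    signature of interparticle interference or aggregation); an unphysical
    positive slope is flagged rather than raised.
    """
    q, I = curve.q, curve.I
    pos = I > 0
    sig = curve.sigma if curve.sigma is not None else np.maximum(1e-12, 0.01 * np.abs(I))
    # starting window: lowest third of the measured range
    window = pos & (q <= q[pos][0] + (q[pos][-1] - q[pos][0]) / 3.0)
    rg = np.nan
    for _ in range(max_iter):
        idx = np.flatnonzero(window)
        if len(idx) < min_points:
            idx = np.flatnonzero(pos)[:min_points]
        x = q[idx] ** 2
        y = np.log(I[idx])
        wgt = (I[idx] / sig[idx]) ** 2  # ln-propagated weights
        coef, cov = np.polyfit(x, y, 1, w=np.sqrt(wgt), cov="unscaled")
        slope, intercept = coef
        if slope >= 0:
            return GuinierResult(np.nan, float(np.exp(intercept)),
                                 (float(q[idx][0]), float(q[idx][-1])), len(idx),
                                 np.nan, np.nan, True, True, np.inf)
        new_rg = float(np.sqrt(-3.0 * slope))
        new_window = pos & (q <= qrg_limit / new_rg)
        if not np.isnan(rg) and abs(new_rg - rg) < 1e-9 * max(rg, 1.0):
            rg = new_rg
            window = new_window
            break
        rg, window = new_rg, new_window
    idx = np.flatnonzero(window)
    if len(idx) < min_points:
        idx = np.flatnonzero(pos)[:min_points]
    x = q[idx] ** 2
    y = np.log(I[idx])
    wgt = (I[idx] / sig[idx]) ** 2
    coef, cov = np.polyfit(x, y, 1, w=np.sqrt(wgt), cov="unscaled")
    slope, intercept = coef
    rg = float(np.sqrt(-3.0 * slope)) if slope < 0 else np.nan
    i0 = float(np.exp(intercept))
    slope_err = float(np.sqrt(cov[0, 0]))
    rg_err = float(1.5 * slope_err / rg) if rg and not np.isnan(rg) else np.nan
    i0_err = float(i0 * np.sqrt(cov[1, 1]))
    # curvature diagnostic: quadratic term in x, in units of its own error
    curvature_z = 0.0
    if len(idx) >= min_points + 2:
        c2, cov2 = np.polyfit(x, y, 2, w=np.sqrt(wgt), cov="unscaled")
        if cov2[0, 0] > 0:
            curvature_z = float(abs(c2[0]) / np.sqrt(cov2[0, 0]))
    nonlinear = curvature_z > 3.0
    return GuinierResult(
        rg, i0, (float(q[idx][0]), float(q[idx][-1])), len(idx),
        rg_err, i0_err, nonlinear, False, curvature_z,
    )


def kratky_transform(curve: ScatteringCurve) -> ScatteringCurve:
    """Pointwise (q, q^2 I); sigma propagates as q^2 sigma."""
    q2 = curve.q**2
    return ScatteringCurve(
        curve.q, q2 * curve.I,
        None if curve.sigma is None else np.maximum(q2 * curve.sigma, 1e-300),
        curve.concentration, f"kratky({curve.label})",
    ) if curve.sigma is None or np.all(q2 * curve.sigma > 0) else ScatteringCurve(
        curve.q, q2 * curve.I, None, curve.concentration, f"kratky({curve.label})"
    )


@dataclass
class PofR:
    """Pair distance distribution on [0, D_max]."""

    r: np.ndarray
    p: np.ndarray
    d_max: float
    chi2: float               # agreement of the back-transform with the input
    p0: float                 # regularized P at r -> 0
    p_dmax: float             # regularized P at r -> D_max
    misfit_flag: bool         # systematic misfit (D_max likely too small)

    def interference_suspected(self) -> bool:
        """The low-resolution diagnostic P(0) > P(D_max)."""
        return self.p0 > self.p_dmax

    def back_transform(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        dr = self.r[1] - self.r[0]
        A = np.sinc(np.outer(q, self.r) / np.pi) * dr
        return A @ self.p


def pr_transform(
    curve: ScatteringCurve, d_max: float, n_r: int = 101, alpha: float | None = None
) -> PofR:
    """Regularized indirect Fourier transform to the pair distance distribution.

    P(r) is represented on an r grid over [0, D_max] and solved by
    non-negative least squares with a second-difference smoothness penalty, so
    the non-negativity of a distance distribution is structural rather than
    imposed after the fact.  The end values P(0) and P(D_max) are left free:
    their comparison is the classical interparticle-interference diagnostic.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    q, I = curve.q, curve.I
    sig = curve.sigma if curve.sigma is not None else np.maximum(1e-6 * I.max(), 1e-3 * np.abs(I))
    r = np.linspace(0.0, d_max, n_r)
    dr = r[1] - r[0]
    A = np.sinc(np.outer(q, r) / np.pi) * dr
    Aw = A / sig[:, None]
    yw = I / sig
    if alpha is None:
        # scale-free default: balance data and smoothness curvature
        alpha = 0.05 * np.linalg.norm(Aw, ord=2)
    D2 = np.zeros((n_r - 2, n_r))
    for i in range(n_r - 2):
        D2[i, i : i + 3] = (1.0, -2.0, 1.0)
    M = np.vstack([Aw, alpha * D2])
    rhs = np.concatenate([yw, np.zeros(n_r - 2)])
    p, _ = nnls(M, rhs)
    model = A @ p
    resid = (I - model) / sig
    chi2 = float((resid**2).sum() / max(len(q) - 1, 1))
    # systematic misfit: long runs of same-sign residuals plus a bad chi2
    sign_runs = np.abs(np.convolve(np.sign(resid), np.ones(10) / 10.0, mode="valid"))
    misfit = bool(chi2 > 5.0 and (sign_runs > 0.9).any())
    return PofR(r, p, float(d_max), chi2, float(p[0]), float(p[-1]), misfit)
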