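"""Relative scaling of wedge data: per-wedge overall scale k and isotropic B.

For each narrow wedge the shell-mean intensities are compared with a
generalized reference curve; under the Wilson model the ratio obeys

    <J_wedge>(s^2) / <J_ref>(s^2) = k * exp(-2 * dB * s^2)

so a weighted linear regression of ln(mean ratio) on s^2 yields ln k and dB.
The reference is built jointly from all wedges as the precision-weighted
average of the scale/B-corrected shell means, and the per-wedge (k, B) are
refit against it until convergence.  The gauge is fixed so that the first
wedge (lowest wedge_index) has B = 0 and the largest scale is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateFitError
from .sim import WedgeDataset

__all__ = ["ShellTable", "WedgeScale", "shell_statistics", "fit_relative_scale_B", "joint_scale_series"]


@dataclass
class ShellTable:
    """Per-resolution-shell statistics of one wedge.

    Shells are equal-width in s^2 (empty shells merged into their lower
    neighbour and flagged).  last shell = highest s^2.
    """

    s2_mid: np.ndarray
    mean_J: np.ndarray
    mean_sigma: np.ndarray
    n_obs: np.ndarray
    edges: np.ndarray
    merged: bool = False
    wedge_index: int = 0
    nominal_dose: float = 0.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.s2_mid) <= 0):
            raise ValueError("shell s^2 midpoints must be increasing")
        if np.any(self.n_obs < 1):
            raise ValueError("every shell must contain at least one reflection")

    @property
    def n_shells(self) -> int:
        return len(self.s2_mid)

    @property
    def last_shell_snr(self) -> float:
        """<J>/<sigma_J> of the highest-resolution shell (inf if noiseless)."""
        ms = self.mean_sigma[-1]
        return float(self.mean_J[-1] / ms) if ms > 0 else float("inf")


def shell_statistics(
    reflections: WedgeDataset, n_shells: int = 10, d_min: float | None = None
) -> ShellTable:
    """Bin reflections into equal-s^2 shells and compute per-shell means.

    `d_min` fixes the upper shell edge at 1/(4 d_min^2) so tables from
    different wedges share a common binning; by default it is taken from the
    dataset (falling back to the data maximum).
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    if len(reflections) == 0:
        raise ValueError("no reflections to bin")
    if d_min is None:
        d_min = reflections.d_min
    s2 = reflections.s2
    s2_max = 1.0 / (4.0 * d_min * d_min) if d_min else float(s2.max()) * (1 + 1e-12)
    edges = np.linspace(0.0, s2_max, n_shells + 1)
    idx = np.clip(np.searchsorted(edges, s2, side="right") - 1, 0, n_shells - 1)

    counts = np.bincount(idx, minlength=n_shells)
    merged = bool(np.any(counts == 0))
    if merged:
        warnings.warn("empty resolution shell(s) merged with lower neighbour", stacklevel=2)
        # reassign each empty bin's (nonexistent) range into the nearest
        # occupied lower bin by collapsing edges
        keep = counts > 0
        # map each original bin to the nearest occupied bin at or below it
        mapping = np.zeros(n_shells, dtype=int)
        last = int(np.argmax(keep))  # first occupied
        for j in range(n_shells):
            if keep[j]:
                last = j
            mapping[j] = last
        idx = mapping[idx]
        occupied = np.unique(mapping)
        remap = {b: i for i, b in enumerate(occupied)}
        idx = np.array([remap[b] for b in idx])
        edges = np.concatenate([[edges[0]], edges[1:][keep]])
        n_shells = len(occupied)
        counts = np.bincount(idx, minlength=n_shells)

    sum_J = np.bincount(idx, weights=reflections.J, minlength=n_shells)
    sum_sig = np.bincount(idx, weights=reflections.sigma_J, minlength=n_shells)
    mean_J = sum_J / counts
    mean_sigma = sum_sig / counts
    # midpoints from actual bin contents keep merged shells meaningful
    sum_s2 = np.bincount(idx, weights=s2, minlength=n_shells)
    s2_mid = sum_s2 / counts
    return ShellTable(
        s2_mid=s2_mid,
        mean_J=mean_J,
        mean_sigma=mean_sigma,
        n_obs=counts,
        edges=edges,
        merged=merged,
        wedge_index=reflections.wedge_index,
        nominal_dose=reflections.nominal_dose,
    )


@dataclass(frozen=True)
class WedgeScale:
    """Relative scale and B-factor of one wedge.

    k is dimensionless (relative to the reference, later normalized so that
    max k = 1); B is in A^2 relative to the first wedge; se_B its standard
    error from the shell regression.
    """

    wedge_index: int
    k: float
    B: float
    se_B: float
    nominal_dose: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("scale k must be > 0")
        if self.se_B < 0:
            raise ValueError("se_B must be >= 0")


def _relative_variances(table: ShellTable) -> np.ndarray:
    """Relative variance of each shell mean under exponential statistics.

    var(mean) ~ (var(J) + <sigma>^2)/n with var(J) = mean^2 for an
    exponential, giving relvar = (1 + (<sigma>/<J>)^2)/n.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(table.mean_J > 0, table.mean_sigma / table.mean_J, 0.0)
    return (1.0 + ratio**2) / table.n_obs


def fit_relative_scale_B(
    wedge: ShellTable, reference: ShellTable, weights: np.ndarray | None = None
) -> WedgeScale:
    """Fit k and dB of a wedge against a reference curve by weighted WLS.

    Regresses y = ln(mean_J_wedge / mean_J_ref) on s^2:
    y = ln k - 2*dB*s^2.  Default weights are the inverse summed relative
    variances of the two shell means (proportional to n_obs over squared
    relative error).  Shells with non-positive means are excluded with a
    warning; fewer than two usable shells is a degenerate fit.
    """
    if wedge.n_shells != reference.n_shells or not np.allclose(
        wedge.s2_mid, reference.s2_mid, rtol=1e-6, atol=1e-12
    ):
        raise ValueError("wedge and reference shell grids are not aligned")
    usable = (wedge.mean_J > 0) & (reference.mean_J > 0)
    if np.any(~usable):
        warnings.warn(
            f"{int(np.sum(~usable))} shell(s) with non-positive mean excluded from log fit",
            stacklevel=2,
        )
    if int(usable.sum()) < 2:
        raise DegenerateFitError("fewer than 2 usable shells for scale/B fit")
    x = wedge.s2_mid[usable]
    y = np.log(wedge.mean_J[usable] / reference.mean_J[usable])
    if weights is None:
        w = 1.0 / (_relative_variances(wedge) + _relative_variances(reference))[usable]
    else:
        w = np.asarray(weights, dtype=float)[usable]

    # weighted normal equations for y = a + b*x with a = ln k, b = -2 dB
    sw = w.sum()
    xm = np.sum(w * x) / sw
    ym = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx <= 0:
        raise DegenerateFitError("no s^2 spread across usable shells")
    b = np.sum(w * (x - xm) * (y - ym)) / sxx
    a = ym - b * xm
    resid = y - (a + b * x)
    dof = max(len(x) - 2, 1)
    chi2_red = float(np.sum(w * resid**2) / dof)
    var_b = max(chi2_red, 1.0) / sxx if len(x) > 2 else 1.0 / sxx
    se_B = 0.5 * np.sqrt(var_b)
    return WedgeScale(
        wedge_index=wedge.wedge_index,
        k=float(np.exp(a)),
        B=float(-0.5 * b),
        se_B=float(se_B),
        nominal_dose=wedge.nominal_dose,
    )


def joint_scale_series(
    wedges: list[ShellTable], max_iter: int = 100, tol: float = 1e-10
) -> list[WedgeScale]:
    """Jointly refine per-wedge (k_i, B_i) against a common reference curve.

    Iterates: (i) reference shell means = precision-weighted average of the
    wedge shell means corrected to the common scale, mean_ij * exp(2*B_i*s^2)
    / k_i; (ii) refit every wedge against the reference.  After convergence
    the gauge is fixed: B is measured relative to the wedge with the lowest
    wedge_index and scales are normalized to max k = 1.  Results do not
    depend on the order of the input list.
    """
    if len(wedges) < 2:
        raise ValueError("need at least 2 wedges for joint scaling")
    n_shells = wedges[0].n_shells
    for t in wedges[1:]:
        if t.n_shells != n_shells or not np.allclose(
            t.s2_mid, wedges[0].s2_mid, rtol=1e-6, atol=1e-12
        ):
            raise ValueError("all wedges must share one shell grid")
    s2 = wedges[0].s2_mid
    mean = np.array([t.mean_J for t in wedges])
    prec = np.array([1.0 / _relative_variances(t) for t in wedges])

    anchor = int(np.argmin([t.wedge_index for t in wedges]))
    k = np.ones(len(wedges))
    B = np.zeros(len(wedges))
    se = np.zeros(len(wedges))
    converged = False
    for _ in range(max_iter):
        corr = np.exp(2.0 * B[:, None] * s2[None, :]) / k[:, None]
        ref_mean = np.sum(prec * mean * corr, axis=0) / np.sum(prec, axis=0)
        ref = ShellTable(
            s2_mid=s2,
            mean_J=ref_mean,
            mean_sigma=np.zeros_like(ref_mean),
            n_obs=np.sum([t.n_obs for t in wedges], axis=0),
            edges=wedges[0].edges,
        )
        B_old = B.copy()
        fits = [fit_relative_scale_B(t, ref) for t in wedges]
        k = np.array([f.k for f in fits])
        B = np.array([f.B for f in fits])
        se = np.array([f.se_B for f in fits])
        # fix the gauge every iteration: the model is invariant under a
        # common shift of B (and rescaling of k) absorbed by the reference
        B = B - B[anchor]
        k = k / k.max()
        if np.max(np.abs(B - B_old)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("joint scaling did not converge; returning last iterate", stacklevel=2)
    return [
        WedgeScale(
            wedge_index=t.wedge_index,
            k=float(k[i]),
            B=float(B[i]),
            se_B=float(se[i]),
            nominal_dose=t.nominal_dose,
            converged=converged,
        )
        for i, t in enumerate(wedges)
    ]
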