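"""Decay-rate estimation: linear fit of B-factor versus absorbed dose.

Under the linear damage model B(D) = B0 + beta*D the per-wedge B-factors
from relative scaling (anchored at B = 0 for the first wedge) fall on a
straight line in the nominal dose; its slope is the decay rate beta in
A^2 MGy^-1.  Multi-position experiments are summarized by the mean and the
population standard deviation (divisor n) of the per-position betas, and a
composition-correction factor converts beta from the nominal dose scale to
the true one: beta_corrected = beta / r, r = true/default dose-rate ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .exceptions import InsufficientDataError
from .scaling import WedgeScale

__all__ = [
    "DecaySeries",
    "DecayResult",
    "SensitivityReport",
    "fit_beta",
    "population_std",
    "summarize_positions",
    "round_report",
]


@dataclass(frozen=True)
class DecaySeries:
    """Per-wedge B-factors (A^2) and scales against nominal dose (MGy)."""

    doses: np.ndarray
    B: np.ndarray
    se_B: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        for name in ("doses", "B", "se_B", "k"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.doses)
        if not (len(self.B) == len(self.se_B) == len(self.k) == n):
            raise ValueError("series columns must have equal length")
        if np.any(np.diff(self.doses) < 0):
            raise ValueError("doses must be non-decreasing")

    @classmethod
    def from_scales(cls, scales: Sequence[WedgeScale]) -> "DecaySeries":
        ordered = sorted(scales, key=lambda s: s.wedge_index)
        return cls(
            doses=np.array([s.nominal_dose for s in ordered]),
            B=np.array([s.B for s in ordered]),
            se_B=np.array([s.se_B for s in ordered]),
            k=np.array([s.k for s in ordered]),
        )


@dataclass(frozen=True)
class DecayResult:
    """Fitted linear decay: B = intercept + beta * D."""

    beta: float
    intercept: float
    se_beta: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.se_beta < 0:
            raise ValueError("se_beta must be >= 0")


def fit_beta(series: DecaySeries, weighted: bool = True) -> DecayResult:
    """(Weighted) least-squares line through the B-versus-dose series.

    Weights are 1/se_B^2 when `weighted` and all standard errors are
    positive, unweighted otherwise.  Requires >= 3 points with non-zero dose
    spread.
    """
    x = series.doses
    y = series.B
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 (dose, B) points")
    if np.ptp(x) == 0:
        raise InsufficientDataError("doses are all equal; slope undefined")
    if weighted and np.all(series.se_B > 0):
        w = 1.0 / series.se_B**2
    else:
        w = np.ones_like(x)
    sw = w.sum()
    xm = np.sum(w * x) / sw
    ym = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xm) ** 2)
    beta = float(np.sum(w * (x - xm) * (y - ym)) / sxx)
    intercept = float(ym - beta * xm)
    resid = y - (intercept + beta * x)
    dof = len(x) - 2
    chi2_red = float(np.sum(w * resid**2) / dof)
    se_beta = float(np.sqrt(chi2_red / sxx))
    ss_tot = float(np.sum(w * (y - ym) ** 2))
    r2 = 1.0 - float(np.sum(w * resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return DecayResult(beta=beta, intercept=intercept, se_beta=se_beta, r_squared=r2)


def population_std(values: Sequence[float]) -> float:
    """Population standard deviation sqrt((1/n) * sum((x - mu)^2))."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("population_std of empty input")
    return float(np.std(v, ddof=0))


def round_report(x: float, decimals: int = 2) -> float:
    """Round half away from zero, as in printed report tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SensitivityReport:
    """Multi-position summary of decay rates for one crystal sample.

    std_is_na flags single-position experiments, where a spread is not
    defined (the population formula gives 0, reported with the flag).
    """

    per_position_betas: tuple[float, ...]
    beta_average: float
    beta_std: float
    beta_corrected: tuple[float, ...]
    correction_factor: float
    std_is_na: bool

    def __post_init__(self) -> None:
        if len(self.per_position_betas) < 1:
            raise ValueError("at least one position required")
        if self.beta_std < 0:
            raise ValueError("beta_std must be >= 0")


def summarize_positions(
    per_position: Sequence[DecayResult | float], correction_factor: float = 1.0
) -> SensitivityReport:
    """Average/spread of per-position betas plus composition correction.

    Accepts DecayResult objects or raw beta values.  beta_corrected divides
    each beta by the dose-rate correction factor (> 1 for compositions more
    absorbing than the default, hence corrected values are smaller).
    """
    betas = tuple(
        float(p.beta) if isinstance(p, DecayResult) else float(p) for p in per_position
    )
    if len(betas) == 0:
        raise InsufficientDataError("no positions to summarize")
    if correction_factor <= 0:
        raise ValueError("correction_factor must be > 0")
    avg = float(np.mean(betas))
    std = population_std(betas)
    return SensitivityReport(
        per_position_betas=betas,
        beta_average=avg,
        beta_std=std,
        beta_corrected=tuple(b / correction_factor for b in betas),
        correction_factor=correction_factor,
        std_is_na=(len(betas) == 1),
    )
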