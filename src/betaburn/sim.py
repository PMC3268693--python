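"""Synthetic diffraction-intensity simulator for burn/collect wedge series.

Emulates the statistical structure the decay analysis relies on: shell mean
intensities following a Wilson curve scale0 * exp(-2*B0*s^2) with acentric
(exponential) intensity statistics, a linear B-factor growth with absorbed
dose — each intensity decays as exp(-2*beta*D*s^2) — optional overall scale
drift, and Poisson-like counting noise with a gain calibrated to a target
last-shell signal-to-noise ratio <J>/<sigma_J>.

Reflections carry synthetic sequential ids and an s^2 = (sin(theta)/lambda)^2
coordinate; no space-group machinery is involved because the analysis uses
resolution-shell means only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .exceptions import CalibrationError

__all__ = [
    "WilsonModel",
    "DamageTruth",
    "NoiseModel",
    "WedgeDataset",
    "simulate_reference",
    "apply_decay",
    "add_noise",
    "simulate_experiment",
    "calibrate_gain",
    "predicted_shell_snr",
]


@dataclass(frozen=True)
class WilsonModel:
    """Zero-dose Wilson intensity curve on a resolution-shell grid.

    B0      overall B-factor at zero dose, A^2
    scale0  shell mean intensity at s^2 = 0 (arbitrary units)
    s2_grid shell midpoints in s^2 = (sin(theta)/lambda)^2, A^-2, increasing
    d_min   high-resolution limit, A (s2_grid spans (0, 1/(4 d_min^2)])
    """

    B0: float
    scale0: float
    s2_grid: tuple[float, ...]
    d_min: float

    def __post_init__(self) -> None:
        if self.B0 < 0:
            raise ValueError("B0 must be >= 0")
        if self.scale0 <= 0:
            raise ValueError("scale0 must be > 0")
        if self.d_min <= 0:
            raise ValueError("d_min must be > 0")
        g = np.asarray(self.s2_grid)
        if g.ndim != 1 or len(g) < 1 or np.any(np.diff(g) <= 0):
            raise ValueError("s2_grid must be strictly increasing")

    @classmethod
    def from_resolution(
        cls, B0: float = 15.0, scale0: float = 1.0, d_min: float = 2.0, n_shells: int = 10
    ) -> "WilsonModel":
        """Equal-width s^2 shells from s^2 = 0 to s_min^2 = 1/(4 d_min^2)."""
        s2_max = 1.0 / (4.0 * d_min * d_min)
        edges = np.linspace(0.0, s2_max, n_shells + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        return cls(B0=B0, scale0=scale0, s2_grid=tuple(mids), d_min=d_min)

    def shell_mean(self, s2) -> np.ndarray:
        """Expected (Wilson) mean intensity at s^2."""
        return self.scale0 * np.exp(-2.0 * self.B0 * np.asarray(s2, dtype=float))


@dataclass(frozen=True)
class DamageTruth:
    """Ground-truth damage parameters for the simulator.

    beta_true    B-factor decay rate, A^2 MGy^-1
    scale_drift  fractional overall scale change per MGy (default none)
    """

    beta_true: float = 1.0
    scale_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.beta_true < 0:
            raise ValueError("beta_true must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Counting-statistics noise: detector counts = gain * intensity.

    Observed J = true J + N(0, (J*gain + background_var)/gain^2); sigma_J is
    the model standard deviation.  gain has units counts per intensity unit,
    background_var counts^2.
    """

    gain: float
    background_var: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.background_var < 0:
            raise ValueError("background_var must be >= 0")


@dataclass
class WedgeDataset:
    """Reflections of one narrow-wedge collection with its nominal dose.

    sigma_J is zero for noiseless (exact) simulation output and positive for
    observed data.  nominal_dose is the cumulative absorbed dose at the wedge
    midpoint, in MGy.
    """

    wedge_index: int
    nominal_dose: float
    ids: np.ndarray
    s2: np.ndarray
    J: np.ndarray
    sigma_J: np.ndarray
    d_min: float | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.s2 = np.asarray(self.s2, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        self.sigma_J = np.asarray(self.sigma_J, dtype=float)
        n = len(self.ids)
        if not (len(self.s2) == len(self.J) == len(self.sigma_J) == n):
            raise ValueError("reflection columns must have equal length")
        if self.nominal_dose < 0:
            raise ValueError("nominal_dose must be >= 0")
        if np.any(~np.isfinite(self.sigma_J)) or np.any(self.sigma_J < 0):
            raise ValueError("sigma_J must be finite and >= 0")
        if np.any(self.s2 < 0):
            raise ValueError("s^2 must be >= 0")
        if self.d_min is not None:
            s2_lim = 1.0 / (4.0 * self.d_min * self.d_min)
            if np.any(self.s2 > s2_lim * (1.0 + 1e-9)):
                raise ValueError("s^2 beyond the stated d_min limit")

    def __len__(self) -> int:
        return len(self.ids)

    def __eq__(self, other) -> bool:
        if not isinstance(other, WedgeDataset):
            return NotImplemented
        return (
            self.wedge_index == other.wedge_index
            and self.nominal_dose == other.nominal_dose
            and self.d_min == other.d_min
            and np.array_equal(self.ids, other.ids)
            and np.array_equal(self.s2, other.s2)
            and np.array_equal(self.J, other.J)
            and np.array_equal(self.sigma_J, other.sigma_J)
        )


def simulate_reference(
    model: WilsonModel, n_per_shell: int, seed: int | np.random.Generator
) -> WedgeDataset:
    """Draw a zero-dose reflection set: exponential intensities per shell.

    Per shell the true intensities are exponential (acentric Wilson
    statistics) with mean scale0 * exp(-2*B0*s^2).  Deterministic for a fixed
    integer seed.
    """
    if n_per_shell < 1:
        raise ValueError("n_per_shell must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    s2 = np.repeat(np.asarray(model.s2_grid, dtype=float), n_per_shell)
    means = model.shell_mean(s2)
    J = rng.exponential(scale=means)
    ids = np.arange(len(s2), dtype=np.int64)
    return WedgeDataset(
        wedge_index=0,
        nominal_dose=0.0,
        ids=ids,
        s2=s2,
        J=J,
        sigma_J=np.zeros_like(J),
        d_min=model.d_min,
    )


def apply_decay(reflections: WedgeDataset, dose: float, truth: DamageTruth) -> WedgeDataset:
    """Attenuate intensities by (1 + drift*D) * exp(-2*beta*D*s^2)."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    factor = (1.0 + truth.scale_drift * dose) * np.exp(
        -2.0 * truth.beta_true * dose * reflections.s2
    )
    return replace(reflections, J=reflections.J * factor, nominal_dose=dose)


def add_noise(
    reflections: WedgeDataset, noise: NoiseModel, seed: int | np.random.Generator
) -> WedgeDataset:
    """Add gaussian counting noise and attach model sigma_J.

    var(J_obs) = (J*gain + background_var) / gain^2, evaluated at the true
    intensity (clipped at zero so variances stay non-negative).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = noise.gain
    var = (np.clip(reflections.J, 0.0, None) * g + noise.background_var) / (g * g)
    sigma = np.sqrt(var)
    J_obs = reflections.J + rng.normal(0.0, 1.0, size=len(reflections)) * sigma
    return replace(reflections, J=J_obs, sigma_J=sigma)


def _mean_sigma_exponential(mean: float, noise: NoiseModel, n_quad: int = 64) -> float:
    """E[sigma_J] over J ~ Exp(mean) by Gauss-Laguerre quadrature."""
    x, w = np.polynomial.laguerre.laggauss(n_quad)
    g = noise.gain
    sig = np.sqrt((mean * x * g + noise.background_var)) / g
    return float(np.sum(w * sig))


def predicted_shell_snr(mean: float, noise: NoiseModel) -> float:
    """Predicted <J>/<sigma_J> for an exponential shell of the given mean.

    With zero background this is (2/sqrt(pi)) * sqrt(gain * mean) in closed
    form; with background the expectation is evaluated by quadrature.
    """
    if mean <= 0:
        return 0.0
    if noise.background_var == 0.0:
        return 2.0 / math.sqrt(math.pi) * math.sqrt(noise.gain * mean)
    return mean / _mean_sigma_exponential(mean, noise)


def calibrate_gain(
    model: WilsonModel,
    noise_target: float = 5.0,
    background_var: float = 0.0,
    max_gain: float = 1e12,
) -> float:
    """Gain giving last-shell <J>/<sigma_J> = noise_target on the first wedge.

    Solves predicted_shell_snr(m_last, gain) = target for the gain; exact in
    closed form for zero background, bisection otherwise.  `max_gain` caps
    the detector dynamic range; targets that would need more raise
    CalibrationError (e.g. overwhelming background).
    """
    if noise_target <= 0:
        raise CalibrationError("noise target must be > 0")
    m_last = float(model.shell_mean(model.s2_grid[-1]))
    if background_var == 0.0:
        gain = math.pi * noise_target**2 / (4.0 * m_last)
        if gain > max_gain:
            raise CalibrationError("noise target beyond the detector dynamic range")
        return gain

    def f(log_g: float) -> float:
        nm = NoiseModel(gain=math.exp(log_g), background_var=background_var)
        return predicted_shell_snr(m_last, nm) - noise_target

    lo, hi = -30.0, math.log(max_gain)
    if f(hi) < 0:
        raise CalibrationError(
            "noise target unreachable within the detector dynamic range: background too high"
        )
    return math.exp(brentq(f, lo, hi, xtol=1e-12))


def simulate_experiment(
    protocol,
    model: WilsonModel,
    truth: DamageTruth,
    noise: NoiseModel | None,
    seed: int,
    n_per_shell: int = 100,
) -> list[WedgeDataset]:
    """Simulate the full burn/collect series: one WedgeDataset per collection.

    The same underlying zero-dose reflection set is decayed to the cumulative
    nominal dose at each collecting-cycle midpoint; fresh counting noise is
    drawn per wedge.  `protocol` is a `betaburn.protocol.Protocol`.
    """
    from .protocol import dose_stamps  # local import to avoid a cycle

    stamps = dose_stamps(protocol)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(stamps) + 1)
    ref = simulate_reference(model, n_per_shell, np.random.default_rng(children[0]))
    wedges: list[WedgeDataset] = []
    for i, d in enumerate(stamps):
        w = apply_decay(ref, float(d), truth)
        if noise is not None:
            w = add_noise(w, noise, np.random.default_rng(children[i + 1]))
        w.wedge_index = i
        wedges.append(w)
    return wedges
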