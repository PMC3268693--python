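"""Burn/collect protocol generation from initial crystal characterization.

The experiment interleaves 11 narrow-wedge data collections with 10 long
"burn" irradiations.  Rules implemented here:

* each collecting cycle deposits at most 0.1 MGy, so the damage incurred
  while measuring is small;
* the first data set targets a last-shell signal-to-noise <J>/<sigma_J> = 5,
  with the resolution limit never finer than d_min = 2.0 A even when the
  crystal would support better (weak crystals get a coarser limit);
* the total absorbed dose is chosen to reduce the last-shell intensity by a
  factor of ~3 under the assumed decay rate (default beta = 1 A^2 MGy^-1):
  D_total = ln(3) / (2 * beta * s_min^2), about 8.8 MGy at 2.0 A and larger
  for coarser resolution limits;
* all cycles (collections and burns) rotate over the same narrow range
  (3-5 degrees, default 4) centred on the characterization angle, keeping
  the illuminated volume constant;
* exposure and attenuator transmission respect the diffractometer limits:
  transmission is maximal subject to the per-frame exposure minimum and
  rotation-speed cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .exceptions import InfeasibleProtocolError
from .sim import NoiseModel, WilsonModel, predicted_shell_snr

__all__ = [
    "CharacterizationInput",
    "CollectionCycle",
    "BurnCycle",
    "Protocol",
    "choose_resolution",
    "total_burn_dose",
    "generate_protocol",
    "dose_stamps",
    "frame_width_and_exposure",
]

N_COLLECTIONS = 11
CYCLE_DOSE_MAX = 0.1   # MGy per collecting cycle
SNR_TARGET = 5.0       # first-set last-shell <J>/<sigma_J>
D_FLOOR = 2.0          # A; never collect finer than this
DEFAULT_ASSUMED_BETA = 1.0  # A^2 MGy^-1
DECAY_FACTOR = 3.0     # target last-shell intensity reduction over the series


@dataclass(frozen=True)
class CharacterizationInput:
    """Everything the generator needs from the initial characterization.

    dose_rate        MGy s^-1 at full transmission
    wilson           zero-dose Wilson estimate (B0, scale0, d_min grid)
    gain_per_mgy     detector counts per intensity unit accumulated per MGy
                     of collecting dose; links dose budget to shell
                     signal-to-noise (beamline + crystal constant estimated
                     from the reference images)
    mosaicity        degrees
    min_exposure_s   shortest exposure per frame the detector allows
    max_rotation_speed  deg s^-1
    transmission_range  usable attenuator range (fractions of full beam)
    center_angle     rotation angle (deg) the wedges are centred on
    rotation_range   total wedge rotation, degrees (3-5 allowed)
    """

    dose_rate: float
    wilson: WilsonModel
    gain_per_mgy: float = 2500.0
    mosaicity: float = 0.5
    min_exposure_s: float = 0.02
    max_rotation_speed: float = 10.0
    transmission_range: tuple[float, float] = (1e-3, 1.0)
    center_angle: float = 0.0
    rotation_range: float = 4.0
    assumed_beta: float = DEFAULT_ASSUMED_BETA
    background_var: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_rate <= 0:
            raise ValueError("dose_rate must be > 0")
        if self.gain_per_mgy <= 0:
            raise ValueError("gain_per_mgy must be > 0")
        if self.min_exposure_s <= 0 or self.max_rotation_speed <= 0:
            raise ValueError("diffractometer limits must be positive")
        lo, hi = self.transmission_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("transmission_range must satisfy 0 < lo <= hi <= 1")
        if not 3.0 <= self.rotation_range <= 5.0:
            raise ValueError("rotation_range must be within [3, 5] degrees")
        if self.mosaicity < 0:
            raise ValueError("mosaicity must be >= 0")
        if self.assumed_beta <= 0:
            raise ValueError("assumed_beta must be > 0")


@dataclass(frozen=True)
class CollectionCycle:
    kind: str
    start_angle: float
    total_rotation: float
    frame_width: float
    exposure_per_frame: float
    transmission: float
    d_min: float
    planned_dose: float

    def __post_init__(self) -> None:
        if not 3.0 <= self.total_rotation <= 5.0:
            raise ValueError("collection rotation must be within [3, 5] degrees")
        if self.planned_dose > CYCLE_DOSE_MAX * (1 + 1e-9):
            raise ValueError("collecting-cycle dose must not exceed 0.1 MGy")
        n = self.total_rotation / self.frame_width
        if abs(n - round(n)) > 1e-6:
            raise ValueError("frame_width must divide total_rotation")


@dataclass(frozen=True)
class BurnCycle:
    kind: str
    start_angle: float
    total_rotation: float
    exposure: float
    transmission: float
    planned_dose: float


@dataclass(frozen=True)
class Protocol:
    """Ordered burn/collect sequence: 11 collections interleaved by 10 burns."""

    cycles: tuple[CollectionCycle | BurnCycle, ...]
    assumed_beta: float
    d_min: float
    dose_rate: float

    def __post_init__(self) -> None:
        kinds = [c.kind for c in self.cycles]
        expected = ["collect" if i % 2 == 0 else "burn" for i in range(2 * N_COLLECTIONS - 1)]
        if kinds != expected:
            raise ValueError("protocol must alternate 11 collections with 10 burns")
        rots = {round(c.total_rotation, 9) for c in self.cycles}
        if len(rots) != 1:
            raise ValueError("all cycles must share the same rotation range")

    @property
    def collections(self) -> list[CollectionCycle]:
        return [c for c in self.cycles if c.kind == "collect"]

    @property
    def burns(self) -> list[BurnCycle]:
        return [c for c in self.cycles if c.kind == "burn"]

    @property
    def total_dose(self) -> float:
        return float(sum(c.planned_dose for c in self.cycles))


def total_burn_dose(d_min: float, assumed_beta: float = DEFAULT_ASSUMED_BETA) -> float:
    """Total dose reducing last-shell intensity by a factor of 3.

    D_total = ln(3) / (2 * beta * s_min^2), s_min = 1/(2*d_min); ~8.8 MGy at
    d_min = 2.0 A and beta = 1, i.e. roughly one-third of the Garman limit.
    """
    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    s2_min = 1.0 / (4.0 * d_min * d_min)
    return math.log(DECAY_FACTOR) / (2.0 * assumed_beta * s2_min)


def choose_resolution(
    wilson: WilsonModel,
    dose_budget: float = CYCLE_DOSE_MAX,
    snr_target: float = SNR_TARGET,
    d_floor: float = D_FLOOR,
    gain_per_mgy: float = 2500.0,
    background_var: float = 0.0,
) -> float:
    """Finest d_min with predicted last-shell <J>/<sigma_J> >= target.

    The predicted signal-to-noise uses the Wilson shell mean and the counting
    noise model with gain = gain_per_mgy * dose_budget.  The result is never
    finer than `d_floor`; crystals too weak to reach the target anywhere
    coarser than 20 A raise InfeasibleProtocolError.
    """
    if snr_target <= 0 or dose_budget <= 0:
        raise ValueError("snr_target and dose_budget must be > 0")
    noise = NoiseModel(gain=gain_per_mgy * dose_budget, background_var=background_var)

    def snr_at(s2: float) -> float:
        return predicted_shell_snr(float(wilson.shell_mean(s2)), noise)

    s2_floor = 1.0 / (4.0 * d_floor * d_floor)
    if snr_at(s2_floor) >= snr_target:
        return d_floor
    s2_lo = 1.0 / (4.0 * 20.0**2)  # 20 A: coarsest limit considered useful
    if snr_at(s2_lo) < snr_target:
        raise InfeasibleProtocolError(
            "predicted last-shell signal-to-noise below target even at 20 A"
        )
    s2_star = brentq(lambda s2: snr_at(s2) - snr_target, s2_lo, s2_floor, xtol=1e-14)
    return 1.0 / (2.0 * math.sqrt(s2_star))


def frame_width_and_exposure(
    char: CharacterizationInput, d_min: float, cycle_dose: float
) -> tuple[float, float, float]:
    """(frame_width deg, exposure per frame s, transmission) for one collection.

    frame_width: largest divisor of the wedge not exceeding the overlap bound
    clip(1.5 - mosaicity, 0.1, 1.0) degrees -- the mosaic spread eats into
    the angular width a frame may cover before reflections overlap, so
    higher mosaicity yields equal or finer slicing.  Transmission is maximal
    subject to the total exposure respecting both the per-frame minimum and
    the rotation-speed cap; below the attenuator minimum the protocol is
    infeasible.
    """
    if cycle_dose <= 0:
        raise ValueError("cycle_dose must be > 0")
    bound = max(0.1, min(1.0, 1.5 - char.mosaicity))
    n_frames = max(1, math.ceil(char.rotation_range / bound - 1e-9))
    frame_width = char.rotation_range / n_frames
    t_min_exposure = n_frames * char.min_exposure_s
    t_min_speed = char.rotation_range / char.max_rotation_speed
    t_floor = max(t_min_exposure, t_min_speed)
    lo, hi = char.transmission_range
    transmission = min(hi, cycle_dose / (char.dose_rate * t_floor))
    if transmission < lo:
        raise InfeasibleProtocolError(
            f"required transmission {transmission:.3g} below attenuator minimum {lo:.3g}"
        )
    exposure_total = cycle_dose / (char.dose_rate * transmission)
    return frame_width, exposure_total / n_frames, transmission


def generate_protocol(char: CharacterizationInput) -> Protocol:
    """Generate the full 11-collection / 10-burn protocol.

    The collecting dose is the full 0.1 MGy budget (the resolution limit is
    chosen so the first set reaches the signal-to-noise target within it);
    the 10 burns share the remaining dose equally so all planned doses sum
    exactly to total_burn_dose(d_min).
    """
    d_min = choose_resolution(
        char.wilson,
        gain_per_mgy=char.gain_per_mgy,
        background_var=char.background_var,
    )
    d_total = total_burn_dose(d_min, char.assumed_beta)
    cycle_dose = CYCLE_DOSE_MAX
    burn_dose = (d_total - N_COLLECTIONS * cycle_dose) / (N_COLLECTIONS - 1)
    if burn_dose <= 0:
        raise InfeasibleProtocolError(
            "collection doses alone exceed the total burn dose; "
            "assumed beta too large for this resolution"
        )
    frame_width, exp_frame, transmission = frame_width_and_exposure(char, d_min, cycle_dose)
    start = char.center_angle - char.rotation_range / 2.0

    cycles: list[CollectionCycle | BurnCycle] = []
    for i in range(N_COLLECTIONS):
        cycles.append(
            CollectionCycle(
                kind="collect",
                start_angle=start,
                total_rotation=char.rotation_range,
                frame_width=frame_width,
                exposure_per_frame=exp_frame,
                transmission=transmission,
                d_min=d_min,
                planned_dose=cycle_dose,
            )
        )
        if i < N_COLLECTIONS - 1:
            cycles.append(
                BurnCycle(
                    kind="burn",
                    start_angle=start,
                    total_rotation=char.rotation_range,
                    exposure=burn_dose / (char.dose_rate * char.transmission_range[1]),
                    transmission=char.transmission_range[1],
                    planned_dose=burn_dose,
                )
            )
    return Protocol(
        cycles=tuple(cycles),
        assumed_beta=char.assumed_beta,
        d_min=d_min,
        dose_rate=char.dose_rate,
    )


def dose_stamps(protocol: Protocol) -> np.ndarray:
    """Cumulative nominal dose (MGy) at the midpoint of each collecting cycle."""
    stamps = []
    acc = 0.0
    for c in protocol.cycles:
        if c.kind == "collect":
            stamps.append(acc + 0.5 * c.planned_dose)
        acc += c.planned_dose
    return np.asarray(stamps)
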