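"""Bath-temperature protocols for imaging and patch-clamp simulations.

Protocol geometry mirrors the recording configurations the analysis expects:

* ``cooling_ramp`` — room-temperature baseline (~24 °C, 50 s), 30 s of cooled
  perfusion reaching ~10 °C in the bath, passive rewarming, and a terminal
  depolarizing High-K+ challenge.
* ``warming_ramp`` — same layout but the ramp heats the bath to 48 °C.
* ``broad_ramp`` — slow descent from 37 °C to 10 °C used for whole-cell
  characterization of channel thermodynamics (no High-K+ epoch).
* ``step_pair`` — warm hold (22 °C), cold hold (12 °C), rewarm, for paired
  fold-activation and drug-block measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TemperatureProtocol", "make_temperature_protocol"]

PROTOCOL_KINDS = ("cooling_ramp", "warming_ramp", "broad_ramp", "step_pair")

ROOM_T = 24.0
COLD_TARGET = 10.0
WARM_TARGET = 48.0
BROAD_START = 37.0
STEP_WARM = 22.0
STEP_COLD = 12.0
RAMP_S = 30.0
BASELINE_S = 50.0
HIGH_K_S = 30.0


@dataclass(frozen=True)
class TemperatureProtocol:
    """Time course of bath temperature with named epoch annotations.

    ``annotations`` maps epoch names (``baseline``, ``ramp``, ``high_k``,
    ``warm``, ``cold``, ``rewarm`` ...) to ``(start_s, end_s)`` intervals.
    """

    times: np.ndarray
    temperatures: np.ndarray
    kind: str
    annotations: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        temp = np.asarray(self.temperatures, dtype=float)
        if t.ndim != 1 or t.size != temp.size:
            raise ValueError("times and temperatures must be 1-D and equal length")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(temp < 0.0) or np.any(temp > 50.0):
            raise ValueError("temperatures must lie within [0, 50] degC")
        spans = sorted(self.annotations.values())
        for (a0, a1) in spans:
            if not (t[0] <= a0 < a1 <= t[-1]):
                raise ValueError("annotated interval outside the time range")
        for (_, a1), (b0, _) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("annotated intervals overlap")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temperatures", temp)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    def temperature_at(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.temperatures)


def _smooth_ramp(t, t0, t1, y0, y1):
    """Piecewise-linear transition from y0 at t0 to y1 at t1."""
    u = np.clip((t - t0) / max(t1 - t0, 1e-12), 0.0, 1.0)
    return y0 + (y1 - y0) * u


def make_temperature_protocol(
    kind: str,
    duration_s: float = 240.0,
    seed: int | None = None,
    sample_hz: float | None = None,
    temp_jitter_sd: float = 0.0,
) -> TemperatureProtocol:
    """Build a named temperature protocol.

    Imaging protocols (``cooling_ramp``/``warming_ramp``) are sampled at 1 Hz
    by default and end with a High-K+ epoch; electrophysiology protocols
    (``broad_ramp``/``step_pair``) default to 5 Hz. ``temp_jitter_sd`` adds
    seeded Gaussian thermistor noise (degC) on top of the deterministic path.
    """
    if kind not in PROTOCOL_KINDS:
        raise ValueError(f"unknown protocol kind {kind!r}; expected one of {PROTOCOL_KINDS}")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")

    imaging = kind in ("cooling_ramp", "warming_ramp")
    if sample_hz is None:
        sample_hz = 1.0 if imaging else 5.0
    t = np.arange(0.0, duration_s + 0.5 / sample_hz, 1.0 / sample_hz)

    ann: dict[str, tuple[float, float]] = {}
    if imaging:
        # baseline 50 s, 30 s ramp, recovery, then High-K ending 10 s before stop
        min_needed = BASELINE_S + RAMP_S + 40.0 + HIGH_K_S + 10.0
        if duration_s < min_needed:
            raise ValueError(
                f"{kind} needs duration_s >= {min_needed:.0f} s to fit baseline, "
                "ramp, recovery and the High-K+ epoch"
            )
        ramp0, ramp1 = BASELINE_S, BASELINE_S + RAMP_S
        hk1 = duration_s - 10.0
        hk0 = hk1 - HIGH_K_S
        target = COLD_TARGET if kind == "cooling_ramp" else WARM_TARGET
        temp = np.full_like(t, ROOM_T)
        temp = np.where(t >= ramp0, _smooth_ramp(t, ramp0, ramp1, ROOM_T, target), temp)
        rec1 = ramp1 + 30.0
        temp = np.where(t >= ramp1, _smooth_ramp(t, ramp1, rec1, target, ROOM_T), temp)
        ann = {"baseline": (0.0, BASELINE_S), "ramp": (ramp0, ramp1), "high_k": (hk0, hk1)}
    elif kind == "broad_ramp":
        hold = min(10.0, 0.05 * duration_s)
        temp = np.where(
            t < hold, BROAD_START, _smooth_ramp(t, hold, duration_s, BROAD_START, COLD_TARGET)
        )
        ann = {"ramp": (hold, duration_s)}
    else:  # step_pair
        third = duration_s / 3.0
        trans = min(5.0, third / 4.0)
        temp = np.full_like(t, STEP_WARM)
        temp = np.where(t >= third, _smooth_ramp(t, third, third + trans, STEP_WARM, STEP_COLD), temp)
        temp = np.where(
            t >= 2 * third, _smooth_ramp(t, 2 * third, 2 * third + trans, STEP_COLD, STEP_WARM), temp
        )
        ann = {
            "warm": (0.0, third),
            "cold": (third + trans, 2 * third),
            "rewarm": (2 * third + trans, duration_s),
        }

    if temp_jitter_sd > 0.0:
        rng = np.random.default_rng(seed)
        temp = temp + rng.normal(0.0, temp_jitter_sd, size=temp.shape)
        temp = np.clip(temp, 0.0, 50.0)

    return TemperatureProtocol(times=t, temperatures=temp, kind=kind, annotations=ann)
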