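"""Synthetic EMG recordings, strides, posture covariates, and timing tables.

Surface-level EMG is emulated as amplitude-modulated band-limited Gaussian
noise: a 30–500 Hz carrier whose local RMS equals the background level
outside bursts and background + gain inside, with 10 ms cosine ramps at burst
edges (the ramp midpoint defines the true onset/offset).  This matches what
the conditioning chain assumes about real signals without modeling motor-unit
biophysics.  Strides, posture/speed covariates with planted linear effects,
and multi-taxon timing tables with controlled phase offsets give every
downstream stage a known ground truth.

All randomness flows from one explicit integer seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ValidationError
from .io import SignalTable, TimingTable
from .strides import StrideEvents

#: Cosine ramp width at burst edges, seconds.
RAMP_S = 0.010


@dataclass
class BurstSchedule:
    """Ground-truth burst plan for one synthetic recording.

    ``bursts`` maps channel label -> list of (onset_s, offset_s, gain µV RMS);
    inside a burst the carrier RMS is ``background_rms + gain``.
    """

    bursts: dict[str, list[tuple[float, float, float]]]
    background_rms: float = 5.0
    carrier_band_hz: tuple[float, float] = (30.0, 500.0)

    def __post_init__(self) -> None:
        if self.background_rms <= 0:
            raise ValidationError("background RMS must be positive")
        for ch, items in self.bursts.items():
            items.sort()
            prev_off = -np.inf
            for on, off, gain in items:
                if off <= on:
                    raise ValidationError(f"{ch}: burst offset {off} <= onset {on}")
                if gain <= 0:
                    raise ValidationError(f"{ch}: burst gain must be positive")
                if on < prev_off:
                    raise ValidationError(f"{ch}: overlapping bursts at {on} s")
                prev_off = off


@dataclass
class GroundTruth:
    """Planted truth stored alongside every simulated dataset."""

    burst_intervals: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    regression_beta: tuple[float, float, float, float] | None = None
    noise_sd: float | None = None
    mid_phases: pd.DataFrame | None = None


def _rms_profile(t: np.ndarray, bursts, background: float) -> np.ndarray:
    prof = np.full(t.size, background)
    half = RAMP_S / 2.0
    for on, off, gain in bursts:
        rise = (t >= on - half) & (t <= on + half)
        fall = (t >= off - half) & (t <= off + half)
        prof[(t > on + half) & (t < off - half)] = background + gain
        prof[rise] = background + gain * 0.5 * (1 - np.cos(np.pi * (t[rise] - (on - half)) / RAMP_S))
        prof[fall] = background + gain * 0.5 * (1 + np.cos(np.pi * (t[fall] - (off - half)) / RAMP_S))
    return prof


def gen_emg_recording(
    schedule: BurstSchedule,
    fs: float = 5000.0,
    duration: float = 8.0,
    seed: int = 0,
) -> tuple[SignalTable, GroundTruth]:
    """Simulate a multichannel EMG recording with known burst times.

    Each channel is independent zero-mean Gaussian noise band-limited to the
    carrier band and scaled to the scheduled RMS profile.  Reproducible given
    the seed.
    """
    lo, hi = schedule.carrier_band_hz
    if fs < 2 * hi:
        raise ValidationError(f"fs {fs} Hz below 2x carrier top {hi} Hz")
    for ch, items in schedule.bursts.items():
        if items and items[-1][1] > duration:
            raise ValidationError(f"{ch}: schedule extends past duration {duration} s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    channels = list(schedule.bursts)
    values = np.empty((n, len(channels)))
    for j, ch in enumerate(channels):
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
        carrier /= carrier.std()
        values[:, j] = carrier * _rms_profile(t, schedule.bursts[ch], schedule.background_rms)
    table = SignalTable(time=t, values=values, channels=channels)
    truth = GroundTruth(
        burst_intervals={ch: [(on, off) for on, off, _ in schedule.bursts[ch]] for ch in channels}
    )
    return table, truth


def stride_burst_schedule(
    channel: str,
    strides: StrideEvents,
    onset_in_stance: float = 0.0,
    offset_in_stance: float = 0.6,
    gain: float = 25.0,
    background_rms: float = 5.0,
) -> BurstSchedule:
    """One burst per stride at fixed positions within stance.

    Convenience for round-trip tests: burst onset/offset are placed at the
    given fractions of each stride's stance phase.
    """
    bursts = []
    for i in range(strides.n_strides):
        td, lo, _ = strides.cycle(i)
        bursts.append(
            (td + onset_in_stance * (lo - td), td + offset_in_stance * (lo - td), gain)
        )
    return BurstSchedule(bursts={channel: bursts}, background_rms=background_rms)


def gen_stride_events(
    n_strides: int,
    stance_s: float = 0.5,
    swing_s: float = 0.2,
    jitter_frac: float = 0.0,
    seed: int = 0,
    start_s: float = 0.0,
) -> StrideEvents:
    """Alternating touchdown/liftoff times with multiplicative duration jitter.

    Default 0.5 s stance / 0.2 s swing gives the study-like ~0.71 stance
    fraction.  Each stride's stance and swing durations are scaled by
    independent ``1 + U(-jitter_frac, jitter_frac)`` factors.
    """
    if n_strides < 1:
        raise ValidationError("need at least one stride")
    if stance_s <= 0 or swing_s <= 0:
        raise ValidationError("stance and swing durations must be positive")
    if not (0 <= jitter_frac < 0.5):
        raise ValidationError("jitter_frac must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    touchdowns = [start_s]
    liftoffs = []
    t = start_s
    for _ in range(n_strides):
        st = stance_s * (1 + rng.uniform(-jitter_frac, jitter_frac))
        sw = swing_s * (1 + rng.uniform(-jitter_frac, jitter_frac))
        liftoffs.append(t + st)
        t += st + sw
        touchdowns.append(t)
    return StrideEvents(touchdowns=np.array(touchdowns), liftoffs=np.array(liftoffs))


def gen_posture_dataset(
    n_steps: int,
    beta: tuple[float, float, float, float] = (100.0, 1.5, 50.0, 0.0),
    angle_range: tuple[float, float] = (-60.0, -20.0),
    speed_range: tuple[float, float] = (0.05, 0.35),
    noise_sd: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-step covariates with a planted linear amplitude model.

    ``amplitude = β0 + βa·(angle − mean) + βv·(speed − mean)
    + βint·(angle − mean)(speed − mean) + ε``, ε ~ N(0, noise_sd²); angle and
    dimensionless speed are uniform on their ranges.  Default ranges mimic a
    sprawling walker: adduction angles (negative, degrees) and slow
    dimensionless speeds.
    """
    if n_steps < 5:
        raise ValidationError("need at least 5 steps")
    rng = np.random.default_rng(seed)
    b0, ba, bv, bint = beta
    angle = rng.uniform(*angle_range, n_steps)
    speed = rng.uniform(*speed_range, n_steps)
    ca = angle - angle.mean()
    cv = speed - speed.mean()
    amp = b0 + ba * ca + bv * cv + bint * ca * cv + rng.normal(0.0, noise_sd, n_steps)
    df = pd.DataFrame(
        {
            "stride_index": np.arange(n_steps),
            "shoulder_adduction_angle": angle,
            "dimensionless_speed": speed,
            "mean_amplitude": amp,
        }
    )
    return df, GroundTruth(regression_beta=beta, noise_sd=noise_sd)


def gen_timing_table(
    taxa: list[str],
    muscles: list[str],
    base_phases: dict[str, float],
    taxon_shifts: dict[str, float],
    burst_halfwidth: float = 0.15,
    stance_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[TimingTable, GroundTruth]:
    """Cross-taxon timing table with controlled phase offsets.

    Each (taxon, muscle) burst runs from ``base + shift - halfwidth`` to
    ``base + shift + halfwidth`` (mod 1), so the true mid phase is exactly
    ``base + shift`` (mod 1).
    """
    if not (0 < burst_halfwidth < 0.5):
        raise ValidationError("burst halfwidth must lie in (0, 0.5)")
    rows = []
    truth_rows = []
    for taxon in taxa:
        shift = taxon_shifts.get(taxon, 0.0)
        for muscle in muscles:
            mid = (base_phases[muscle] + shift) % 1.0
            rows.append(
                {
                    "taxon": taxon,
                    "muscle": muscle,
                    "burst_index": 1,
                    "onset": (mid - burst_halfwidth) % 1.0,
                    "offset": (mid + burst_halfwidth) % 1.0,
                    "stance_fraction": stance_fraction,
                }
            )
            truth_rows.append({"taxon": taxon, "muscle": muscle, "mid_phase": mid})
    table = TimingTable(pd.DataFrame(rows))
    truth = GroundTruth(
        mid_phases=pd.DataFrame(truth_rows).pivot(
            index="taxon", columns="muscle", values="mid_phase"
        )
    )
    return table, truth
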