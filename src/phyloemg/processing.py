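"""Digital conditioning of raw EMG: bandpass, rectification, envelope, downsampling.

The chain mirrors standard fine-wire EMG processing: a 10–500 Hz order-2
Butterworth bandpass removes motion artefact and high-frequency noise, the
signal is full-wave rectified, a 10 Hz order-2 Butterworth lowpass extracts
the envelope, and everything is decimated to 500 Hz.  Filters are applied
zero-phase (forward–backward) by default because burst onset/offset timing is
the payload and causal filters delay it by their group delay; note the
effective filter order doubles under zero-phase application.  A causal mode is
available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .io import RunConfig, SignalTable

#: Reflective padding horizon for zero-phase filtering, in seconds.
EDGE_PAD_S = 1.0


def _sos(kind: str, edges, fs: float, order: int):
    return sps.butter(order, edges, btype=kind, fs=fs, output="sos")


def _apply(sos, x: np.ndarray, fs: float, zero_phase: bool) -> np.ndarray:
    if not zero_phase:
        return sps.sosfilt(sos, x)
    padlen = min(int(round(EDGE_PAD_S * fs)), x.size - 2)
    return sps.sosfiltfilt(sos, x, padtype="odd", padlen=max(padlen, 0))


def butterworth_bandpass(
    x: np.ndarray,
    fs: float,
    low: float,
    high: float,
    order: int = 2,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth bandpass, zero-phase by default. Removes DC."""
    x = np.asarray(x, dtype=float)
    if not (0 < low < high < fs / 2):
        raise ValidationError(
            f"band edges must satisfy 0 < {low} < {high} < Nyquist {fs / 2}"
        )
    return _apply(_sos("bandpass", [low, high], fs, order), x, fs, zero_phase)


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(x, dtype=float))


def lowpass_envelope(
    x: np.ndarray,
    fs: float,
    cutoff: float = 10.0,
    order: int = 2,
    zero_phase: bool = True,
) -> np.ndarray:
    """Lowpass the rectified signal to trace its envelope.

    Filter ringing can undershoot zero on sharp transients; negatives are
    clipped because downstream thresholds assume a nonnegative envelope.
    """
    x = np.asarray(x, dtype=float)
    if not (0 < cutoff < fs / 2):
        raise ValidationError(f"cutoff must satisfy 0 < {cutoff} < Nyquist {fs / 2}")
    return np.clip(_apply(_sos("lowpass", cutoff, fs, order), x, fs, zero_phase), 0.0, None)


def resample_to(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Decimate by keeping every (fs/target_fs)-th sample.

    The preceding lowpass stage is relied on as the anti-alias guard, so no
    additional filtering happens here.  The ratio must be integral.
    """
    x = np.asarray(x)
    ratio = fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValidationError(
            f"sample rate {fs} Hz is not an integer multiple of target {target_fs} Hz"
        )
    return x[:: int(round(ratio))]


@dataclass
class ProcessedChannel:
    """One channel after conditioning, at the target rate.

    ``rectified`` (bandpassed + rectified) feeds amplitude metrics;
    ``envelope`` (additionally lowpassed and clipped) feeds burst detection.
    """

    channel: str
    rectified: np.ndarray
    envelope: np.ndarray
    sample_rate: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rectified.shape != self.envelope.shape:
            raise ValidationError("rectified and envelope series must have equal length")
        if np.any(self.rectified < 0) or np.any(self.envelope < 0):
            raise ValidationError("processed series must be nonnegative")


def process_emg(raw: SignalTable, cfg: RunConfig | None = None) -> dict[str, ProcessedChannel]:
    """Run the full conditioning chain on every channel of a recording.

    Stage order is fixed: bandpass -> rectify -> (branch A: keep rectified,
    resampled, for amplitude metrics; branch B: lowpass -> clip -> resample
    for detection).
    """
    cfg = cfg or RunConfig()
    fs = raw.sample_rate
    cfg.validate_against_signal(fs)
    provenance = {
        "band_hz": (cfg.band_low_hz, cfg.band_high_hz),
        "filter_order": cfg.filter_order,
        "envelope_cutoff_hz": cfg.envelope_cutoff_hz,
        "envelope_order": cfg.envelope_order,
        "input_fs_hz": fs,
        "target_fs_hz": cfg.target_fs_hz,
        "zero_phase": cfg.zero_phase,
    }
    out: dict[str, ProcessedChannel] = {}
    for label in raw.channels:
        x = raw.channel(label)
        bp = butterworth_bandpass(
            x, fs, cfg.band_low_hz, cfg.band_high_hz, cfg.filter_order, cfg.zero_phase
        )
        rect = rectify(bp)
        env = lowpass_envelope(
            rect, fs, cfg.envelope_cutoff_hz, cfg.envelope_order, cfg.zero_phase
        )
        out[label] = ProcessedChannel(
            channel=label,
            rectified=resample_to(rect, fs, cfg.target_fs_hz),
            envelope=resample_to(env, fs, cfg.target_fs_hz),
            sample_rate=cfg.target_fs_hz,
            provenance=dict(provenance),
        )
    return out
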