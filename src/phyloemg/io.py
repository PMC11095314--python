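"""Reading and writing the pipeline's external representations.

Canonical formats are delimited text (CSV with a header) for signals,
burst/timing tables and distance matrices, Newick for trees, YAML for run
configuration, and JSON for the machine-readable run log.  Times are in
seconds, amplitudes in microvolts (µV), and cycle times are dimensionless in
``[0, 1)`` with touchdown at 0.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DegenerateSignalError,
    EmptyInputError,
    FormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Relative tolerance on the uniformity of the sample interval.
TIME_STEP_RTOL = 1e-9

TIMING_COLUMNS = ["taxon", "muscle", "burst_index", "onset", "offset", "stance_fraction"]


@dataclass
class SignalTable:
    """Multichannel raw EMG signal with a uniform time base.

    Parameters
    ----------
    time:
        Sample times in seconds, strictly increasing with a constant step.
    values:
        Matrix of amplitudes in µV, one column per channel.
    channels:
        Ordered channel labels, conventionally ``"MUSCLE_individual_chN"``
        (e.g. ``"PEC_al15_ch2"``).
    """

    time: np.ndarray
    values: np.ndarray
    channels: list[str]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and self.time.size > 1:
            self.values = self.values.reshape(self.time.size, -1)
        if len(self.channels) == 0:
            raise ValidationError("a SignalTable needs at least one channel")
        if self.values.shape != (self.time.size, len(self.channels)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{self.time.size} samples x {len(self.channels)} channels"
            )
        if self.time.size < 2:
            raise ValidationError("need at least two samples to define a sample rate")
        if not np.all(np.isfinite(self.time)) or not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite values are not allowed in a SignalTable")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            k = int(np.argmax(steps <= 0))
            raise FormatError(f"time not strictly increasing at row {k + 2}")
        dt = steps[0]
        bad = np.abs(steps - dt) > TIME_STEP_RTOL * max(abs(dt), 1.0)
        if np.any(bad):
            k = int(np.argmax(bad))
            raise FormatError(
                f"non-uniform time step at row {k + 2}: "
                f"step {steps[k]:.9g} s differs from {dt:.9g} s"
            )

    @property
    def sample_rate(self) -> float:
        """Sampling rate in Hz inferred from the time column."""
        return 1.0 / float(self.time[1] - self.time[0])

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by label."""
        try:
            j = self.channels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None
        return self.values[:, j]


def read_signal_table(path: str | Path, delimiter: str = ",") -> SignalTable:
    """Read a delimited signal file (``time`` column + one column per channel)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, delimiter=delimiter)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    if df.empty:
        raise EmptyInputError(f"{path} contains a header but no samples")
    if "time" not in df.columns:
        raise FormatError(f"{path} has no 'time' column")
    channels = [c for c in df.columns if c != "time"]
    if not channels:
        raise FormatError(f"{path} has no channel columns")
    body = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(body)):
        i, j = np.argwhere(~np.isfinite(body))[0]
        raise FormatError(f"{path}: non-finite cell at row {i + 1}, column {df.columns[j]!r}")
    return SignalTable(time=df["time"].to_numpy(), values=df[channels].to_numpy(), channels=channels)


def write_signal_table(table: SignalTable, path: str | Path, delimiter: str = ",") -> None:
    df = pd.DataFrame(table.values, columns=table.channels)
    df.insert(0, "time", table.time)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.12g")


@dataclass
class TimingTable:
    """Cross-taxon burst timing table on a declared stance-fraction cycle.

    Rows carry (taxon, muscle, burst_index, onset, offset, stance_fraction),
    with onset/offset as cycle times in ``[0, 1)`` (touchdown = 0) and
    ``stance_fraction`` the stance share of the cycle the timings refer to.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in TIMING_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"timing table missing columns: {missing}")
        if df.empty:
            raise EmptyInputError("timing table has no rows")
        df["burst_index"] = df["burst_index"].astype(int)
        if (df["burst_index"] < 1).any():
            raise ValidationError("burst_index must be >= 1")
        df["onset"] = np.mod(df["onset"].astype(float), 1.0)
        df["offset"] = np.mod(df["offset"].astype(float), 1.0)
        if np.any(df["onset"].to_numpy() == df["offset"].to_numpy()):
            bad = df[df["onset"] == df["offset"]].iloc[0]
            raise DegenerateSignalError(
                f"degenerate burst (onset == offset) for {bad['taxon']}/{bad['muscle']}"
            )
        sf = df["stance_fraction"].astype(float)
        if sf.isna().any():
            raise FormatError("stance_fraction missing for some rows")
        if ((sf <= 0) | (sf >= 1)).any():
            raise ValidationError("stance_fraction must lie in (0, 1)")
        df["stance_fraction"] = sf
        key = df[["taxon", "muscle", "burst_index"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate (taxon, muscle, burst_index) = "
                f"({dup['taxon']}, {dup['muscle']}, {dup['burst_index']})"
            )
        self.data = df.reset_index(drop=True)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.data["taxon"].unique())

    @property
    def muscles(self) -> list[str]:
        return sorted(self.data["muscle"].unique())


def read_timing_table(path: str | Path) -> TimingTable:
    """Read a cross-taxon burst timing CSV.

    ``onset``/``offset`` outside ``[0, 1)`` are reduced mod 1 on load.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    return TimingTable(df)


def write_timing_table(table: TimingTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, float_format="%.12g")


@dataclass
class RunConfig:
    """All tunable settings of the pipeline, with study defaults.

    Defaults follow the published conditioning chain: 10–500 Hz order-2
    Butterworth bandpass, 10 Hz order-2 lowpass envelope, downsampling to
    500 Hz, 50 equally spaced thresholds over the observed signal range, and
    a 0.71 stance fraction for cycle normalization.
    """

    band_low_hz: float = 10.0
    band_high_hz: float = 500.0
    filter_order: int = 2
    envelope_cutoff_hz: float = 10.0
    envelope_order: int = 2
    target_fs_hz: float = 500.0
    n_thresholds: int = 50
    n_permutations: int = 10
    seed: int = 0
    stance_fraction: float = 0.71
    min_burst_duration_s: float = 0.03
    max_merge_gap_s: float = 0.05
    min_shared_muscles: int = 3
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValidationError(
                f"bandpass edges must satisfy 0 < low < high, got "
                f"{self.band_low_hz}-{self.band_high_hz} Hz"
            )
        if self.n_thresholds < 2:
            raise ValidationError("n_thresholds must be >= 2")
        if not (0 < self.stance_fraction < 1):
            raise ValidationError("stance_fraction must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.min_burst_duration_s < 0 or self.max_merge_gap_s < 0:
            raise ValidationError("durations and gaps must be nonnegative")

    def validate_against_signal(self, fs: float) -> None:
        """Check band edges against the Nyquist frequency of an input signal."""
        if self.band_high_hz >= fs / 2:
            raise ValidationError(
                f"bandpass high edge {self.band_high_hz} Hz is not below "
                f"Nyquist ({fs / 2} Hz) of a {fs} Hz signal"
            )


def read_config(path: str | Path | None) -> RunConfig:
    """Read a YAML run configuration; absent keys fall back to study defaults.

    Unknown keys emit a warning (and a log entry) but do not fail the run.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a key-value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        msg = f"ignoring unknown config keys: {unknown}"
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)
    return RunConfig(**{k: v for k, v in raw.items() if k in known})


def write_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labelled symmetric distance matrix CSV."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column labels differ")
    return df


def write_distance_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, float_format="%.12g")


def write_run_log(
    out_dir: str | Path,
    cfg: RunConfig,
    seed: int,
    command: str,
    outputs: dict[str, str] | None = None,
) -> Path:
    """Write the machine-readable run log (JSON) that makes a run repeatable."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = {
        "command": command,
        "seed": int(seed),
        "config": dataclasses.asdict(cfg),
        "outputs": outputs or {},
    }
    path = out_dir / "run_log.json"
    path.write_text(json.dumps(log, indent=2) + "\n")
    return path
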