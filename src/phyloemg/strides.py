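"""Stride-cycle normalization, timing summaries, and posture/speed regressions.

Event times are re-expressed as relative stride time in ``[0, 1)``: stance
maps linearly onto ``[0, sf)`` and swing onto ``[sf, 1)``, with the stance
fraction ``sf`` fixed at the study-wide mean (0.71 stance / 0.29 swing by
default) rather than each stride's own ratio, so strides of different
absolute duration become comparable.  Regressions of burst amplitude (or
normalized duration) on shoulder adduction angle and dimensionless speed use
mean-centered predictors and their interaction, fitted per channel by
ordinary least squares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .detection import BurstInterval
from .errors import ValidationError

logger = logging.getLogger(__name__)

GRAVITY = 9.81  # m/s^2


@dataclass
class StrideEvents:
    """Alternating touchdown/liftoff times delimiting strides.

    ``touchdowns`` has one more entry than ``liftoffs``: the final touchdown
    closes the last cycle.  Cycle ``i`` is ``[touchdowns[i], touchdowns[i+1])``
    with stance ending at ``liftoffs[i]``.
    """

    touchdowns: np.ndarray
    liftoffs: np.ndarray

    def __post_init__(self) -> None:
        self.touchdowns = np.asarray(self.touchdowns, dtype=float)
        self.liftoffs = np.asarray(self.liftoffs, dtype=float)
        if self.touchdowns.size != self.liftoffs.size + 1:
            raise ValidationError(
                "need n+1 touchdowns for n liftoffs "
                f"(got {self.touchdowns.size} and {self.liftoffs.size})"
            )
        if self.liftoffs.size == 0:
            raise ValidationError("need at least one complete stride")
        events = np.empty(self.touchdowns.size + self.liftoffs.size)
        events[0::2] = self.touchdowns
        events[1::2] = self.liftoffs
        if np.any(np.diff(events) <= 0):
            raise ValidationError(
                "events must strictly alternate touchdown < liftoff < next touchdown"
            )

    @property
    def n_strides(self) -> int:
        return int(self.liftoffs.size)

    def cycle(self, i: int) -> tuple[float, float, float]:
        """(touchdown, liftoff, next touchdown) of stride ``i``."""
        return (
            float(self.touchdowns[i]),
            float(self.liftoffs[i]),
            float(self.touchdowns[i + 1]),
        )

    def stance_fractions(self) -> np.ndarray:
        stance = self.liftoffs - self.touchdowns[:-1]
        total = np.diff(self.touchdowns)
        return stance / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stride_index": np.arange(self.n_strides),
                "touchdown_s": self.touchdowns[:-1],
                "liftoff_s": self.liftoffs,
                "next_touchdown_s": self.touchdowns[1:],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StrideEvents":
        td = np.append(df["touchdown_s"].to_numpy(), df["next_touchdown_s"].iloc[-1])
        return cls(touchdowns=td, liftoffs=df["liftoff_s"].to_numpy())


def normalize_event_time(
    t: float, cycle: tuple[float, float, float], stance_fraction: float
) -> float:
    """Map an event time inside one cycle to relative stride time in [0, 1).

    Stance ``[touchdown, liftoff)`` maps linearly onto ``[0, sf)`` and swing
    ``[liftoff, next touchdown)`` onto ``[sf, 1)``.
    """
    td, lo, nxt = cycle
    if not (0 < stance_fraction < 1):
        raise ValidationError("stance_fraction must lie in (0, 1)")
    if not (td <= t < nxt):
        raise ValidationError(f"time {t} outside cycle [{td}, {nxt})")
    if t < lo:
        return stance_fraction * (t - td) / (lo - td)
    return stance_fraction + (1 - stance_fraction) * (t - lo) / (nxt - lo)


def _cycle_phase(t: float, strides: StrideEvents, stance_fraction: float) -> float:
    """Unwrapped phase: stride index plus within-cycle relative time.

    Times up to one cycle before the first touchdown or after the last are
    handled by extending the first/last cycle's timing pattern, so bursts
    whose onset precedes the first recorded touchdown still normalize.
    """
    td = strides.touchdowns
    n = strides.n_strides
    if t < td[0]:
        d_st = strides.liftoffs[0] - td[0]
        d_cy = td[1] - td[0]
        virtual = (td[0] - d_cy, td[0] - d_cy + d_st, td[0])
        if t < virtual[0]:
            raise ValidationError(f"time {t} more than one cycle before the first touchdown")
        return normalize_event_time(t, virtual, stance_fraction) - 1.0
    if t >= td[-1]:
        d_st = strides.liftoffs[-1] - td[-2]
        d_cy = td[-1] - td[-2]
        virtual = (td[-1], td[-1] + d_st, td[-1] + d_cy)
        if t >= virtual[2]:
            raise ValidationError(f"time {t} more than one cycle after the last touchdown")
        return n + normalize_event_time(t, virtual, stance_fraction)
    i = int(np.searchsorted(td, t, side="right")) - 1
    i = min(i, n - 1)
    return i + normalize_event_time(t, strides.cycle(i), stance_fraction)


def normalize_bursts(
    bursts: list[BurstInterval],
    strides: StrideEvents,
    stance_fraction: float = 0.71,
) -> list[BurstInterval]:
    """Express burst onset/offset in stride-cycle time.

    Each burst is assigned to the stride containing its midpoint; onset and
    offset are normalized within that stride's cycle and reduced mod 1, so a
    late-swing onset belonging to the previous cycle appears as a value near
    1.  ``normalized duration = (offset_cycle - onset_cycle) mod 1``.  Bursts
    spanning more than two cycles, or falling outside the recorded strides,
    are excluded with a log entry.
    """
    if strides.n_strides == 0:
        raise ValidationError("empty stride list")
    td = strides.touchdowns
    out: list[BurstInterval] = []
    for b in bursts:
        inside = np.count_nonzero((td > b.onset_s) & (td < b.offset_s))
        if inside >= 2:
            logger.warning(
                "burst %s [%.3f, %.3f] s spans more than two cycles; excluded",
                b.channel, b.onset_s, b.offset_s,
            )
            continue
        mid = 0.5 * (b.onset_s + b.offset_s)
        if not (td[0] <= mid < td[-1]):
            logger.warning(
                "burst %s midpoint %.3f s outside recorded strides; excluded",
                b.channel, mid,
            )
            continue
        try:
            phi_on = _cycle_phase(b.onset_s, strides, stance_fraction)
            phi_off = _cycle_phase(b.offset_s, strides, stance_fraction)
        except ValidationError as exc:
            logger.warning("burst %s excluded: %s", b.channel, exc)
            continue
        i = int(np.searchsorted(td, mid, side="right")) - 1
        out.append(
            BurstInterval(
                channel=b.channel,
                onset_s=b.onset_s,
                offset_s=b.offset_s,
                mean_amplitude=b.mean_amplitude,
                stride_index=i,
                onset_cycle=phi_on % 1.0,
                offset_cycle=phi_off % 1.0,
            )
        )
    return out


def normalized_duration(b: BurstInterval) -> float:
    """(offset_cycle - onset_cycle) mod 1 for a normalized burst."""
    if b.onset_cycle is None or b.offset_cycle is None:
        raise ValidationError("burst has not been normalized to a stride cycle")
    return (b.offset_cycle - b.onset_cycle) % 1.0


def _circular_mean(values: np.ndarray) -> float:
    ang = 2 * np.pi * values
    m = math.atan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi)
    m %= 1.0
    return 0.0 if m >= 1.0 else m  # -eps % 1 rounds up to exactly 1.0


def aggregate_timings(
    bursts: pd.DataFrame,
    by: tuple[str, ...] = ("muscle", "burst_index"),
    circular: bool = False,
) -> pd.DataFrame:
    """Mean ± SE of onset/offset cycle times per muscle (and burst index).

    Expects a table with columns ``onset_cycle``, ``offset_cycle`` plus the
    grouping columns and, optionally, ``channel`` / ``animal`` whose distinct
    counts are reported alongside.  Strides are the unit of replication;
    SE = sd/sqrt(n), reported as NaN for single observations.  With
    ``circular=True`` the mean is the direction of the 2π-wrapped values,
    re-expressed in [0, 1).
    """
    rows = []
    for key, grp in bursts.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        row["n_strides"] = len(grp)
        for extra in ("channel", "animal"):
            if extra in grp.columns:
                row[f"n_{extra}s"] = grp[extra].nunique()
        for col, name in (("onset_cycle", "onset"), ("offset_cycle", "offset")):
            v = grp[col].to_numpy(dtype=float)
            row[f"{name}_mean"] = _circular_mean(v) if circular else float(v.mean())
            row[f"{name}_se"] = (
                float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def dimensionless_speed(v: float, h: float, g: float = GRAVITY) -> float:
    """Froude-type speed normalization: v / sqrt(g * h).

    ``h`` is the extended hindlimb length (hip to ankle) in meters.
    """
    if h <= 0:
        raise ValidationError("hindlimb length must be positive")
    if v < 0:
        raise ValidationError("speed must be nonnegative")
    return v / math.sqrt(g * h)


@dataclass
class RegressionResult:
    """OLS fit of a burst response on centered posture/speed predictors."""

    n: int
    response: str
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    r_squared: float

    def to_frame(self) -> pd.DataFrame:
        terms = list(self.coefficients)
        return pd.DataFrame(
            {
                "term": terms,
                "coef": [self.coefficients[t] for t in terms],
                "se": [self.standard_errors[t] for t in terms],
                "p": [self.p_values[t] for t in terms],
            }
        )


TERMS = ("intercept", "angle", "speed", "interaction")


def fit_posture_model(
    steps: pd.DataFrame,
    response: str = "mean_amplitude",
    angle_col: str = "shoulder_adduction_angle",
    speed_col: str = "dimensionless_speed",
) -> RegressionResult:
    """OLS of a burst response on centered angle, centered speed, and their product.

    Predictors are centered around their sample means (reducing collinearity
    with the interaction term); two-sided t-test p-values are reported per
    coefficient.  Fit one channel at a time — pooling across electrodes is
    deliberately unsupported because amplitudes are not comparable across
    electrode placements.
    """
    n = len(steps)
    if n < 5:
        raise ValidationError(f"need at least 5 steps to fit, got {n}")
    for col in (response, angle_col, speed_col):
        if col not in steps.columns:
            raise ValidationError(f"steps table lacks column {col!r}")
    y = steps[response].to_numpy(dtype=float)
    ca = steps[angle_col].to_numpy(dtype=float)
    cv = steps[speed_col].to_numpy(dtype=float)
    if np.ptp(ca) == 0 or np.ptp(cv) == 0:
        raise ValidationError("predictors must vary across steps")
    ca = ca - ca.mean()
    cv = cv - cv.mean()
    X = np.column_stack([np.ones(n), ca, cv, ca * cv])
    if np.linalg.cond(X) > 1e8:
        raise ValidationError("predictors are collinear (condition number > 1e8)")
    if np.ptp(y) == 0:
        # degenerate response: slopes are exactly 0 and carry no evidence
        return RegressionResult(
            n=n,
            response=response,
            coefficients=dict(zip(TERMS, [float(y[0]), 0.0, 0.0, 0.0])),
            standard_errors=dict(zip(TERMS, [0.0] * 4)),
            p_values=dict(zip(TERMS, [0.0, 1.0, 1.0, 1.0])),
            r_squared=0.0,
        )
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        n=n,
        response=response,
        coefficients=dict(zip(TERMS, fit.params)),
        standard_errors=dict(zip(TERMS, fit.bse)),
        p_values=dict(zip(TERMS, fit.pvalues)),
        r_squared=float(fit.rsquared),
    )
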