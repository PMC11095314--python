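"""Cross-taxon comparison of muscle activation phases.

Burst timings from different species are first re-expressed on a common
0.5 stance / 0.5 swing cycle, cleaned by declarative burst rules (grouping a
split burst, dropping a short secondary burst), and summarized by their mid
burst phase — the circular (mod 1) midpoint of onset and offset.  Pairwise
taxon dissimilarity per muscle is the wrapped distance between mid phases,
doubled onto a 0–1 scale, and the overall taxon × taxon matrix is the maximum
observable rescaled distance (MORD): the Euclidean distance over the muscles
a pair shares, divided by the maximum realizable distance given that many
shared muscles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateSignalError, ValidationError
from .io import TimingTable

logger = logging.getLogger(__name__)


def renormalize_cycle(
    onset: float, offset: float, sf_in: float, sf_out: float = 0.5
) -> tuple[float, float]:
    """Remap cycle times from one stance fraction to another.

    Each endpoint ``u`` maps piecewise-linearly: stance ``[0, sf_in)`` onto
    ``[0, sf_out)`` and swing ``[sf_in, 1)`` onto ``[sf_out, 1)``.
    """
    if not (0 < sf_in < 1 and 0 < sf_out < 1):
        raise ValidationError("stance fractions must lie in (0, 1)")

    def remap(u: float) -> float:
        u = u % 1.0
        if u < sf_in:
            return u * sf_out / sf_in
        return sf_out + (u - sf_in) * (1 - sf_out) / (1 - sf_in)

    return remap(onset), remap(offset)


def mid_phase(onset: float, offset: float) -> float:
    """Circular midpoint of a burst on the normalized cycle (mod 1).

    ``onset + (offset - onset)/2``; when the burst wraps touchdown
    (offset < onset) the offset is advanced by a full cycle first, so e.g.
    a burst from 0.8 to 0.4 has mid phase 0.1.
    """
    onset, offset = onset % 1.0, offset % 1.0
    if onset == offset:
        raise DegenerateSignalError("zero-extent burst has no mid phase")
    if offset < onset:
        offset += 1.0
    return (onset + (offset - onset) / 2.0) % 1.0


def phase_distance(p: float, q: float) -> float:
    """Doubled wrapped distance between two cycle phases, on a 0–1 scale.

    ``2 * min(|p - q|, 1 - |p - q|)``: antiphase (half a cycle apart) scores
    the maximum 1.
    """
    d = abs(p % 1.0 - q % 1.0)
    return 2.0 * min(d, 1.0 - d)


@dataclass
class BurstRule:
    """One declarative cleaning action for a (taxon, muscle) pair."""

    taxon: str
    muscle: str
    action: str  # "group" | "drop_secondary"

    def __post_init__(self) -> None:
        if self.action not in ("group", "drop_secondary"):
            raise ValidationError(f"unknown burst-rule action {self.action!r}")


def load_burst_rules(path=None) -> list[BurstRule]:
    """Load burst rules from YAML; without a path, the packaged defaults.

    The shipped defaults encode the cross-taxon cleaning used for the
    sauropsid comparison: group the split scapular-triceps burst in
    *Trachemys*, and drop the short secondary supracoracoideus bursts in
    *Alligator* and *Varanus* and the secondary biceps burst in *Sturnus*.
    """
    if path is None:
        text = resources.files("phyloemg.data").joinpath("default_burst_rules.yaml").read_text()
    else:
        from pathlib import Path

        text = Path(path).read_text()
    raw = yaml.safe_load(text) or []
    return [BurstRule(**r) for r in raw]


def apply_burst_rules(table: TimingTable, rules: list[BurstRule]) -> TimingTable:
    """Apply grouping/removal rules to a timing table.

    ``group`` replaces bursts 1 and 2 of the named muscle by a single burst
    spanning from the first onset to the second offset (mod 1);
    ``drop_secondary`` keeps burst 1 only.  A rule naming an absent entry is
    an error listing the offender.
    """
    df = table.data.copy()
    for rule in rules:
        mask = (df["taxon"] == rule.taxon) & (df["muscle"] == rule.muscle)
        sub = df[mask]
        if sub.empty:
            raise ValidationError(
                f"burst rule references absent entry ({rule.taxon}, {rule.muscle})"
            )
        if rule.action == "drop_secondary":
            df = df[~(mask & (df["burst_index"] > 1))]
        else:  # group
            if not {1, 2}.issubset(set(sub["burst_index"])):
                raise ValidationError(
                    f"group rule needs bursts 1 and 2 for ({rule.taxon}, {rule.muscle})"
                )
            first = sub[sub["burst_index"] == 1].iloc[0]
            second = sub[sub["burst_index"] == 2].iloc[0]
            df = df[~mask]
            merged = first.copy()
            merged["offset"] = second["offset"]
            df = pd.concat([df, merged.to_frame().T], ignore_index=True)
    df = df.sort_values(["taxon", "muscle", "burst_index"]).reset_index(drop=True)
    return TimingTable(df)


def mid_phase_table(table: TimingTable, sf_out: float = 0.5) -> pd.DataFrame:
    """Taxon × muscle table of mid burst phases on the ``sf_out`` cycle.

    Each row's onset/offset is renormalized from its declared stance fraction
    before the circular midpoint is taken.  Expects one burst per
    (taxon, muscle) — apply burst rules first; multiple remaining bursts are
    an error.  Missing (taxon, muscle) combinations come out as NaN.
    """
    df = table.data
    dup = df.duplicated(subset=["taxon", "muscle"], keep=False)
    if dup.any():
        offender = df[dup].iloc[0]
        raise ValidationError(
            "multiple bursts remain for "
            f"({offender['taxon']}, {offender['muscle']}); apply burst rules first"
        )
    records = []
    for _, row in df.iterrows():
        on, off = renormalize_cycle(row["onset"], row["offset"], row["stance_fraction"], sf_out)
        records.append((row["taxon"], row["muscle"], mid_phase(on, off)))
    out = pd.DataFrame(records, columns=["taxon", "muscle", "mid_phase"])
    return out.pivot(index="taxon", columns="muscle", values="mid_phase")


@dataclass
class MordResult:
    """Taxon × taxon MORD matrix with per-muscle layers and shared counts."""

    overall: pd.DataFrame
    per_muscle: dict[str, pd.DataFrame]
    shared_counts: pd.DataFrame
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)

    def drop_excluded_taxa(self) -> pd.DataFrame:
        """Largest complete submatrix: greedily drop the taxa causing exclusions."""
        m = self.overall.copy()
        while m.isna().any().any():
            worst = m.isna().sum().idxmax()
            m = m.drop(index=worst, columns=worst)
        return m


def mord_matrix(midphases: pd.DataFrame, min_shared: int = 3) -> MordResult:
    """Maximum observable rescaled distance between all taxon pairs.

    For a pair sharing ``m`` muscles with doubled wrapped per-muscle phase
    distances ``d_i``, MORD = sqrt(sum d_i^2) / sqrt(m): the denominator is
    the Euclidean distance attained when every shared muscle is at the
    antiphase maximum (d_i = 1), so values live on a strict 0–1 scale.
    Pairs sharing fewer than ``min_shared`` muscles are excluded (NaN) with a
    log entry; shared-muscle counts are reported per pair.
    """
    taxa = list(midphases.index)
    if len(taxa) < 2:
        raise ValidationError("need at least 2 taxa")
    n = len(taxa)
    overall = pd.DataFrame(np.zeros((n, n)), index=taxa, columns=taxa)
    shared = pd.DataFrame(np.zeros((n, n), dtype=int), index=taxa, columns=taxa)
    per_muscle = {
        m: pd.DataFrame(np.full((n, n), np.nan), index=taxa, columns=taxa)
        for m in midphases.columns
    }
    for m in midphases.columns:
        np.fill_diagonal(per_muscle[m].values, 0.0)
    excluded = []
    for i, a in enumerate(taxa):
        shared.iloc[i, i] = int(midphases.loc[a].notna().sum())
        for j in range(i + 1, n):
            b = taxa[j]
            both = midphases.loc[a].notna() & midphases.loc[b].notna()
            muscles = list(midphases.columns[both])
            shared.loc[a, b] = shared.loc[b, a] = len(muscles)
            d = np.array(
                [phase_distance(midphases.loc[a, m], midphases.loc[b, m]) for m in muscles]
            )
            for m, dm in zip(muscles, d):
                per_muscle[m].loc[a, b] = per_muscle[m].loc[b, a] = dm
            if len(muscles) < min_shared:
                overall.loc[a, b] = overall.loc[b, a] = np.nan
                excluded.append((a, b))
                logger.info(
                    "pair (%s, %s) excluded: %d shared muscles < %d",
                    a, b, len(muscles), min_shared,
                )
                continue
            overall.loc[a, b] = overall.loc[b, a] = float(
                np.sqrt(np.sum(d**2)) / np.sqrt(len(muscles))
            )
    return MordResult(
        overall=overall, per_muscle=per_muscle, shared_counts=shared, excluded_pairs=excluded
    )
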