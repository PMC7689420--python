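"""Threshold classification, hit scoring/ranking and the annotation table.

A point is a hit when it clears both the effect-size and the significance
cutoff.  Classification is three-way:

* ``increased``: x > fc_high and y > sig
* ``decreased``: x < fc_low and y > sig
* ``unchanged``: everything else (points exactly on a threshold line are
  unchanged — the dashed lines are unambiguous separators).

Hits are ranked by one of four criteria measured from the origin (0, 0):
Manhattan distance |x| + |y| (the default), Euclidean distance
sqrt(x^2 + y^2), absolute fold change |x|, or significance y.  Ranking is
a stable descending sort, so ties keep their input order, and the top n
points are annotated.  Manually searched names are merged in afterwards
without duplication.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ForeignRecordError
from .io import VolcanoData, VolcanoRecord

CATEGORIES = ("unchanged", "decreased", "increased")
CRITERIA = ("manhattan", "euclidean", "fold_change", "significance")
DIRECTIONS = ("increased", "decreased", "significant")


@dataclass(frozen=True)
class Thresholds:
    """Effect-size cutoffs (fc_low < fc_high) plus significance cutoff."""

    fc_low: float
    fc_high: float
    sig: float

    def __post_init__(self) -> None:
        if not self.fc_low < self.fc_high:
            raise ValueError(
                f"fc_low must be below fc_high, got ({self.fc_low}, {self.fc_high})"
            )
        if self.sig < 0:
            raise ValueError(f"significance cutoff must be >= 0, got {self.sig}")

    @classmethod
    def symmetric(cls, s: float, sig: float) -> "Thresholds":
        """Expand a single fold-change cutoff s to the pair (-s, +s)."""
        return cls(-abs(s), abs(s), sig)

    @property
    def is_symmetric(self) -> bool:
        return math.isclose(self.fc_low, -self.fc_high)


@dataclass(frozen=True)
class RankingSpec:
    """Which criterion to rank by, which direction to keep, how many to show."""

    criterion: str = "manhattan"
    direction: str = "increased"
    n_top: int = 10

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(
                f"unknown criterion {self.criterion!r}; choose from {CRITERIA}"
            )
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"unknown direction {self.direction!r}; choose from {DIRECTIONS}"
            )
        if self.n_top < 0:
            raise ValueError("n_top must be non-negative")


@dataclass(frozen=True)
class HitEntry:
    record: VolcanoRecord
    score: float
    rank: Optional[int]  # 1-based for ranked entries, None for manual ones
    origin: str  # "ranked" | "manual"


@dataclass
class HitTable:
    """Ordered annotation set: ranked hits first, manual additions after."""

    entries: list[HitEntry]
    criterion: str
    thresholds: Thresholds
    source: Optional[VolcanoData] = None

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.record.name for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [e.record.name for e in self.entries],
                "x": [e.record.x for e in self.entries],
                "y": [e.record.y for e in self.entries],
                "category": [e.record.category for e in self.entries],
                "score": [e.score for e in self.entries],
                "rank": [e.rank for e in self.entries],
                "origin": [e.origin for e in self.entries],
            }
        )

    def to_csv(self, path_or_buf) -> None:
        """Export as CSV with name, x, y, category, score, rank, origin."""
        self.to_frame().to_csv(path_or_buf, index=False)


def classify(record: VolcanoRecord, t: Thresholds) -> str:
    """Three-way category for one point; boundary points are unchanged."""
    if record.y > t.sig:
        if record.x > t.fc_high:
            return "increased"
        if record.x < t.fc_low:
            return "decreased"
    return "unchanged"


def classify_data(data: VolcanoData, t: Thresholds) -> VolcanoData:
    """Assign categories to every record, in place, and return the data."""
    data.records = [r.with_category(classify(r, t)) for r in data.records]
    return data


def score(record: VolcanoRecord, criterion: str = "manhattan") -> float:
    """Ranking score of one point, measured from the origin.

    significance uses y as-is (not |y|): y is -log10 p and non-negative
    by construction, so malformed negative values rank last naturally.
    """
    if criterion == "manhattan":
        return abs(record.x) + abs(record.y)
    if criterion == "euclidean":
        return math.hypot(record.x, record.y)
    if criterion == "fold_change":
        return abs(record.x)
    if criterion == "significance":
        return record.y
    raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")


def _eligible_categories(direction: str) -> frozenset[str]:
    if direction == "significant":
        return frozenset({"increased", "decreased"})
    return frozenset({direction})


def top_hits(
    data: VolcanoData, t: Thresholds, spec: RankingSpec = RankingSpec()
) -> HitTable:
    """Rank the direction-eligible hits and keep the top ``spec.n_top``.

    Classification is (re)computed internally, the eligible records are
    stably sorted by descending score and the first min(n_top, eligible)
    are returned with origin ``ranked``.  An empty eligible set yields an
    empty table.
    """
    classify_data(data, t)
    wanted = _eligible_categories(spec.direction)
    eligible = [r for r in data.records if r.category in wanted]
    # sort is stable: ties keep original input order
    ordered = sorted(eligible, key=lambda r: -score(r, spec.criterion))
    top = ordered[: spec.n_top]
    entries = [
        HitEntry(r, score(r, spec.criterion), rank=i + 1, origin="ranked")
        for i, r in enumerate(top)
    ]
    return HitTable(entries, spec.criterion, t, source=data)


def select_by_name(
    data: VolcanoData, queries: Sequence[str]
) -> list[VolcanoRecord]:
    """Exact, case-folded, whitespace-trimmed name lookup.

    Duplicate names return every matching record.  Unmatched queries emit
    a warning rather than an error so a stale gene list never blocks a
    plot.
    """
    wanted = {q.strip().casefold() for q in queries if q.strip()}
    found: list[VolcanoRecord] = []
    matched: set[str] = set()
    for r in data.records:
        key = r.name.strip().casefold()
        if key in wanted:
            found.append(r)
            matched.add(key)
    missing = sorted(wanted - matched)
    if missing:
        warnings.warn(
            "names not found in the data: " + ", ".join(missing),
            stacklevel=2,
        )
    return found


def merge_annotations(
    ranked: HitTable, manual: Iterable[VolcanoRecord]
) -> HitTable:
    """Union of ranked hits and manual selections, without duplication.

    Manual-only entries are appended after the ranked block with origin
    ``manual`` and no rank; a manual pick that is already ranked keeps its
    ranked entry.
    """
    src = ranked.source
    def _key(r: VolcanoRecord) -> tuple[str, float, float]:
        return (r.name, r.x, r.y)

    already = {_key(e.record) for e in ranked.entries}
    in_source = {_key(r) for r in src.records} if src is not None else None
    entries = list(ranked.entries)
    for rec in manual:
        if in_source is not None and _key(rec) not in in_source:
            raise ForeignRecordError(
                f"foreign record {rec.name!r}: not part of the dataset this "
                "hit table was built from"
            )
        if _key(rec) in already:
            continue
        already.add(_key(rec))
        entries.append(
            HitEntry(rec, score(rec, ranked.criterion), rank=None, origin="manual")
        )
    return HitTable(entries, ranked.criterion, ranked.thresholds, source=src)
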