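"""Domain types, file IO, and study-design operations.

The pipeline's universal input is a samples x taxa count table together with
per-sample metadata (individual, collection date, season, nucleic-acid
fraction), per-(individual, month) behavior rates in minutes per hour, and
per-month mean precipitation. Trees are rooted Newick phylogenies with branch
lengths, handled as :class:`skbio.TreeNode`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date as _date
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CountTable",
    "SampleRecord",
    "FocalRecord",
    "TaxonomyHit",
    "Season",
    "assign_season",
    "filter_samples_by_depth",
    "filter_taxonomy_hits",
    "aggregate_behavior",
    "select_one_sample_per_individual_month",
    "read_count_table",
    "write_count_table",
    "read_newick",
    "read_metadata",
    "write_metadata",
    "read_behavior",
    "write_behavior",
    "read_climate",
    "write_climate",
]

Season = Literal["dry", "rainy"]

#: Months belonging to the cold dry season (April through October); the
#: remaining months (November through March) form the warm rainy season.
DRY_MONTHS = frozenset(range(4, 11))

BEHAVIOR_RATE_COLUMNS = ("fruit_rate", "leaf_rate", "flower_rate", "affiliation_rate")

#: map from focal-record behavior label to the behavior-table rate column
_BEHAVIOR_TO_COLUMN = {
    "feeding-fruit": "fruit_rate",
    "feeding-leaves": "leaf_rate",
    "feeding-flowers": "flower_rate",
    "affiliation": "affiliation_rate",
}


class ParseError(ValueError):
    """Raised when an input file violates the declared dialect or invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountTable:
    """Samples x taxa abundance matrix.

    ``counts`` holds non-negative integers for raw tables; after
    normalization (``normalized=True``) entries may be non-negative reals.
    """

    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    counts: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon identifiers")
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise ValueError("counts must be finite and non-negative")
        if not self.normalized and not np.allclose(counts, np.round(counts)):
            raise ValueError("raw counts must be integer-valued")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]

    def select_samples(self, keep: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return replace(self, sample_ids=tuple(keep), counts=self.counts[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.sample_ids), columns=list(self.taxon_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, normalized: bool = False) -> "CountTable":
        return cls(
            sample_ids=tuple(str(i) for i in frame.index),
            taxon_ids=tuple(str(c) for c in frame.columns),
            counts=frame.to_numpy(dtype=float),
            normalized=normalized,
        )


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample study metadata."""

    sample_id: str
    individual_id: str
    collection_date: _date
    fraction: Literal["entire", "active"] = "entire"

    @property
    def month(self) -> int:
        return self.collection_date.month

    @property
    def season(self) -> Season:
        return assign_season(self.month)


@dataclass(frozen=True)
class FocalRecord:
    """One behavior tally from a continuous focal observation.

    ``focal_id`` groups records that came from the same focal follow so its
    observation window is counted once; when omitted, each record is treated
    as its own focal.
    """

    individual_id: str
    date: _date
    observation_minutes: float
    behavior: str
    duration_minutes: float
    focal_id: str | None = None

    def __post_init__(self):
        if not 0 <= self.duration_minutes <= self.observation_minutes:
            raise ValueError(
                f"duration {self.duration_minutes} outside [0, {self.observation_minutes}]"
            )
        if self.behavior not in _BEHAVIOR_TO_COLUMN:
            raise ValueError(f"unknown behavior {self.behavior!r}")


@dataclass(frozen=True)
class TaxonomyHit:
    """A best database hit for a query sequence.

    ``lineage`` is ordered domain -> species; shorter lineages are allowed
    when deeper ranks were not assigned.
    """

    query_id: str
    lineage: tuple[str, ...]
    percent_identity: float
    percent_coverage: float
    accepted: bool | None = None

    def __post_init__(self):
        if not (0 <= self.percent_identity <= 100 and 0 <= self.percent_coverage <= 100):
            raise ValueError("identity and coverage must lie in [0, 100]")


# ---------------------------------------------------------------------------
# study-design operations
# ---------------------------------------------------------------------------


def assign_season(month: int) -> Season:
    """Map a calendar month to the study-site season.

    The site has a cold dry season from April through October and a warm
    rainy season from November through March.
    """
    if not isinstance(month, (int, np.integer)) or not 1 <= int(month) <= 12:
        raise ValueError(f"month must be an integer in 1..12, got {month!r}")
    return "dry" if int(month) in DRY_MONTHS else "rainy"


def filter_samples_by_depth(
    table: CountTable,
    min_reads: int,
    mode: Literal["at_least", "greater_than"] = "at_least",
) -> CountTable:
    """Drop samples with insufficient sequencing depth.

    ``at_least`` keeps samples whose total is >= ``min_reads`` (the reading of
    "samples with < N reads were excluded"); ``greater_than`` keeps strictly
    deeper samples.
    """
    if min_reads <= 0:
        raise ValueError("min_reads must be positive")
    if mode not in ("at_least", "greater_than"):
        raise ValueError(f"unknown mode {mode!r}")
    totals = table.sample_totals()
    keep = totals >= min_reads if mode == "at_least" else totals > min_reads
    return replace(
        table,
        sample_ids=tuple(s for s, k in zip(table.sample_ids, keep) if k),
        counts=table.counts[keep],
    )


def filter_taxonomy_hits(
    hits: Iterable[TaxonomyHit],
    min_identity: float = 90.0,
    accept_threshold: float = 93.0,
    species_floor: float = 98.7,
    genus_floor: float = 94.5,
) -> list[TaxonomyHit]:
    """Apply the taxonomy-hit acceptance rule and rank corrections.

    A hit is accepted iff identity >= ``min_identity`` and
    ``(identity + coverage) / 2 >= accept_threshold``. Among accepted hits the
    species label is replaced by ``"unclassified"`` when identity falls below
    ``species_floor``; below ``genus_floor`` both genus and species are
    cleared, keeping the lineage internally consistent. Lineages are assumed
    ranked domain -> species (7 ranks when complete); corrections only apply
    to lineages long enough to carry the rank.
    """
    out = []
    for hit in hits:
        score = (hit.percent_identity + hit.percent_coverage) / 2.0
        accepted = hit.percent_identity >= min_identity and score >= accept_threshold
        lineage = list(hit.lineage)
        if accepted:
            if hit.percent_identity < genus_floor:
                for rank in (5, 6):  # genus, species
                    if len(lineage) > rank:
                        lineage[rank] = "unclassified"
            elif hit.percent_identity < species_floor:
                if len(lineage) > 6:
                    lineage[6] = "unclassified"
        out.append(replace(hit, lineage=tuple(lineage), accepted=accepted))
    return out


def aggregate_behavior(records: Iterable[FocalRecord]) -> pd.DataFrame:
    """Aggregate focal observations into monthly behavior rates (min/h).

    For each (individual, month), the rate of a behavior is
    ``60 * total duration / total observation time`` where the denominator
    pools every focal of that individual in that month.  Months without any
    observation time produce no row.

    Returns a frame with columns ``individual_id, month`` plus the four rate
    columns, sorted by individual then month.
    """
    obs: dict[tuple[str, int], float] = {}
    dur: dict[tuple[str, int], dict[str, float]] = {}
    seen_focal: set[tuple] = set()
    for i, rec in enumerate(records):
        key = (rec.individual_id, rec.date.month)
        # observation windows counted once per focal follow
        focal_key = (rec.individual_id, rec.date, rec.focal_id if rec.focal_id is not None else i)
        if focal_key not in seen_focal:
            obs[key] = obs.get(key, 0.0) + rec.observation_minutes
            seen_focal.add(focal_key)
        col = _BEHAVIOR_TO_COLUMN[rec.behavior]
        dur.setdefault(key, dict.fromkeys(BEHAVIOR_RATE_COLUMNS, 0.0))
        dur[key][col] += rec.duration_minutes
    rows = []
    for (ind, month), total in sorted(obs.items()):
        if total <= 0:
            continue
        durations = dur.get((ind, month), dict.fromkeys(BEHAVIOR_RATE_COLUMNS, 0.0))
        rows.append(
            {
                "individual_id": ind,
                "month": month,
                **{c: 60.0 * durations[c] / total for c in BEHAVIOR_RATE_COLUMNS},
            }
        )
    return pd.DataFrame(rows, columns=["individual_id", "month", *BEHAVIOR_RATE_COLUMNS])


def select_one_sample_per_individual_month(
    metadata: pd.DataFrame, table: CountTable
) -> CountTable:
    """Keep one sample per (individual, month): the earliest-dated one.

    Ties on date are broken by sample identifier order, making the selection
    deterministic and auditable.
    """
    meta = metadata.set_index("sample_id")
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise KeyError(f"samples without metadata: {missing}")
    best: dict[tuple[str, int], tuple] = {}
    for s in table.sample_ids:
        row = meta.loc[s]
        d = pd.Timestamp(row["date"]).date()
        key = (str(row["individual_id"]), d.month)
        cand = (d, s)
        if key not in best or cand < best[key]:
            best[key] = cand
    keep = {s for _, s in best.values()}
    return table.select_samples([s for s in table.sample_ids if s in keep])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_count_table(path) -> CountTable:
    """Read a TSV count table (first column ``sample_id``, remaining columns taxa)."""
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    if frame.columns[0] != "sample_id":
        raise ParseError(f"first column must be 'sample_id', got {frame.columns[0]!r}")
    frame = frame.set_index("sample_id")
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].tolist()
        raise ParseError(f"duplicate sample identifiers: {dupes}")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = frame.columns[[not np.issubdtype(d, np.number) for d in frame.dtypes]]
        raise ParseError(f"non-numeric count columns: {list(bad)}")
    if np.any(values < 0):
        bad_rows = frame.index[(values < 0).any(axis=1)].tolist()
        raise ParseError(f"negative counts in samples: {bad_rows}")
    normalized = not np.allclose(values, np.round(values))
    return CountTable.from_frame(frame, normalized=normalized)


def write_count_table(table: CountTable, path) -> None:
    frame = table.to_frame()
    if not table.normalized:
        frame = frame.astype(np.int64)
    frame.to_csv(path, sep="\t", index_label="sample_id", float_format="%.12g")


def read_newick(path) -> TreeNode:
    """Read a rooted Newick tree with branch lengths.

    Trees whose root has more than two children are treated as unrooted and
    rejected; rooting is an upstream step, not performed here.
    """
    tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    if len(tree.children) > 2:
        raise ParseError(
            f"tree root has {len(tree.children)} children; expected a rooted "
            "(bifurcating at the root) tree"
        )
    return tree


def _read_csv_checked(path, required: Sequence[str], name: str) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{name} file missing columns {missing}")
    return frame


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata CSV: sample_id, individual_id, date, fraction.

    Dates are ISO-8601; ``month`` and ``season`` columns are derived from the
    date. An explicit ``season`` column, if present, must agree with the
    month-based assignment.
    """
    frame = _read_csv_checked(path, ["sample_id", "individual_id", "date", "fraction"], "metadata")
    frame["sample_id"] = frame["sample_id"].astype(str)
    frame["individual_id"] = frame["individual_id"].astype(str)
    if frame["sample_id"].duplicated().any():
        raise ParseError(
            f"duplicate sample_id rows: {frame['sample_id'][frame['sample_id'].duplicated()].tolist()}"
        )
    try:
        frame["date"] = pd.to_datetime(frame["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"unparseable ISO-8601 date in metadata: {exc}") from exc
    bad_fraction = ~frame["fraction"].isin(["entire", "active"])
    if bad_fraction.any():
        raise ParseError(
            f"unknown fraction labels in rows {frame.index[bad_fraction].tolist()}"
        )
    frame["month"] = frame["date"].dt.month
    derived = frame["month"].map(assign_season)
    if "season" in frame.columns:
        clash = frame["season"].astype(str) != derived
        if clash.any():
            raise ParseError(
                f"season labels inconsistent with month in rows {frame.index[clash].tolist()}"
            )
    frame["season"] = derived
    return frame


def write_metadata(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_behavior(path) -> pd.DataFrame:
    """Read behavior rates CSV: individual_id, month, four min/h rate columns."""
    frame = _read_csv_checked(
        path, ["individual_id", "month", *BEHAVIOR_RATE_COLUMNS], "behavior"
    )
    frame["individual_id"] = frame["individual_id"].astype(str)
    if frame.duplicated(["individual_id", "month"]).any():
        raise ParseError("duplicate (individual_id, month) rows in behavior table")
    rates = frame[list(BEHAVIOR_RATE_COLUMNS)].to_numpy(dtype=float)
    if np.any(rates < 0) or not np.all(np.isfinite(rates)):
        raise ParseError("behavior rates must be finite and non-negative")
    return frame


def write_behavior(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format="%.12g")


def read_climate(path) -> pd.DataFrame:
    """Read climate CSV: month, precipitation_mm (one row per month)."""
    frame = _read_csv_checked(path, ["month", "precipitation_mm"], "climate")
    if frame["month"].duplicated().any():
        raise ParseError("duplicate month rows in climate table")
    if (frame["precipitation_mm"] < 0).any():
        raise ParseError("precipitation must be non-negative")
    return frame


def write_climate(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format="%.12g")
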