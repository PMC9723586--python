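"""Count normalization and compositional transforms.

GMPR size factors absorb uneven library sizes in zero-inflated count tables;
rarefaction subsamples to a common depth for diversity analyses; proportions,
rare-taxon grouping and the per-sample centered log-ratio (CLR) transform feed
the compositional mixed model.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .core import CountTable

__all__ = [
    "gmpr_size_factors",
    "normalize_gmpr",
    "rarefy",
    "to_proportions",
    "group_rare",
    "clr_transform",
]

logger = logging.getLogger(__name__)


def gmpr_size_factors(table: CountTable) -> pd.Series:
    """Geometric mean of pairwise ratios (GMPR) size factors.

    For samples i and j, ``r_ij`` is the median over taxa with nonzero counts
    in both samples of ``count_i / count_j``; the size factor of sample i is
    the geometric mean of ``r_ij`` over all j for which ``r_ij`` is defined
    (the trivial self-ratio ``r_ii = 1`` included), and the factors are then
    rescaled to unit geometric mean. Under this convention scaling a sample
    elementwise by ``c`` scales its factor by exactly ``c``, and recomputing
    factors on a normalized table returns 1 for every sample (a fixed
    point). Robust to zero inflation because only shared-support taxa enter
    each pairwise median.
    """
    if table.n_samples < 2:
        raise ValueError("GMPR needs at least two samples")
    counts = table.counts
    n = table.n_samples
    log_r = np.full((n, n), np.nan)
    np.fill_diagonal(log_r, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = (counts[i] > 0) & (counts[j] > 0)
            if shared.any():
                # median taken in ratio space: for an even number of shared
                # taxa this differs from the log-space median
                log_r[i, j] = np.log(np.median(counts[i, shared] / counts[j, shared]))
    defined = ~np.isnan(log_r)
    np.fill_diagonal(defined, False)
    orphans = [table.sample_ids[i] for i in range(n) if not defined[i].any()]
    if orphans:
        raise ValueError(
            f"samples sharing no taxa with any other sample: {orphans}"
        )
    log_factors = np.nanmean(log_r, axis=1)
    log_factors -= log_factors.mean()  # unit geometric mean
    return pd.Series(
        np.exp(log_factors), index=list(table.sample_ids), name="size_factor"
    )


def normalize_gmpr(table: CountTable) -> CountTable:
    """Divide each sample's counts by its GMPR size factor."""
    factors = gmpr_size_factors(table)
    return replace(
        table, counts=table.counts / factors.to_numpy()[:, None], normalized=True
    )


def rarefy(table: CountTable, depth: int, seed: int | None = None) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a logged warning
    rather than raising, mirroring the depth-exclusion practice for
    under-sequenced libraries. Deterministic per seed.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if table.normalized:
        raise ValueError("rarefaction requires raw integer counts")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning(
            "rarefy: dropping %d samples below depth %d: %s", len(dropped), depth, dropped
        )
    counts = table.counts[keep].astype(np.int64)
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return replace(
        table,
        sample_ids=tuple(s for s, k in zip(table.sample_ids, keep) if k),
        counts=out.astype(float),
    )


def to_proportions(table: CountTable) -> CountTable:
    """Convert each sample to relative abundances summing to one."""
    totals = table.sample_totals()
    if np.any(totals <= 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"all-zero samples cannot be converted to proportions: {bad}")
    return replace(table, counts=table.counts / totals[:, None], normalized=True)


def group_rare(proportions: CountTable, threshold: float = 0.02) -> CountTable:
    """Pool taxa that never reach ``threshold`` into a single ``rare`` column.

    A taxon is absorbed only if its proportion is below the threshold in
    every sample; row sums are preserved exactly.
    """
    counts = proportions.counts
    rare_mask = (counts < threshold).all(axis=0)
    if not rare_mask.any():
        return proportions
    kept = ~rare_mask
    new_counts = np.column_stack([counts[:, kept], counts[:, rare_mask].sum(axis=1)])
    taxa = tuple(t for t, k in zip(proportions.taxon_ids, kept) if k) + ("rare",)
    return replace(proportions, taxon_ids=taxa, counts=new_counts)


def clr_transform(proportions: CountTable, min_prop: float = 0.005) -> pd.DataFrame:
    """Per-sample centered log-ratio transform after a low-abundance filter.

    Entries with proportion below ``min_prop`` (default 0.5%, guarding
    against index hopping) are dropped per sample; the retained entries are
    renormalized to sum to one and CLR-transformed:
    ``clr = ln p - mean(ln p)`` over that sample's retained taxa. Removed
    (sample, taxon) pairs are absent from the output — not zeros — so a
    downstream model simply lacks those observations.

    Returns a long frame with columns ``sample_id, taxon_id, clr``.
    """
    rows = []
    for i, sample in enumerate(proportions.sample_ids):
        p = proportions.counts[i]
        keep = p >= min_prop if min_prop > 0 else p > 0
        if keep.sum() < 2:
            raise ValueError(
                f"sample {sample!r} retains fewer than 2 taxa at min_prop={min_prop}"
            )
        q = p[keep] / p[keep].sum()
        logq = np.log(q)
        clr = logq - logq.mean()
        for t, v in zip(np.asarray(proportions.taxon_ids)[keep], clr):
            rows.append((sample, t, v))
    return pd.DataFrame(rows, columns=["sample_id", "taxon_id", "clr"])
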