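"""Repeated-measures ANCOM-style differential abundance between seasons.

For every pair of taxa the log-ratio of (pseudocounted) counts is modelled
with a mixed model — season as the fixed effect, a random intercept per
individual to absorb repeated sampling — and tested with a likelihood-ratio
test. A taxon's W statistic counts how many of its m-1 pairwise tests
survive Benjamini-Hochberg adjustment at ``alpha``; taxa with
``W >= ceil(cutoff_fraction * (m - 1))`` are flagged as differentially
abundant. Zero counts are handled by a uniform pseudocount; structural-zero
classification and outlier handling of the original ANCOM machinery are
deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2, false_discovery_control

from .core import CountTable
from .lmm import LMMSpec, RandomTerm, fit_lmm

__all__ = ["AncomResult", "ancom_w", "season_log2fc"]


@dataclass
class AncomResult:
    table: pd.DataFrame  # taxon_id, w, detected, log2fc
    cutoff: int
    m: int
    alpha: float
    cutoff_fraction: float


def _season_lrt_p(ratio: np.ndarray, season01: np.ndarray, individual: np.ndarray) -> float:
    """LRT p-value for season in a random-intercept-by-individual model."""
    frame = pd.DataFrame(
        {"y": ratio, "season": season01, "individual_id": individual}
    )
    spec_full = LMMSpec(
        fixed=("season",), random=(RandomTerm("individual_id", ()),), response="y"
    )
    spec_null = LMMSpec(fixed=(), random=(RandomTerm("individual_id", ()),), response="y")
    full = fit_lmm(spec_full, frame)
    null = fit_lmm(spec_null, frame)
    stat = max(0.0, 2.0 * (full.log_likelihood - null.log_likelihood))
    return float(chi2.sf(stat, 1))


def ancom_w(
    table: CountTable,
    season: Mapping[str, str],
    individual: Mapping[str, str],
    alpha: float = 0.05,
    cutoff_fraction: float = 0.7,
    pseudocount: float = 1.0,
) -> AncomResult:
    """W statistic for seasonal differential abundance with repeated measures.

    ``season`` and ``individual`` map each sample to its season label and
    individual. Pairs (i, j) and (j, i) give sign-flipped log-ratios and
    therefore identical likelihood-ratio p-values; each unordered pair is
    fitted once and shared.
    """
    if table.n_taxa < 3:
        raise ValueError("ANCOM needs at least 3 taxa")
    seasons = np.asarray([season[s] for s in table.sample_ids])
    labels, counts_per = np.unique(seasons, return_counts=True)
    if len(labels) < 2:
        raise ValueError("both seasons must be present")
    if (counts_per < 2).any():
        small = labels[counts_per < 2].tolist()
        raise ValueError(f"seasons with fewer than 2 samples: {small}")
    individuals = np.asarray([individual[s] for s in table.sample_ids])
    season01 = (seasons == labels[-1]).astype(float)

    m = table.n_taxa
    logc = np.log(table.counts + pseudocount)
    pvals = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            p = _season_lrt_p(logc[:, i] - logc[:, j], season01, individuals)
            pvals[i, j] = pvals[j, i] = p

    cutoff = math.ceil(cutoff_fraction * (m - 1))
    log2fc = season_log2fc(table, season, pseudocount=pseudocount)
    rows = []
    for i, taxon in enumerate(table.taxon_ids):
        pw = np.delete(pvals[i], i)
        adjusted = false_discovery_control(pw, method="bh")
        w = int((adjusted < alpha).sum())
        rows.append(
            {
                "taxon_id": taxon,
                "w": w,
                "detected": w >= cutoff,
                "log2fc": log2fc[taxon],
            }
        )
    return AncomResult(
        table=pd.DataFrame(rows),
        cutoff=cutoff,
        m=m,
        alpha=alpha,
        cutoff_fraction=cutoff_fraction,
    )


def season_log2fc(
    table: CountTable, season: Mapping[str, str], pseudocount: float = 1.0
) -> pd.Series:
    """Per-taxon log2 fold change of mean abundance, rainy over dry.

    Positive values mean higher mean abundance in the rainy season. Zero
    means are replaced by the pseudocount so the ratio stays defined.
    """
    seasons = np.asarray([season[s] for s in table.sample_ids])
    if not {"dry", "rainy"} <= set(seasons):
        raise ValueError("both 'dry' and 'rainy' seasons must be present")
    mean_rainy = table.counts[seasons == "rainy"].mean(axis=0)
    mean_dry = table.counts[seasons == "dry"].mean(axis=0)
    mean_rainy = np.where(mean_rainy > 0, mean_rainy, pseudocount)
    mean_dry = np.where(mean_dry > 0, mean_dry, pseudocount)
    return pd.Series(
        np.log2(mean_rainy / mean_dry), index=list(table.taxon_ids), name="log2fc"
    )
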