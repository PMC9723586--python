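"""Strata-aware permutation inference on distance matrices and ordinations.

Repeated sampling of the same individuals breaks free exchangeability, so
the environmental-vector fit restricts permutations to within-individual
blocks (strata). All tests share the ``(1 + b) / (M + 1)`` p-value
convention — the observed statistic counts once — which floors p at
``1/(M+1)`` (0.001 at M = 999) and keeps p strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .diversity import DistanceMatrix, OrdinationResult

__all__ = [
    "PermTestResult",
    "EnvfitVector",
    "ProcrustesResult",
    "envfit",
    "permanova",
    "mantel",
    "time_distance",
    "procrustes",
    "protest",
]


@dataclass(frozen=True)
class PermTestResult:
    statistic_observed: float
    null_statistics: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic_observed,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class EnvfitVector:
    variable: str
    direction: np.ndarray  # unit-norm cosines on the fitted axes (zero if r2 == 0)
    r_squared: float
    p_value: float
    n_permutations: int


@dataclass(frozen=True)
class ProcrustesResult:
    m_squared: float
    rotation: np.ndarray
    scaling: float
    translation: np.ndarray  # shift applied to Y's centroid, in X's frame
    t_statistic: float
    p_value: float | None = None
    null_statistics: np.ndarray | None = None
    n_permutations: int | None = None


def _permute_within_strata(
    rng: np.random.Generator, n: int, strata: np.ndarray | None
) -> np.ndarray:
    if strata is None:
        return rng.permutation(n)
    perm = np.arange(n)
    for block in np.unique(strata):
        idx = np.flatnonzero(strata == block)
        perm[idx] = idx[rng.permutation(len(idx))]
    return perm


def _r_squared(axes: np.ndarray, v: np.ndarray) -> float:
    """Coefficient of determination of v regressed on the axes (with intercept)."""
    vc = v - v.mean()
    ss_tot = vc @ vc
    if ss_tot <= 0:
        return 0.0
    coef, *_ = np.linalg.lstsq(axes, vc, rcond=None)
    resid = vc - axes @ coef
    return float(1.0 - (resid @ resid) / ss_tot)


def envfit(
    ordination: OrdinationResult,
    variables: pd.DataFrame | Mapping[str, Sequence[float]],
    n_axes: int = 2,
    strata: Mapping[str, str] | None = None,
    permutations: int = 999,
    seed: int | None = None,
) -> list[EnvfitVector]:
    """Fit external variables onto ordination axes, with strata permutations.

    Each variable is least-squares-projected onto the first ``n_axes``
    coordinates; r² is the coefficient of determination and the direction the
    unit vector of regression coefficients. Significance comes from permuting
    the variable's values — only within strata blocks when ``strata`` maps
    samples to blocks — with ``p = (1 + #{null r2 >= observed}) / (M + 1)``.
    Constant variables get r² = 0 and p = 1 by convention.
    """
    frame = pd.DataFrame(variables)
    ids = list(ordination.sample_ids)
    if strata is not None:
        blocks = np.asarray([strata[s] for s in ids])
    else:
        blocks = None
    n_axes = min(n_axes, ordination.n_axes)
    axes = ordination.coordinates[:, :n_axes]
    axes = axes - axes.mean(axis=0)
    rng = np.random.default_rng(seed)
    results = []
    for name in frame.columns:
        v = frame[name].to_numpy(dtype=float)
        if len(v) != len(ids):
            raise ValueError(f"variable {name!r} has {len(v)} values for {len(ids)} samples")
        r2 = _r_squared(axes, v)
        if np.ptp(v) == 0:
            results.append(
                EnvfitVector(str(name), np.zeros(n_axes), 0.0, 1.0, permutations)
            )
            continue
        vc = v - v.mean()
        coef, *_ = np.linalg.lstsq(axes, vc, rcond=None)
        norm = np.linalg.norm(coef)
        direction = coef / norm if norm > 0 else np.zeros(n_axes)
        exceed = 0
        for _ in range(permutations):
            perm = _permute_within_strata(rng, len(v), blocks)
            if _r_squared(axes, v[perm]) >= r2:
                exceed += 1
        p = (1 + exceed) / (permutations + 1)
        results.append(EnvfitVector(str(name), direction, r2, p, permutations))
    return results


def _pseudo_f(sq: np.ndarray, groups: np.ndarray) -> float:
    """One-way PERMANOVA pseudo-F from squared distances."""
    n = sq.shape[0]
    labels, inverse = np.unique(groups, return_inverse=True)
    a = len(labels)
    iu = np.triu_indices(n, k=1)
    ss_total = sq[iu].sum() / n
    ss_within = 0.0
    for g in range(a):
        idx = np.flatnonzero(inverse == g)
        if len(idx) > 1:
            sub = sq[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    dist: DistanceMatrix,
    groups: Mapping[str, str] | Sequence[str],
    permutations: int = 999,
    seed: int | None = None,
) -> PermTestResult:
    """One-way permutational multivariate ANOVA on a distance matrix.

    ``SS_total = sum_{i<j} d_ij^2 / N`` and ``SS_within`` sums the analogous
    per-group terms; the pseudo-F compares among- to within-group variation.
    Group labels are permuted freely.
    """
    ids = list(dist.ids)
    if isinstance(groups, Mapping):
        labels = np.asarray([groups[s] for s in ids])
    else:
        labels = np.asarray(list(groups))
        if len(labels) != len(ids):
            raise ValueError("groups length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    sq = dist.data**2
    f_obs = _pseudo_f(sq, labels)
    rng = np.random.default_rng(seed)
    null = np.empty(permutations)
    for k in range(permutations):
        null[k] = _pseudo_f(sq, labels[rng.permutation(len(labels))])
    p = (1 + int((null >= f_obs).sum())) / (permutations + 1)
    return PermTestResult(f_obs, null, p, permutations, seed)


def time_distance(metadata: pd.DataFrame, individual: str) -> DistanceMatrix:
    """Pairwise |days between collection dates| for one individual's samples."""
    sub = metadata.loc[metadata["individual_id"].astype(str) == str(individual)]
    if sub.empty:
        raise KeyError(f"no samples for individual {individual!r}")
    if sub["date"].isna().any():
        raise ValueError("missing collection dates")
    days = pd.to_datetime(sub["date"]).astype("int64").to_numpy() / 86_400e9
    mat = np.abs(days[:, None] - days[None, :])
    return DistanceMatrix(mat, ids=[str(s) for s in sub["sample_id"]])


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    permutations: int = 999,
    seed: int | None = None,
) -> PermTestResult:
    """Mantel correlation between two distance matrices over the same samples.

    The statistic is the rank (Spearman) or product-moment (Pearson)
    correlation of the lower-triangle entries; the null permutes rows and
    columns of ``d2`` simultaneously. One-sided: large positive correlations
    are extreme.
    """
    if tuple(d1.ids) != tuple(d2.ids):
        raise ValueError("distance matrices must share sample set and order")
    n = d1.shape[0]
    if n < 3:
        raise ValueError("Mantel needs at least 3 samples")
    il = np.tril_indices(n, k=-1)

    if method == "spearman":
        stat = lambda a, b: spearmanr(a, b).statistic  # noqa: E731
    elif method == "pearson":
        stat = lambda a, b: np.corrcoef(a, b)[0, 1]  # noqa: E731
    else:
        raise ValueError(f"unknown correlation {method!r}")

    x = d1.data[il]
    obs = float(stat(x, d2.data[il]))
    rng = np.random.default_rng(seed)
    null = np.empty(permutations)
    for k in range(permutations):
        perm = rng.permutation(n)
        null[k] = stat(x, d2.data[np.ix_(perm, perm)][il])
    p = (1 + int((null >= obs).sum())) / (permutations + 1)
    return PermTestResult(obs, null, p, permutations, seed)


def _procrustes_core(x: np.ndarray, y: np.ndarray):
    """Center and unit-trace-scale both configurations, rotate y onto x."""
    mu_x, mu_y = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mu_x, y - mu_y
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("rank-0 configuration: all points identical")
    xc, yc = xc / nx, yc / ny
    u, s, vt = np.linalg.svd(xc.T @ yc)
    rotation = vt.T @ u.T  # yc @ rotation approximates xc
    scaling = s.sum()
    m_sq = float(max(0.0, 1.0 - scaling**2))
    return xc, yc, rotation, scaling, m_sq, mu_x, mu_y


def _pad_columns(x: np.ndarray, y: np.ndarray):
    k = max(x.shape[1], y.shape[1])
    pad = lambda a: np.pad(a, ((0, 0), (0, k - a.shape[1])))  # noqa: E731
    return pad(x), pad(y)


def procrustes(x: np.ndarray, y: np.ndarray) -> ProcrustesResult:
    """Optimal superposition of configuration ``y`` onto ``x``.

    Both configurations are centered and scaled to unit trace
    (``||.||_F = 1``); ``y`` is then rotated and scaled to minimize the
    residual sum of squares ``m² = 1 - (sum of singular values)²``, which is
    bounded in [0, 1]. The Procrustes correlation is ``t = sqrt(1 - m²)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("configurations must have the same number of points")
    x, y = _pad_columns(x, y)
    _, _, rotation, scaling, m_sq, mu_x, mu_y = _procrustes_core(x, y)
    return ProcrustesResult(
        m_squared=m_sq,
        rotation=rotation,
        scaling=scaling,
        translation=mu_x - mu_y,
        t_statistic=float(np.sqrt(1.0 - m_sq)),
    )


def protest(
    x: np.ndarray,
    y: np.ndarray,
    permutations: int = 999,
    seed: int | None = None,
) -> ProcrustesResult:
    """Procrustes significance test.

    Permutes the rows of ``y`` and recomputes the Procrustes correlation
    ``t = sqrt(1 - m²)``; ``p = (1 + #{t_perm >= t_obs}) / (M + 1)``.
    """
    base = procrustes(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = _pad_columns(x, y)
    rng = np.random.default_rng(seed)
    null = np.empty(permutations)
    for k in range(permutations):
        perm = rng.permutation(y.shape[0])
        null[k] = np.sqrt(1.0 - _procrustes_core(x, y[perm])[4])
    p = (1 + int((null >= base.t_statistic).sum())) / (permutations + 1)
    return ProcrustesResult(
        m_squared=base.m_squared,
        rotation=base.rotation,
        scaling=base.scaling,
        translation=base.translation,
        t_statistic=base.t_statistic,
        p_value=p,
        null_statistics=null,
        n_permutations=permutations,
    )
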