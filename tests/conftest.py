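import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import longgut as lg


@pytest.fixture(scope="session")
def toy_tree() -> TreeNode:
    return TreeNode.read(io.StringIO("((A:1,B:2):0.5,C:3);"))


@pytest.fixture(scope="session")
def four_taxon_tree() -> TreeNode:
    return TreeNode.read(io.StringIO("((A:1,B:2):0.5,(C:3,D:1):0.25);"))


@pytest.fixture
def toy_table() -> lg.CountTable:
    return lg.CountTable(
        sample_ids=("s1", "s2", "s3"),
        taxon_ids=("A", "B", "C", "D"),
        counts=np.array(
            [
                [10, 5, 0, 1],
                [20, 10, 2, 0],
                [1, 0, 8, 4],
            ]
        ),
    )


@pytest.fixture(scope="session")
def small_bundle() -> lg.StudyBundle:
    """A small default-conditions bundle shared across tests."""
    return lg.generate_study(lg.SynthConfig(n_taxa=12, seed=42))


@pytest.fixture(scope="session")
def small_long_table(small_bundle) -> pd.DataFrame:
    from longgut.lmm import build_long_table

    clr = lg.clr_transform(lg.to_proportions(small_bundle.table))
    return build_long_table(
        clr, small_bundle.metadata, small_bundle.behavior, small_bundle.climate
    )


def gaussian_lmm_data(
    seed: int = 0,
    n_groups: int = 8,
    n_per: int = 10,
    beta=(1.0, 0.5),
    intercept_sd: float = 0.7,
    slope_sd: float = 0.4,
    resid_sd: float = 0.5,
) -> pd.DataFrame:
    """Draw data straight from a random-intercept-and-slope Gaussian LMM."""
    rng = np.random.default_rng(seed)
    n = n_groups * n_per
    df = pd.DataFrame(
        {
            "g": np.repeat([f"g{i}" for i in range(n_groups)], n_per),
            "x": rng.normal(size=n),
        }
    )
    df["y"] = (
        beta[0]
        + beta[1] * df["x"]
        + np.repeat(rng.normal(0, intercept_sd, n_groups), n_per)
        + df["x"] * np.repeat(rng.normal(0, slope_sd, n_groups), n_per)
        + rng.normal(0, resid_sd, n)
    )
    return df


def dense_mvn_loglik(design, theta: np.ndarray) -> float:
    """Independent oracle: profiled ML log-likelihood via the dense
    covariance V0 = I + Z Lambda Lambda' Z' evaluated directly."""
    n = design.n
    X, y = design.X, design.y
    if design.q == 0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r2 = float((y - X @ beta) @ (y - X @ beta))
        return -0.5 * (n * np.log(2 * np.pi * r2 / n) + n)
    Z = design.Z.toarray()
    lam = np.zeros((design.q, design.q))
    for lay in design.layouts:
        T = design.term_factor(lay, theta)
        for lev in range(lay.n_levels):
            i0 = lay.col_slice.start + lev * lay.k
            lam[i0 : i0 + lay.k, i0 : i0 + lay.k] = T
    v0 = np.eye(n) + Z @ lam @ lam.T @ Z.T
    vi = np.linalg.inv(v0)
    beta = np.linalg.solve(X.T @ vi @ X, X.T @ vi @ y)
    resid = y - X @ beta
    r2 = float(resid @ vi @ resid)
    _, logdet = np.linalg.slogdet(v0)
    return -0.5 * (logdet + n * np.log(2 * np.pi * r2 / n) + n)
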