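"""Gaussian linear mixed models by maximum likelihood, and the compositional
taxon-random-slope analysis built on them.

The engine fits ``y = X beta + Z b + e`` with ``b ~ N(0, sigma^2 Lambda
Lambda')`` and ``e ~ N(0, sigma^2 I)``, where ``Lambda`` is block-diagonal
over random-effect terms and levels with a repeated per-term factor: a
lower-triangular Cholesky factor for terms with correlated components, a
diagonal of relative standard deviations for uncorrelated ones. ``beta`` and
``sigma`` are profiled out, leaving the deviance a function of the relative
covariance parameters alone; it is minimized with analytic gradients. ML
(never REML) is used throughout because differences of log-likelihoods
across models with different random structures are the test statistics.

Crossed grouping factors (individual, taxon, sample, taxon nested in
individual) are supported directly: the profiled deviance only needs the
sufficient statistics Z'Z, Z'X, Z'y, X'X, X'y, y'y, so the cost per
evaluation is one Cholesky factorization of a q x q matrix (q = total number
of random-effect coefficients), independent of the number of observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.stats import chi2

from .core import BEHAVIOR_RATE_COLUMNS, assign_season
from .permtests import PermTestResult

__all__ = [
    "RandomTerm",
    "LMMSpec",
    "LMMFit",
    "SlopePermutationResult",
    "AlphaModelResult",
    "TEST_PREDICTORS",
    "CONTROL_PREDICTOR",
    "build_long_table",
    "composition_model_spec",
    "fit_lmm",
    "permute_taxa_within_sample",
    "taxon_slope_permutation_test",
    "extract_top_blups",
    "vif",
    "loio_stability",
    "alpha_diversity_model",
]

#: behavioral test predictors of the composition and alpha models (min/h)
TEST_PREDICTORS = ("fruit_rate", "leaf_rate", "flower_rate", "affiliation_rate")
#: climatic control predictor (mm)
CONTROL_PREDICTOR = "precipitation_mm"

TAXON_INDIVIDUAL = "taxon_individual"


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomTerm:
    """One random-effect term: a grouping factor with intercept and slopes.

    ``correlated=True`` estimates a full covariance among the term's
    components (intercept and slopes); ``False`` estimates independent
    variances only.
    """

    group: str
    slopes: tuple[str, ...] = ()
    correlated: bool = True

    @property
    def components(self) -> tuple[str, ...]:
        return ("intercept", *self.slopes)

    @property
    def k(self) -> int:
        return 1 + len(self.slopes)

    @property
    def n_theta(self) -> int:
        return self.k * (self.k + 1) // 2 if self.correlated else self.k


@dataclass(frozen=True)
class LMMSpec:
    """Fixed covariates (intercept implicit) and random terms."""

    fixed: tuple[str, ...]
    random: tuple[RandomTerm, ...] = ()
    response: str = "clr"

    def drop_taxon_slopes(self, predictors: Sequence[str], group: str = "taxon_id") -> "LMMSpec":
        """Reduced spec with the given slopes removed from one grouping factor."""
        new_terms = []
        for term in self.random:
            if term.group == group:
                term = replace(
                    term, slopes=tuple(s for s in term.slopes if s not in predictors)
                )
            new_terms.append(term)
        return replace(self, random=tuple(new_terms))


def composition_model_spec(
    test_predictors: Sequence[str] = TEST_PREDICTORS,
    control_predictor: str = CONTROL_PREDICTOR,
) -> LMMSpec:
    """The compositional model for CLR abundances.

    Fixed effects: intercept plus the four behavioral test predictors and
    precipitation as control. Random structure: intercepts for sample,
    individual, taxon, and taxon-within-individual; random slopes for all
    predictors within taxon (correlated with the intercept), within
    individual (uncorrelated — correlations are unidentifiable there), and
    within taxon-individual (correlated) except the flower slope, which is
    dropped from the taxon-individual term.
    """
    predictors = (*test_predictors, control_predictor)
    ti_slopes = tuple(p for p in predictors if p != "flower_rate")
    return LMMSpec(
        fixed=predictors,
        random=(
            RandomTerm("sample_id", (), correlated=True),
            RandomTerm("individual_id", predictors, correlated=False),
            RandomTerm("taxon_id", predictors, correlated=True),
            RandomTerm(TAXON_INDIVIDUAL, ti_slopes, correlated=True),
        ),
        response="clr",
    )


# ---------------------------------------------------------------------------
# long-table construction
# ---------------------------------------------------------------------------


def build_long_table(
    clr_long: pd.DataFrame,
    metadata: pd.DataFrame,
    behavior: pd.DataFrame,
    climate: pd.DataFrame,
) -> pd.DataFrame:
    """Join covariates onto each (sample, taxon) CLR observation.

    Covariates are sample-constant: the behavior rates of the sample's
    (individual, month) cell and the month's mean precipitation, all on their
    natural scales. Missing behavior or climate cells raise with the full
    list of offending cells.
    """
    meta = metadata[["sample_id", "individual_id", "month"]].copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    data = clr_long.merge(meta, on="sample_id", how="left", validate="many_to_one")
    if data["individual_id"].isna().any():
        missing = sorted(data.loc[data["individual_id"].isna(), "sample_id"].unique())
        raise KeyError(f"samples without metadata: {missing}")
    data = data.merge(behavior, on=["individual_id", "month"], how="left")
    no_behavior = data[list(BEHAVIOR_RATE_COLUMNS)].isna().any(axis=1)
    if no_behavior.any():
        cells = sorted(
            set(zip(data.loc[no_behavior, "individual_id"], data.loc[no_behavior, "month"]))
        )
        raise KeyError(f"(individual, month) cells without behavior rates: {cells}")
    data = data.merge(climate[["month", "precipitation_mm"]], on="month", how="left")
    if data["precipitation_mm"].isna().any():
        months = sorted(data.loc[data["precipitation_mm"].isna(), "month"].unique())
        raise KeyError(f"months without climate data: {months}")
    data[TAXON_INDIVIDUAL] = (
        data["taxon_id"].astype(str) + "|" + data["individual_id"].astype(str)
    )
    if data.duplicated(["sample_id", "taxon_id"]).any():
        raise ValueError("duplicate (sample, taxon) observations")
    return data


def permute_taxa_within_sample(
    data: pd.DataFrame, seed: int | None = None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Shuffle taxon labels among the observations of each sample.

    Responses, sample identities, and covariates are untouched; only the
    ``taxon_id`` column is permuted within each sample, and the
    taxon-within-individual grouping is recomputed from the new labels. This
    is the exchangeability operation of the taxon-slope permutation test:
    under the null of no taxon-specific covariate effects, which taxon label
    carries which CLR value within a sample is arbitrary.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = data.copy()
    taxa = out["taxon_id"].to_numpy().copy()
    for _, idx in out.groupby("sample_id", sort=False).indices.items():
        taxa[idx] = taxa[idx[rng.permutation(len(idx))]]
    out["taxon_id"] = taxa
    if TAXON_INDIVIDUAL in out.columns:
        out[TAXON_INDIVIDUAL] = (
            out["taxon_id"].astype(str) + "|" + out["individual_id"].astype(str)
        )
    return out


# ---------------------------------------------------------------------------
# engine internals
# ---------------------------------------------------------------------------


@dataclass
class _TermLayout:
    term: RandomTerm
    levels: np.ndarray  # level labels, in order of first appearance
    col_slice: slice  # columns of Z / rows of u, level-major
    theta_slice: slice
    comp_scales: np.ndarray  # internal standardization of slope covariates
    tri_rows: np.ndarray | None = None  # lower-tri index pairs (correlated)
    tri_cols: np.ndarray | None = None

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def k(self) -> int:
        return self.term.k


class _Design:
    """Design matrices and sufficient statistics for one dataset + spec."""

    def __init__(self, spec: LMMSpec, data: pd.DataFrame):
        self.spec = spec
        n = len(data)
        y = data[spec.response].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(n)] + [data[c].to_numpy(dtype=float) for c in spec.fixed]
        )
        self.fixed_names = ["intercept", *spec.fixed]
        if n <= X.shape[1]:
            raise ValueError("need more observations than fixed coefficients")
        self.n, self.p = n, X.shape[1]

        layouts: list[_TermLayout] = []
        z_blocks = []
        col0, th0 = 0, 0
        for term in spec.random:
            codes, levels = pd.factorize(data[term.group], sort=True)
            k = term.k
            ncols = len(levels) * k
            rows = np.repeat(np.arange(n), k)
            cols = (codes[:, None] * k + np.arange(k)[None, :]).ravel()
            # slope covariates are standardized inside Z for optimizer
            # conditioning; estimates are mapped back to original units
            slope_cols = [data[s].to_numpy(dtype=float) for s in term.slopes]
            scales = np.array([1.0] + [c.std() or 1.0 for c in slope_cols])
            vals = np.column_stack(
                [np.ones(n)] + [c / sc for c, sc in zip(slope_cols, scales[1:])]
            ).ravel()
            z_blocks.append(
                sp.coo_matrix((vals, (rows, cols)), shape=(n, ncols)).tocsr()
            )
            lay = _TermLayout(
                term=term,
                levels=np.asarray(levels),
                col_slice=slice(col0, col0 + ncols),
                theta_slice=slice(th0, th0 + term.n_theta),
                comp_scales=scales,
            )
            if term.correlated:
                tri = np.tril_indices(k)
                lay.tri_rows, lay.tri_cols = tri
            layouts.append(lay)
            col0 += ncols
            th0 += term.n_theta
        self.layouts = layouts
        self.q = col0
        self.n_theta = th0

        if self.q:
            Z = sp.hstack(z_blocks, format="csr")
            self.A = np.asarray((Z.T @ Z).todense())
            self.ZtX = np.asarray(Z.T @ X)
            self.Zty = np.asarray(Z.T @ y)
            self.Z = Z
        else:
            self.A = np.zeros((0, 0))
            self.ZtX = np.zeros((0, self.p))
            self.Zty = np.zeros(0)
            self.Z = None
        self.X, self.y = X, y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    # -- theta handling ----------------------------------------------------

    def theta_start(self) -> np.ndarray:
        theta = np.zeros(self.n_theta)
        for lay in self.layouts:
            part = np.zeros(lay.term.n_theta)
            if lay.term.correlated:
                part[lay.tri_rows == lay.tri_cols] = 1.0
            else:
                part[:] = 1.0
            theta[lay.theta_slice] = part
        return theta

    def theta_bounds(self) -> list[tuple[float | None, float | None]]:
        bounds: list[tuple[float | None, float | None]] = [(None, None)] * self.n_theta
        for lay in self.layouts:
            idx = np.arange(lay.theta_slice.start, lay.theta_slice.stop)
            if lay.term.correlated:
                diag = idx[lay.tri_rows == lay.tri_cols]
            else:
                diag = idx
            for i in diag:
                bounds[i] = (0.0, None)
        return bounds

    def term_factor(self, lay: _TermLayout, theta: np.ndarray) -> np.ndarray:
        """The per-level k x k relative covariance factor T of one term."""
        part = theta[lay.theta_slice]
        k = lay.k
        T = np.zeros((k, k))
        if lay.term.correlated:
            T[lay.tri_rows, lay.tri_cols] = part
        else:
            np.fill_diagonal(T, part)
        return T

    # -- Lambda products (block structure, no q x q multiply) --------------

    def _lambda_right(self, B: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """B @ Lambda for B with q columns."""
        out = np.empty_like(B, dtype=float)
        for lay in self.layouts:
            T = self.term_factor(lay, theta)
            view = B[:, lay.col_slice].reshape(B.shape[0], lay.n_levels, lay.k)
            out[:, lay.col_slice] = (view @ T).reshape(B.shape[0], -1)
        return out

    def _lambda_tleft(self, B: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Lambda.T @ B for B with q rows (B may be 1-D)."""
        one_d = B.ndim == 1
        Bm = B[:, None] if one_d else B
        out = np.empty_like(Bm, dtype=float)
        for lay in self.layouts:
            T = self.term_factor(lay, theta)
            view = Bm[lay.col_slice].reshape(lay.n_levels, lay.k, Bm.shape[1])
            out[lay.col_slice] = np.matmul(T.T, view).reshape(-1, Bm.shape[1])
        return out[:, 0] if one_d else out

    def _lambda_apply(self, u: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Lambda @ u."""
        out = np.empty_like(u, dtype=float)
        for lay in self.layouts:
            T = self.term_factor(lay, theta)
            view = u[lay.col_slice].reshape(lay.n_levels, lay.k)
            out[lay.col_slice] = (view @ T.T).ravel()
        return out

    # -- profiled deviance -------------------------------------------------

    def solve(self, theta: np.ndarray):
        """Profiled solution at theta.

        Returns (deviance, beta, u, r2, logdet, L, RZX, cz, S_chol).
        """
        n, p = self.n, self.p
        if self.q == 0:
            S = cholesky(self.XtX, lower=True)
            beta = cho_solve((S, True), self.Xty)
            r2 = self.yty - beta @ self.Xty
            dev = n * (1.0 + np.log(2.0 * np.pi * r2 / n))
            return dev, beta, np.zeros(0), r2, 0.0, None, None, None, S
        AL = self._lambda_right(self.A, theta)  # A @ Lambda
        M = self._lambda_tleft(AL, theta)
        M[np.diag_indices_from(M)] += 1.0
        L = cholesky(M, lower=True, check_finite=False)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        CX = self._lambda_tleft(self.ZtX, theta)
        cz_raw = self._lambda_tleft(self.Zty, theta)
        RZX = solve_triangular(L, CX, lower=True, check_finite=False)
        cz = solve_triangular(L, cz_raw, lower=True, check_finite=False)
        S = self.XtX - RZX.T @ RZX
        S_chol = cholesky(S, lower=True, check_finite=False)
        rhs_beta = self.Xty - RZX.T @ cz
        beta = cho_solve((S_chol, True), rhs_beta, check_finite=False)
        u = solve_triangular(L, cz - RZX @ beta, lower=True, trans="T", check_finite=False)
        r2 = self.yty - u @ cz_raw - beta @ self.Xty
        r2 = max(r2, 1e-12)
        dev = logdet + n * (1.0 + np.log(2.0 * np.pi * r2 / n))
        return dev, beta, u, r2, logdet, L, RZX, cz, S_chol

    def deviance_and_grad(self, theta: np.ndarray):
        dev, beta, u, r2, _, L, _, _, _ = self.solve(theta)
        if self.q == 0:
            return dev, np.zeros(0)
        # G = M^{-1} Lambda' A ; trace term per theta entry (i, j) of a term
        # is 2 * sum over levels of G[(lev, j), (lev, i)].
        LtA = self._lambda_tleft(self.A, theta)
        G = cho_solve((L, True), LtA, check_finite=False)
        # residual projection w = Z'e with e = y - X beta - Z Lambda u
        w = self.Zty - self.ZtX @ beta - self.A @ self._lambda_apply(u, theta)
        grad = np.zeros(self.n_theta)
        scale = 2.0 * self.n / r2
        for lay in self.layouts:
            k, nl = lay.k, lay.n_levels
            Gv = G[lay.col_slice, lay.col_slice].reshape(nl, k, nl, k)
            # diagonal level blocks: Gblocks[l] = G[lev l rows, lev l cols]
            Gblocks = Gv[np.arange(nl), :, np.arange(nl), :]  # (nl, k, k)
            trace_block = Gblocks.sum(axis=0)  # sum over levels
            wv = w[lay.col_slice].reshape(nl, k)
            uv = u[lay.col_slice].reshape(nl, k)
            outer = wv.T @ uv  # (k_i, k_j): sum_lev w[i] u[j]
            full = 2.0 * trace_block.T - scale * outer
            if lay.term.correlated:
                grad[lay.theta_slice] = full[lay.tri_rows, lay.tri_cols]
            else:
                grad[lay.theta_slice] = np.diag(full)
        return dev, grad


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------


@dataclass
class LMMFit:
    """Maximum-likelihood fit of an LMM."""

    spec: LMMSpec
    beta: pd.Series
    sigma: float
    theta: np.ndarray
    log_likelihood: float
    blups: dict[str, pd.DataFrame]
    var_components: dict[str, dict]
    fitted: np.ndarray
    residuals: np.ndarray
    n_obs: int
    converged: bool
    singular: bool
    n_evaluations: int
    message: str = ""

    @property
    def deviance(self) -> float:
        return -2.0 * self.log_likelihood


def _extract_components(design: _Design, theta: np.ndarray, sigma: float, u: np.ndarray):
    blups: dict[str, pd.DataFrame] = {}
    var_components: dict[str, dict] = {}
    singular = False
    b = design._lambda_apply(u, theta) if design.q else np.zeros(0)
    for lay in design.layouts:
        T = design.term_factor(lay, theta)
        cov = sigma**2 * T @ T.T
        sd = np.sqrt(np.diag(cov))
        if np.any(sd < 1e-8 * max(sigma, 1e-300)):
            singular = True
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / np.outer(sd, sd)
        corr[~np.isfinite(corr)] = 0.0
        comps = list(lay.term.components)
        var_components[lay.term.group] = {
            "sd": pd.Series(sd / lay.comp_scales, index=comps),
            "corr": pd.DataFrame(corr, index=comps, columns=comps)
            if lay.term.correlated
            else None,
        }
        blups[lay.term.group] = pd.DataFrame(
            b[lay.col_slice].reshape(lay.n_levels, lay.k) / lay.comp_scales,
            index=list(lay.levels),
            columns=comps,
        )
    return blups, var_components, singular, b


def fit_lmm(
    spec: LMMSpec,
    data: pd.DataFrame,
    tol: float = 1e-9,
    max_iter: int = 500,
    seed: int = 0,
    start: np.ndarray | None = None,
    n_restarts: int = 3,
) -> LMMFit:
    """Fit an LMM by maximum likelihood.

    The profiled deviance is minimized with L-BFGS-B (analytic gradients)
    over the relative covariance parameters, starting from unit relative SDs
    and zero correlations unless ``start`` (e.g. a previous optimum, for warm
    starts) is given. Non-convergence triggers seeded jittered restarts and,
    failing that, is flagged on the result rather than raised. Singular fits
    (a variance estimated at zero) are legitimate and flagged.
    """
    design = _Design(spec, data)
    if design.n_theta == 0:
        dev, beta, u, r2, *_ = design.solve(np.zeros(0))
        sigma = float(np.sqrt(r2 / design.n))
        return LMMFit(
            spec=spec,
            beta=pd.Series(beta, index=design.fixed_names),
            sigma=sigma,
            theta=np.zeros(0),
            log_likelihood=-0.5 * dev,
            blups={},
            var_components={},
            fitted=design.X @ beta,
            residuals=design.y - design.X @ beta,
            n_obs=design.n,
            converged=True,
            singular=False,
            n_evaluations=1,
        )
    rng = np.random.default_rng(seed)
    theta0 = design.theta_start() if start is None else np.asarray(start, dtype=float)
    bounds = design.theta_bounds()
    for i, (lo, _) in enumerate(bounds):
        if lo == 0.0 and theta0[i] < 0:
            theta0[i] = 0.0

    def _projected_grad_norm(x: np.ndarray, g: np.ndarray) -> float:
        pg = g.copy()
        at_lower = np.array([b[0] == 0.0 for b in bounds]) & (x <= 1e-12)
        pg[at_lower & (pg > 0)] = 0.0
        return float(np.max(np.abs(pg))) if pg.size else 0.0

    best = None
    best_ok = False
    n_eval = 0
    message = ""
    for attempt in range(n_restarts + 1):
        res = optimize.minimize(
            design.deviance_and_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-4, "maxcor": 30},
        )
        n_eval += res.nfev
        # the line-search occasionally aborts on a flat boundary with the
        # optimum effectively reached; accept when the projected gradient of
        # the deviance is negligible
        ok = bool(res.success) or _projected_grad_norm(res.x, res.jac) < 1e-2
        if best is None or res.fun < best.fun - 1e-10:
            best, best_ok = res, ok
        if ok:
            break
        message = str(res.message)
        theta0 = design.theta_start() * np.exp(rng.normal(0, 0.3, design.n_theta))
        theta0[[b[0] == 0.0 for b in bounds]] = np.abs(
            theta0[[b[0] == 0.0 for b in bounds]]
        )
    res = best
    theta = res.x
    dev, beta, u, r2, *_ = design.solve(theta)
    sigma = float(np.sqrt(r2 / design.n))
    blups, var_components, singular, b = _extract_components(design, theta, sigma, u)
    fitted = design.X @ beta + (design.Z @ b if design.q else 0.0)
    return LMMFit(
        spec=spec,
        beta=pd.Series(beta, index=design.fixed_names),
        sigma=sigma,
        theta=theta,
        log_likelihood=-0.5 * dev,
        blups=blups,
        var_components=var_components,
        fitted=np.asarray(fitted).ravel(),
        residuals=design.y - np.asarray(fitted).ravel(),
        n_obs=design.n,
        converged=bool(res.success),
        singular=singular,
        n_evaluations=n_eval,
        message=message if not res.success else "",
    )


# ---------------------------------------------------------------------------
# taxon-slope permutation inference
# ---------------------------------------------------------------------------


@dataclass
class SlopePermutationResult:
    """Full-null and per-predictor permutation tests of taxon-specific slopes."""

    full_null: PermTestResult | None
    per_predictor: dict[str, PermTestResult]
    n_failed: int = 0


def taxon_slope_permutation_test(
    data: pd.DataFrame,
    spec: LMMSpec | None = None,
    permutations: int = 1000,
    seed: int | None = None,
    predictors: Sequence[str] | None = None,
    include_full_null: bool = True,
    control_predictors: Sequence[str] = (CONTROL_PREDICTOR,),
    max_failure_rate: float = 0.05,
    refit_tol: float = 1e-7,
) -> SlopePermutationResult:
    """Permutation test of the taxon-specific random slopes.

    The statistic is ``logLik(full) - logLik(reduced)``. The full-null
    reduced model drops all test-predictor slopes from the within-taxon term
    (the control predictor's slope is retained); each per-predictor reduced
    model drops only that predictor's slope. The observed data counts as
    permutation 1 of ``permutations``; the remaining datasets shuffle taxon
    labels within samples. ``p = #{statistic >= observed} / permutations``,
    flooring at ``1/permutations``. One shared permutation sequence serves
    all reductions.

    Every refit — observed and permuted alike — starts the optimizer from
    the same data-independent point: the statistic must be the identical
    function of every relabelled dataset for the permutation distribution to
    be exchangeable, and warm-starting permuted refits from a previous
    optimum measurably biases their statistics low (a liberal test).
    Non-converged refits are dropped with a warning; more than
    ``max_failure_rate`` failures aborts the test.
    """
    if spec is None:
        spec = composition_model_spec()
    taxon_term = next((t for t in spec.random if t.group == "taxon_id"), None)
    if taxon_term is None:
        raise ValueError("spec has no within-taxon random term")
    test_slopes = tuple(s for s in taxon_term.slopes if s not in control_predictors)
    if predictors is None:
        predictors = test_slopes
    unknown = [p for p in predictors if p not in test_slopes]
    if unknown:
        raise ValueError(f"predictors without a within-taxon test slope: {unknown}")

    models: dict[str, LMMSpec] = {}
    if include_full_null:
        models["full_null"] = spec.drop_taxon_slopes(test_slopes)
    for p in predictors:
        models[p] = spec.drop_taxon_slopes([p])

    rng = np.random.default_rng(seed)
    stats: dict[str, list[float]] = {name: [] for name in models}
    n_failed = 0

    current = data
    for it in range(permutations):
        if it > 0:
            current = permute_taxa_within_sample(data, rng=rng)
        full_fit = fit_lmm(spec, current, seed=it, tol=refit_tol)
        ok = full_fit.converged
        reduced_ll = {}
        for name, mspec in models.items():
            rfit = fit_lmm(mspec, current, seed=it, tol=refit_tol)
            if not rfit.converged:
                ok = False
            reduced_ll[name] = rfit.log_likelihood
        if not ok:
            n_failed += 1
            continue
        for name in models:
            stats[name].append(full_fit.log_likelihood - reduced_ll[name])

    if n_failed:
        warnings.warn(f"{n_failed} of {permutations} permutation refits failed to converge")
        if n_failed > max_failure_rate * permutations:
            raise RuntimeError(
                f"{n_failed}/{permutations} permutation refits failed "
                f"(> {max_failure_rate:.0%})"
            )

    def _result(name: str) -> PermTestResult:
        values = np.asarray(stats[name])
        obs = values[0]
        m = len(values)
        p = float((values >= obs - 1e-10).sum()) / m
        return PermTestResult(float(obs), values[1:], p, m, seed)

    return SlopePermutationResult(
        full_null=_result("full_null") if include_full_null else None,
        per_predictor={p: _result(p) for p in predictors},
        n_failed=n_failed,
    )


def extract_top_blups(fit: LMMFit, predictor: str, k: int = 20) -> pd.DataFrame:
    """Taxa whose predictor effect deviates most from the population average.

    Ranks the within-taxon BLUPs of ``predictor`` by absolute value
    (descending), breaking ties by taxon identifier, and returns the top
    ``k`` with their signed values.
    """
    if "taxon_id" not in fit.blups:
        raise KeyError("fit has no within-taxon random term")
    frame = fit.blups["taxon_id"]
    if predictor not in frame.columns:
        raise KeyError(f"no within-taxon random slope for {predictor!r}")
    values = frame[predictor]
    order = sorted(values.index, key=lambda t: (-abs(values[t]), str(t)))
    top = values.loc[order[:k]]
    return pd.DataFrame({"taxon_id": top.index, "blup": top.to_numpy()}).reset_index(
        drop=True
    )


def vif(data: pd.DataFrame, covariates: Sequence[str]) -> pd.Series:
    """Variance inflation factors on the fixed-effects-only design.

    ``VIF_j = 1 / (1 - R2_j)`` where ``R2_j`` regresses covariate j on the
    remaining covariates plus an intercept. Exact collinearity yields ``inf``.
    """
    covariates = list(covariates)
    if len(covariates) < 2:
        raise ValueError("VIF needs at least two covariates")
    M = data[covariates].to_numpy(dtype=float)
    if np.any(np.ptp(M, axis=0) == 0):
        bad = [c for c, r in zip(covariates, np.ptp(M, axis=0)) if r == 0]
        raise ValueError(f"constant covariates: {bad}")
    out = {}
    for j, name in enumerate(covariates):
        others = np.column_stack([np.ones(len(M)), np.delete(M, j, axis=1)])
        target = M[:, j] - M[:, j].mean()
        coef, *_ = np.linalg.lstsq(others, M[:, j], rcond=None)
        resid = M[:, j] - others @ coef
        r2 = 1.0 - (resid @ resid) / (target @ target)
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def loio_stability(
    data: pd.DataFrame, spec: LMMSpec, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Leave-one-individual-out refits of the model.

    Returns the per-subset fixed-effect (plus sigma) estimates and the
    maximum absolute deviation of each parameter from the all-data fit.
    Non-converged subset refits are flagged in a ``converged`` column.
    """
    individuals = sorted(data["individual_id"].astype(str).unique())
    if len(individuals) < 3:
        raise ValueError("stability check needs at least 3 individuals")
    full = fit_lmm(spec, data, seed=seed)
    rows = []
    for ind in individuals:
        subset = data.loc[data["individual_id"].astype(str) != ind]
        fit = fit_lmm(spec, subset, start=full.theta, seed=seed)
        rows.append(
            {
                "left_out": ind,
                **fit.beta.to_dict(),
                "sigma": fit.sigma,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows).set_index("left_out")
    params = [*full.beta.index, "sigma"]
    reference = pd.Series({**full.beta.to_dict(), "sigma": full.sigma})
    deviations = (table[params] - reference).abs().max(axis=0)
    return table, deviations


# ---------------------------------------------------------------------------
# alpha-diversity models
# ---------------------------------------------------------------------------


@dataclass
class AlphaModelResult:
    fit: LMMFit
    lrt_table: pd.DataFrame
    full_null: tuple[float, int, float]  # (chi2, df, p)
    data: pd.DataFrame = field(repr=False)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot z-transform a constant predictor")
    return (x - x.mean()) / sd


def alpha_diversity_model(
    pd_values: pd.Series,
    metadata: pd.DataFrame,
    behavior: pd.DataFrame,
    climate: pd.DataFrame,
    log_response: bool = False,
    seed: int = 0,
) -> AlphaModelResult:
    """Mixed model for Faith's PD against diet, affiliation, and climate.

    The response is PD (optionally log-transformed, as appropriate for the
    RNA-derived active community). Affiliation rates are log-transformed —
    with an offset of half the smallest positive rate to admit zero months —
    to symmetrize their distribution; all predictors are then z-transformed.
    Random structure: intercept plus the slopes of all fixed effects within
    individual (uncorrelated components). Inference is by likelihood-ratio
    tests: the full model against a null without the four behavioral test
    predictors (df = 4), and drop-one reductions for every fixed effect
    (df = 1 each).
    """
    meta = metadata.set_index(metadata["sample_id"].astype(str))
    rows = []
    for sample, value in pd_values.items():
        if sample not in meta.index:
            raise KeyError(f"sample {sample!r} missing from metadata")
        m = meta.loc[sample]
        rows.append(
            {
                "sample_id": str(sample),
                "individual_id": str(m["individual_id"]),
                "month": int(m["month"]),
                "pd": float(value),
            }
        )
    frame = pd.DataFrame(rows)
    frame = frame.merge(behavior, on=["individual_id", "month"], how="left")
    if frame[list(BEHAVIOR_RATE_COLUMNS)].isna().any(axis=None):
        bad = frame.loc[frame[list(BEHAVIOR_RATE_COLUMNS)].isna().any(axis=1), "sample_id"]
        raise KeyError(f"samples without behavior rates: {sorted(bad)}")
    frame = frame.merge(climate[["month", "precipitation_mm"]], on="month", how="left")
    if frame["precipitation_mm"].isna().any():
        raise KeyError("months without climate data")

    if log_response:
        if (frame["pd"] <= 0).any():
            raise ValueError("log response requires strictly positive PD values")
        frame["response"] = np.log(frame["pd"])
    else:
        frame["response"] = frame["pd"]

    aff = frame["affiliation_rate"].to_numpy(dtype=float)
    positive = aff[aff > 0]
    offset = 0.5 * positive.min() if positive.size else 1.0
    frame["log_affiliation"] = np.log(aff + offset)

    predictors = ["fruit_rate", "leaf_rate", "flower_rate", "log_affiliation", CONTROL_PREDICTOR]
    test_predictors = predictors[:4]
    for p in predictors:
        frame[f"z_{p}"] = _zscore(frame[p].to_numpy(dtype=float))
    z_predictors = [f"z_{p}" for p in predictors]

    spec = LMMSpec(
        fixed=tuple(z_predictors),
        random=(RandomTerm("individual_id", tuple(z_predictors), correlated=False),),
        response="response",
    )
    full = fit_lmm(spec, frame, seed=seed)

    def _lrt(reduced_fixed: tuple[str, ...], df: int) -> tuple[float, int, float]:
        rspec = replace(spec, fixed=reduced_fixed)
        rfit = fit_lmm(rspec, frame, seed=seed)
        stat = max(0.0, 2.0 * (full.log_likelihood - rfit.log_likelihood))
        return stat, df, float(chi2.sf(stat, df)) if df > 0 else 1.0

    z_tests = [f"z_{p}" for p in test_predictors]
    null_fixed = tuple(c for c in z_predictors if c not in z_tests)
    full_null = _lrt(null_fixed, len(z_tests))

    lrt_rows = []
    for p in z_predictors:
        stat, df, pval = _lrt(tuple(c for c in z_predictors if c != p), 1)
        lrt_rows.append(
            {"predictor": p, "estimate": full.beta[p], "chi2": stat, "df": df, "p_value": pval}
        )
    return AlphaModelResult(
        fit=full,
        lrt_table=pd.DataFrame(lrt_rows),
        full_null=full_null,
        data=frame,
    )
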