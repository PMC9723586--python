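import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import longgut as lg
from longgut.lmm import (
    CONTROL_PREDICTOR,
    TEST_PREDICTORS,
    LMMSpec,
    RandomTerm,
    _Design,
    alpha_diversity_model,
    build_long_table,
    composition_model_spec,
    extract_top_blups,
    fit_lmm,
    loio_stability,
    permute_taxa_within_sample,
    taxon_slope_permutation_test,
    vif,
)

from conftest import dense_mvn_loglik, gaussian_lmm_data


def crossed_data(seed=0, n_g=6, n_h=5, n_rep=2):
    rng = np.random.default_rng(seed)
    rows = list(itertools.product(range(n_g), range(n_h), range(n_rep)))
    df = pd.DataFrame(rows, columns=["gi", "hi", "rep"])
    df["g"] = "g" + df["gi"].astype(str)
    df["h"] = "h" + df["hi"].astype(str)
    df["x"] = rng.normal(size=len(df))
    df["y"] = (
        0.3
        + rng.normal(0, 0.8, n_g)[df["gi"]]
        + rng.normal(0, 0.5, n_h)[df["hi"]]
        + df["x"] * rng.normal(0, 0.3, n_g)[df["gi"]]
        + rng.normal(0, 0.6, len(df))
    )
    return df


SPECS = {
    "intercept_only": LMMSpec(("x",), (RandomTerm("g", ()),), response="y"),
    "correlated_slope": LMMSpec(("x",), (RandomTerm("g", ("x",), correlated=True),), response="y"),
    "uncorrelated_slope": LMMSpec(("x",), (RandomTerm("g", ("x",), correlated=False),), response="y"),
}


class TestEngineOracle:
    def test_no_random_terms_equals_ols(self):
        df = gaussian_lmm_data(seed=1)
        fit = fit_lmm(LMMSpec(("x",), (), response="y"), df)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        beta, *_ = np.linalg.lstsq(X, df["y"], rcond=None)
        rss = float(((df["y"] - X @ beta) ** 2).sum())
        n = len(df)
        ll_ols = -0.5 * (n * np.log(2 * np.pi * rss / n) + n)
        assert fit.log_likelihood == pytest.approx(ll_ols, abs=1e-8)
        np.testing.assert_allclose(fit.beta.to_numpy(), beta, atol=1e-8)

    @pytest.mark.parametrize("spec_name", list(SPECS))
    def test_deviance_matches_dense_mvn(self, spec_name):
        """At arbitrary covariance parameters — not just the optimum — the
        profiled deviance equals the dense multivariate-normal evaluation."""
        df = gaussian_lmm_data(seed=2, n_groups=6, n_per=8)
        design = _Design(SPECS[spec_name], df)
        rng = np.random.default_rng(0)
        for _ in range(3):
            theta = np.abs(rng.normal(0.8, 0.3, design.n_theta))
            dev, *_ = design.solve(theta)
            assert -dev / 2 == pytest.approx(dense_mvn_loglik(design, theta), abs=1e-6)

    def test_crossed_design_matches_dense_mvn(self):
        df = crossed_data(seed=4)
        spec = LMMSpec(
            ("x",),
            (RandomTerm("g", ("x",), correlated=True), RandomTerm("h", ())),
            response="y",
        )
        design = _Design(spec, df)
        theta = np.array([0.9, 0.2, 0.4, 0.7])
        dev, *_ = design.solve(theta)
        assert -dev / 2 == pytest.approx(dense_mvn_loglik(design, theta), abs=1e-6)

    def test_analytic_gradient_matches_finite_differences(self):
        df = crossed_data(seed=5)
        spec = LMMSpec(
            ("x",),
            (RandomTerm("g", ("x",), correlated=True), RandomTerm("h", ())),
            response="y",
        )
        design = _Design(spec, df)
        theta = np.array([0.7, -0.1, 0.5, 0.6])
        _, grad = design.deviance_and_grad(theta)
        eps = 1e-6
        for k in range(len(theta)):
            e = np.zeros_like(theta)
            e[k] = eps
            num = (design.solve(theta + e)[0] - design.solve(theta - e)[0]) / (2 * eps)
            assert grad[k] == pytest.approx(num, abs=1e-4)

    def test_balanced_one_way_closed_form(self):
        """ML variance components of the balanced one-way layout have a
        closed form; the engine must reproduce the same maximum."""
        rng = np.random.default_rng(7)
        a, n = 10, 6
        groups = np.repeat([f"g{i}" for i in range(a)], n)
        y = np.repeat(rng.normal(0, 1.0, a), n) + rng.normal(0, 0.5, a * n)
        df = pd.DataFrame({"g": groups, "y": y})
        fit = fit_lmm(LMMSpec((), (RandomTerm("g", ()),), response="y"), df)

        means = df.groupby("g")["y"].mean().to_numpy()
        grand = y.mean()
        ssw = float(((y - np.repeat(means, n)) ** 2).sum())
        ssb = float(n * ((means - grand) ** 2).sum())
        sigma_e2 = ssw / (a * (n - 1))
        lam = ssb / a  # = sigma_e^2 + n * tau^2 at the ML optimum
        total = a * n
        ll = -0.5 * (
            total * np.log(2 * np.pi)
            + a * (n - 1) * np.log(sigma_e2)
            + a * np.log(lam)
            + (total - a)
            + a
        )
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-5)
        tau2 = (lam - sigma_e2) / n
        assert fit.var_components["g"]["sd"]["intercept"] ** 2 == pytest.approx(tau2, rel=1e-3)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        df = gaussian_lmm_data(seed=11)
        fit = fit_lmm(SPECS["correlated_slope"], df)
        sm = smf.mixedlm("y ~ x", df, groups=df["g"], re_formula="~x").fit(
            reml=False, method="lbfgs"
        )
        assert fit.log_likelihood >= sm.llf - 1e-4
        np.testing.assert_allclose(fit.beta.to_numpy(), sm.fe_params.to_numpy(), atol=1e-3)

    def test_matches_lme4(self, tmp_path):
        """Independent cross-check against R's reference implementation."""
        df = gaussian_lmm_data(seed=3, n_groups=8, n_per=12)
        fit = fit_lmm(SPECS["correlated_slope"], df)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(y ~ x + (1 + x | g), data = d, REML = FALSE)
            cat(sprintf("%.8f %.8f %.8f", logLik(m), fixef(m)[1], fixef(m)[2]))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ll, b0, b1 = map(float, out.stdout.split())
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-4)
        assert fit.beta["intercept"] == pytest.approx(b0, abs=1e-4)
        assert fit.beta["x"] == pytest.approx(b1, abs=1e-4)

    def test_nested_model_loglik_ordering(self, small_long_table):
        spec = composition_model_spec()
        reduced = spec.drop_taxon_slopes(TEST_PREDICTORS)
        full_fit = fit_lmm(spec, small_long_table)
        red_fit = fit_lmm(reduced, small_long_table)
        assert full_fit.log_likelihood >= red_fit.log_likelihood - 1e-4


class TestCompositionSpec:
    def test_structure(self):
        spec = composition_model_spec()
        assert len(spec.random) == 4
        by_group = {t.group: t for t in spec.random}
        assert by_group["taxon_id"].k == 6 and by_group["taxon_id"].correlated
        assert by_group["individual_id"].k == 6 and not by_group["individual_id"].correlated
        assert "flower_rate" not in by_group["taxon_individual"].slopes
        assert by_group["taxon_individual"].k == 5
        assert by_group["sample_id"].k == 1
        assert spec.fixed == (*TEST_PREDICTORS, CONTROL_PREDICTOR)


class TestBuildLongTable:
    def test_join_arity_and_sample_constant_covariates(self, small_bundle):
        clr = lg.clr_transform(lg.to_proportions(small_bundle.table))
        data = build_long_table(
            clr, small_bundle.metadata, small_bundle.behavior, small_bundle.climate
        )
        assert len(data) == len(clr)
        per_sample = data.groupby("sample_id")[list(lg.core.BEHAVIOR_RATE_COLUMNS)].nunique()
        assert (per_sample == 1).all(axis=None)

    def test_covariates_match_behavior_cells(self, small_bundle, small_long_table):
        merged = small_long_table.merge(
            small_bundle.behavior,
            on=["individual_id", "month"],
            suffixes=("", "_ref"),
        )
        for col in lg.core.BEHAVIOR_RATE_COLUMNS:
            np.testing.assert_allclose(merged[col], merged[f"{col}_ref"])

    def test_missing_behavior_cell_errors(self, small_bundle):
        clr = lg.clr_transform(lg.to_proportions(small_bundle.table))
        behavior = small_bundle.behavior.iloc[:-1]
        with pytest.raises(KeyError, match="behavior"):
            build_long_table(clr, small_bundle.metadata, behavior, small_bundle.climate)


class TestPermuteTaxaWithinSample:
    def test_single_taxon_sample_unchanged(self):
        data = pd.DataFrame(
            {
                "sample_id": ["s1"],
                "taxon_id": ["t1"],
                "individual_id": ["I1"],
                "clr": [0.5],
            }
        )
        out = permute_taxa_within_sample(data, seed=0)
        assert out["taxon_id"].tolist() == ["t1"]

    def test_preserves_sample_response_multiset(self, small_long_table):
        out = permute_taxa_within_sample(small_long_table, seed=1)
        key = lambda d: sorted(zip(d["sample_id"], d["clr"]))  # noqa: E731
        assert key(out) == key(small_long_table)
        assert sorted(out["taxon_id"]) == sorted(small_long_table["taxon_id"])

    def test_uniform_over_permutations(self):
        data = pd.DataFrame(
            {
                "sample_id": ["s1"] * 3,
                "taxon_id": ["a", "b", "c"],
                "individual_id": ["I1"] * 3,
                "clr": [1.0, 2.0, 3.0],
            }
        )
        rng = np.random.default_rng(0)
        counts = {}
        n_rep = 1200
        for _ in range(n_rep):
            out = permute_taxa_within_sample(data, rng=rng)
            counts[tuple(out["taxon_id"])] = counts.get(tuple(out["taxon_id"]), 0) + 1
        assert len(counts) == 6
        se = np.sqrt((1 / 6) * (5 / 6) / n_rep)
        for v in counts.values():
            assert abs(v / n_rep - 1 / 6) < 3 * se + 0.01


class TestSlopePermutationTest:
    def reduced_spec(self):
        return LMMSpec(
            fixed=("fruit_rate",),
            random=(RandomTerm("taxon_id", ("fruit_rate",), correlated=True),),
        )

    def planted_data(self, tau=0.5, seed=7):
        cfg = lg.SynthConfig(
            n_individuals=5,
            n_months=6,
            samples_per_month=1,
            n_taxa=8,
            tau={**{p: 0.0 for p in lg.simulate.PREDICTORS}, "fruit_rate": tau},
            seed=seed,
        )
        bundle = lg.generate_study(cfg)
        clr = lg.clr_transform(lg.to_proportions(bundle.table))
        return build_long_table(clr, bundle.metadata, bundle.behavior, bundle.climate)

    def test_degenerate_reduction_gives_p_one(self):
        data = self.planted_data(tau=0.0, seed=1)
        spec = LMMSpec(
            fixed=("fruit_rate",),
            random=(RandomTerm("taxon_id", (), correlated=True),),
        )
        res = taxon_slope_permutation_test(
            data, spec=spec, permutations=20, seed=0, predictors=[], control_predictors=()
        )
        assert res.full_null.statistic_observed == pytest.approx(0.0, abs=1e-8)
        assert res.full_null.p_value == 1.0

    def test_overwhelming_effect_attains_floor(self):
        data = self.planted_data(tau=0.6)
        res = taxon_slope_permutation_test(
            data,
            spec=self.reduced_spec(),
            permutations=50,
            seed=3,
            predictors=[],
            control_predictors=(),
        )
        assert res.full_null.p_value == pytest.approx(1 / 50)
        assert res.full_null.statistic_observed > max(res.full_null.null_statistics)

    def test_p_values_on_permutation_grid(self):
        data = self.planted_data(tau=0.1, seed=2)
        res = taxon_slope_permutation_test(
            data,
            spec=self.reduced_spec(),
            permutations=10,
            seed=1,
            predictors=["fruit_rate"],
            control_predictors=(),
        )
        for ptr in [res.full_null, *res.per_predictor.values()]:
            assert ptr.p_value in {k / ptr.n_permutations for k in range(1, ptr.n_permutations + 1)}


class TestBlups:
    def test_planted_opposite_effects_rank_first(self):
        cfg = lg.SynthConfig(n_taxa=10, seed=21)
        bundle = lg.generate_study(cfg)
        truth = bundle.truth.clr_slopes["fruit_rate"]
        clr = lg.clr_transform(lg.to_proportions(bundle.table))
        data = build_long_table(clr, bundle.metadata, bundle.behavior, bundle.climate)
        spec = LMMSpec(
            fixed=("fruit_rate", CONTROL_PREDICTOR),
            random=(
                RandomTerm("sample_id", ()),
                RandomTerm("taxon_id", ("fruit_rate",), correlated=True),
            ),
        )
        fit = fit_lmm(spec, data)
        top = extract_top_blups(fit, "fruit_rate", k=3)
        top_truth = truth.abs().sort_values(ascending=False).index[:3]
        assert len(set(top["taxon_id"]) & set(top_truth)) >= 2

    def test_k_larger_than_taxa_returns_all_sorted(self, small_long_table):
        spec = LMMSpec(
            fixed=("fruit_rate",),
            random=(RandomTerm("taxon_id", ("fruit_rate",), correlated=True),),
        )
        fit = fit_lmm(spec, small_long_table)
        out = extract_top_blups(fit, "fruit_rate", k=999)
        assert len(out) == small_long_table["taxon_id"].nunique()
        mags = out["blup"].abs().to_numpy()
        assert np.all(np.diff(mags) <= 1e-12)

    def test_missing_slope_errors(self, small_long_table):
        spec = LMMSpec(
            fixed=("fruit_rate",),
            random=(RandomTerm("taxon_id", (), correlated=True),),
        )
        fit = fit_lmm(spec, small_long_table)
        with pytest.raises(KeyError):
            extract_top_blups(fit, "fruit_rate")


class TestVIF:
    def test_orthogonal_covariates_unit_vif(self):
        data = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        out = vif(data, ["a", "b"])
        np.testing.assert_allclose(out, 1.0, atol=1e-12)

    def test_known_correlation_closed_form(self):
        rng = np.random.default_rng(0)
        n = 20000
        a = rng.normal(size=n)
        b = 0.5 * a + np.sqrt(1 - 0.25) * rng.normal(size=n)
        out = vif(pd.DataFrame({"a": a, "b": b}), ["a", "b"])
        assert out["a"] == pytest.approx(4 / 3, abs=0.02)

    def test_duplicated_covariate_infinite(self):
        data = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8], "c": [1.0, 0, 1, 0]})
        out = vif(data, ["a", "b", "c"])
        assert np.isinf(out["a"]) and np.isinf(out["b"])


class TestLoioStability:
    def test_arity_and_near_zero_deviation_for_exchangeable_data(self):
        cfg = lg.SynthConfig(
            n_taxa=8,
            n_months=6,
            samples_per_month=1,
            individual_sd=0.0,
            seed=13,
        )
        bundle = lg.generate_study(cfg)
        clr = lg.clr_transform(lg.to_proportions(bundle.table))
        data = build_long_table(clr, bundle.metadata, bundle.behavior, bundle.climate)
        spec = LMMSpec(
            fixed=("fruit_rate",),
            random=(RandomTerm("taxon_id", ("fruit_rate",), correlated=True),),
        )
        table, deviations = loio_stability(data, spec)
        assert len(table) == cfg.n_individuals
        assert table["converged"].all()
        assert deviations["fruit_rate"] < 0.1


class TestAlphaModel:
    def simulate_pd(self, bundle, flower_beta=0.0, seed=0):
        """PD values drawn from the alpha analysis model itself."""
        rng = np.random.default_rng(seed)
        meta = bundle.metadata.merge(bundle.behavior, on=["individual_id", "month"])
        z = (meta["flower_rate"] - meta["flower_rate"].mean()) / meta["flower_rate"].std(ddof=0)
        intercepts = dict(
            zip(
                meta["individual_id"].unique(),
                rng.normal(0, 0.3, meta["individual_id"].nunique()),
            )
        )
        pd_vals = (
            10.0
            + flower_beta * z
            + meta["individual_id"].map(intercepts)
            + rng.normal(0, 0.3, len(meta))
        )
        return pd.Series(pd_vals.to_numpy(), index=meta["sample_id"].to_numpy())

    def test_z_transform_contract(self, small_bundle):
        pd_vals = self.simulate_pd(small_bundle, seed=1)
        res = alpha_diversity_model(
            pd_vals, small_bundle.metadata, small_bundle.behavior, small_bundle.climate
        )
        for col in res.data.filter(like="z_").columns:
            assert res.data[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert res.data[col].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_planted_negative_flower_effect_recovered(self, small_bundle):
        pd_vals = self.simulate_pd(small_bundle, flower_beta=-1.0, seed=2)
        res = alpha_diversity_model(
            pd_vals, small_bundle.metadata, small_bundle.behavior, small_bundle.climate
        )
        row = res.lrt_table.set_index("predictor").loc["z_flower_rate"]
        assert row["estimate"] < 0
        assert row["p_value"] <= 0.05
        assert res.full_null[2] <= 0.05

    def test_log_response_requires_positive_pd(self, small_bundle):
        pd_vals = self.simulate_pd(small_bundle, seed=3) - 100.0
        with pytest.raises(ValueError):
            alpha_diversity_model(
                pd_vals,
                small_bundle.metadata,
                small_bundle.behavior,
                small_bundle.climate,
                log_response=True,
            )
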