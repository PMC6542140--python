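"""ABC machinery: priors, rejection, regression adjustment, posterior
summaries and the PCA goodness-of-fit check."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, norm

from fireant_demog.abc_inference import (
    PriorSpec,
    Prior,
    ReferenceTable,
    build_reference_table,
    draw_priors,
    goodness_of_fit_pca,
    posterior_summarize,
    prior_posterior_overlap,
    regression_adjust,
    reject,
    standardise,
    weighted_quantile,
)
from fireant_demog.coalescent_sim import SampleSpec
from fireant_demog.summary_stats import SummaryStatVector


def _vec(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"s{i}" for i in range(values.size)]
    return SummaryStatVector(names=list(names), values=values)


def _toy_reference(rng, n=400, n_stats=4):
    params = pd.DataFrame(
        {
            "N_N1": np.exp(rng.uniform(np.log(1e4), np.log(1e8), n)),
            "N_F": rng.uniform(1, 500, n),
        }
    )
    stats = pd.DataFrame(
        rng.normal(0, 1, (n, n_stats)), columns=[f"s{i}" for i in range(n_stats)]
    )
    return ReferenceTable(params=params, stats=stats, seed=0)


class TestPriors:
    def test_bounded_draws_respect_stated_ranges(self):
        df = draw_priors(PriorSpec(), 4000, seed=1)
        assert df["T_I"].between(0, 180).all()
        assert df["N_F"].between(1, 500).all()
        assert df["T_B"].between(0, 40).all()

    def test_event_order_constraint_holds(self):
        df = draw_priors(PriorSpec(), 4000, seed=2)
        assert (df["T_B"] <= df["T_I"]).all()
        assert (df["T_I"] <= df["T_D"]).all()

    def test_unconstrained_marginal_matches_configured_family(self):
        # N_N1 is not touched by the ordering constraint: log-uniform KS check
        df = draw_priors(PriorSpec(), 10000, seed=3)
        z = np.log(df["N_N1"])
        stat, p = kstest(z, "uniform", args=(np.log(1e4), np.log(1e8) - np.log(1e4)))
        assert p > 0.01

    def test_truncnorm_family_supported(self):
        prior = Prior("truncnorm", 0.0, 180.0, mean=90.0, sd=30.0)
        rng = np.random.default_rng(0)
        x = prior.draw(rng, 5000)
        assert ((x >= 0) & (x <= 180)).all()
        assert abs(x.mean() - 90) < 2.0

    def test_zero_mass_support_rejected(self):
        with pytest.raises(ValueError, match="zero-mass"):
            Prior("uniform", 5.0, 5.0)


class TestRejection:
    def test_retained_count_is_ceil_of_fraction(self, rng):
        ref = _toy_reference(rng, n=1000)
        idx, _ = reject(ref, _vec(np.zeros(4)), 0.01)
        assert len(idx) == 10
        idx, _ = reject(ref, _vec(np.zeros(4)), 0.0101)
        assert len(idx) == math.ceil(0.0101 * 1000)

    def test_exact_match_retained_at_distance_zero(self, rng):
        ref = _toy_reference(rng)
        obs = _vec(ref.stats.iloc[17].to_numpy(), list(ref.stats.columns))
        idx, dist = reject(ref, obs, 0.01)
        assert 17 in idx
        assert dist.min() == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_sort(self, rng):
        ref = _toy_reference(rng, n=300)
        obs = _vec(rng.normal(0, 1, 4), list(ref.stats.columns))
        idx, dist = reject(ref, obs, 0.05)
        stats = ref.stats.to_numpy()
        mad = np.median(np.abs(stats - np.median(stats, axis=0)), axis=0)
        z = stats / mad
        d = np.sqrt(((z - obs.values / mad) ** 2).sum(axis=1))
        expected = np.argsort(d, kind="stable")[: len(idx)]
        np.testing.assert_array_equal(idx, expected)
        assert np.all(np.diff(dist) >= 0)

    def test_constant_column_excluded_with_warning(self, rng):
        ref = _toy_reference(rng)
        ref.stats["s0"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            reject(ref, _vec(np.zeros(4), list(ref.stats.columns)), 0.05)

    def test_shrinking_tolerance_never_raises_mean_distance(self, rng):
        ref = _toy_reference(rng, n=800)
        obs = _vec(rng.normal(0, 1, 4), list(ref.stats.columns))
        means = []
        for tol in (0.2, 0.1, 0.05, 0.01):
            _, dist = reject(ref, obs, tol)
            means.append(dist.mean())
        assert means == sorted(means, reverse=True)


class TestRegressionAdjustment:
    def test_identical_statistics_leave_parameters_unchanged(self, rng):
        n = 50
        params = pd.DataFrame({"N_F": rng.uniform(1, 500, n)})
        stats = pd.DataFrame(np.ones((n, 3)), columns=list("abc"))
        obs = _vec(np.ones(3), list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            adjusted, w = regression_adjust(params, stats, obs, np.linspace(0.1, 1, n))
        pd.testing.assert_frame_equal(adjusted, params)
        assert w == pytest.approx(w[::-1].tolist() if False else w)  # weights valid
        assert w.sum() == pytest.approx(1.0)

    def test_exact_linear_relation_is_recovered(self, rng):
        n = 80
        s = rng.normal(0, 1, n)
        params = pd.DataFrame({"N_F": 100.0 + 30.0 * s})
        stats = pd.DataFrame({"a": s})
        obs = _vec([0.4], ["a"])
        adjusted, _ = regression_adjust(
            params, stats, obs, distances=np.abs(s - 0.4)
        )
        np.testing.assert_allclose(adjusted["N_F"], 100.0 + 30.0 * 0.4, atol=1e-9)

    def test_matches_weighted_normal_equations_oracle(self, rng):
        n = 120
        stats = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("abc"))
        params = pd.DataFrame(
            {"N_F": rng.uniform(1, 500, n), "N_N1": rng.uniform(1e4, 1e8, n)}
        )
        obs = _vec(rng.normal(0, 1, 3), list("abc"))
        dist = rng.uniform(0.1, 2.0, n)
        adjusted, w = regression_adjust(params, stats, obs, dist)
        # independent oracle: solve the weighted normal equations directly
        mad = np.median(np.abs(stats.to_numpy() - stats.median().to_numpy()), axis=0)
        x = stats.to_numpy() / mad - obs.values / mad
        design = np.column_stack([np.ones(n), x])
        ww = 1 - (dist / dist.max()) ** 2
        ww = np.where(ww > 0, ww, 0)
        ww = ww / ww.sum()
        wmat = np.diag(ww)
        beta = np.linalg.solve(
            design.T @ wmat @ design, design.T @ wmat @ params.to_numpy()
        )
        expected = beta[0] + (params.to_numpy() - design @ beta)
        np.testing.assert_allclose(adjusted.to_numpy(), expected, atol=1e-6)

    def test_logit_transform_keeps_support_and_needs_priors(self, rng):
        n = 120
        prior = PriorSpec()
        params = pd.DataFrame(
            {"N_F": rng.uniform(1, 500, n), "T_B": rng.uniform(0, 40, n)}
        )
        stats = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)})
        obs = _vec([3.0, -3.0], ["a", "b"])  # far outside: strong shift
        adjusted, _ = regression_adjust(
            params, stats, obs, rng.uniform(0.5, 1, n),
            prior_spec=prior, transform="logit",
        )
        assert adjusted["N_F"].between(1, 500).all()
        assert adjusted["T_B"].between(0, 40).all()
        with pytest.raises(ValueError, match="prior_spec"):
            regression_adjust(params, stats, obs, rng.uniform(0.5, 1, n),
                              transform="logit")

    def test_too_few_particles_skips_with_warning(self, rng):
        params = pd.DataFrame({"N_F": [1.0, 2.0, 3.0]})
        stats = pd.DataFrame(rng.normal(0, 1, (3, 5)))
        obs = _vec(np.zeros(5), [str(c) for c in stats.columns])
        stats.columns = obs.names
        with pytest.warns(UserWarning, match="too few"):
            adjusted, _ = regression_adjust(params, stats, obs, np.array([1.0, 2, 3]))
        pd.testing.assert_frame_equal(adjusted, params)


class TestPosteriorSummaries:
    def test_degenerate_particles(self):
        adj = pd.DataFrame({"N_F": [39.0] * 10})
        post = posterior_summarize(adj, np.full(10, 0.1))
        assert post.map_estimates["N_F"] == 39.0
        assert post.ci_low["N_F"] == post.ci_high["N_F"] == 39.0

    def test_gaussian_quantiles_match_closed_form(self, rng):
        x = rng.normal(10.0, 2.0, 20000)
        adj = pd.DataFrame({"p": x})
        post = posterior_summarize(adj, np.full(x.size, 1.0 / x.size))
        assert post.ci_low["p"] == pytest.approx(norm.ppf(0.025, 10, 2), abs=0.1)
        assert post.ci_high["p"] == pytest.approx(norm.ppf(0.975, 10, 2), abs=0.1)
        assert post.map_estimates["p"] == pytest.approx(10.0, abs=0.3)

    def test_weighted_quantile_equals_expanded_sample_oracle(self, rng):
        values = rng.normal(0, 1, 40)
        reps = rng.integers(1, 30, 40)
        weights = reps / reps.sum()
        expanded = np.repeat(values, reps)
        for q in (0.025, 0.5, 0.975):
            got = weighted_quantile(values, weights, q)
            exact = np.quantile(expanded, q, method="interpolated_inverted_cdf")
            assert got == pytest.approx(exact, abs=0.12)

    def test_requires_two_particles(self):
        with pytest.raises(ValueError, match="2 particles"):
            posterior_summarize(pd.DataFrame({"p": [1.0]}), np.array([1.0]))


class TestGoodnessOfFit:
    def test_centroid_scores_low_percentile(self, rng):
        stats = pd.DataFrame(rng.normal(0, 1, (500, 6)))
        stats.columns = [f"s{i}" for i in range(6)]
        obs = _vec(stats.mean(axis=0).to_numpy(), list(stats.columns))
        out = goodness_of_fit_pca(stats, obs, seed=0, fraction=0.5)
        assert out["percentile"] < 15

    def test_distant_outlier_scores_high_percentile(self, rng):
        stats = pd.DataFrame(rng.normal(0, 1, (500, 6)))
        stats.columns = [f"s{i}" for i in range(6)]
        obs = _vec(stats.mean(axis=0).to_numpy() + 10 * stats.std(axis=0).to_numpy(),
                   list(stats.columns))
        out = goodness_of_fit_pca(stats, obs, seed=0, fraction=0.5)
        assert out["percentile"] > 99

    def test_projection_reproduces_eigen_decomposition(self, rng):
        stats = pd.DataFrame(rng.normal(0, 1, (200, 4)) @ rng.normal(0, 1, (4, 4)))
        stats.columns = [f"s{i}" for i in range(4)]
        obs = _vec(np.zeros(4), list(stats.columns))
        out = goodness_of_fit_pca(stats, obs, seed=1, fraction=1.0, n_components=4)
        sub = stats.to_numpy()
        centred = sub - sub.mean(axis=0)
        cov = centred.T @ centred / (len(sub) - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        proj = centred @ evecs[:, order]
        # components agree up to sign
        for k in range(4):
            assert (
                np.allclose(out["coordinates"][:, k], proj[:, k], atol=1e-8)
                or np.allclose(out["coordinates"][:, k], -proj[:, k], atol=1e-8)
            )

    def test_too_few_vectors_rejected(self, rng):
        stats = pd.DataFrame(rng.normal(0, 1, (2, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match=">= 3"):
            goodness_of_fit_pca(stats, _vec(np.zeros(3), list("abc")), seed=0,
                                fraction=1.0)


class TestEndToEndABC:
    def test_reference_table_smoke_and_determinism(self):
        spec = SampleSpec(samples={"N1": 4, "N2": 4, "I": 4}, n_loci=30)
        a = build_reference_table(PriorSpec(), spec, 10, seed=5)
        b = build_reference_table(PriorSpec(), spec, 10, seed=5)
        assert len(a) == 10
        pd.testing.assert_frame_equal(a.params, b.params)
        pd.testing.assert_frame_equal(a.stats, b.stats)

    def test_founder_size_prior_shift_moves_introduced_diversity(self):
        spec = SampleSpec(samples={"N1": 4, "N2": 4, "I": 6}, n_loci=60)
        means = {}
        for lo, hi in ((1.0, 20.0), (400.0, 500.0)):
            prior = PriorSpec(
                priors={"N_F": Prior("uniform", lo, hi), "T_B": Prior("uniform", 30, 40)}
            )
            ref = build_reference_table(prior, spec, 150, seed=9)
            means[(lo, hi)] = ref.stats["I_mean_gene_div_all"].mean()
        assert means[(1.0, 20.0)] < means[(400.0, 500.0)]

    def test_uninformative_parameter_overlaps_its_prior(self, rng):
        """Parameters the data carry no information on keep a posterior
        close to the prior (overlap coefficient near 1)."""
        prior = rng.uniform(0, 180, 4000)
        posterior = rng.uniform(0, 180, 300)
        informative = rng.normal(40, 5, 300)
        assert prior_posterior_overlap(prior, posterior) > 0.85
        assert prior_posterior_overlap(prior, informative) < 0.4
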