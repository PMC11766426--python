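"""Latent-class model: sampler correctness, derived-metric identities,
convergence diagnostics."""

import logging

import numpy as np
import pandas as pd
import pytest

from descent_dta.errors import ConfigurationError, SchemaError
from descent_dta.lca import (
    LCAConfig,
    LCAPosterior,
    derive_metrics,
    diagnostics,
    effective_sample_size,
    geweke_z,
    gibbs_lca,
    log_likelihood,
)
from descent_dta.synthetic import simulate_binary_tests

SHORT = LCAConfig(burn_in=500, iterations=4_500, thinning=4, rng_seed=0)

# study operating points used as simulation truth
TRUTH_SENS = {"EP": 0.784, "MRI": 0.743, "TPUS": 0.653, "EVUS": 0.582}
TRUTH_SPEC = {"EP": 0.730, "MRI": 0.762, "TPUS": 0.762, "EVUS": 0.775}
TRUTH_PREV = 0.55


def make_posterior(prevalence, sens, spec, names=("A",)):
    """Assemble an LCAPosterior from explicit draw arrays."""
    sens = np.atleast_2d(np.asarray(sens, dtype=float).T).reshape(len(prevalence), -1)
    spec = np.atleast_2d(np.asarray(spec, dtype=float).T).reshape(len(prevalence), -1)
    theta = np.stack([1.0 - spec, sens], axis=2)
    return LCAPosterior(
        test_names=list(names),
        prevalence=np.asarray(prevalence, dtype=float),
        theta=theta,
    )


class TestConfig:
    def test_default_retained_draw_count(self):
        assert LCAConfig().n_retained == 4750

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            LCAConfig(burn_in=10, iterations=10).validate()
        with pytest.raises(ConfigurationError):
            LCAConfig(thinning=0).validate()
        with pytest.raises(ConfigurationError):
            LCAConfig(prior_prevalence=(0.0, 1.0)).validate()


class TestGibbs:
    def test_perfectly_separated_classes(self):
        matrix = pd.DataFrame(
            np.vstack([np.ones((100, 4)), np.zeros((100, 4))]),
            columns=["EP", "MRI", "TPUS", "EVUS"],
        )
        post = gibbs_lca(matrix, SHORT)
        table = derive_metrics(post).set_index(["test", "metric"])
        assert table.loc[("(cohort)", "prevalence"), "mean"] == pytest.approx(0.5, abs=0.03)
        for t in ["EP", "MRI", "TPUS", "EVUS"]:
            assert table.loc[(t, "sensitivity"), "mean"] > 0.95
            assert table.loc[(t, "specificity"), "mean"] > 0.95

    def test_retained_draw_count_matches_config(self):
        _, matrix = simulate_binary_tests(80, 0.5, TRUTH_SENS, TRUTH_SPEC, rng_seed=1)
        cfg = LCAConfig(burn_in=100, iterations=1_100, thinning=7, rng_seed=2)
        post = gibbs_lca(matrix, cfg)
        assert post.n_draws == cfg.n_retained == 1000 // 7

    def test_deterministic_given_seed(self):
        _, matrix = simulate_binary_tests(60, 0.5, TRUTH_SENS, TRUTH_SPEC, rng_seed=3)
        cfg = LCAConfig(burn_in=50, iterations=550, thinning=5, rng_seed=9)
        p1 = gibbs_lca(matrix, cfg)
        p2 = gibbs_lca(matrix, cfg)
        np.testing.assert_array_equal(p1.prevalence, p2.prevalence)
        np.testing.assert_array_equal(p1.theta, p2.theta)

    def test_parameter_recovery_at_n1000(self):
        """Posterior means recover the generating parameters and the 95% CrIs
        cover them (single replicate; the replicated coverage study runs in
        the acceptance suite)."""
        _, matrix = simulate_binary_tests(
            1000, TRUTH_PREV, TRUTH_SENS, TRUTH_SPEC, rng_seed=7
        )
        post = gibbs_lca(matrix, SHORT)
        table = derive_metrics(post).set_index(["test", "metric"])
        prev = table.loc[("(cohort)", "prevalence")]
        assert prev["mean"] == pytest.approx(TRUTH_PREV, abs=0.07)
        assert prev["cri_low"] <= TRUTH_PREV <= prev["cri_high"]
        for t in TRUTH_SENS:
            for metric, truth in (
                ("sensitivity", TRUTH_SENS[t]),
                ("specificity", TRUTH_SPEC[t]),
            ):
                row = table.loc[(t, metric)]
                assert row["mean"] == pytest.approx(truth, abs=0.07)
                assert row["cri_low"] <= truth <= row["cri_high"]

    def test_relabelling_keeps_diseased_class_more_positive(self):
        _, matrix = simulate_binary_tests(150, 0.5, TRUTH_SENS, TRUTH_SPEC, rng_seed=4)
        post = gibbs_lca(matrix, SHORT)
        mean_pos = post.theta.mean(axis=1)  # (draws, 2)
        assert (mean_pos[:, 1] >= mean_pos[:, 0]).all()

    def test_symmetric_noise_gives_half_prevalence(self):
        """Two noninformative tests on a pattern-balanced cohort: by symmetry
        the prevalence posterior centres on 1/2."""
        patterns = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        matrix = pd.DataFrame(np.repeat(patterns, 25, axis=0), columns=["A", "B"])
        post = gibbs_lca(matrix, SHORT)
        assert post.prevalence.mean() == pytest.approx(0.5, abs=0.08)

    def test_seed_invariance_of_summaries(self):
        _, matrix = simulate_binary_tests(400, 0.6, TRUTH_SENS, TRUTH_SPEC, rng_seed=5)
        means = []
        for seed in (1, 2):
            post = gibbs_lca(matrix, LCAConfig(
                burn_in=500, iterations=6_500, thinning=4, rng_seed=seed
            ))
            means.append(
                np.concatenate([
                    [post.prevalence.mean()],
                    post.sensitivity.mean(axis=0),
                    post.specificity.mean(axis=0),
                ])
            )
        np.testing.assert_allclose(means[0], means[1], atol=0.03)

    def test_missing_entries_are_ignored_not_imputed(self):
        """Making one test entirely missing for half the cohort leaves the
        other tests' estimates close to the complete-data run."""
        _, matrix = simulate_binary_tests(400, 0.55, TRUTH_SENS, TRUTH_SPEC, rng_seed=6)
        holed = matrix.copy()
        holed.iloc[:200, holed.columns.get_loc("MRI")] = np.nan
        post = gibbs_lca(holed, SHORT)
        full = gibbs_lca(matrix, SHORT)
        np.testing.assert_allclose(
            post.sensitivity.mean(axis=0), full.sensitivity.mean(axis=0), atol=0.1
        )

    def test_patient_with_no_observations_rejected(self):
        matrix = pd.DataFrame({"A": [1.0, np.nan], "B": [0.0, np.nan]})
        with pytest.raises(SchemaError):
            gibbs_lca(matrix, SHORT)

    def test_single_test_rejected(self):
        with pytest.raises(SchemaError):
            gibbs_lca(pd.DataFrame({"A": [1.0, 0.0]}), SHORT)

    def test_constant_test_warns_but_proceeds(self, caplog):
        matrix = pd.DataFrame({"A": [1.0] * 30, "B": [0.0, 1.0] * 15})
        with caplog.at_level(logging.WARNING, logger="descent_dta.lca"):
            post = gibbs_lca(matrix, LCAConfig(burn_in=50, iterations=550,
                                               thinning=5, rng_seed=0))
        assert "no variation" in caplog.text
        assert post.n_draws == 100

    def test_marginal_likelihood_matches_pattern_enumeration(self):
        """On complete 2-test data the likelihood factorises over the 4
        response patterns; direct enumeration must agree."""
        _, matrix = simulate_binary_tests(
            200, 0.55,
            {"A": 0.8, "B": 0.7}, {"A": 0.75, "B": 0.8},
            rng_seed=8,
        )
        post = gibbs_lca(matrix, SHORT)
        pi = post.prevalence.mean()
        theta = post.theta.mean(axis=0)  # (tests, 2)
        impl = log_likelihood(matrix, pi, theta)

        counts = matrix.value_counts()
        oracle = 0.0
        for (a, b), count in counts.items():
            p = 0.0
            for c, w in ((0, 1 - pi), (1, pi)):
                pa = theta[0, c] if a == 1 else 1 - theta[0, c]
                pb = theta[1, c] if b == 1 else 1 - theta[1, c]
                p += w * pa * pb
            oracle += count * np.log(p)
        assert impl == pytest.approx(oracle, abs=1e-8)


class TestDeriveMetrics:
    def test_ppv_npv_formula_values(self):
        post = make_posterior([0.5], [0.8], [0.75])
        table = derive_metrics(post).set_index(["test", "metric"])
        assert table.loc[("A", "ppv"), "mean"] == pytest.approx(0.762, abs=5e-4)
        assert table.loc[("A", "npv"), "mean"] == pytest.approx(0.789, abs=5e-4)

    def test_likelihood_ratio_values(self):
        post = make_posterior([0.5], [0.8], [0.75])
        table = derive_metrics(post).set_index(["test", "metric"])
        assert table.loc[("A", "lr_pos"), "mean"] == pytest.approx(3.2)
        assert table.loc[("A", "lr_neg"), "mean"] == pytest.approx(0.267, abs=5e-4)
        assert table.loc[("A", "auc"), "mean"] == pytest.approx(0.775)

    def test_perfect_test_draw(self):
        post = make_posterior([0.5], [1.0], [1.0])
        table = derive_metrics(post).set_index(["test", "metric"])
        assert table.loc[("A", "ppv"), "mean"] == 1.0
        assert table.loc[("A", "npv"), "mean"] == 1.0
        assert table.loc[("A", "lr_neg"), "mean"] == 0.0
        assert table.loc[("A", "auc"), "mean"] == 1.0

    def test_infinite_lr_excluded_from_mean_kept_in_percentiles(self):
        post = make_posterior(
            [0.5, 0.5, 0.5, 0.5],
            [0.8, 0.8, 0.8, 0.8],
            [1.0, 0.75, 0.75, 0.75],  # one spec=1 draw -> LR+ = inf
        )
        table = derive_metrics(post).set_index(["test", "metric"])
        lr = table.loc[("A", "lr_pos")]
        assert np.isfinite(lr["mean"])
        assert lr["mean"] == pytest.approx(3.2)
        assert lr["cri_high"] == np.inf

    def test_cri_brackets_point_estimate(self):
        rng = np.random.default_rng(0)
        post = make_posterior(
            rng.uniform(0.4, 0.6, 200),
            rng.uniform(0.6, 0.9, 200),
            rng.uniform(0.6, 0.9, 200),
        )
        table = derive_metrics(post)
        finite = table[np.isfinite(table["mean"])]
        assert (finite["cri_low"] <= finite["mean"] + 1e-12).all()
        assert (finite["mean"] <= finite["cri_high"] + 1e-12).all()


class TestDiagnostics:
    def test_iid_chain_ess_near_n(self, rng):
        chain = rng.standard_normal(4000)
        assert effective_sample_size(chain) == pytest.approx(4000, rel=0.15)

    def test_ar1_chain_matches_closed_form(self, rng):
        # AR(1) with phi = 0.9: ESS -> n (1-phi)/(1+phi)
        phi, n = 0.9, 60_000
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        expected = n * (1 - phi) / (1 + phi)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.2)

    def test_constant_chain_flagged_degenerate(self):
        post = make_posterior([0.5] * 100, [0.8] * 100, [0.7] * 100)
        report = diagnostics(post).set_index("parameter")
        assert report["degenerate"].all()
        assert report["flagged"].all()

    def test_geweke_flags_drifting_chain(self):
        drift = np.linspace(0.2, 0.8, 2000)
        assert abs(geweke_z(drift)) > 3.0

    def test_healthy_sampler_chains_unflagged(self):
        _, matrix = simulate_binary_tests(300, 0.55, TRUTH_SENS, TRUTH_SPEC, rng_seed=2)
        post = gibbs_lca(matrix, LCAConfig(
            burn_in=1000, iterations=21_000, thinning=4, rng_seed=1
        ))
        report = diagnostics(post)
        assert not report["flagged"].any()
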