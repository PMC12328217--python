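"""The ordinal probit mixed model: chain arithmetic, pMCMC, prediction,
backward elimination, calibration, and the multi-response morphospace model."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

import threatspace as ts
from threatspace.risk import CATEGORIES


@pytest.fixture(scope="module")
def quick_fit(decline_table):
    """A short-chain fit on a small world, for structural checks."""
    w = ts.generate_world(n_species=80, at_risk_fraction=1.0, seed=21)
    design = ts.build_design(w.threats, w.at_risk, decline_table)
    pc = ts.phylo_covariance(w.tree, 1.0)
    cfg = ts.OrdinalModelConfig(n_iterations=2_000, burn_in=500, thinning=15,
                                seed=2, bin_width=w.truth["bin_width"])
    samples = ts.fit_ordinal(design, pc, w.spatial,
                             w.categories.loc[w.at_risk], cfg)
    return w, design, pc, cfg, samples


class TestConfig:
    def test_default_chain_arithmetic(self):
        assert ts.OrdinalModelConfig().n_retained == 1000

    def test_invalid_chain_settings_rejected(self):
        with pytest.raises(ValueError):
            ts.OrdinalModelConfig(n_iterations=1000, burn_in=1000, thinning=10)
        with pytest.raises(ValueError):
            ts.OrdinalModelConfig(n_iterations=1050, burn_in=50, thinning=300)


class TestPmcmc:
    def test_one_sided_extremes(self):
        assert ts.pmcmc(np.ones(1000)) == 0.0
        assert ts.pmcmc(np.concatenate([np.ones(500), -np.ones(500)])) == 1.0

    def test_direct_count(self):
        draws = np.concatenate([np.ones(975), -np.ones(25)])
        assert ts.pmcmc(draws) == pytest.approx(0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ts.pmcmc(np.array([1.0]))


class TestFitOrdinal:
    def test_retained_draw_count(self, quick_fit):
        _, _, _, cfg, samples = quick_fit
        assert samples.n_draws == cfg.n_retained == 100

    def test_probability_rows_normalized(self, quick_fit):
        samples = quick_fit[-1]
        np.testing.assert_allclose(samples.cat.sum(axis=1), 1.0, atol=1e-12)

    def test_cutpoints_strictly_ascending_every_draw(self, quick_fit):
        samples = quick_fit[-1]
        assert (np.diff(samples.cutpoints, axis=1) > 0).all()
        np.testing.assert_array_equal(samples.cutpoints[:, 0], 0.0)

    def test_deterministic_under_seed(self, quick_fit):
        w, design, pc, cfg, samples = quick_fit
        again = ts.fit_ordinal(design, pc, w.spatial,
                               w.categories.loc[w.at_risk], cfg)
        np.testing.assert_array_equal(samples.beta, again.beta)
        np.testing.assert_array_equal(samples.cat, again.cat)

    def test_single_category_rejected(self, decline_table):
        design = pd.DataFrame({"1.1": [1.0, 2.0]}, index=["a", "b"])
        cats = pd.Series(["VU", "VU"], index=["a", "b"])
        with pytest.raises(ValueError):
            ts.fit_ordinal(design, None, None, cats,
                           ts.OrdinalModelConfig(use_phylo=False,
                                                 use_spatial=False))

    def test_unmodelled_category_rejected(self, decline_table):
        design = pd.DataFrame({"1.1": [1.0, 2.0]}, index=["a", "b"])
        cats = pd.Series(["VU", "LC"], index=["a", "b"])
        with pytest.raises(ValueError):
            ts.fit_ordinal(design, None, None, cats,
                           ts.OrdinalModelConfig(use_phylo=False,
                                                 use_spatial=False))


class TestPredictScenario:
    def test_identity_on_fitted_design(self, quick_fit):
        _, design, _, _, samples = quick_fit
        probs = ts.predict_scenario(samples, design)
        np.testing.assert_allclose(probs, samples.cat, atol=1e-12)

    def test_rows_sum_to_one(self, quick_fit):
        _, design, _, _, samples = quick_fit
        zeroed = design * 0.0
        probs = ts.predict_scenario(samples, zeroed)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_random_effects_persist_under_abatement(self, quick_fit):
        """A species with a large positive random effect keeps elevated CR
        probability even when every threat covariate is zeroed."""
        _, design, _, _, samples = quick_fit
        probs = ts.predict_scenario(samples, design * 0.0)
        mean_re = samples.random_sum.mean(axis=0)
        hot = int(np.argmax(mean_re))
        cr = probs[:, CATEGORIES.index("CR"), :].mean(axis=0)
        assert cr[hot] > cr.mean()

    def test_column_mismatch_rejected(self, quick_fit):
        _, design, _, _, samples = quick_fit
        with pytest.raises(ValueError):
            ts.predict_scenario(samples, design.iloc[:, :-1])


class TestAccuracy:
    def test_one_hot_truth_is_perfect(self):
        listed = pd.Series(["NT", "CR", "EN"])
        cat = np.zeros((5, 4, 3))
        for s, lab in enumerate(listed):
            cat[:, CATEGORIES.index(lab), s] = 1.0
        assert ts.classification_accuracy(cat, listed) == 1.0

    def test_uniform_probabilities_tie_break_to_higher_risk(self):
        # all categories equally likely -> the documented tie rule picks CR,
        # so accuracy equals the frequency of CR in the listed labels
        listed = pd.Series(["CR", "NT", "VU", "CR"])
        cat = np.full((10, 4, 4), 0.25)
        assert ts.classification_accuracy(cat, listed) == pytest.approx(0.5)

    def test_strong_signal_fit_beats_chance(self, fitted):
        w = fitted["world"]
        acc = ts.classification_accuracy(fitted["samples"],
                                         w.categories.loc[w.at_risk])
        assert acc > 0.5


class TestBackwardElimination:
    def test_all_significant_is_identity(self, fitted):
        """Refitting only the truly active covariates removes nothing."""
        w = fitted["world"]
        cfg = ts.OrdinalModelConfig(n_iterations=3_000, burn_in=1_000,
                                    thinning=20, seed=3,
                                    bin_width=w.truth["bin_width"])
        samples, kept, trail = ts.backward_eliminate(
            fitted["design"], fitted["pc"], w.spatial,
            w.categories.loc[w.at_risk], cfg)
        assert trail == []
        assert kept == list(fitted["design"].columns)

    def test_pure_noise_column_is_removed(self, decline_table):
        """A covariate with no true effect should be eliminated at close to
        the nominal 1 - threshold = 90% rate (binomial slack at 20 reps)."""
        hits = 0
        for rep in range(20):
            w = ts.generate_world(n_species=120, at_risk_fraction=1.0,
                                  seed=300 + rep, n_active=2, beta_scale=1.2,
                                  sigma2_phylo=0.0, sigma2_spatial=0.0)
            design = ts.build_design(w.threats, w.at_risk, decline_table)
            active = w.truth["active_columns"]
            noise = [c for c in design.columns if c not in active][0]
            cfg = ts.OrdinalModelConfig(n_iterations=3_000, burn_in=1_000,
                                        thinning=20, seed=rep,
                                        use_phylo=False, use_spatial=False)
            _, _, trail = ts.backward_eliminate(
                design[active + [noise]], None, None,
                w.categories.loc[w.at_risk], cfg)
            hits += noise in [c for c, _ in trail]
        assert hits >= 16

    def test_empty_design_reports_empty_model(self, decline_table):
        design = pd.DataFrame(index=["a", "b"])
        cats = pd.Series(["VU", "CR"], index=["a", "b"])
        cfg = ts.OrdinalModelConfig(use_phylo=False, use_spatial=False)
        samples, kept, trail = ts.backward_eliminate(design, None, None,
                                                     cats, cfg)
        assert samples is None and kept == []


def test_simulation_based_calibration():
    """Rank of the true coefficient within posterior draws is approximately
    uniform across replicates (truths drawn from the fitting prior)."""
    rng = np.random.default_rng(2024)
    cfg = ts.OrdinalModelConfig(n_iterations=3_000, burn_in=1_000,
                                thinning=50, use_phylo=False,
                                use_spatial=False, seed=0)
    M = cfg.n_retained
    ranks = []
    rep = 0
    while len(ranks) < 60:
        rep += 1
        beta_true = rng.standard_cauchy() * cfg.cauchy_scale
        x = rng.standard_normal(60)
        latent = x * beta_true + rng.standard_normal(60)
        codes = np.searchsorted([0.0, 0.9, 1.8], latent)
        cats = pd.Series(np.array(CATEGORIES)[codes],
                         index=[f"s{i}" for i in range(60)])
        if cats.nunique() < 2:
            continue
        design = pd.DataFrame({"1.1": x}, index=cats.index)
        s = ts.fit_ordinal(design, None, None, cats,
                           dataclasses.replace(cfg, seed=1000 + rep))
        # the fitted scale is the standardized-covariate scale
        ranks.append(int(np.sum(s.beta[:, 1] < beta_true * s.scale[0])))
    bins = np.floor(np.array(ranks) * 8 / (M + 1)).astype(int)
    obs = np.bincount(bins, minlength=8)
    assert chisquare(obs).pvalue > 0.01


class TestMultiResponse:
    @staticmethod
    def _simulate(rep, slope):
        tree = ts.generate_tree(100, seed=700 + rep)
        species = [l.taxon.label for l in tree.leaf_node_iter()]
        pc = ts.phylo_covariance(tree, 1.0)
        rng = np.random.default_rng(rep)
        x = rng.integers(0, 1001, 100).astype(float)
        L = np.linalg.cholesky(pc.matrix + 1e-10 * np.eye(100))
        def noise():
            return (L @ rng.standard_normal(100)) * 0.5 \
                + rng.standard_normal(100) * 0.5
        resp = pd.DataFrame(
            {"pPC1": slope * x + noise(), "pPC2": noise()}, index=species)
        cov = pd.DataFrame({"habitat loss and degradation": x}, index=species)
        return resp, cov, pc

    def test_planted_slope_recovered_and_null_calibrated(self):
        sig_hits = 0
        null_sig = 0
        cfg0 = ts.MultiResponseConfig(n_iterations=3_000, burn_in=1_000,
                                      thinning=20)
        for rep in range(20):
            resp, cov, pc = self._simulate(rep, slope=0.002)
            cfg = dataclasses.replace(cfg0, seed=rep)
            _, summary = ts.fit_multiresponse(resp, cov, pc, cfg)
            s1 = summary[summary.response == "pPC1"].iloc[0]
            s2 = summary[summary.response == "pPC2"].iloc[0]
            sig_hits += (s1["mean"] > 0) and (s1["pmcmc"] < 0.1)
            null_sig += s2["pmcmc"] < 0.1
        assert sig_hits >= 18          # planted effect found with its sign
        assert null_sig <= 7           # null flagged at roughly the 10% rate

    def test_duplicated_responses_give_identical_summaries(self):
        resp, cov, pc = self._simulate(0, slope=0.002)
        resp2 = resp.copy()
        resp2["pPC2"] = resp2["pPC1"]
        cfg = ts.MultiResponseConfig(n_iterations=1_000, burn_in=200,
                                     thinning=10, seed=4)
        slopes, summary = ts.fit_multiresponse(resp2, cov, pc, cfg)
        np.testing.assert_array_equal(slopes[:, :, 0], slopes[:, :, 1])

    def test_misaligned_inputs_rejected(self):
        resp, cov, pc = self._simulate(0, slope=0.0)
        with pytest.raises(ValueError):
            ts.fit_multiresponse(resp.iloc[::-1], cov, pc)
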