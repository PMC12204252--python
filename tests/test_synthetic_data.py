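"""Generator contracts: determinism, moments, ratings and outcome models."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
import statsmodels.api as sm

from ofc_biosig.bfmm import build_bspline_basis
from ofc_biosig.containers import condition_key
from ofc_biosig.phenotyping import hyperalgesia_threshold
from ofc_biosig.synthetic_data import (OutcomeModel, SimConfig,
                                       clbp_default_config,
                                       default_true_surface, generate_cohort,
                                       generate_outcomes, generate_ratings)


def zero_noise_config(**overrides):
    base = dict(n_per_group={"widespread_hyperalgesia": 2,
                             "localized_pain": 2},
                sigma_subject=0.0, sigma_subject_condition=0.0,
                sigma_noise=0.0,
                covariate_effects={"age": 0, "sex": 0, "pain_intensity": 0},
                seed=0)
    base.update(overrides)
    return SimConfig(**base)


class TestGenerateCohort:
    def test_degenerate_config_yields_all_zero_tfrs(self):
        cfg = zero_noise_config(group_condition_amplitudes={
            (g, condition_key(c)): 0.0
            for g in ("widespread_hyperalgesia", "localized_pain")
            for c in SimConfig.__dataclass_fields__["conditions"].default})
        ds, _ = generate_cohort(cfg)
        for s in ds.subjects:
            for tfr in s.tfrs.values():
                assert np.allclose(tfr.values, 0.0)

    def test_noiseless_amplitude_is_exact_multiple_of_surface(self):
        cfg = zero_noise_config()
        amps = {k: 0.0 for k in cfg.group_condition_amplitudes}
        amps[("widespread_hyperalgesia", "affected_high")] = 5.0
        cfg = zero_noise_config(group_condition_amplitudes=amps)
        ds, truth = generate_cohort(cfg)
        wide = [s for s in ds.subjects
                if s.phenotype == "widespread_hyperalgesia"]
        for s in wide:
            vals = s.tfrs[("mOFC-left", "affected_high")].values
            assert np.allclose(vals, 5.0 * truth.true_surface, atol=1e-12)

    def test_seed_determinism(self):
        a, _ = generate_cohort(clbp_default_config(seed=3))
        b, _ = generate_cohort(clbp_default_config(seed=3))
        c, _ = generate_cohort(clbp_default_config(seed=4))
        key = ("mOFC-left", "affected_high")
        assert np.array_equal(a.subjects[0].tfrs[key].values,
                              b.subjects[0].tfrs[key].values)
        assert not np.array_equal(a.subjects[0].tfrs[key].values,
                                  c.subjects[0].tfrs[key].values)
        pd.testing.assert_frame_equal(a.covariate_table(),
                                      b.covariate_table())

    def test_monte_carlo_mean_recovers_amplitude_times_surface(self):
        # per-cell mean over 200 subjects ~ 5 * surface within MC error
        amp = 5.0
        cfg = SimConfig(
            n_per_group={"widespread_hyperalgesia": 200},
            rois=("mOFC-left",),
            covariate_effects={"age": 0, "sex": 0, "pain_intensity": 0},
            group_condition_amplitudes={
                ("widespread_hyperalgesia", ck): amp for ck in
                ("affected_low", "affected_high", "unaffected_low",
                 "unaffected_high")},
            seed=21)
        ds, truth = generate_cohort(cfg)
        stack = np.stack([s.tfrs[("mOFC-left", "affected_high")].values
                          for s in ds.subjects])
        mean = stack.mean(axis=0)
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(ds))
        z = (mean - amp * truth.true_surface) / sem
        # ~0.3% of cells may exceed 3 SEM by chance alone
        assert (np.abs(z) > 3).mean() < 0.01

    def test_cellwise_variance_matches_basis_propagation(self, grid):
        # Var(cell) = (sig_s^2 + sig_sc^2) * ||basis row||^2 + sig_n^2
        cfg = SimConfig(
            n_per_group={"localized_pain": 400}, rois=("mOFC-left",),
            conditions=(("affected", "high"),),
            covariate_effects={"age": 0, "sex": 0, "pain_intensity": 0},
            group_condition_amplitudes={
                ("localized_pain", "affected_high"): 0.0},
            sigma_subject=0.7, sigma_subject_condition=0.4,
            sigma_noise=0.5, seed=22)
        ds, _ = generate_cohort(cfg)
        stack = np.stack([s.tfrs[("mOFC-left", "affected_high")].values
                          for s in ds.subjects])
        emp_var = stack.var(axis=0, ddof=1).ravel()
        basis = build_bspline_basis(grid)
        row_sq = (basis.tensor ** 2).sum(axis=1)
        theo = (0.7 ** 2 + 0.4 ** 2) * row_sq + 0.5 ** 2
        assert np.abs(emp_var / theo - 1).mean() < 0.10

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_per_group={})
        with pytest.raises(ValueError):
            SimConfig(n_per_group={"no_pain": 0})
        with pytest.raises(ValueError):
            SimConfig(n_per_group={"no_pain": 2}, sigma_noise=-1.0)
        with pytest.raises(ValueError):
            SimConfig(n_per_group={"no_pain": 2},
                      true_surface=np.ones((27, 45)))  # not unit norm


def test_default_surface_has_unit_norm_and_signed_bands(grid):
    S = default_true_surface(grid)
    assert np.linalg.norm(S) == pytest.approx(1.0)
    window = (grid.times >= 0.4) & (grid.times <= 0.7)
    delta_theta = (grid.freqs >= 1) & (grid.freqs <= 7)
    alpha = (grid.freqs >= 8) & (grid.freqs <= 12)
    assert S[np.ix_(window, delta_theta)].sum() > 0
    assert S[np.ix_(window, alpha)].sum() < 0


class TestGenerateRatings:
    def test_ratings_bounded_and_deterministic(self):
        cfg = clbp_default_config(seed=5)
        phen = {f"s{i}": g for i, g in enumerate(
            ["no_pain", "localized_pain", "widespread_hyperalgesia"] * 4)}
        r1 = generate_ratings(cfg, phen)
        r2 = generate_ratings(cfg, phen)
        pd.testing.assert_frame_equal(r1, r2)
        assert r1["rating"].between(0, 10).all()

    def test_degenerate_controls_rate_zero(self):
        cfg = clbp_default_config(seed=5)
        cfg.rating_model = {("no_pain", ck): (0.0, 0.0) for ck in
                            ("affected_low", "affected_high",
                             "unaffected_low", "unaffected_high")}
        out = generate_ratings(cfg, {"c1": "no_pain", "c2": "no_pain"})
        assert (out["rating"] == 0).all()

    def test_full_separation_classifies_every_widespread(self):
        # zero rating noise, widespread far above the control threshold
        cfg = clbp_default_config(seed=6)
        model = {}
        for ck in ("affected_low", "affected_high", "unaffected_low",
                   "unaffected_high"):
            model[("no_pain", ck)] = (1.0, 0.0)
            model[("widespread_hyperalgesia", ck)] = (3.0, 0.0)
        cfg.rating_model = model
        phen = {f"c{i}": "no_pain" for i in range(5)}
        phen.update({f"w{i}": "widespread_hyperalgesia" for i in range(5)})
        ratings = generate_ratings(cfg, phen)
        low = ratings[(ratings.site == "unaffected")
                      & (ratings.intensity == "low")]
        means = low.groupby("subject")["rating"].mean()
        thr = hyperalgesia_threshold(
            means[[f"c{i}" for i in range(5)]].to_numpy())
        assert all(means[f"w{i}"] > thr for i in range(5))

    def test_classification_rate_matches_truncnorm_tail(self):
        # single-trial ratings: P(rating > thr) has a closed form
        mean, sd, thr = 3.0, 1.0, 1.5
        cfg = clbp_default_config(seed=7, n_rating_trials=1)
        cfg.rating_model = {("widespread_hyperalgesia", ck): (mean, sd)
                            for ck in ("affected_low", "affected_high",
                                       "unaffected_low", "unaffected_high")}
        n = 1000
        phen = {f"w{i}": "widespread_hyperalgesia" for i in range(n)}
        ratings = generate_ratings(cfg, phen)
        low = ratings[(ratings.site == "unaffected")
                      & (ratings.intensity == "low")]
        emp = (low["rating"] > thr).mean()
        a, b = (0 - mean) / sd, (10 - mean) / sd
        exact = st.truncnorm.sf(thr, a, b, loc=mean, scale=sd)
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(emp - exact) < 3 * se


class TestGenerateOutcomes:
    def test_noiseless_outcomes_recover_model_exactly(self):
        cfg = clbp_default_config(seed=8)
        cfg.outcome_model = OutcomeModel(intercept=-1.0, score_coef=0.1,
                                         phenotype_coef=0.5,
                                         interaction_coef=-0.08,
                                         score_center=0.0, noise_sd=0.0)
        rng = np.random.default_rng(0)
        scores = rng.normal(0, 5, 40)
        phen = np.array(["widespread_hyperalgesia", "localized_pain"] * 20)
        out = generate_outcomes(cfg, scores, phen)
        wide = (phen == "widespread_hyperalgesia").astype(float)
        X = sm.add_constant(np.column_stack(
            [scores, wide, scores * wide]))
        # use the latent change (pre-clipping is identical here)
        fit = sm.OLS(out["pain_change"], X).fit()
        assert np.allclose(fit.params, [-1.0, 0.1, 0.5, -0.08], atol=1e-8)
        assert fit.rsquared == pytest.approx(1.0)

    def test_noisy_coefficients_within_three_standard_errors(self):
        cfg = clbp_default_config(seed=9)
        truth = OutcomeModel(intercept=-1.0, score_coef=0.1,
                             phenotype_coef=0.5, interaction_coef=-0.08,
                             score_center=0.0, noise_sd=0.5,
                             baseline_mean=6.0, baseline_sd=0.5)
        cfg.outcome_model = truth
        rng = np.random.default_rng(1)
        scores = rng.normal(0, 5, 200)
        phen = np.array(["widespread_hyperalgesia", "localized_pain"] * 100)
        out = generate_outcomes(cfg, scores, phen)
        wide = (phen == "widespread_hyperalgesia").astype(float)
        X = sm.add_constant(np.column_stack([scores, wide, scores * wide]))
        fit = sm.OLS(out["pain_change"], X).fit()
        target = [truth.intercept, truth.score_coef, truth.phenotype_coef,
                  truth.interaction_coef]
        assert np.all(np.abs(fit.params - target) < 3 * fit.bse)

    def test_widespread_non_response_config_yields_zero_responders(self):
        cfg = clbp_default_config(seed=10)
        cfg.outcome_model = OutcomeModel(intercept=0.0, score_coef=0.0,
                                         phenotype_coef=0.5,
                                         interaction_coef=0.0,
                                         score_center=0.0, noise_sd=0.0)
        phen = np.array(["widespread_hyperalgesia"] * 5)
        out = generate_outcomes(cfg, np.zeros(5), phen)
        assert not out["responder"].any()

    def test_mismatched_lengths_rejected(self):
        cfg = clbp_default_config(seed=11)
        with pytest.raises(ValueError):
            generate_outcomes(cfg, np.zeros(3),
                              np.array(["no_pain"] * 4))
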