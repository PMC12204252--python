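"""Spline basis, Gibbs sampler invariants, oracle equivalence and rank
selection for the functional mixed model."""

import numpy as np
import pytest

from ofc_biosig.bfmm import (BasisSpec, ModelSpec, PosteriorDraws,
                             build_bspline_basis, build_design,
                             contrast_draws, effect_surface, fit_mcmc,
                             select_rank, summarize_contrast)
from ofc_biosig.containers import TimeFreqGrid, condition_key
from ofc_biosig.synthetic_data import SimConfig, generate_cohort

CONTRAST = "widespread_hyperalgesia:affected_high"


def small_cohort(seed=0, **overrides):
    base = dict(
        n_per_group={"widespread_hyperalgesia": 6, "localized_pain": 8},
        rois=("mOFC-left",), sigma_subject=0.3,
        sigma_subject_condition=0.3, sigma_noise=0.5, seed=seed)
    base.update(overrides)
    ds, truth = generate_cohort(SimConfig(**base))
    return ds, truth


def quick_spec(**overrides):
    base = dict(roi="mOFC-left", burn_in=300, keep=150, seed=11)
    base.update(overrides)
    return ModelSpec(**base)


class TestBasis:
    def test_partition_of_unity_on_both_margins(self, basis):
        assert np.allclose(basis.time_basis.sum(axis=1), 1.0)
        assert np.allclose(basis.freq_basis.sum(axis=1), 1.0)

    def test_tensor_has_fifty_surfaces_full_rank(self, basis):
        B = basis.tensor
        assert B.shape == (27 * 45, 50)
        assert np.linalg.matrix_rank(B) == 50

    def test_constants_reproduced_exactly(self, basis):
        # cubic splines reproduce polynomials up to degree 3
        target = np.full(27, 2.5)
        coef, res, *_ = np.linalg.lstsq(basis.time_basis, target, rcond=None)
        assert np.allclose(basis.time_basis @ coef, target)

    def test_too_few_grid_points_rejected(self):
        tiny = TimeFreqGrid(times=np.linspace(0, 0.7, 4),
                            freqs=np.arange(1, 46))
        with pytest.raises(ValueError):
            build_bspline_basis(tiny, n_time=5)


class TestDesign:
    def test_rank_deficient_design_names_columns(self):
        ds, _ = small_cohort(seed=1)
        for s in ds.subjects:
            s.age = 50.0  # constant -> zero column after standardization
        with pytest.raises(ValueError, match="age"):
            build_design(ds, quick_spec())

    def test_non_finite_data_rejected(self):
        ds, _ = small_cohort(seed=2)
        ds.subjects[0].tfrs[("mOFC-left", "affected_high")].values[0, 0] \
            = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            build_design(ds, quick_spec())

    def test_reference_coding_yields_one_contrast_column_per_condition(self):
        ds, _ = small_cohort(seed=3)
        info = build_design(ds, quick_spec())
        per_cond = [c for c in info.col_names
                    if c.startswith("widespread_hyperalgesia:")]
        assert len(per_cond) == 4
        assert CONTRAST in info.col_names


@pytest.fixture(scope="module")
def fitted():
    ds, truth = small_cohort(seed=4)
    draws = fit_mcmc(ds, quick_spec())
    return ds, truth, draws


class TestSamplerInvariants:
    def test_unit_norm_direction_vectors_on_every_draw(self, fitted):
        _, _, draws = fitted
        assert np.allclose(np.linalg.norm(draws.u, axis=2), 1.0)
        assert np.allclose(np.linalg.norm(draws.v, axis=2), 1.0)

    def test_sign_convention_delta_theta_nonnegative(self, fitted):
        _, _, draws = fitted
        basis = draws.basis
        t_in = (basis.grid.times >= 0.4) & (basis.grid.times <= 0.7)
        f_in = (basis.grid.freqs >= 1) & (basis.grid.freqs <= 7)
        for d in range(draws.n_keep):
            surf = basis.surface(draws.u[d, 0], draws.v[d, 0])
            assert surf[np.ix_(t_in, f_in)].mean() >= 0

    def test_variances_positive(self, fitted):
        _, _, draws = fitted
        assert np.all(draws.sigma2 > 0)
        assert np.all(draws.sigma_subj2 > 0)
        assert np.all(draws.sigma_sc2 > 0)

    def test_seed_determinism(self):
        ds, _ = small_cohort(seed=5)
        d1 = fit_mcmc(ds, quick_spec(seed=42))
        d2 = fit_mcmc(ds, quick_spec(seed=42))
        d3 = fit_mcmc(ds, quick_spec(seed=43))
        assert np.array_equal(d1.gamma, d2.gamma)
        assert np.array_equal(d1.u, d2.u)
        assert not np.array_equal(d1.gamma, d3.gamma)

    def test_contrast_recovers_generative_amplitude(self, fitted):
        _, truth, draws = fitted
        delta = (truth.amplitude_table[
            ("widespread_hyperalgesia", "affected_high")]
            - truth.amplitude_table[("localized_pain", "affected_high")])
        cs = summarize_contrast(draws, CONTRAST)
        assert cs.mean == pytest.approx(delta, rel=0.25)
        assert cs.lower <= cs.mean <= cs.upper

    def test_recovered_surface_direction_matches_truth(self, fitted):
        _, truth, draws = fitted
        surf = effect_surface(draws, CONTRAST)
        cos = np.sum(surf * truth.true_surface) / np.linalg.norm(surf)
        assert cos > 0.95


class TestDegenerateData:
    def test_all_zero_data_shrinks_everything(self):
        ds, _ = small_cohort(seed=6, sigma_subject=0.0,
                             sigma_subject_condition=0.0, sigma_noise=0.0,
                             covariate_effects={"age": 0, "sex": 0,
                                                "pain_intensity": 0},
                             group_condition_amplitudes={
                                 ("widespread_hyperalgesia", ck): 0.0
                                 for ck in ("affected_low", "affected_high",
                                            "unaffected_low",
                                            "unaffected_high")} | {
                                 ("localized_pain", ck): 0.0
                                 for ck in ("affected_low", "affected_high",
                                            "unaffected_low",
                                            "unaffected_high")})
        spec = quick_spec(store_random_effects=True, sigma2_floor=1e-10)
        draws = fit_mcmc(ds, spec)
        assert np.abs(draws.gamma.mean(axis=0)).max() < 1e-3
        assert np.abs(draws.b_subject).max() < 1e-3
        # error variance collapses to its configured floor
        assert draws.sigma2.max() <= 1e-9


class TestOracleEquivalence:
    def test_noiseless_rank1_matches_svd_least_squares(self):
        # no random effects, no noise: posterior concentrates on the
        # rank-1 truncated-SVD least-squares solution
        ds, truth = small_cohort(
            seed=7, sigma_subject=0.0, sigma_subject_condition=0.0,
            sigma_noise=0.0)
        spec = quick_spec(include_subject_re=False,
                          include_subject_condition_re=False,
                          burn_in=500, keep=200)
        draws = fit_mcmc(ds, spec)
        info = build_design(ds, spec)
        B = draws.basis.tensor
        G = B.T @ B
        C = np.linalg.solve(G, B.T @ info.Y.T @ info.X) @ np.linalg.inv(
            info.X.T @ info.X)
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        C1 = s[0] * np.outer(U[:, 0], Vt[0])
        for col in (CONTRAST, "cond[affected_high]"):
            k = draws.column_index(col)
            oracle = draws.basis.coef_surface(C1[:, k])
            fitted = effect_surface(draws, col)
            err = np.linalg.norm(fitted - oracle) / np.linalg.norm(oracle)
            assert err < 0.01


class TestSummaries:
    def test_null_contrast_gives_degenerate_interval(self):
        ds, _ = small_cohort(seed=8)
        draws = fit_mcmc(ds, quick_spec())
        cs = summarize_contrast(draws, {CONTRAST: 0.0})
        assert cs.mean == 0.0 and (cs.lower, cs.upper) == (0.0, 0.0)

    def test_interval_endpoints_are_equal_tailed_quantiles(self):
        ds, _ = small_cohort(seed=8)
        draws = fit_mcmc(ds, quick_spec())
        cs = summarize_contrast(draws, CONTRAST, level=0.90)
        vals = contrast_draws(draws, CONTRAST)
        assert cs.lower == pytest.approx(np.quantile(vals, 0.05))
        assert cs.upper == pytest.approx(np.quantile(vals, 0.95))

    def test_unknown_column_rejected(self):
        ds, _ = small_cohort(seed=8)
        draws = fit_mcmc(ds, quick_spec(burn_in=50, keep=20))
        with pytest.raises(KeyError):
            summarize_contrast(draws, "nonexistent:column")

    def test_effect_surface_single_draw_is_direct_product(self, basis):
        u = np.array([1.0, 2.0, 0.0, -1.0, 0.5])
        u /= np.linalg.norm(u)
        v = np.zeros(10)
        v[2] = 1.0
        gamma = np.zeros((1, 3, 1))
        gamma[0, 1, 0] = 4.0
        draws = PosteriorDraws(
            basis=basis, col_names=["a", "b", "c"],
            u=u[None, None], v=v[None, None], gamma=gamma,
            sigma2=np.ones(1), sigma_subj2=None, sigma_sc2=None,
            tau2=np.ones(1), lambda2=np.ones((1, 3)), phi=np.ones((1, 1)))
        expected = 4.0 * np.outer(basis.time_basis @ u,
                                  basis.freq_basis @ v)
        assert np.allclose(effect_surface(draws, "b"), expected)
        assert np.allclose(effect_surface(draws, "a"), 0.0)


class TestRankSelection:
    def test_rank1_truth_selects_one(self):
        ds, _ = small_cohort(seed=9, sigma_noise=0.4)
        sel = select_rank(ds, quick_spec(burn_in=400, keep=200), R_max=3)
        assert sel.selected == 1
        assert sel.active[0] and not any(sel.active[1:])

    def test_rank2_truth_selects_two(self, basis):
        # two well-separated components in different columns
        conds = (("affected", "high"), ("unaffected", "high"))
        cfg = SimConfig(
            n_per_group={"widespread_hyperalgesia": 8,
                         "localized_pain": 8},
            rois=("mOFC-left",), conditions=conds,
            sigma_subject=0.0, sigma_subject_condition=0.0, sigma_noise=0.3,
            covariate_effects={"age": 0, "sex": 0, "pain_intensity": 0},
            group_condition_amplitudes={
                (g, condition_key(c)): 0.0
                for g in ("widespread_hyperalgesia", "localized_pain")
                for c in conds},
            seed=10)
        ds, _ = generate_cohort(cfg)
        u1 = np.array([1.0, 0, 0, 0, 0])
        v1 = np.r_[1.0, 1.0, np.zeros(8)] / np.sqrt(2)
        u2 = np.array([0, 0, 0, 0, 1.0])
        v2 = np.r_[np.zeros(8), 1.0, 1.0] / np.sqrt(2)
        S1, S2 = basis.surface(u1, v1), basis.surface(u2, v2)
        for s in ds.subjects:
            if s.phenotype != "widespread_hyperalgesia":
                continue
            s.tfrs[("mOFC-left", "affected_high")].values += 10 * S1
            s.tfrs[("mOFC-left", "unaffected_high")].values += 10 * S2
        sel = select_rank(ds, quick_spec(burn_in=500, keep=250), R_max=3)
        assert sel.selected == 2

    def test_pure_noise_defaults_to_rank_one_untruncated(self):
        conds = (("affected", "high"),)
        cfg = SimConfig(
            n_per_group={"widespread_hyperalgesia": 6, "localized_pain": 6},
            rois=("mOFC-left",), conditions=conds,
            covariate_effects={"age": 0, "sex": 0, "pain_intensity": 0},
            group_condition_amplitudes={
                (g, "affected_high"): 0.0
                for g in ("widespread_hyperalgesia", "localized_pain")},
            sigma_subject=0.0, sigma_subject_condition=0.0,
            sigma_noise=1.0, seed=13)
        ds, _ = generate_cohort(cfg)
        sel = select_rank(ds, quick_spec(burn_in=300, keep=150), R_max=2)
        assert sel.selected == 1
        assert not any(sel.active)
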