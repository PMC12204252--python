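"""Synthetic cohort generator with the statistical structure the pipeline
assumes.

Each subject's TFR for an ROI and stimulus condition is built as

    amplitude(group, condition) * true_surface
    + (covariate effects) * true_surface
    + subject random surface + subject-by-condition random surface
    + i.i.d. cell noise,

where ``true_surface`` is a unit-Frobenius-norm ``T x F`` pattern (default:
a positive delta/theta bump minus an alpha bump, both centered at 0.55 s,
projected into the 5 x 10 tensor spline span so the generative model lies
inside the fitted model family) and the random surfaces are spline-basis
coefficient draws through the same tensor basis. The generator also emulates
0-10 pain ratings per stimulation condition (truncated normals) and a
post-treatment outcome model linking biosignature scores and phenotype to
pain change, so that phenotyping, model fitting, scoring and prediction are
all exercisable without real recordings.

A ``GroundTruth`` record of every realized latent quantity accompanies each
cohort, enabling parameter-recovery tests downstream.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import cohorts
from .bfmm import BasisSpec, build_bspline_basis
from .containers import (DEFAULT_CONDITIONS, CohortDataset, Condition,
                         SubjectRecord, TFRMatrix, TimeFreqGrid,
                         condition_key)
from .phenotyping import classify_responder, is_widespread

#: Default standardization constants applied to covariates inside the
#: generative linear predictor (age ~ U[25, 70]; pain on the 0-10 scale).
AGE_CENTER, AGE_SCALE = 47.5, 13.0
PAIN_CENTER, PAIN_SCALE = 3.0, 2.5


def default_true_surface(grid: TimeFreqGrid | None = None,
                         basis: BasisSpec | None = None,
                         t_center: float = 0.55, t_sd: float = 0.08,
                         f_pos: float = 4.0, f_neg: float = 10.0,
                         f_sd: float = 1.5) -> np.ndarray:
    """Unit-Frobenius-norm effect surface: +delta/theta, -alpha bumps.

    A Gaussian time profile centered late in the post-stimulus window
    multiplies a frequency profile of a positive bump at ``f_pos`` minus a
    negative bump at ``f_neg`` (rank-1 by construction). The profiles are
    least-squares-projected onto the marginal spline bases so the surface
    lies exactly in the tensor-spline span used by the model.
    """
    if grid is None:
        grid = TimeFreqGrid.default()
    if basis is None:
        basis = build_bspline_basis(grid)
    gt = np.exp(-0.5 * ((grid.times - t_center) / t_sd) ** 2)
    gf = (np.exp(-0.5 * ((grid.freqs - f_pos) / f_sd) ** 2)
          - np.exp(-0.5 * ((grid.freqs - f_neg) / f_sd) ** 2))
    a, *_ = np.linalg.lstsq(basis.time_basis, gt, rcond=None)
    b, *_ = np.linalg.lstsq(basis.freq_basis, gf, rcond=None)
    surf = np.outer(basis.time_basis @ a, basis.freq_basis @ b)
    return surf / np.linalg.norm(surf)


def default_amplitudes(groups, conditions=DEFAULT_CONDITIONS,
                       widespread_delta: float = 9.0) -> dict:
    """Per-(group, condition) amplitude table.

    Every group shares a base evoked response (low intensity 2 dB-units,
    high 5); widespread-hyperalgesia subjects additionally express the
    surface more strongly, most at the affected-site high-intensity
    condition (``widespread_delta``, default 9) with graded spillover to
    the unaffected site.
    """
    base = {"low": 2.0, "high": 5.0}
    extra_widespread = {
        ("affected", "high"): widespread_delta,
        ("unaffected", "high"): widespread_delta * 4.0 / 9.0,
        ("unaffected", "low"): widespread_delta * 2.0 / 9.0,
        ("affected", "low"): 0.0,
    }
    amps = {}
    for g in groups:
        for c in conditions:
            amp = base[c[1]]
            if is_widespread(g):
                amp += extra_widespread[tuple(c)]
            amps[(g, condition_key(c))] = amp
    return amps


def default_rating_model(groups) -> dict:
    """(mean, sd) of the 0-10 rating truncated normal per group x condition.

    Widespread subjects rate the low-force unaffected-site stimulus well
    above the control-derived threshold; localized/segmental subjects rate
    it near controls.
    """
    table = {
        "no_pain": {("affected", "low"): (0.3, 0.5),
                    ("affected", "high"): (2.0, 0.8),
                    ("unaffected", "low"): (0.3, 0.5),
                    ("unaffected", "high"): (2.0, 0.8)},
        "localized": {("affected", "low"): (3.0, 1.0),
                      ("affected", "high"): (6.0, 1.2),
                      ("unaffected", "low"): (0.5, 0.6),
                      ("unaffected", "high"): (3.0, 1.0)},
        "widespread": {("affected", "low"): (4.0, 1.2),
                       ("affected", "high"): (7.0, 1.2),
                       ("unaffected", "low"): (3.0, 1.0),
                       ("unaffected", "high"): (5.0, 1.2)},
    }
    alias = {"no_pain": "no_pain", "no_hyperalgesia": "no_pain",
             "localized_pain": "localized",
             "segmental_hyperalgesia": "localized",
             "widespread_hyperalgesia": "widespread"}
    out = {}
    for g in groups:
        for cond, ms in table[alias[g]].items():
            out[(g, condition_key(cond))] = ms
    return out


@dataclass
class OutcomeModel:
    """Linear model for post-treatment pain change (negative = improvement).

    With s = score - score_center (the centering puts a typical
    non-widespread subject's biosignature score near zero under default
    generator settings):

    change = intercept + score_coef * s + phenotype_coef * is_widespread
             + interaction_coef * s * is_widespread + N(0, noise_sd^2)
    """

    intercept: float = -1.2
    score_coef: float = 0.06
    phenotype_coef: float = 1.0
    interaction_coef: float = -0.06
    score_center: float = 40.0
    noise_sd: float = 0.8
    baseline_mean: float = 4.0
    baseline_sd: float = 1.5
    baseline_range: tuple[float, float] = (1.0, 10.0)


@dataclass
class SimConfig:
    """Full specification of one synthetic cohort."""

    n_per_group: dict[str, int]
    conditions: tuple[Condition, ...] = DEFAULT_CONDITIONS
    grid: TimeFreqGrid = field(default_factory=TimeFreqGrid.default)
    rois: tuple[str, ...] = ("mOFC-left", "mOFC-right")
    true_surface: np.ndarray | None = None
    group_condition_amplitudes: dict | None = None
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.5, "sex": 0.3,
                                 "pain_intensity": 0.8})
    sigma_subject: float = 0.5
    sigma_subject_condition: float = 0.5
    sigma_noise: float = 1.0
    rating_model: dict | None = None
    n_rating_trials: int = 10
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    n_trials_per_condition: int = 10
    cohort_name: str = "clbp"
    seed: int = 0

    def __post_init__(self):
        if not self.n_per_group or all(n == 0 for n in
                                       self.n_per_group.values()):
            raise ValueError("at least one group must have subjects")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be >= 0")
        for name in ("sigma_subject", "sigma_subject_condition",
                     "sigma_noise"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be a finite SD >= 0")
        if self.true_surface is None:
            self.true_surface = default_true_surface(self.grid)
        self.true_surface = np.asarray(self.true_surface, dtype=float)
        if self.true_surface.shape != self.grid.shape:
            raise ValueError("true_surface shape does not match grid")
        norm = np.linalg.norm(self.true_surface)
        if not np.isclose(norm, 1.0, rtol=1e-6):
            raise ValueError(
                f"true_surface must have unit Frobenius norm (got {norm:g})")
        if self.group_condition_amplitudes is None:
            self.group_condition_amplitudes = default_amplitudes(
                self.n_per_group, self.conditions)
        if not all(np.isfinite(list(
                self.group_condition_amplitudes.values()))):
            raise ValueError("amplitudes must be finite")
        if self.rating_model is None:
            self.rating_model = default_rating_model(self.n_per_group)

    @property
    def groups(self) -> list[str]:
        return list(self.n_per_group)


@dataclass
class GroundTruth:
    """Latent quantities realized during generation."""

    config: SimConfig
    amplitude_table: dict
    covariate_effects: dict[str, float]
    true_surface: np.ndarray
    subject_surfaces: dict          # (subject, roi) -> (q,) coefficients
    subject_condition_surfaces: dict  # (subject, roi, ck) -> coefficients
    outcome_model: OutcomeModel


def clbp_default_config(seed: int = 0, **overrides) -> SimConfig:
    """Cohort mirroring the cLBP-frame study composition (25/30/12)."""
    cfg = dict(n_per_group=dict(cohorts.CLBP_PHENOTYPE_COUNTS),
               cohort_name="clbp", seed=seed)
    cfg.update(overrides)
    return SimConfig(**cfg)


def cp_default_config(seed: int = 0, **overrides) -> SimConfig:
    """Cohort mirroring the CP-frame study composition (6/4/8)."""
    cfg = dict(n_per_group=dict(cohorts.CP_PHENOTYPE_COUNTS),
               cohort_name="cp", seed=seed)
    cfg.update(overrides)
    return SimConfig(**cfg)


def recovery_config(seed: int = 0, delta: float = 9.0,
                    **overrides) -> SimConfig:
    """40-subject cohort with a known widespread-vs-localized amplitude
    difference (default 9) at the affected-site high-intensity condition,
    for parameter-recovery studies."""
    n = {"no_pain": 12, "localized_pain": 16, "widespread_hyperalgesia": 12}
    amps = default_amplitudes(n, DEFAULT_CONDITIONS, widespread_delta=delta)
    cfg = dict(n_per_group=n, group_condition_amplitudes=amps,
               cohort_name="clbp", seed=seed)
    cfg.update(overrides)
    return SimConfig(**cfg)


def _truncnorm_rvs(rng, mean, sd, low, high, size):
    if sd == 0:
        if not (low <= mean <= high):
            raise ValueError(f"degenerate distribution at {mean} outside "
                             f"[{low}, {high}]")
        return np.full(size, float(mean))
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                         random_state=rng)


def generate_cohort(config: SimConfig) -> tuple[CohortDataset, GroundTruth]:
    """Draw a full cohort and its ground-truth record.

    Identical configs and seeds give bit-identical output.
    """
    config = copy.deepcopy(config)
    rng = np.random.default_rng(config.seed)
    basis = build_bspline_basis(config.grid)
    B = basis.tensor
    S = config.true_surface
    shape = config.grid.shape
    q = basis.n_coef

    pain_dists = {g: (cohorts.CLBP_BASELINE if g in cohorts.CLBP_BASELINE.index
                      else cohorts.CP_BASELINE).loc[g]
                  for g in config.groups}

    subjects: list[SubjectRecord] = []
    subj_surf, sc_surf = {}, {}
    idx = 0
    for g in config.groups:
        for _ in range(config.n_per_group[g]):
            idx += 1
            sid = f"{config.cohort_name}{idx:03d}"
            age = rng.uniform(25.0, 70.0)
            sex = int(rng.random() < 0.5)
            row = pain_dists[g]
            pain = float(_truncnorm_rvs(rng, row["pain_mean"],
                                        row["pain_sd"], 0.0, 10.0, 1)[0])
            cov_term = (config.covariate_effects.get("age", 0.0)
                        * (age - AGE_CENTER) / AGE_SCALE
                        + config.covariate_effects.get("sex", 0.0)
                        * (sex - 0.5)
                        + config.covariate_effects.get("pain_intensity", 0.0)
                        * (pain - PAIN_CENTER) / PAIN_SCALE)
            rec = SubjectRecord(subject=sid, age=age, sex=sex,
                                pain_intensity=pain, phenotype=g,
                                cohort=config.cohort_name)
            for roi in config.rois:
                b_i = config.sigma_subject * rng.standard_normal(q)
                subj_surf[(sid, roi)] = b_i
                surf_i = (B @ b_i).reshape(shape)
                for cond in config.conditions:
                    ck = condition_key(cond)
                    b_ic = (config.sigma_subject_condition
                            * rng.standard_normal(q))
                    sc_surf[(sid, roi, ck)] = b_ic
                    amp = config.group_condition_amplitudes[(g, ck)]
                    values = ((amp + cov_term) * S + surf_i
                              + (B @ b_ic).reshape(shape)
                              + config.sigma_noise
                              * rng.standard_normal(shape))
                    rec.tfrs[(roi, ck)] = TFRMatrix(
                        grid=config.grid, values=values, subject=sid,
                        roi=roi, condition=cond,
                        n_trials=config.n_trials_per_condition)
            subjects.append(rec)

    dataset = CohortDataset(grid=config.grid, subjects=subjects,
                            name=config.cohort_name)
    truth = GroundTruth(
        config=config,
        amplitude_table=dict(config.group_condition_amplitudes),
        covariate_effects=dict(config.covariate_effects),
        true_surface=S, subject_surfaces=subj_surf,
        subject_condition_surfaces=sc_surf,
        outcome_model=config.outcome_model)
    return dataset, truth


def generate_ratings(config: SimConfig, phenotypes: dict[str, str] | pd.Series,
                     seed_offset: int = 1) -> pd.DataFrame:
    """Per-trial 0-10 pain ratings for every subject x condition.

    ``phenotypes`` maps subject id -> group label (e.g. the cohort table).
    Ratings are truncated normals on [0, 10] with group- and condition-
    specific means from ``config.rating_model``.
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    phenotypes = dict(phenotypes)
    rows = []
    for sid, g in phenotypes.items():
        for cond in config.conditions:
            ck = condition_key(cond)
            mean, sd = config.rating_model[(g, ck)]
            vals = _truncnorm_rvs(rng, mean, sd, 0.0, 10.0,
                                  config.n_rating_trials)
            for t, r in enumerate(vals):
                rows.append(dict(subject=sid, site=cond[0],
                                 intensity=cond[1], trial=t,
                                 rating=float(r)))
    return pd.DataFrame(rows)


def generate_outcomes(config: SimConfig, scores, phenotypes,
                      seed_offset: int = 2) -> pd.DataFrame:
    """Baseline / 3-month pain severities from the outcome model.

    ``scores`` and ``phenotypes`` are aligned sequences (or mappings with
    identical keys): per-subject biosignature scores and phenotype labels.
    Pain change is the linear predictor plus noise; follow-up severity is
    the clipped baseline + change and the responder flag follows the >= 30%
    relative-reduction rule.
    """
    if isinstance(scores, (pd.Series, dict)):
        scores = pd.Series(dict(scores))
        phen = pd.Series(dict(phenotypes))
        if not scores.index.equals(phen.index):
            phen = phen.reindex(scores.index)
            if phen.isna().any():
                raise ValueError("scores and phenotypes indices differ")
        subjects = list(scores.index)
        scores = scores.to_numpy(float)
        phenotypes = phen.to_numpy()
    else:
        scores = np.asarray(scores, float)
        phenotypes = np.asarray(phenotypes)
        subjects = [f"s{i:03d}" for i in range(scores.size)]
    if scores.size != phenotypes.size:
        raise ValueError("scores and phenotypes must have equal length")

    m = config.outcome_model
    rng = np.random.default_rng(config.seed + seed_offset)
    wide = np.array([is_widespread(g) for g in phenotypes], dtype=float)
    baseline = _truncnorm_rvs(rng, m.baseline_mean, m.baseline_sd,
                              *m.baseline_range, scores.size)
    s = scores - m.score_center
    change = (m.intercept + m.score_coef * s + m.phenotype_coef * wide
              + m.interaction_coef * s * wide
              + m.noise_sd * rng.standard_normal(scores.size))
    followup = np.clip(baseline + change, 0.0, 10.0)
    return pd.DataFrame(dict(
        subject=subjects, phenotype=phenotypes, score=scores,
        baseline=baseline, followup=followup,
        pain_change=followup - baseline,
        responder=[classify_responder(b, f)
                   for b, f in zip(baseline, followup)]))
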