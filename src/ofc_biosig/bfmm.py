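"""Bayesian functional mixed-effects model for time-frequency outcomes.

Each subject x condition outcome is a ``T x F`` matrix of baseline-corrected
dB power, modeled as a 2D functional response expanded in a tensor-product
cubic B-spline basis (5 time x 10 frequency functions by default):

    Y_ic = (x_ic' gamma) * S(u, v) + Z b_i + Z b_ic + noise,

where the shared fixed-effect surface ``S(u, v) = (B_t u)(B_f v)'`` is a
rank-1 outer product of unit-norm direction vectors through the marginal
spline bases, scaled per fixed-effect column by scalar amplitudes ``gamma``
(rank R >= 1 sums R such components); ``b_i`` and ``b_ic`` are subject and
subject-by-condition random surfaces expanded in the same 50-dim tensor
basis; and the noise is i.i.d. Gaussian over grid cells.

Priors and sampler
------------------
* Direction vectors: uniform on the unit sphere, sampled by parameter
  expansion — the unconstrained Gaussian full conditional is drawn and
  normalized, the norm being absorbed into ``gamma``.
* Amplitudes: local-global conjugate shrinkage
  ``gamma_{k,r} ~ N(0, tau^2 lambda_k^2 / phi_r)`` with inverse-gamma
  hyperpriors on ``lambda_k^2`` and ``tau^2`` and a multiplicative-gamma
  ordered shrinkage ``phi_r`` across rank components (used by the automatic
  rank-selection rule).
* Random-effect coefficients: ``N(0, sigma_b^2)`` per family with
  InvGamma(0.001, 0.001) hyperpriors.
* Error variance: Jeffreys prior ``p(sigma^2) ∝ 1/sigma^2`` giving a proper
  inverse-gamma full conditional.

All full conditionals are conjugate, so the sampler is a plain Gibbs scheme;
with a fixed seed the draws are reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .containers import (CohortDataset, Condition, TimeFreqGrid,
                         condition_key)
from .phenotyping import harmonize_label

logger = logging.getLogger(__name__)

#: Region that fixes the sign of each rank's basis surface: the surface mean
#: over delta/theta (1-7 Hz) cells in the 0.4-0.7 s window is kept >= 0,
#: which resolves the (u, v, gamma) -> (-u, -v, gamma) indeterminacy.
SIGN_WINDOW = (0.4, 0.7)
SIGN_BAND = (1.0, 7.0)


# ----------------------------------------------------------------------
# B-spline tensor basis
# ----------------------------------------------------------------------

def _marginal_bspline(x: np.ndarray, n_basis: int, degree: int) -> np.ndarray:
    """Open-uniform B-spline design matrix with ``n_basis`` columns on the
    range of ``x``; forms a partition of unity on [x0, x1]."""
    if n_basis < degree + 1:
        raise ValueError(f"need at least degree+1={degree + 1} basis "
                         f"functions, got {n_basis}")
    if x.size < n_basis:
        raise ValueError(f"{x.size} grid points cannot support {n_basis} "
                         "basis functions")
    x0, x1 = float(x[0]), float(x[-1])
    n_interior = n_basis - degree - 1
    interior = np.linspace(x0, x1, n_interior + 2)[1:-1]
    knots = np.r_[[x0] * (degree + 1), interior, [x1] * (degree + 1)]
    # nudge the right endpoint into the last interval so the closed edge
    # evaluates to the partition of unity rather than zero
    xe = np.minimum(x, x1 - 1e-12 * max(1.0, abs(x1)))
    design = BSpline.design_matrix(xe, knots, degree).toarray()
    return design


@dataclass
class BasisSpec:
    """Evaluated tensor-product B-spline basis on a time-frequency grid."""

    grid: TimeFreqGrid
    time_basis: np.ndarray   # (T, n_time)
    freq_basis: np.ndarray   # (F, n_freq)
    degree: int = 3

    @property
    def n_time(self) -> int:
        return self.time_basis.shape[1]

    @property
    def n_freq(self) -> int:
        return self.freq_basis.shape[1]

    @property
    def n_coef(self) -> int:
        return self.n_time * self.n_freq

    @property
    def tensor(self) -> np.ndarray:
        """(T*F, n_coef) evaluated tensor basis; vec order is row-major
        (T, F) so that ``tensor @ kron(u_coef, v_coef)`` evaluates the
        outer-product surface."""
        return np.kron(self.time_basis, self.freq_basis)

    def surface(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Rank-1 surface ``(B_t u)(B_f v)'`` as a (T, F) array."""
        return np.outer(self.time_basis @ u, self.freq_basis @ v)

    def coef_surface(self, coef: np.ndarray) -> np.ndarray:
        """General surface from a flat (n_coef,) coefficient vector."""
        c = coef.reshape(self.n_time, self.n_freq)
        return self.time_basis @ c @ self.freq_basis.T


def build_bspline_basis(grid: TimeFreqGrid | None = None, n_time: int = 5,
                        n_freq: int = 10, degree: int = 3) -> BasisSpec:
    """Bivariate cubic B-spline basis (default 5 x 10) on the grid."""
    if grid is None:
        grid = TimeFreqGrid.default()
    return BasisSpec(
        grid=grid,
        time_basis=_marginal_bspline(grid.times, n_time, degree),
        freq_basis=_marginal_bspline(grid.freqs, n_freq, degree),
        degree=degree)


# ----------------------------------------------------------------------
# Model specification and design construction
# ----------------------------------------------------------------------

@dataclass
class ShrinkagePrior:
    """Hyperparameters of the local-global-ordered shrinkage on gamma."""

    lambda_shape: float = 1.0
    lambda_rate: float = 1.0
    tau_shape: float = 0.001
    tau_rate: float = 0.001
    mgp_a1: float = 2.0   # first-rank gamma shape
    mgp_a2: float = 3.0   # later-rank gamma shapes (>1 favors decay)


@dataclass
class ModelSpec:
    """What to fit: design, random effects, priors and MCMC controls."""

    roi: str = "mOFC-left"
    conditions: tuple[Condition, ...] | None = None
    reference_group: str = "localized_pain"
    covariates: tuple[str, ...] = ("age", "sex", "pain_intensity")
    pooled_cohort_effect: bool = False
    rank: int = 1
    include_subject_re: bool = True
    include_subject_condition_re: bool = True
    shrinkage: ShrinkagePrior = field(default_factory=ShrinkagePrior)
    re_var_shape: float = 0.001
    re_var_rate: float = 0.001
    burn_in: int = 1500
    keep: int = 500
    thin: int = 1
    seed: int = 0
    sigma2_floor: float = 1e-10
    store_random_effects: bool = False

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.keep < 1 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("invalid MCMC controls")


@dataclass
class DesignInfo:
    Y: np.ndarray                 # (n_obs, T*F)
    X: np.ndarray                 # (n_obs, p)
    col_names: list[str]
    subject_ids: list[str]        # unique, order of subject index
    subj_idx: np.ndarray          # (n_obs,)
    condition_keys: list[str]     # per obs


def build_design(dataset: CohortDataset, spec: ModelSpec) -> DesignInfo:
    """Stack outcomes and the fixed-effect design for one ROI.

    Fixed-effect columns: one intercept indicator per condition, one
    group-by-condition indicator per non-reference phenotype group, then
    shared covariates (age and pain intensity z-scored across included
    subjects, sex as 0/1, cohort as 0/1 in pooled runs). A subject x
    condition cell with no TFR is simply dropped from the likelihood.
    """
    conditions = (tuple(dataset.conditions) if spec.conditions is None
                  else tuple(spec.conditions))
    cond_keys = [condition_key(c) for c in conditions]

    records = [s for s in dataset.subjects
               if any((spec.roi, ck) in s.tfrs for ck in cond_keys)]
    if not records:
        raise ValueError(f"no subjects with ROI {spec.roi!r} data")

    labels = {s.subject: harmonize_label(s.phenotype) for s in records}
    groups = sorted({g for g in labels.values() if g != spec.reference_group})

    age = np.array([s.age for s in records], float)
    pain = np.array([s.pain_intensity for s in records], float)

    def zscore(x):
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else x - x.mean()

    age_z = dict(zip((s.subject for s in records), zscore(age)))
    pain_z = dict(zip((s.subject for s in records), zscore(pain)))

    col_names = [f"cond[{ck}]" for ck in cond_keys]
    col_names += [f"{g}:{ck}" for g in groups for ck in cond_keys]
    col_names += list(spec.covariates)
    if spec.pooled_cohort_effect:
        col_names.append("cohort")

    rows_y, rows_x, subj_idx, obs_ck = [], [], [], []
    subject_ids = [s.subject for s in records]
    for i, s in enumerate(records):
        for ck in cond_keys:
            if (spec.roi, ck) not in s.tfrs:
                continue
            rows_y.append(s.tfrs[(spec.roi, ck)].values.ravel())
            x = np.zeros(len(col_names))
            x[col_names.index(f"cond[{ck}]")] = 1.0
            g = labels[s.subject]
            if g != spec.reference_group:
                x[col_names.index(f"{g}:{ck}")] = 1.0
            for cov in spec.covariates:
                j = col_names.index(cov)
                if cov == "age":
                    x[j] = age_z[s.subject]
                elif cov == "pain_intensity":
                    x[j] = pain_z[s.subject]
                elif cov == "sex":
                    x[j] = float(s.sex)
                else:
                    x[j] = float(s.extra.get(cov, 0.0))
            if spec.pooled_cohort_effect:
                x[col_names.index("cohort")] = float(s.cohort != "clbp")
            rows_x.append(x)
            subj_idx.append(i)
            obs_ck.append(ck)

    Y = np.asarray(rows_y)
    X = np.asarray(rows_x)
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite outcome data")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            keep = [c for c in range(X.shape[1]) if c != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(col_names[j])
        raise ValueError(f"rank-deficient fixed-effect design; "
                         f"offending columns: {bad}")
    return DesignInfo(Y=Y, X=X, col_names=col_names,
                      subject_ids=subject_ids,
                      subj_idx=np.asarray(subj_idx), condition_keys=obs_ck)


# ----------------------------------------------------------------------
# Posterior container
# ----------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Kept MCMC draws; axis 0 of every array is the draw index."""

    basis: BasisSpec
    col_names: list[str]
    u: np.ndarray          # (n_keep, R, n_time), unit norm per draw/rank
    v: np.ndarray          # (n_keep, R, n_freq), unit norm per draw/rank
    gamma: np.ndarray      # (n_keep, p, R)
    sigma2: np.ndarray     # (n_keep,)
    sigma_subj2: np.ndarray | None
    sigma_sc2: np.ndarray | None
    tau2: np.ndarray       # (n_keep,)
    lambda2: np.ndarray    # (n_keep, p)
    phi: np.ndarray        # (n_keep, R) rank-shrinkage precisions
    b_subject: np.ndarray | None = None   # (n_keep, n_subj, n_coef)
    b_subj_cond: np.ndarray | None = None  # (n_keep, n_obs, n_coef)
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n_keep(self) -> int:
        return self.gamma.shape[0]

    @property
    def rank(self) -> int:
        return self.gamma.shape[2]

    def column_index(self, column: str) -> int:
        try:
            return self.col_names.index(column)
        except ValueError:
            raise KeyError(f"unknown design column {column!r}; available: "
                           f"{self.col_names}") from None


# ----------------------------------------------------------------------
# Gibbs sampler
# ----------------------------------------------------------------------

def _sample_mvn_prec(rng, prec: np.ndarray, lin: np.ndarray) -> np.ndarray:
    """Draw from N(prec^-1 lin, prec^-1)."""
    L = np.linalg.cholesky(prec)
    mean = cho_solve((L, True), lin)
    z = rng.standard_normal(lin.size)
    return mean + solve_triangular(L.T, z, lower=False)


def fit_mcmc(dataset: CohortDataset, spec: ModelSpec,
             basis: BasisSpec | None = None) -> PosteriorDraws:
    """Gibbs sampler for the rank-constrained functional mixed model."""
    if basis is None:
        basis = build_bspline_basis(dataset.grid)
    info = build_design(dataset, spec)
    return _run_gibbs(info, spec, basis)


def _run_gibbs(info: DesignInfo, spec: ModelSpec,
               basis: BasisSpec) -> PosteriorDraws:
    rng = np.random.default_rng(spec.seed)
    Y, X = info.Y, info.X
    n_obs, p = X.shape
    R = spec.rank
    q = basis.n_coef
    B = basis.tensor                       # (T*F, q)
    G = B.T @ B                            # (q, q)
    By = Y @ B                             # (n_obs, q)
    y_sq = np.einsum("ij,ij->i", Y, Y)
    n_cells = Y.shape[1]
    subj_idx = info.subj_idx
    n_subj = len(info.subject_ids)
    counts = np.bincount(subj_idx, minlength=n_subj).astype(float)
    XtX = X.T @ X
    sh = spec.shrinkage

    # sign-convention cell mask (delta/theta band in the late window)
    t_in = ((basis.grid.times >= SIGN_WINDOW[0])
            & (basis.grid.times <= SIGN_WINDOW[1]))
    f_in = ((basis.grid.freqs >= SIGN_BAND[0])
            & (basis.grid.freqs <= SIGN_BAND[1]))

    # --- state ---
    u = rng.standard_normal((R, basis.n_time))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = rng.standard_normal((R, basis.n_freq))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    gamma = np.zeros((p, R))
    b_subj = np.zeros((n_subj, q))
    b_sc = np.zeros((n_obs, q))
    sigma2 = max(float(np.var(Y)), spec.sigma2_floor)
    sigma_subj2 = 1.0
    sigma_sc2 = 1.0
    tau2 = 1.0
    lambda2 = np.ones(p)
    delta = np.ones(R)

    n_iter = spec.burn_in + spec.keep * spec.thin
    kept = dict(
        u=np.empty((spec.keep, R, basis.n_time)),
        v=np.empty((spec.keep, R, basis.n_freq)),
        gamma=np.empty((spec.keep, p, R)),
        sigma2=np.empty(spec.keep), tau2=np.empty(spec.keep),
        lambda2=np.empty((spec.keep, p)), phi=np.empty((spec.keep, R)),
        sigma_subj2=np.empty(spec.keep) if spec.include_subject_re else None,
        sigma_sc2=(np.empty(spec.keep)
                   if spec.include_subject_condition_re else None),
        b_subject=(np.empty((spec.keep, n_subj, q))
                   if spec.store_random_effects and spec.include_subject_re
                   else None),
        b_subj_cond=(np.empty((spec.keep, n_obs, q))
                     if spec.store_random_effects
                     and spec.include_subject_condition_re else None),
    )

    eye_q = np.eye(q)
    ridge = 1e-8
    ref_surf: list = [None] * R

    def fixed_coef():
        """(n_obs, q) fixed-effect coefficient vectors."""
        out = np.zeros((n_obs, q))
        for r in range(R):
            w = np.kron(u[r], v[r])
            out += np.outer(X @ gamma[:, r], w)
        return out

    k_save = 0
    for it in range(n_iter):
        Fc = fixed_coef()

        # ---- subject-by-condition random surfaces ----
        if spec.include_subject_condition_re:
            theta_other = Fc + b_subj[subj_idx]
            resid_proj = By - theta_other @ G          # (n_obs, q)
            prec = G / sigma2 + eye_q / sigma_sc2
            L = np.linalg.cholesky(prec)
            mean = cho_solve((L, True), resid_proj.T / sigma2).T
            z = rng.standard_normal((n_obs, q))
            b_sc = mean + solve_triangular(L.T, z.T, lower=False).T

        # ---- subject random surfaces ----
        if spec.include_subject_re:
            theta_other = Fc + b_sc
            resid_proj = By - theta_other @ G
            rhs = np.zeros((n_subj, q))
            np.add.at(rhs, subj_idx, resid_proj)
            rhs /= sigma2
            for n_c in np.unique(counts):
                sel = counts == n_c
                prec = n_c * G / sigma2 + eye_q / sigma_subj2
                L = np.linalg.cholesky(prec)
                mean = cho_solve((L, True), rhs[sel].T).T
                z = rng.standard_normal((int(sel.sum()), q))
                b_subj[sel] = mean + solve_triangular(L.T, z.T,
                                                      lower=False).T

        # ---- direction vectors (parameter-expanded sphere updates) ----
        re_coef = b_subj[subj_idx] + b_sc
        base_proj = By - re_coef @ G                    # (n_obs, q)
        for r in range(R):
            # residual projection excluding rank r's fixed term
            proj = base_proj.copy()
            for r2 in range(R):
                if r2 == r:
                    continue
                w2 = np.kron(u[r2], v[r2])
                proj -= np.outer(X @ gamma[:, r2], w2 @ G)

            # update u_r
            a = X @ gamma[:, r]
            A2 = float(a @ a)
            M = np.kron(np.eye(basis.n_time), v[r][:, None])  # (q, n_time)
            prec_u = A2 * (M.T @ G @ M) / sigma2
            prec_u[np.diag_indices_from(prec_u)] += ridge
            lin_u = M.T @ (a @ proj) / sigma2
            u_star = _sample_mvn_prec(rng, prec_u, lin_u)
            nu = np.linalg.norm(u_star)
            if nu > 0:
                u[r] = u_star / nu
                gamma[:, r] *= nu

            # update v_r
            a = X @ gamma[:, r]
            A2 = float(a @ a)
            M = np.kron(u[r][:, None], np.eye(basis.n_freq))  # (q, n_freq)
            prec_v = A2 * (M.T @ G @ M) / sigma2
            prec_v[np.diag_indices_from(prec_v)] += ridge
            lin_v = M.T @ (a @ proj) / sigma2
            v_star = _sample_mvn_prec(rng, prec_v, lin_v)
            nv = np.linalg.norm(v_star)
            if nv > 0:
                v[r] = v_star / nv
                gamma[:, r] *= nv

            # sign identifiability: basis surface positive on delta/theta;
            # a component with essentially no mass there is instead kept
            # aligned with its previous draw, so signs stay coherent
            surf = basis.surface(u[r], v[r])
            criterion = surf[np.ix_(t_in, f_in)].mean()
            if abs(criterion) <= 0.01 * np.linalg.norm(surf):
                if ref_surf[r] is not None:
                    criterion = float(np.sum(surf * ref_surf[r]))
                else:
                    criterion = surf.flat[np.abs(surf).argmax()]
            if criterion < 0:
                v[r] = -v[r]
                gamma[:, r] = -gamma[:, r]
                surf = -surf
            ref_surf[r] = surf

        # ---- amplitudes gamma ----
        phi = np.cumprod(delta)
        W = np.stack([np.kron(u[r], v[r]) for r in range(R)])  # (R, q)
        S = W @ G @ W.T                                        # (R, R)
        prec_g = np.kron(S, XtX) / sigma2
        prior_prec = np.concatenate(
            [phi[r] / (tau2 * lambda2) for r in range(R)])
        prec_g[np.diag_indices_from(prec_g)] += prior_prec
        T_mat = base_proj @ W.T                                # (n_obs, R)
        lin_g = (X.T @ T_mat).flatten(order="F") / sigma2
        g = _sample_mvn_prec(rng, prec_g, lin_g)
        gamma = g.reshape(R, p).T

        # ---- shrinkage hyperparameters ----
        g2 = gamma ** 2                                        # (p, R)
        lambda2 = 1.0 / rng.gamma(
            sh.lambda_shape + R / 2.0,
            1.0 / (sh.lambda_rate + (g2 * phi).sum(axis=1) / (2 * tau2)))
        tau2 = 1.0 / rng.gamma(
            sh.tau_shape + p * R / 2.0,
            1.0 / (sh.tau_rate
                   + float((g2 * phi / lambda2[:, None]).sum()) / 2.0))
        scaled = g2 / lambda2[:, None] / tau2                  # (p, R)
        for h in range(R):
            shape = (sh.mgp_a1 if h == 0 else sh.mgp_a2) \
                + p * (R - h) / 2.0
            phi_wo = np.cumprod(delta)
            phi_wo[h:] /= delta[h]
            rate = 1.0 + 0.5 * float(
                (phi_wo[h:] * scaled[:, h:].sum(axis=0)).sum())
            delta[h] = rng.gamma(shape, 1.0 / rate)

        # ---- random-effect variances ----
        if spec.include_subject_re:
            sigma_subj2 = 1.0 / rng.gamma(
                spec.re_var_shape + n_subj * q / 2.0,
                1.0 / (spec.re_var_rate + float((b_subj ** 2).sum()) / 2.0))
        if spec.include_subject_condition_re:
            sigma_sc2 = 1.0 / rng.gamma(
                spec.re_var_shape + n_obs * q / 2.0,
                1.0 / (spec.re_var_rate + float((b_sc ** 2).sum()) / 2.0))

        # ---- error variance (Jeffreys) ----
        theta = fixed_coef() + b_subj[subj_idx] + b_sc
        ssr = float(y_sq.sum() - 2.0 * np.sum(theta * By)
                    + np.sum((theta @ G) * theta))
        ssr = max(ssr, 0.0)
        sigma2 = 1.0 / rng.gamma(n_obs * n_cells / 2.0,
                                 1.0 / (ssr / 2.0 + 1e-300))
        sigma2 = max(sigma2, spec.sigma2_floor)

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            kept["u"][k_save] = u
            kept["v"][k_save] = v
            kept["gamma"][k_save] = gamma
            kept["sigma2"][k_save] = sigma2
            kept["tau2"][k_save] = tau2
            kept["lambda2"][k_save] = lambda2
            kept["phi"][k_save] = np.cumprod(delta)
            if kept["sigma_subj2"] is not None:
                kept["sigma_subj2"][k_save] = sigma_subj2
            if kept["sigma_sc2"] is not None:
                kept["sigma_sc2"][k_save] = sigma_sc2
            if kept["b_subject"] is not None:
                kept["b_subject"][k_save] = b_subj
            if kept["b_subj_cond"] is not None:
                kept["b_subj_cond"][k_save] = b_sc
            k_save += 1
        if (it + 1) % 500 == 0:
            logger.info("MCMC iteration %d/%d (sigma2=%.4g)", it + 1,
                        n_iter, sigma2)

    return PosteriorDraws(
        basis=basis, col_names=list(info.col_names), u=kept["u"],
        v=kept["v"], gamma=kept["gamma"], sigma2=kept["sigma2"],
        sigma_subj2=kept["sigma_subj2"], sigma_sc2=kept["sigma_sc2"],
        tau2=kept["tau2"], lambda2=kept["lambda2"], phi=kept["phi"],
        b_subject=kept["b_subject"], b_subj_cond=kept["b_subj_cond"],
        subject_ids=list(info.subject_ids))


# ----------------------------------------------------------------------
# Posterior summaries
# ----------------------------------------------------------------------

@dataclass
class ContrastSummary:
    name: str
    mean: float
    lower: float
    upper: float
    level: float
    exceeds_zero: bool
    draws: np.ndarray | None = None

    def as_dict(self) -> dict:
        return dict(name=self.name, mean=self.mean, lower=self.lower,
                    upper=self.upper, level=self.level,
                    exceeds_zero=self.exceeds_zero)


def _contrast_vector(draws: PosteriorDraws,
                     contrast: str | dict[str, float]) -> np.ndarray:
    c = np.zeros(len(draws.col_names))
    if isinstance(contrast, str):
        c[draws.column_index(contrast)] = 1.0
    else:
        for col, w in contrast.items():
            c[draws.column_index(col)] += float(w)
    return c


def contrast_draws(draws: PosteriorDraws,
                   contrast: str | dict[str, float],
                   scale: str = "surface") -> np.ndarray:
    """Per-draw scalar contrast of the amplitudes.

    ``scale='surface'`` multiplies each rank's amplitude by the Frobenius
    norm of that rank's basis surface, putting the contrast on the scale of
    a unit-norm effect surface (comparable across draws and to generative
    amplitudes); ``scale='basis'`` reports the raw amplitude sum.
    """
    c = _contrast_vector(draws, contrast)
    amp = np.einsum("p,dpr->dr", c, draws.gamma)         # (n_keep, R)
    if scale == "basis":
        return amp.sum(axis=1)
    if scale != "surface":
        raise ValueError("scale must be 'surface' or 'basis'")
    tnorm = np.linalg.norm(
        np.einsum("tj,drj->drt", draws.basis.time_basis, draws.u), axis=2)
    fnorm = np.linalg.norm(
        np.einsum("fj,drj->drf", draws.basis.freq_basis, draws.v), axis=2)
    return (amp * tnorm * fnorm).sum(axis=1)


def summarize_contrast(draws: PosteriorDraws,
                       contrast: str | dict[str, float],
                       level: float = 0.90,
                       scale: str = "surface") -> ContrastSummary:
    """Posterior mean and equal-tailed credible interval of a contrast."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    vals = contrast_draws(draws, contrast, scale=scale)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    name = contrast if isinstance(contrast, str) else \
        " + ".join(f"{w:+g}*{k}" for k, w in contrast.items())
    return ContrastSummary(name=name, mean=float(vals.mean()),
                           lower=float(lo), upper=float(hi), level=level,
                           exceeds_zero=bool(lo > 0 or hi < 0),
                           draws=vals)


def summarize_all_contrasts(draws: PosteriorDraws, columns=None,
                            level: float = 0.90) -> pd.DataFrame:
    """Contrast table (one row per design column) for CSV export."""
    columns = draws.col_names if columns is None else columns
    rows = [summarize_contrast(draws, col, level=level).as_dict()
            for col in columns]
    return pd.DataFrame(rows)


def effect_surface(draws: PosteriorDraws, column: str) -> np.ndarray:
    """Posterior-mean (T, F) effect surface for one design column."""
    k = draws.column_index(column)
    basis = draws.basis
    out = np.zeros(basis.grid.shape)
    for d in range(draws.n_keep):
        for r in range(draws.rank):
            out += draws.gamma[d, k, r] * basis.surface(draws.u[d, r],
                                                        draws.v[d, r])
    return out / draws.n_keep


def basis_surface_mean(draws: PosteriorDraws, rank: int = 0) -> np.ndarray:
    """Posterior-mean basis surface of one rank component (Frobenius-
    normalized per draw), for display next to the amplitude summaries."""
    basis = draws.basis
    out = np.zeros(basis.grid.shape)
    for d in range(draws.n_keep):
        s = basis.surface(draws.u[d, rank], draws.v[d, rank])
        out += s / np.linalg.norm(s)
    return out / draws.n_keep


# ----------------------------------------------------------------------
# Automatic rank selection
# ----------------------------------------------------------------------

@dataclass
class RankSelection:
    selected: int
    active: list[bool]
    table: pd.DataFrame
    truncated: bool
    draws: PosteriorDraws


def select_rank(dataset: CohortDataset, spec: ModelSpec,
                basis: BasisSpec | None = None, R_max: int = 3,
                level: float = 0.95) -> RankSelection:
    """Fit at ``R_max`` with ordered shrinkage; keep the smallest rank past
    which every component's amplitude credible intervals all cover zero.

    A rank component is "active" when at least one design column's
    amplitude interval excludes zero. If no component is active the
    selected rank is 1 (flagged as untruncated signal-free)."""
    if R_max < 1:
        raise ValueError("R_max must be >= 1")
    import dataclasses as _dc
    spec_rmax = _dc.replace(spec, rank=R_max)
    draws = fit_mcmc(dataset, spec_rmax, basis)
    alpha = (1.0 - level) / 2.0
    rows, active = [], []
    for r in range(R_max):
        lo = np.quantile(draws.gamma[:, :, r], alpha, axis=0)
        hi = np.quantile(draws.gamma[:, :, r], 1.0 - alpha, axis=0)
        excl = (lo > 0) | (hi < 0)
        active.append(bool(excl.any()))
        rows.append(dict(rank=r + 1, n_active_columns=int(excl.sum()),
                         max_abs_mean=float(
                             np.abs(draws.gamma[:, :, r].mean(axis=0)).max())))
    if any(active):
        selected = max(r + 1 for r in range(R_max) if active[r])
        truncated = selected < R_max
    else:
        selected, truncated = 1, False
        logger.warning("no rank component has amplitudes bounded away from "
                       "zero; defaulting to rank 1")
    if selected == R_max and any(active):
        logger.warning("no truncation triggered at R_max=%d", R_max)
    return RankSelection(selected=selected, active=active,
                         table=pd.DataFrame(rows),
                         truncated=truncated, draws=draws)
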