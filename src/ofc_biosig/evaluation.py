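"""Group-difference testing and treatment-response prediction.

The transfer-validation stage: projection scores are compared across pain
phenotype groups with a one-way ANOVA and Tukey's HSD post-hoc tests
(Tukey-Kramer standard errors for unequal group sizes), and 3-month pain
change is predicted from the biosignature score, the binary widespread-
hyperalgesia phenotype and their interaction, with leave-one-out cross-
validated classification metrics and comparisons against phenotype-only
models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .phenotyping import is_widespread


@dataclass
class GroupTestResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        d = dict(f_stat=self.f_stat, df_between=self.df_between,
                 df_within=self.df_within, p_value=self.p_value)
        if self.tukey is not None:
            d["tukey"] = self.tukey.to_dict(orient="records")
        return d


def _split_groups(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size != labels.size:
        raise ValueError("scores and labels must have equal length")
    names = [g for g in pd.unique(labels)]
    groups = [scores[labels == g] for g in names]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group needs >= 1 value")
    if scores.size <= len(groups):
        raise ValueError("total n must exceed the number of groups")
    return names, groups


def one_way_anova(scores, labels) -> GroupTestResult:
    """Classical one-way ANOVA of scores by group label."""
    names, groups = _split_groups(scores, labels)
    f, p = st.f_oneway(*groups)
    if not np.isfinite(f):
        raise ValueError("ANOVA undefined (zero within-group variance?)")
    return GroupTestResult(f_stat=float(f), df_between=len(groups) - 1,
                           df_within=sum(g.size for g in groups)
                           - len(groups), p_value=float(p))


def tukey_hsd(scores, labels, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Tukey HSD table (Tukey-Kramer under unequal group sizes).

    Columns: group_a, group_b, difference (mean_a - mean_b), p_adj,
    lower/upper simultaneous confidence bounds, reject.
    """
    names, groups = _split_groups(scores, labels)
    res = st.tukey_hsd(*groups)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(dict(
                group_a=names[i], group_b=names[j],
                difference=float(res.statistic[i, j]),
                p_adj=float(res.pvalue[i, j]),
                lower=float(ci.low[i, j]), upper=float(ci.high[i, j]),
                reject=bool(res.pvalue[i, j] < alpha)))
    return pd.DataFrame(rows)


def group_test(scores, labels, alpha: float = 0.05) -> GroupTestResult:
    """ANOVA plus the Tukey post-hoc table in one result."""
    res = one_way_anova(scores, labels)
    res.tukey = tukey_hsd(scores, labels, alpha=alpha)
    return res


# ----------------------------------------------------------------------
# Treatment-response prediction
# ----------------------------------------------------------------------

def _design(model: str, score: np.ndarray, wide: np.ndarray,
            three_level: np.ndarray | None = None) -> tuple[np.ndarray,
                                                            list[str]]:
    if model == "interaction":
        X = np.column_stack([score, wide, score * wide])
        names = ["score", "widespread", "score:widespread"]
    elif model == "widespread_only":
        X = wide[:, None]
        names = ["widespread"]
    elif model == "three_level":
        # two indicators, no-hyperalgesia (non-widespread, non-segmental)
        # as reference
        levels = sorted(map(str, pd.unique(three_level)))
        if len(levels) < 2:
            raise ValueError("three-level phenotype has < 2 levels")
        ref = next((l for l in levels if l.startswith("no")), levels[0])
        others = [l for l in levels if l != ref]
        X = np.column_stack([(three_level == l).astype(float)
                             for l in others])
        names = [f"phenotype[{l}]" for l in others]
    else:
        raise ValueError(f"unknown model {model!r}")
    return X, names


@dataclass
class PredictionReport:
    model: str
    coefficients: dict[str, float]
    r2: float
    adj_r2: float
    loocv_auc: float = float("nan")
    accuracy: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    comparisons: list["PredictionReport"] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = dict(model=self.model, coefficients=self.coefficients,
                 r2=self.r2, adj_r2=self.adj_r2, loocv_auc=self.loocv_auc,
                 accuracy=self.accuracy, sensitivity=self.sensitivity,
                 specificity=self.specificity)
        if self.comparisons:
            d["comparisons"] = [c.as_dict() for c in self.comparisons]
        return d


def fit_interaction_model(score, is_widespread_flag, pain_change
                          ) -> PredictionReport:
    """OLS of pain change on score, phenotype and their interaction."""
    score = np.asarray(score, float)
    wide = np.asarray(is_widespread_flag, float)
    y = np.asarray(pain_change, float)
    if y.size <= 4:
        raise ValueError("need n > 4 for the 4-parameter interaction model")
    X, names = _design("interaction", score, wide)
    return _fit_ols("interaction", X, names, y)


def _fit_ols(model: str, X: np.ndarray, names: list[str],
             y: np.ndarray) -> PredictionReport:
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError(f"perfectly collinear design in model {model!r}")
    fit = sm.OLS(y, Xc).fit()
    coefs = dict(zip(["intercept"] + names, map(float, fit.params)))
    return PredictionReport(model=model, coefficients=coefs,
                            r2=float(fit.rsquared),
                            adj_r2=float(fit.rsquared_adj))


def auc_concordance(predictions, labels) -> float:
    """AUC as the concordant-pair proportion with half credit for ties.

    Orientation: a *higher* prediction value is more responder-like.
    """
    predictions = np.asarray(predictions, float)
    labels = np.asarray(labels, bool)
    if labels.all() or not labels.any():
        raise ValueError("both responder classes must be present")
    return float(roc_auc_score(labels.astype(int), predictions))


def loocv_predictions(data: pd.DataFrame, model: str = "interaction"
                      ) -> np.ndarray:
    """Held-out pain-change prediction per subject.

    For each subject the chosen linear model is refit on the remaining
    subjects and used to predict that subject's pain change; folds with a
    collinear training design are flagged with a warning and left NaN.
    Factor levels are fixed on the full data so every fold shares columns.
    """
    data = data.reset_index(drop=True)
    n = len(data)
    if n < 3:
        raise ValueError("need n >= 3 for LOOCV")
    y = (data["pain_change"] if "pain_change" in data
         else data["followup"] - data["baseline"]).to_numpy(float)
    score = data["score"].to_numpy(float)
    wide = np.array([is_widespread(g) for g in data["phenotype"]], float)
    three = data["phenotype"].to_numpy()
    X_all, _ = _design(model, score, wide,
                       three if model == "three_level" else None)
    Xc_all = sm.add_constant(X_all, has_constant="add")
    preds = np.full(n, np.nan)
    for i in range(n):
        tr = np.arange(n) != i
        Xc = Xc_all[tr]
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            warnings.warn(f"LOOCV fold {i}: collinear design, fold skipped")
            continue
        beta, *_ = np.linalg.lstsq(Xc, y[tr], rcond=None)
        preds[i] = float(Xc_all[i] @ beta)
    return preds


def loocv_classification(data: pd.DataFrame, model: str = "interaction"
                         ) -> tuple[float, float, float, float]:
    """Leave-one-out cross-validated (AUC, accuracy, sensitivity,
    specificity) for predicting treatment response.

    ``data`` needs columns score, phenotype, baseline, followup (or
    pain_change) and responder. AUC ranks the negated held-out predicted
    change against observed responder labels (more-negative predicted
    change = more responder-like, midranks for ties); the binary metrics
    threshold the predicted relative reduction at 30%.
    """
    data = data.reset_index(drop=True)
    responder = data["responder"].to_numpy(bool)
    if responder.all() or not responder.any():
        raise ValueError("both responder classes must be present")
    preds = loocv_predictions(data, model=model)
    ok = np.isfinite(preds)
    auc = auc_concordance(-preds[ok], responder[ok])
    baseline = data["baseline"].to_numpy(float)
    pred_responder = (-preds[ok] / baseline[ok]) >= 0.30
    obs = responder[ok]
    tp = np.sum(pred_responder & obs)
    tn = np.sum(~pred_responder & ~obs)
    accuracy = (tp + tn) / ok.sum()
    sensitivity = tp / obs.sum()
    specificity = tn / (~obs).sum()
    return auc, float(accuracy), float(sensitivity), float(specificity)


def compare_models(data: pd.DataFrame) -> PredictionReport:
    """Fit and cross-validate the interaction model and the two
    phenotype-only alternatives; the lead report carries the comparisons."""
    y = (data["pain_change"] if "pain_change" in data
         else data["followup"] - data["baseline"]).to_numpy(float)
    score = data["score"].to_numpy(float)
    wide = np.array([is_widespread(g) for g in data["phenotype"]], float)
    three = data["phenotype"].to_numpy()

    reports = []
    for model in ("interaction", "widespread_only", "three_level"):
        X, names = _design(model, score, wide,
                           three if model == "three_level" else None)
        rep = _fit_ols(model, X, names, y)
        (rep.loocv_auc, rep.accuracy, rep.sensitivity,
         rep.specificity) = loocv_classification(data, model=model)
        reports.append(rep)
    lead = reports[0]
    lead.comparisons = reports[1:]
    return lead
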