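"""Fixed time-frequency signature mask and per-subject projection scores.

The biosignature of widespread hyperalgesia is a fixed ``T x F`` weight grid:
+1 on delta/theta cells (1-7 Hz), -1 on alpha cells (8-12 Hz), restricted to
the 0.4-0.7 s post-stimulus window, and 0 elsewhere. A subject's projection
score is the weighted sum of their baseline-corrected dB power over the grid,
averaged across a fixed set of stimulus conditions (by default: high
intensity at the affected and unaffected sites, and low intensity at the
unaffected site) and optionally across the two medial-orbitofrontal
hemispheres. Higher scores express the widespread-hyperalgesia pattern:
elevated delta/theta with suppressed alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (CohortDataset, Condition, SubjectRecord, TFRMatrix,
                         TimeFreqGrid, condition_key)

#: Conditions entering the subject-level score.
DEFAULT_SCORE_CONDITIONS: tuple[Condition, ...] = (
    ("affected", "high"), ("unaffected", "high"), ("unaffected", "low"))

DEFAULT_HEMISPHERES = {"left": "mOFC-left", "right": "mOFC-right"}


@dataclass(frozen=True)
class SignatureMask:
    """``T x F`` weight grid in {+1, -1, 0}.

    Band and window membership is decided on bin centers with closed
    intervals: a bin belongs to ``[a, b]`` iff ``a <= center <= b``.
    """

    grid: TimeFreqGrid
    weights: np.ndarray
    window: tuple[float, float] = (0.4, 0.7)
    pos_band: tuple[float, float] = (1.0, 7.0)
    neg_band: tuple[float, float] = (8.0, 12.0)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not np.all(np.isin(w, (-1.0, 0.0, 1.0))):
            raise ValueError("mask weights must be in {-1, 0, +1}")


def build_signature_mask(grid: TimeFreqGrid | None = None,
                         window: tuple[float, float] = (0.4, 0.7),
                         pos_band: tuple[float, float] = (1.0, 7.0),
                         neg_band: tuple[float, float] = (8.0, 12.0),
                         ) -> SignatureMask:
    """Construct the ±1 delta-theta/alpha signature mask on a grid."""
    if grid is None:
        grid = TimeFreqGrid.default()
    if not (pos_band[1] < neg_band[0] or neg_band[1] < pos_band[0]):
        raise ValueError(f"bands overlap: {pos_band} vs {neg_band}")
    t0, t1 = window
    if t0 > t1 or t1 < grid.times[0] or t0 > grid.times[-1]:
        raise ValueError(f"window {window} outside time grid "
                         f"[{grid.times[0]}, {grid.times[-1]}]")
    in_window = (grid.times >= t0) & (grid.times <= t1)
    if not in_window.any():
        raise ValueError(f"no time-bin centers inside window {window}")
    pos = (grid.freqs >= pos_band[0]) & (grid.freqs <= pos_band[1])
    neg = (grid.freqs >= neg_band[0]) & (grid.freqs <= neg_band[1])
    weights = np.zeros(grid.shape)
    weights[np.ix_(in_window, pos)] = 1.0
    weights[np.ix_(in_window, neg)] = -1.0
    return SignatureMask(grid=grid, weights=weights, window=window,
                         pos_band=pos_band, neg_band=neg_band)


def mask_to_frame(mask: SignatureMask) -> pd.DataFrame:
    """Mask as a times x freqs DataFrame, for CSV export / inspection."""
    return pd.DataFrame(mask.weights, index=mask.grid.times,
                        columns=mask.grid.freqs)


def project_score(tfr: TFRMatrix | np.ndarray, mask: SignatureMask) -> float:
    """Weighted sum of dB power over the mask: sum of weight x power."""
    if isinstance(tfr, TFRMatrix):
        if tfr.grid != mask.grid:
            raise ValueError("TFR grid does not match mask grid")
        values = tfr.values
    else:
        values = np.asarray(tfr, dtype=float)
        if values.shape != mask.grid.shape:
            raise ValueError("TFR shape does not match mask grid")
    return float(np.sum(mask.weights * values))


@dataclass
class ProjectionScore:
    subject: str
    hemisphere: str  # "left", "right" or "mean"
    score: float
    conditions: tuple[Condition, ...] = field(
        default_factory=lambda: DEFAULT_SCORE_CONDITIONS)


def subject_score(record: SubjectRecord, mask: SignatureMask,
                  conditions: tuple[Condition, ...] = DEFAULT_SCORE_CONDITIONS,
                  hemispheres: dict[str, str] | None = None,
                  ) -> list[ProjectionScore]:
    """Per-hemisphere and hemisphere-mean projection scores for one subject.

    For each hemisphere ROI, the score is the arithmetic mean of
    ``project_score`` over the specified conditions; the "mean" entry
    averages left and right.
    """
    hemispheres = dict(DEFAULT_HEMISPHERES if hemispheres is None
                       else hemispheres)
    out: list[ProjectionScore] = []
    for hemi, roi in hemispheres.items():
        missing = [condition_key(c) for c in conditions
                   if (roi, condition_key(c)) not in record.tfrs]
        if missing:
            raise KeyError(
                f"subject {record.subject}, ROI {roi}: missing conditions "
                f"{missing}")
        vals = [project_score(record.tfrs[(roi, condition_key(c))], mask)
                for c in conditions]
        out.append(ProjectionScore(record.subject, hemi,
                                   float(np.mean(vals)), tuple(conditions)))
    if len(hemispheres) > 1:
        out.append(ProjectionScore(
            record.subject, "mean",
            float(np.mean([p.score for p in out])), tuple(conditions)))
    return out


def score_cohort(dataset: CohortDataset, mask: SignatureMask,
                 conditions: tuple[Condition, ...] = DEFAULT_SCORE_CONDITIONS,
                 hemispheres: dict[str, str] | None = None) -> pd.DataFrame:
    """Score every subject; wide table with one row per subject.

    Columns: subject, phenotype, cohort, score_left, score_right, score_mean
    (hemisphere columns follow the supplied hemisphere names).
    """
    rows = []
    for rec in dataset.subjects:
        scores = subject_score(rec, mask, conditions, hemispheres)
        row = dict(subject=rec.subject, phenotype=rec.phenotype,
                   cohort=rec.cohort)
        for p in scores:
            row[f"score_{p.hemisphere}"] = p.score
        rows.append(row)
    return pd.DataFrame(rows)
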