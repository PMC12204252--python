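"""Rule-based pain phenotyping and treatment-response classification.

Two cohort frames are supported:

* the chronic-low-back-pain (cLBP) frame with labels
  ``{no_pain, localized_pain, widespread_hyperalgesia}``, assigned from pain
  ratings to low-force stimulation at a site unaffected by the disease; and
* the chronic-pancreatitis (CP) frame with labels
  ``{no_hyperalgesia, segmental_hyperalgesia, widespread_hyperalgesia}``,
  assigned by an external quantitative-sensory-testing battery and consumed
  here as given.

For pooled analyses the frames are harmonized on the widespread-hyperalgesia
axis: CP ``no/segmental`` and cLBP ``localized`` collapse into a single
"localized pain" class, while controls remain "no pain".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CLBP_LABELS = ("no_pain", "localized_pain", "widespread_hyperalgesia")
CP_LABELS = ("no_hyperalgesia", "segmental_hyperalgesia",
             "widespread_hyperalgesia")

WIDESPREAD = "widespread_hyperalgesia"

#: CP and cLBP non-widespread patient labels map to the pooled
#: "localized pain" class; controls stay "no pain".
_POOLED = {
    "no_pain": "no_pain",
    "localized_pain": "localized_pain",
    "no_hyperalgesia": "localized_pain",
    "segmental_hyperalgesia": "localized_pain",
    "widespread_hyperalgesia": WIDESPREAD,
}


def is_widespread(label: str) -> bool:
    """Harmonized binary flag: True iff the 3-level label is widespread."""
    if label not in _POOLED:
        raise ValueError(f"unknown phenotype label {label!r}")
    return label == WIDESPREAD


def harmonize_label(label: str) -> str:
    """Map a cohort-frame label onto the pooled 3-level frame."""
    if label not in _POOLED:
        raise ValueError(f"unknown phenotype label {label!r}")
    return _POOLED[label]


def hyperalgesia_threshold(control_ratings) -> float:
    """Hyperalgesia cut-off: control mean + 2 sample standard deviations.

    The threshold is derived from pain-free controls' ratings of low-force
    stimulation at the disease-unaffected site; the sample (n-1) standard
    deviation is used.
    """
    x = np.asarray(control_ratings, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need >= 2 control ratings to form a threshold")
    if not np.all(np.isfinite(x)):
        raise ValueError("control ratings must be finite")
    return float(x.mean() + 2.0 * x.std(ddof=1))


def classify_clbp(mean_rating: float, threshold: float,
                  has_pain: bool) -> str:
    """Classify one participant in the cLBP frame.

    Controls (``has_pain=False``) are "no pain" regardless of rating.
    Patients are widespread iff their mean rating at the unaffected-site
    low-force condition is strictly above the threshold; a rating exactly
    at the threshold counts as localized.
    """
    if not np.isfinite(mean_rating):
        raise ValueError("mean rating must be finite")
    if not has_pain:
        return "no_pain"
    return WIDESPREAD if mean_rating > threshold else "localized_pain"


def classify_cohort(ratings: pd.DataFrame, has_pain: pd.Series | dict,
                    site: str = "unaffected", intensity: str = "low"
                    ) -> pd.Series:
    """Phenotype every subject in a long ratings table.

    Parameters
    ----------
    ratings : DataFrame with columns subject, site, intensity, rating
        Per-trial 0-10 numerical rating scale values.
    has_pain : mapping subject -> bool
        False marks pain-free controls (who also define the threshold).
    """
    mask = (ratings["site"] == site) & (ratings["intensity"] == intensity)
    sub = ratings.loc[mask]
    if sub.empty:
        raise ValueError(f"no ratings for condition ({site}, {intensity})")
    means = sub.groupby("subject")["rating"].mean()
    has_pain = pd.Series(dict(has_pain))
    controls = means.index[~has_pain.reindex(means.index).astype(bool)]
    thr = hyperalgesia_threshold(means.loc[controls].to_numpy())
    return pd.Series(
        {sid: classify_clbp(means[sid], thr, bool(has_pain[sid]))
         for sid in means.index}, name="phenotype")


def classify_responder(baseline: float, followup: float) -> bool:
    """Treatment responder: >= 30% reduction in pain severity vs baseline."""
    if not (np.isfinite(baseline) and np.isfinite(followup)):
        raise ValueError("pain severities must be finite")
    if baseline <= 0:
        raise ValueError("relative reduction undefined for baseline <= 0")
    return (baseline - followup) / baseline >= 0.30
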