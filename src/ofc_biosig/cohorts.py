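"""Reference cohort composition tables.

Group counts and baseline summaries for the two study cohorts whose design
the synthetic generator emulates: a chronic-low-back-pain (cLBP) cohort with
pain-free controls, phenotyped into no pain / localized pain / widespread
hyperalgesia, and a chronic-pancreatitis (CP) cohort phenotyped into
no / segmental / widespread hyperalgesia. These tables seed the generator's
default sample sizes and covariate distributions.
"""

from __future__ import annotations

import pandas as pd

#: cLBP-frame cohort composition (controls + patients).
CLBP_PHENOTYPE_COUNTS = {
    "no_pain": 25,
    "localized_pain": 30,
    "widespread_hyperalgesia": 12,
}

#: CP-frame cohort composition.
CP_PHENOTYPE_COUNTS = {
    "no_hyperalgesia": 6,
    "segmental_hyperalgesia": 4,
    "widespread_hyperalgesia": 8,
}

#: Baseline covariate summaries by phenotype (mean, SD) used as generator
#: defaults: average pain intensity on the 0-10 scale and age in years, plus
#: the fraction of male participants.
CLBP_BASELINE = pd.DataFrame(
    {
        "pain_mean": [0.28, 5.53, 6.25],
        "pain_sd": [0.84, 2.03, 2.38],
        "age_mean": [46.00, 50.73, 54.25],
        "age_sd": [14.98, 17.18, 14.92],
        "male_frac": [0.80, 16 / 30, 0.75],
    },
    index=["no_pain", "localized_pain", "widespread_hyperalgesia"],
)

CP_BASELINE = pd.DataFrame(
    {
        "pain_mean": [4.29, 3.38, 3.84],
        "pain_sd": [2.58, 2.26, 1.41],
        "age_mean": [61.83, 53.25, 52.50],
        "age_sd": [17.37, 7.37, 17.55],
        "male_frac": [1.00, 0.50, 0.50],
    },
    index=["no_hyperalgesia", "segmental_hyperalgesia",
           "widespread_hyperalgesia"],
)


def widespread_fraction_clbp() -> float:
    """Fraction of cLBP *patients* (controls excluded) with widespread
    hyperalgesia."""
    n_wide = CLBP_PHENOTYPE_COUNTS["widespread_hyperalgesia"]
    n_patients = n_wide + CLBP_PHENOTYPE_COUNTS["localized_pain"]
    return n_wide / n_patients
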