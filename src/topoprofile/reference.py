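"""Reference cohort-level profile weights used in worked examples.

These are literature-reported weight estimates for three neurodegenerative
cohorts -- Alzheimer's disease (AD), primary progressive multiple sclerosis
(PPMS), and healthy ageing (HA) -- over the nine network metrics, in the
package's canonical metric order. They serve as fixed inputs for the
profile-summarization worked examples (sparsification, descriptor grouping,
percentage view) and for documentation; nothing in the pipeline depends on
them.
"""
from __future__ import annotations

import pandas as pd

from .metrics import METRIC_NAMES

#: full (pre-sparsification) cohort weight estimates
COHORT_WEIGHTS = pd.DataFrame(
    {
        "AD":   [0.21, 0.01, 0.03, 0.19, 0.05, 0.01, 0.65, 0.06, 0.07],
        "PPMS": [0.10, 0.11, 0.07, 0.14, 0.17, 0.32, 0.06, 0.22, 0.08],
        "HA":   [0.09, 0.03, 0.13, 0.10, 0.01, 0.01, 0.01, 0.64, 0.19],
    },
    index=list(METRIC_NAMES),
)

#: late-stage (end-stage-atrophy-only) counterparts of the same cohorts
LATE_STAGE_WEIGHTS = pd.DataFrame(
    {
        "AD":   [0.15, 0.01, 0.03, 0.07, 0.06, 0.09, 0.30, 0.12, 0.04],
        "PPMS": [0.11, 0.06, 0.11, 0.11, 0.12, 0.25, 0.05, 0.15, 0.10],
        "HA":   [0.05, 0.01, 0.09, 0.03, 0.06, 0.01, 0.02, 0.15, 0.33],
    },
    index=list(METRIC_NAMES),
)
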