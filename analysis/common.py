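"""Shared configuration of the demo analysis.

The demo cohort is scaled down from the full design (12 subjects instead
of 60, 15-s records instead of 300-s) so the whole five-script sequence
runs in minutes on one CPU; every stage is otherwise identical to a
full-scale run.
"""

from pathlib import Path

from erpscreen import CohortSpec, CVSpec

RESULTS = Path(__file__).resolve().parent.parent / "results"

DEMO_COHORT = CohortSpec(n_per_group=6, n_stimuli=10)

#: 2-fold subject-grouped CV: folds of 6 subjects, 3 per class, so the
#: permutation-null accuracy of every classifier is centred at 50%.
DEMO_CV = CVSpec(n_folds=2, grouped=True)

DL_MAX_ITER = 15  # the 50-layer net plateaus within ~15 epochs


def cohort_dir() -> Path:
    return RESULTS / "cohort"
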