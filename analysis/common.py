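"""Shared study configuration for the numbered analysis drivers.

One synthetic cohort at the study's scale — 20 participants, two stages,
231 time points at TR 2.6 s — on a 30-seed atlas (keeping C(S,2) = 435
connections tractable on a desktop), with 12 planted connectivity
changes of +0.4 and a 0.2% rate of injected extreme FC values, enough
for the robust outlier screen's total attrition to land near the scale
seen on real cohorts of this size (roughly a third of all features).  Every driver derives its inputs from this
config, so the whole analysis is reproducible end to end.
"""

from pathlib import Path

from fcstage.synthetic import CohortConfig, cohort_fc, toy_atlas

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STUDY = CohortConfig(
    n_participants=20,
    n_seeds=30,
    n_timepoints=231,
    tr_seconds=2.6,
    band_hz=(0.01, 0.1),
    n_planted=12,
    effect_size=0.4,
    outlier_rate=0.002,
    rng_seed=2018,
)

ATLAS = toy_atlas(STUDY.n_seeds)


def study_cohort():
    """(X_pre, X_post, participants, truth) for the shared study cohort."""
    RESULTS.mkdir(exist_ok=True)
    return cohort_fc(STUDY, ATLAS)
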