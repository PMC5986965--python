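import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fcstage.synthetic import CohortConfig, cohort_fc, toy_atlas

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def planted_cohort():
    """Study-scale planted-effect cohort shared across tests.

    20 participants, 30 seeds, 231 time points, 12 seed pairs whose
    latent correlation rises by 0.4 from pre to post.
    """
    cfg = CohortConfig(
        n_participants=20,
        n_seeds=30,
        n_timepoints=231,
        n_planted=12,
        effect_size=0.4,
        rng_seed=11,
    )
    atlas = toy_atlas(30)
    x_pre, x_post, participants, truth = cohort_fc(cfg, atlas)
    return {
        "config": cfg,
        "atlas": atlas,
        "x_pre": x_pre,
        "x_post": x_post,
        "participants": participants,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def null_replicates():
    """Twenty independent null cohorts (no planted effect) with their
    nested and pooled-fit LOOCV accuracies; shared by the calibration
    and leakage-bias checks."""
    import warnings

    from fcstage.classify import loocv_by_participant

    nested, faithful = [], []
    for seed in range(20):
        cfg = CohortConfig(
            n_participants=20, n_seeds=30, n_timepoints=231,
            n_planted=0, effect_size=0.0, rng_seed=100 + seed,
        )
        x_pre, x_post, parts, _ = cohort_fc(cfg, toy_atlas(30))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nested.append(loocv_by_participant(x_pre, x_post, parts, mode="nested").accuracy)
            faithful.append(
                loocv_by_participant(x_pre, x_post, parts, mode="pooled").accuracy
            )
    return np.array(nested), np.array(faithful)
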