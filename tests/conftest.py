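import numpy as np
import pytest

from hgfbehav import analysis
from hgfbehav.bms import bma, rfx_bms
from hgfbehav.inversion import InversionOptions, evidence_matrix, fit_subject
from hgfbehav.respmodel import MODEL_NAMES
from hgfbehav.task import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def recovery_study():
    """Model/parameter recovery at desk scale: 20 model-A agents, 5 runs,
    pi_a grid {0.8, 1.2, 1.6}, all 8 variants fitted per run."""
    return analysis.run_recovery(
        ["A"], [0.8, 1.2, 1.6], n_subjects=20, seed=20,
        inversion_opts=InversionOptions(n_restarts=2, seed=20),
        n_bms_samples=100_000,
    )


@pytest.fixture(scope="session")
def nt_like_pipeline():
    """Full pipeline on a 26-agent cohort at the study-condition defaults
    (group-mean pi_a 1.37, omega2 -0.72, omega3 -6.23 with the printed
    between-subject SDs): simulate -> fit 8 models per run -> BMS -> BMA
    -> behavioral scoring."""
    cohort = simulate_cohort(26, seed=2026, spec=CohortSpec())
    opts = InversionOptions(n_restarts=2, seed=2026)
    all_fits = [
        fit_subject(s["responses"], s["schedule"], opts=opts,
                    subject=s["subject"])
        for s in cohort
    ]
    lme = evidence_matrix(all_fits)
    bms = rfx_bms(lme, model_names=list(MODEL_NAMES), n_samples=200_000,
                  seed=2026)
    bma_table = bma(all_fits, bms)
    scores = [analysis.score_behavior(s["responses"], s["schedule"])
              for s in cohort]
    return {
        "cohort": cohort,
        "all_fits": all_fits,
        "evidence": lme,
        "bms": bms,
        "bma": bma_table,
        "scores": scores,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
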