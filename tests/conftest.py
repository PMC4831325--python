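"""Shared fixtures: acquisition grid, a typical AIF, and seeded cohorts.

The cohort fixtures are session-scoped because the full-pipeline fits
over 29 subjects x 4 methods x 2 hematocrit modes dominate the suite's
runtime; every test that needs cohort-level results reuses them.
"""

import numpy as np
import pytest

from mrgfr import model_fitting as mf
from mrgfr import pk_models as pk
from mrgfr import synthetic_cohort as sc

COHORT_SEED = 20160413  # study-date seed used for the default cohorts

METHODS = ("ss", "fixed90", "fixed110", "inflow_outflow")
HCT_MODES = ("subject", "fixed41")


@pytest.fixture(scope="session")
def times():
    """The study acquisition grid: 135 samples at 1.7 s."""
    return 1.7 * np.arange(135)


@pytest.fixture(scope="session")
def typical_aif():
    """A plasma AIF representative of the synthetic cohort family.

    First-pass peak 1.0 at ~29 s, recirculation/retention hump peaking at
    0.3 around 111 s with an 11 s washout constant.
    """
    peak1, b1, c1 = 1.0, 3.0, 2.6
    peak2, b2, c2 = 0.3, 6.0, 11.0
    return pk.AifModel(
        a1=peak1 / ((b1 * c1) ** b1 * np.exp(-b1)), b1=b1, c1=c1, t1=21.0,
        a2=peak2 / ((b2 * c2) ** b2 * np.exp(-b2)), b2=b2, c2=c2, t2=45.0,
    )


@pytest.fixture(scope="session")
def noisefree_cohort():
    cfg = sc.CohortConfig(seed=COHORT_SEED, noise_sd=0.0, reference_noise_sd=0.0)
    return sc.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisefree_ss_fits(noisefree_cohort):
    return [mf.estimate_subject_gfr(r, "ss", "subject") for r in noisefree_cohort]


@pytest.fixture(scope="session")
def noisy_cohort():
    return sc.simulate_cohort(sc.CohortConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def noisy_fits(noisy_cohort):
    """All kidney fits of the default noisy cohort, keyed (method, hct_mode)."""
    out = {}
    for hm in HCT_MODES:
        for me in METHODS:
            out[(me, hm)] = [
                mf.estimate_subject_gfr(r, me, hm) for r in noisy_cohort
            ]
    return out
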