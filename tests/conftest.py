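import warnings

import numpy as np
import pytest

from cuffbp import preprocess as pp
from cuffbp import synth

warnings.filterwarnings("ignore", message="upper band edge clipped")


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise-free cohort configuration for exact-ground-truth checks."""
    return synth.SynthCohortConfig(duration_s=30.0, noise_sd=0.0, bp_noise_sd=0.0,
                                   seed=11)


@pytest.fixture(scope="session")
def clean_record(clean_cfg):
    rec, truth = synth.generate_record(clean_cfg, np.random.default_rng(11))
    return rec, truth


@pytest.fixture(scope="session")
def clean_fiducials(clean_record):
    rec, truth = clean_record
    ecg = pp.compensate_group_delay(pp.filter_ecg(rec.ecg, rec.fs), 50)
    r = pp.detect_r_peaks(ecg, rec.fs)
    fid = pp.detect_ppg_fiducials(rec.ppg, rec.fs, r)
    return rec, truth, fid


@pytest.fixture(scope="session")
def planted_table():
    return synth.generate_feature_table(n_rows=2000, seed=0)
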