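import numpy as np
import pytest

from uraman import preprocess as pp
from uraman import spectra_io as io
from uraman import synthetic_data as sd


@pytest.fixture(scope="session")
def grid():
    return io.DEFAULT_GRID


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny mixed-sex cohort with control, raw scans + metadata."""
    cfg = sd.CohortConfig(
        n_female=6,
        n_male=4,
        specimens_per_donor=2,
        scans_per_specimen=3,
        seed=5,
    )
    scans, meta = sd.generate_cohort(cfg)
    cscans, cmeta = sd.generate_control(cfg, 3)
    return cfg, scans + cscans, meta, cmeta


@pytest.fixture(scope="session")
def preprocessed_cohort(small_cohort):
    """The small cohort preprocessed and truncated to the analysis window."""
    cfg, scans, meta, cmeta = small_cohort
    spectra = io.assemble_set(scans, cfg.grid)
    pre = pp.preprocess_set(spectra)
    return pp.truncate_window(pre), meta, cmeta
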