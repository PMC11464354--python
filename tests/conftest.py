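import numpy as np
import pytest

from scnkit.prep import residualize, zscore_reference
from scnkit.synthetic import CohortConfig, generate_cohort, records_to_frame

#: coarse admitted range used by fast end-to-end tests
FAST_GRID = tuple(np.round(np.arange(0.10, 0.181, 0.02), 2))


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured two-group cohort (8 CI / 10 NCI)."""
    cfg = CohortConfig(n_ci=8, n_nci=10, seed=42)
    table, records = generate_cohort(cfg)
    return cfg, table, records


@pytest.fixture(scope="session")
def small_zscores(small_cohort):
    _, table, records = small_cohort
    subs = records_to_frame(records)
    resid = residualize(table, subs)
    ref = tuple(subs.index[subs["group"] == "NCI"])
    return zscore_reference(resid, ref), subs


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
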