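import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from strainpop import synthdata
from strainpop.coresnp import SnpMatrix

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


def make_snp_matrix(alleles, positions=None, strain_ids=None, genome_length=0):
    """Build a SnpMatrix from a 0/1/-1 allele array (helper for toy cases)."""
    al = np.asarray(alleles, dtype=np.int8)
    n, m = al.shape
    pos = (np.asarray(positions, dtype=np.int64) if positions is not None
           else np.arange(1, m + 1, dtype=np.int64))
    ids = strain_ids or [f"s{i + 1}" for i in range(n)]
    return SnpMatrix(ids, "reference", pos,
                     np.zeros(m, dtype=np.int8), np.ones(m, dtype=np.int8),
                     al, genome_length=genome_length or int(pos[-1]) + 10)


@pytest.fixture(scope="session")
def default_cohort():
    """One full synthetic cohort under the default study conditions."""
    cfg = synthdata.SimConfig(seed=0)
    return cfg, synthdata.simulate_cohort(cfg)
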