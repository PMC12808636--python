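import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pwmr.sumstats import SumStatTable

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.filter_too_much])
settings.load_profile("suite")

_DEFAULTS = dict(chrom="1", pos=100, ea="A", nea="G", eaf=0.3,
                 beta=0.1, se=0.05, pval=1e-4, n=10_000)


def build_table(rows, trait_id="trait", trait_type="exposure") -> SumStatTable:
    """Build a SumStatTable from partial row dicts, filling sane defaults."""
    full = []
    for i, row in enumerate(rows):
        d = {**_DEFAULTS, "rsid": f"rs{i + 1}", **row}
        full.append(d)
    return SumStatTable(trait_id=trait_id, df=pd.DataFrame(full),
                        trait_type=trait_type)


@pytest.fixture
def mk_table():
    return build_table


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
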