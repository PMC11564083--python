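import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from redprev import load_registry

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture()
def rng():
    return np.random.default_rng(20_250_901)


def make_allele_table(rows):
    """Build a cohort allele table from (sample, locus, a1, a2, sex, pop) tuples."""
    return pd.DataFrame(
        [
            {
                "sample_id": r[0],
                "locus": r[1],
                "allele1": float(r[2]),
                "allele2": np.nan if r[3] is None else float(r[3]),
                "sex": r[4] if len(r) > 4 else "female",
                "population": r[5] if len(r) > 5 else "EUR",
                "qc_pass": r[6] if len(r) > 6 else True,
            }
            for r in rows
        ]
    )
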