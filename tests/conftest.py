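import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def graph():
    from neurogg.pathway import default_graph
    return default_graph()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def quant_from_conc(conc: dict, sample_id: str = "s1", anchor: str = "36:1;O2") -> pd.DataFrame:
    """Helper: glycan→conc map to a single-sample quant table."""
    return pd.DataFrame(
        [
            {"sample_id": sample_id, "glycan": g, "anchor": anchor, "conc_nmol_per_mg": c}
            for g, c in conc.items()
        ]
    )
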