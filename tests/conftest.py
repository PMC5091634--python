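import numpy as np
import pandas as pd
import pytest

from tp53ihc.classify import classify_cohort
from tp53ihc.datasets import load_table4_cohort


@pytest.fixture(scope="session")
def table4():
    """The packaged 249-case contingency fixture, classified."""
    return classify_cohort(load_table4_cohort())


@pytest.fixture()
def rng():
    return np.random.default_rng(20160713)


def random_labelled_cohort(rng, n: int) -> pd.DataFrame:
    """A cohort with arbitrary class/pattern labels for tabulation testing."""
    return pd.DataFrame({
        "case_id": [f"R{i}" for i in range(n)],
        "histotype": rng.choice(["HGSOC", "EC"], size=n),
        "variant": ["NDM"] * n,  # placeholder; functional_class set directly below
        "functional_class": rng.choice(["GOF", "LOF", "NDM"], size=n),
        "pattern_m1": rng.choice(
            ["OE", "CA", "WT", "CY", "unscored"], size=n, p=[0.4, 0.2, 0.3, 0.05, 0.05]
        ),
    })
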