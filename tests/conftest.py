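import hypothesis
import pandas as pd
import pytest

import marshsim as ms

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def table3_panels() -> pd.DataFrame:
    """The four seasonal site-mean records (one per marsh), original units."""
    return pd.DataFrame({
        "site": ["Sage Lot Pond", "Hamblin Pond", "Great Pond", "Eel Pond"],
        "timestamp": pd.to_datetime(["2013-07-15 12:00"] * 4),
        "nee": [5.5, 6.9, 4.5, 4.1],
        "par": [1511.7, 1602.5, 1065.1, 1211.5],
        "st": [17.5, 18.7, 17.2, 17.1],
        "ss": [31.0, 26.0, 31.0, 34.0],
        "pa": [1015.4, 1011.3, 1016.6, 1018.8],
    })


@pytest.fixture(scope="session")
def synthetic_campaign():
    """One default-condition synthetic campaign with its truth table."""
    panels, truth = ms.generate_panels(ms.GeneratorConfig(), seed=20130501)
    return panels, truth
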