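import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stepscreen import SearchLog, build_lexicon

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large],
)
settings.load_profile("suite")

SPAN = (pd.Timestamp("2016-11-01"), pd.Timestamp("2017-08-01"))


def make_log(rows, span=SPAN):
    """Build a SearchLog from (user_id, iso_timestamp, query_text[, url]) tuples."""
    df = pd.DataFrame(
        {
            "user_id": [r[0] for r in rows],
            "timestamp": pd.to_datetime([r[1] for r in rows]),
            "query_text": [r[2] for r in rows],
            "clicked_url": [r[3] if len(r) > 3 else "" for r in rows],
        }
    )
    return SearchLog(df, span[0], span[1])


@pytest.fixture(scope="session")
def tiny_lexicon():
    return build_lexicon(
        {
            "diaphoresis": ["sweating", "heavy sweating"],
            "pyrosis": ["heartburn"],
            "rash": ["skin rash"],
            "tinnitus": ["ears ringing", "ringing in the ears"],
            "dizziness": ["dizzy"],
        }
    )
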