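import pandas as pd
import pytest

from hcpmediate import AnalysisSettings, generate_trial
from hcpmediate.simulate import scenario_s0


@pytest.fixture(scope="session")
def s0_dataset():
    """One draw of the default school-trial scenario."""
    return generate_trial(scenario_s0(), seed=1)


@pytest.fixture(scope="session")
def fast_settings():
    """Analysis settings without Monte-Carlo interval draws."""
    return AnalysisSettings(seed=None)


@pytest.fixture()
def toy_frame():
    """4 clusters (2 per arm) x 3 members, complete, hand-checkable."""
    rows = []
    for cid, t in [("A", 0), ("B", 0), ("C", 1), ("D", 1)]:
        for i, (m, y) in enumerate([(1.0, 10.0), (2.0, 11.0), (3.0, 9.0)]):
            rows.append({"cluster": cid, "treatment": t,
                         "mediator": m + i * 0.0, "outcome": y})
    return pd.DataFrame(rows)
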