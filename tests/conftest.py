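import numpy as np
import pytest

import quasicw as q

CONDITION_CODES = ["[c25,00]", "[c50,00]", "[c100,00]", "[c200,00]"]


@pytest.fixture(scope="session")
def thp1_df():
    return q.load_thp1()


@pytest.fixture(scope="session")
def thp1_records():
    return q.load_thp1_records()


@pytest.fixture(scope="session")
def split1():
    return q.load_split1()


@pytest.fixture(scope="session")
def set_series(thp1_df):
    """(observed, calculated) arrays per split-1 set label."""

    def get(label):
        sub = thp1_df[thp1_df.set_label == label]
        return sub.endpoint.to_numpy(), sub.calculated.to_numpy()

    return {lab: get(lab) for lab in "APCV"}


def validation_r2(trace, records):
    """Squared correlation of observed vs predicted on the V set."""
    pred = {r.id: q.predict(r, trace.weight_table, trace.model) for r in records}
    obs = np.array([r.endpoint for r in records if r.set_label == "V"])
    calc = np.array([pred[r.id] for r in records if r.set_label == "V"])
    return q.r2(obs, calc)
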