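import numpy as np
import pandas as pd
import pytest

import leapd


@pytest.fixture(scope="session")
def worked_cohort():
    """The fixed 8-subject, 2-electrode, 10 s cohort."""
    return leapd.generate_worked_example()


@pytest.fixture(scope="session")
def worked_pre(worked_cohort):
    """Preprocessed (normalized, notch-cleaned) worked-example recordings."""
    return {sid: leapd.preprocess_recording(rec)
            for sid, rec in worked_cohort.recordings.items()}


@pytest.fixture(scope="session")
def worked_configs():
    """Fixed electrode configurations for the worked example."""
    return [leapd.ElectrodeConfig("P8", (4.0, 30.0), 7, 3),
            leapd.ElectrodeConfig("PO7", (4.0, 30.0), 7, 3)]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240601)


def make_table(scores, score_name="MoCA", ages=None):
    ids = [f"S{i + 1:03d}" for i in range(len(scores))]
    table = pd.DataFrame({"id": ids, score_name: scores})
    if ages is not None:
        table["age"] = ages
    return table


@pytest.fixture()
def tiny_table():
    return make_table([25, 10, 22, 30, 26, 28])
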