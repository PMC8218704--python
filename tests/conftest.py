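import numpy as np
import pytest

from ddctdna import datasets
from ddctdna.io_formats import AmplitudeTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def table1():
    """Detected-sample reference table (printed droplet counts and VAFs)."""
    return datasets.detected_samples()


def make_table(ch1, ch2, well_id="w1", cluster=None):
    return AmplitudeTable(well_id=well_id, ch1=np.asarray(ch1, float),
                         ch2=np.asarray(ch2, float), cluster=cluster)
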