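import numpy as np
import pytest

from adipomr.sumstats import HarmonisedDataset


def make_dataset(gamma, Gamma, se_Gamma, se_gamma=None, **names) -> HarmonisedDataset:
    """Build a HarmonisedDataset from plain sequences."""
    gamma = np.asarray(gamma, dtype=float)
    if se_gamma is None:
        se_gamma = np.abs(gamma) / 8.0 + 1e-6
    return HarmonisedDataset(
        exposure_name=names.get("exposure_name", "bmi"),
        outcome_name=names.get("outcome_name", "disease"),
        source_name=names.get("source_name", "source_1"),
        variant_id=np.array([f"rs{i}" for i in range(len(gamma))], dtype=object),
        gamma=gamma,
        se_gamma=np.asarray(se_gamma, dtype=float),
        Gamma=np.asarray(Gamma, dtype=float),
        se_Gamma=np.asarray(se_Gamma, dtype=float),
    )


@pytest.fixture
def dataset_factory():
    return make_dataset
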