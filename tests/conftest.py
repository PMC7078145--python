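import pytest

from driftfate import build_marray, reference_config, simulate_study


@pytest.fixture(scope="session")
def ref_cfg():
    """Reference-design simulation config (Gulf drift study shape), seed 7."""
    return reference_config(seed=7)


@pytest.fixture(scope="session")
def ref_records(ref_cfg):
    return simulate_study(ref_cfg)


@pytest.fixture(scope="session")
def ref_marray(ref_cfg, ref_records):
    return build_marray(ref_records, ref_cfg.design)
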