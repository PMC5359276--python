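import numpy as np
import pytest
from hypothesis import settings

from hybridnf.protocol import Block, ProtocolSpec, validate_protocol
from hybridnf.synthetic import SimConfig, gen_eeg, gen_task_design

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def proto_20_20x2():
    """20 s Task / 20 s Rest, 2 repetitions, 0.5 s update period."""
    return validate_protocol(ProtocolSpec(
        blocks=[Block("TASK", 20.0), Block("REST", 20.0)],
        update_period=0.5, repetitions=2,
    ))


@pytest.fixture(scope="session")
def nfb_protocol():
    """Rest-first feedback protocol with a BEGIN warm-up period."""
    return validate_protocol(ProtocolSpec(
        blocks=[Block("BEGIN", 4.0), Block("REST", 20.0), Block("TASK", 20.0)],
        update_period=0.5, repetitions=4,
    ))


@pytest.fixture(scope="session")
def contaminated_run(proto_20_20x2):
    """A default-artifact session: stream, ground truth, config, design."""
    cfg = SimConfig(seed=3, n_volumes=40)
    design, _ = gen_task_design(proto_20_20x2, cfg.tr)
    stream, truth = gen_eeg(cfg, np.ones(40), design)
    return cfg, design, stream, truth
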