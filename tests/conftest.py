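import numpy as np
import pytest

from herdsim import default_config


@pytest.fixture
def cfg():
    return default_config()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


class FixedRng:
    """Stub generator returning scripted uniforms (for boundary cases like u=0)."""

    def __init__(self, values):
        self._values = list(values)

    def random(self, *args, **kwargs):
        return self._values.pop(0)


@pytest.fixture
def degenerate_cfg(cfg):
    """All randomness collapsed: certain heat and conception, zero SDs and losses,
    no stochastic culling, all-female calves."""
    return cfg.copy(
        female_prob_by_semen={"sexed": 1.0},
        first_ovulation_delay_sd=0.0,
        cycle_length_sd=0.0,
        gestation_sd=0.0,
        heat_detection_prob=1.0,
        conception_first_service=1.0,
        conception_decrement_per_service=0.0,
        daily_loss_rates=(0.0, 0.0),
        culling_reason_probs={r: 0.0 for r in cfg.culling_reason_probs},
    )
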