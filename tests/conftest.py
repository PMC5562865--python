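"""Shared fixtures: architectures, event models and small curve batches."""

import logging

import pytest

from cntnmech.architecture import cntn4_architecture
from cntnmech.simulate import SimConfig, cntn4_event_model

logging.getLogger("cntnmech.pipeline").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def arch():
    return cntn4_architecture()


@pytest.fixture(scope="session")
def plain_event_model():
    """No secondary features, full-length attachment: one event per module."""
    return cntn4_event_model(
        p_hump=0.0, p_partial=0.0, p_horseshoe=0.0, p_adhesion=0.0,
        random_pickup=False,
    )


@pytest.fixture()
def quiet_config():
    """Noiseless acquisition for structural round-trip checks."""
    return SimConfig(noise_sd_pN=0.0, seed=0)
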