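"""Shared fixtures: default parameter sets and cached condition runs."""

import pytest

from nvcgaba import Config, StimulusProtocol, run_condition
from nvcgaba.params import ChannelParams, SignallingParams, SurrogateParams


@pytest.fixture(scope="session")
def sig():
    return SignallingParams()


@pytest.fixture(scope="session")
def chan():
    return ChannelParams()


@pytest.fixture(scope="session")
def surr():
    return SurrogateParams()


@pytest.fixture(scope="session")
def config():
    return Config()


@pytest.fixture(scope="session")
def traces(config):
    """Hemoglobin traces for the four experimental conditions (one run each)."""
    out = {}
    for kind in ("whisker", "optogenetic"):
        for lname in (False, True):
            proto = StimulusProtocol(kind=kind, lname=lname)
            out[(kind, lname)] = run_condition(proto, config)
    return out
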