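"""Shared fixtures: the worked micro example and one full synthetic screen.

The synthetic screen (generation + end-to-end run) takes a few seconds, so
it is built once per session and shared by every test that inspects it.
"""

from __future__ import annotations

import numpy as np
import pytest

from ssnscreen import REDUCTASE_SCOPE, run_screen, simulate
from ssnscreen.synthetic_data import SimConfig, make_worked_micro_example

SIM_SEED = 1


@pytest.fixture(scope="session")
def micro():
    return make_worked_micro_example()


@pytest.fixture(scope="session")
def sim():
    return simulate(SimConfig(seed=SIM_SEED))


@pytest.fixture(scope="session")
def screen(sim):
    return run_screen(
        sim.transcripts,
        sim.annotation,
        sim.expression,
        sim.config.taxa,
        REDUCTASE_SCOPE,
        bait_gene=sim.truth.bait_transcript,
        controls=[sim.truth.control_transcript],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
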