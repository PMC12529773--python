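"""Shared fixtures; expensive grid/workflow results are session-scoped."""

import numpy as np
import pytest

from ncitraj.grid_engine import NCIParams, pair_integrals
from ncitraj.synthetic_fixtures import (
    make_apolar_dimer,
    make_hbond_dimer,
    make_toy_folding_trajectory,
)


@pytest.fixture(scope="session")
def hbond_dimer():
    return make_hbond_dimer()


@pytest.fixture(scope="session")
def apolar_dimer():
    return make_apolar_dimer()


@pytest.fixture(scope="session")
def hbond_integrals(hbond_dimer):
    """H-bond dimer integrals at 0.1 and 0.05 bohr (production path)."""
    return {
        sp: pair_integrals(hbond_dimer.fragA, hbond_dimer.fragB, NCIParams(spacing=sp))
        for sp in (0.1, 0.05)
    }


@pytest.fixture(scope="session")
def apolar_integrals(apolar_dimer):
    return {
        sp: pair_integrals(apolar_dimer.fragA, apolar_dimer.fragB, NCIParams(spacing=sp))
        for sp in (0.1, 0.05)
    }


@pytest.fixture(scope="session")
def toy20():
    """The 20-event, 60/40-mix toy trajectory used for pathway recovery."""
    return make_toy_folding_trajectory(n_events=20, pathway1_fraction=0.6, seed=11)


@pytest.fixture(scope="session")
def toy20_result(toy20):
    from ncitraj.workflow import RunConfig, run_workflow

    config = RunConfig(nci=NCIParams(spacing=0.3), seed=11)
    return run_workflow(toy20.fragments, toy20.xyz, config)


@pytest.fixture(scope="session")
def toy_small():
    """A short toy trajectory for cheap unit tests."""
    return make_toy_folding_trajectory(n_events=2, seed=5)


@pytest.fixture()
def coarse_params():
    """Cheap NCI parameters for unit tests that only need plumbing."""
    return NCIParams(spacing=0.3, refine_resolution=0.15)
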