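"""Shared fixtures: small synthetic systems generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from membind import (
    BilayerSpec,
    BindingMode,
    EncounterParams,
    build_bilayer,
    build_protein_model,
    simulate_encounter,
)


@pytest.fixture(scope="session")
def bilayer():
    """Default 800-lipid 75/20/5 bilayer."""
    return build_bilayer(BilayerSpec(), seed=1)


@pytest.fixture(scope="session")
def protein():
    """Default 324-residue sphere model with the two-region hotspot cap."""
    return build_protein_model(seed=3)


@pytest.fixture(scope="session")
def fast_params():
    """Short productive-mode encounter used by several closed-loop tests."""
    return EncounterParams(n_frames=400, dt=0.5, tau=20.0, noise_sigma=0.0,
                           modes=(BindingMode(rzz=1.0, weight=1.0),),
                           tumble_step=0.1, bound_jitter=0.0, seed=7)


@pytest.fixture(scope="session")
def bound_run(protein, bilayer, fast_params):
    """A noiseless, single-mode encounter trajectory plus its truth."""
    return simulate_encounter(protein, bilayer, fast_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
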