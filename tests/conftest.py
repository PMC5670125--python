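import numpy as np
import pytest

from rigidiscope import (
    BlockSpec,
    make_reference_structure,
    simulate_block_trajectory,
    uniform_blocks,
)


@pytest.fixture(scope="session")
def ref_tetramer():
    """4-chain, 30-residue-per-chain Cα-trace reference (120 atoms)."""
    return make_reference_structure(4, 30, seed=7)


@pytest.fixture(scope="session")
def ref_monomer():
    return make_reference_structure(1, 12, seed=3)


@pytest.fixture
def block_traj_factory(ref_tetramer):
    """Build a block trajectory on the shared tetramer reference."""

    def _make(sigma_block=0.5, sigma_local=0.3, scale=1.0, n_frames=200,
              seed=11, rigid_motion=False, n_blocks=4):
        spec = BlockSpec(
            uniform_blocks(ref_tetramer, n_blocks),
            sigma_block=sigma_block,
            sigma_local=sigma_local,
            scale=scale,
        )
        return simulate_block_trajectory(
            ref_tetramer, spec, n_frames, seed, rigid_motion=rigid_motion
        )

    return _make


@pytest.fixture
def rigid_rng():
    return np.random.default_rng(2024)
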