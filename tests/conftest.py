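import numpy as np
import pytest

from ttrkit import contacts, fma, synth


@pytest.fixture(scope="session")
def toy4():
    """Default four-chain toy oligomer (96 residues per chain)."""
    return synth.make_toy_oligomer(4, 96, seed=0)


@pytest.fixture(scope="session")
def toy_small():
    """Small single-chain toy for brute-force oracles."""
    return synth.make_toy_oligomer(1, 20, seed=0)


@pytest.fixture(scope="session")
def unfolding(toy4):
    """Default C/D-region unfolding trajectory of chain A, with fold Q.

    Returns (frames, q, aligned main-chain frames of chain A, chain A
    structure, main-chain mask) — the standard pipeline input reused by the
    contacts/FMA/acceptance tests.
    """
    fold_a = contacts.build_contacts(toy4, "fold", chain="A")
    frames = synth.make_unfolding_trajectory(toy4, ["C", "D"], 1000, seed=1)
    q = contacts.q_timeseries(frames, {"A": fold_a}).q["A"]
    sub_a = toy4.select_chains("A")
    mcm = fma.main_chain_mask(sub_a)
    idx = np.flatnonzero(toy4.chain_ids == "A")
    aligned = fma.align_frames(frames[:, idx][:, mcm], sub_a.coords[mcm])
    return frames, q, aligned, sub_a, mcm
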