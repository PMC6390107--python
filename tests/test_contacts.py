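"""Native-contact lists and the fraction of native contacts Q."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from ttrkit import contacts as ct
from ttrkit.structure import Structure


def brute_force_contacts(ref, mode, cutoff=4.5, min_sep=3):
    """Independent oracle: naive double loop over all heavy-atom pairs."""
    heavy = np.flatnonzero(ref.heavy_mask)
    pairs, r0 = [], []
    for a in range(len(heavy)):
        for b in range(a + 1, len(heavy)):
            i, j = heavy[a], heavy[b]
            d = float(np.linalg.norm(ref.coords[i] - ref.coords[j]))
            if d > cutoff:
                continue
            same = ref.chain_ids[i] == ref.chain_ids[j]
            if mode == "fold":
                if not same or abs(int(ref.resids[i]) - int(ref.resids[j])) < min_sep + 1:
                    continue
            elif same:
                continue
            pairs.append((min(i, j), max(i, j)))
            r0.append(d)
    return sorted(zip(pairs, r0))


def brute_force_q(coords, cs, beta=5.0, lam=1.8):
    total = 0.0
    for (i, j), r0 in zip(cs.pairs, cs.r0):
        r = float(np.linalg.norm(coords[i] - coords[j]))
        total += 1.0 / (1.0 + np.exp(beta * (r - lam * r0)))
    return total / len(cs)


def two_atom_structure(d):
    return Structure(
        chain_ids=np.array(["A", "A"], dtype=object),
        resids=np.array([1, 10]),
        resnames=np.array(["ALA", "ALA"], dtype=object),
        atom_names=np.array(["CA", "CA"], dtype=object),
        elements=np.array(["C", "C"], dtype=object),
        coords=np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]))


class TestBuildContacts:
    @staticmethod
    def _assert_same(cs, oracle):
        got = sorted(zip(map(tuple, cs.pairs), cs.r0))
        assert [p for p, _ in got] == [p for p, _ in oracle]
        assert np.allclose([r for _, r in got], [r for _, r in oracle],
                           atol=1e-12)

    def test_matches_brute_force_oracle(self, toy_small):
        self._assert_same(ct.build_contacts(toy_small, "fold"),
                          brute_force_contacts(toy_small, "fold"))

    def test_interface_matches_brute_force(self, toy4):
        self._assert_same(ct.build_contacts(toy4, "interface"),
                          brute_force_contacts(toy4, "interface"))

    def test_sequence_separation_excludes_near_neighbours(self):
        st_ = two_atom_structure(3.0)
        st_.resids = np.array([1, 2])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cs = ct.build_contacts(st_, "fold")
        assert len(cs) == 0

    def test_chain_pair_restricts_interface(self, toy4):
        ab = ct.build_contacts(toy4, "interface", chain_pair=("A", "B"))
        for i, j in ab.pairs:
            assert {toy4.chain_ids[i], toy4.chain_ids[j]} == {"A", "B"}
        dd = ct.build_contacts(toy4, "interface", chain_pair=("AB", "CD"))
        assert len(dd) > 0
        for i, j in dd.pairs:
            sides = {toy4.chain_ids[i], toy4.chain_ids[j]}
            assert sides & {"A", "B"} and sides & {"C", "D"}

    def test_all_reference_distances_within_cutoff(self, toy4):
        cs = ct.build_contacts(toy4, "fold", chain="A")
        assert np.all(cs.r0 <= 4.5)
        assert len(np.unique(cs.pairs, axis=0)) == len(cs)

    def test_unknown_chain_rejected(self, toy4):
        with pytest.raises(ValueError, match="unknown chain"):
            ct.build_contacts(toy4, "fold", chain="Z")

    def test_hydrogens_excluded(self, toy_small):
        noisy = toy_small.subset(np.arange(toy_small.n_atoms))
        noisy.elements = noisy.elements.copy()
        noisy.elements[:4] = "H"
        cs = ct.build_contacts(noisy, "fold")
        assert not np.isin(cs.pairs, [0, 1, 2, 3]).any()


class TestQValue:
    def test_native_frame_scores_near_one(self, toy4):
        cs = ct.build_contacts(toy4, "fold", chain="A")
        assert ct.q_value(toy4.coords, cs) >= 0.999

    def test_single_pair_at_sigmoid_midpoint_is_half(self):
        st_ = two_atom_structure(3.0)
        cs = ct.build_contacts(st_, "fold")
        moved = st_.coords.copy()
        moved[1, 0] = 3.0 * 1.8  # exactly lambda * r0
        assert ct.q_value(moved, cs) == pytest.approx(0.5, abs=1e-12)

    def test_fully_displaced_frame_scores_near_zero(self, toy_small):
        cs = ct.build_contacts(toy_small, "fold")
        far = toy_small.coords + np.outer(
            50.0 * np.arange(toy_small.n_atoms), [1.0, 0.0, 0.0])[:, :3] * [1, 0, 0]
        assert ct.q_value(far, cs) < 1e-6

    def test_matches_brute_force_to_1e10(self, toy_small):
        cs = ct.build_contacts(toy_small, "fold")
        rng = np.random.default_rng(0)
        frame = toy_small.coords + rng.normal(0, 1.5, toy_small.coords.shape)
        assert ct.q_value(frame, cs) == pytest.approx(
            brute_force_q(frame, cs), abs=1e-10)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_rigid_motion(self, toy_small, seed):
        cs = ct.build_contacts(toy_small, "fold")
        rng = np.random.default_rng(seed)
        frame = toy_small.coords + rng.normal(0, 1.0, toy_small.coords.shape)
        rot = Rotation.random(random_state=int(seed)).as_matrix()
        moved = frame @ rot.T + rng.uniform(-50, 50, 3)
        assert ct.q_value(moved, cs) == pytest.approx(
            ct.q_value(frame, cs), abs=1e-9)

    def test_monotone_in_single_pair_distance(self):
        st_ = two_atom_structure(4.0)
        cs = ct.build_contacts(st_, "fold")
        distances = np.linspace(4.0, 20.0, 30)
        qs = []
        for d in distances:
            c = st_.coords.copy()
            c[1, 0] = d
            qs.append(ct.q_value(c, cs))
        assert np.all(np.diff(qs) < 0)

    def test_empty_contact_set_rejected(self, toy_small):
        cs = ct.ContactSet(np.empty((0, 2), dtype=int), np.empty(0), "fold")
        with pytest.raises(ValueError, match="undefined"):
            ct.q_value(toy_small.coords, cs)


class TestQTimeseries:
    def test_single_frame_equals_q_value(self, toy_small):
        cs = ct.build_contacts(toy_small, "fold")
        qs = ct.q_timeseries(toy_small.coords[None], {"fold": cs})
        assert qs.q["fold"][0] == pytest.approx(
            ct.q_value(toy_small.coords, cs), abs=1e-12)

    def test_units_evaluated_independently(self, toy4):
        fold_a = ct.build_contacts(toy4, "fold", chain="A")
        fold_b = ct.build_contacts(toy4, "fold", chain="B")
        rng = np.random.default_rng(1)
        frame = toy4.coords.copy()
        frame[toy4.chain_ids == "B"] += rng.normal(0, 6.0, (int((toy4.chain_ids == "B").sum()), 3))
        qs = ct.q_timeseries(frame[None], {"A": fold_a, "B": fold_b})
        assert qs.q["A"][0] > 0.99
        assert qs.q["B"][0] < 0.5

    def test_atom_index_mismatch_reported(self, toy_small):
        cs = ct.build_contacts(toy_small, "fold")
        with pytest.raises(ValueError, match="frame"):
            ct.q_timeseries(toy_small.coords[None, :10], {"fold": cs})


class TestQByRegion:
    def test_uniform_displacement_gives_equal_regions(self, toy_small):
        cs = ct.build_contacts(toy_small, "fold")
        # uniform scaling displaces every pair proportionally to its r0
        frame = toy_small.coords * 1.5
        regions = {"first": set(range(1, 11)), "second": set(range(11, 21))}
        qs = ct.q_by_region(frame[None], cs, toy_small, regions)
        vals = [qs.q[k][0] for k in qs.q]
        assert np.ptp(vals) < 0.2  # both regions respond alike

    def test_perturbed_region_scores_lowest(self, toy4, unfolding):
        frames, _, _, _, _ = unfolding
        cs = ct.build_contacts(toy4, "fold", chain="A")
        qs = ct.q_by_region(frames[-1][None], cs, toy4, toy4.regions)
        finals = {k: qs.q[k][0] for k in qs.q}
        perturbed = min(finals["C"], finals["D"])
        for lab in "AE":
            assert finals[lab] > perturbed

    def test_partition_recovers_global_q_as_weighted_mean(self, toy_small):
        cs = ct.build_contacts(toy_small, "fold")
        rng = np.random.default_rng(3)
        frame = toy_small.coords + rng.normal(0, 2.0, toy_small.coords.shape)
        # partition of contacts by lower atom index residue: weights sum to N
        resid_lo = toy_small.resids[cs.pairs[:, 0]]
        groups = {"lo": cs.subset(resid_lo <= 10), "hi": cs.subset(resid_lo > 10)}
        qg = ct.q_value(frame, cs)
        weighted = sum(len(g) * ct.q_value(frame, g) for g in groups.values()) / len(cs)
        assert weighted == pytest.approx(qg, abs=1e-6)

    def test_empty_region_omitted_with_warning(self, toy_small):
        cs = ct.build_contacts(toy_small, "fold")
        with pytest.warns(UserWarning, match="omitted"):
            qs = ct.q_by_region(toy_small.coords[None], cs, toy_small,
                                {"ghost": {999}, "all": set(range(1, 21))})
        assert "ghost" not in qs.q and "all" in qs.q
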