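"""Fraction of native contacts (Q) for folds and inter-chain interfaces.

A native contact is a pair of heavy atoms within 4.5 Å in the reference
(native) structure, either on residues more than three residues apart in
sequence on the same chain (fold mode) or on two different chains (interface
mode). For a configuration x, each contact contributes a smoothed indicator

    q_ij(x) = 1 / (1 + exp(beta * (r_ij(x) - lam * r0_ij)))

with beta = 5 Å^-1 and lam = 1.8 (the fluctuation allowance appropriate for
atomistic simulations), and Q(x) is the mean over the contact list. Q near 1
means the unit is native-like; near 0, unfolded or dissociated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure

__all__ = ["ContactSet", "QSeries", "build_contacts", "q_value",
           "q_timeseries", "q_by_region"]

DEFAULT_CUTOFF = 4.5  # Å
DEFAULT_BETA = 5.0  # Å^-1
DEFAULT_LAMBDA = 1.8


@dataclass
class ContactSet:
    """Native-contact list: atom index pairs with reference distances (Å)."""

    pairs: np.ndarray  # (N, 2) int, each row sorted, unique
    r0: np.ndarray  # (N,) Å
    mode: str  # "fold" | "interface"
    labels: np.ndarray | None = None  # optional per-pair region tag

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.r0 = np.asarray(self.r0, dtype=float)
        if len(self.pairs) != len(self.r0):
            raise ValueError("pairs and r0 length mismatch")

    def __len__(self) -> int:
        return len(self.pairs)

    def subset(self, mask: np.ndarray) -> "ContactSet":
        mask = np.asarray(mask, dtype=bool)
        labels = self.labels[mask] if self.labels is not None else None
        return ContactSet(self.pairs[mask], self.r0[mask], self.mode, labels)


@dataclass
class QSeries:
    """Per-frame Q for one or more tracked units (monomers, interfaces, regions)."""

    frames: np.ndarray  # frame indices
    q: dict  # unit name -> (n_frames,) array

    def to_frame(self):
        import pandas as pd

        rows = [(int(f), unit, float(v))
                for unit, vals in self.q.items()
                for f, v in zip(self.frames, vals)]
        return pd.DataFrame(rows, columns=["frame", "unit", "Q"])


def build_contacts(ref: Structure, mode: str = "fold",
                   cutoff: float = DEFAULT_CUTOFF, min_sep: int = 3,
                   chain: str | None = None,
                   chain_pair: tuple | None = None) -> ContactSet:
    """Enumerate native contacts in a reference structure.

    Fold mode keeps intra-chain heavy-atom pairs whose residues are separated
    by more than ``min_sep`` other residues (|Δresid| >= min_sep + 1),
    optionally restricted to one chain. Interface mode keeps pairs on two
    different chains, optionally restricted to an unordered ``chain_pair``
    such as ("A", "B") for a monomer–monomer interface or with grouped ids
    like ("AB", "CD") for the dimer–dimer interface.
    """
    if mode not in ("fold", "interface"):
        raise ValueError(f"unknown mode {mode!r}")
    known = set(str(c) for c in np.unique(ref.chain_ids))
    for arg in ([chain] if chain else []) + (list("".join(chain_pair)) if chain_pair else []):
        if arg not in known:
            raise ValueError(f"unknown chain id {arg!r}; structure has {sorted(known)}")

    heavy = np.flatnonzero(ref.heavy_mask)
    if chain is not None:
        heavy = heavy[ref.chain_ids[heavy] == chain]
    coords = ref.coords[heavy]
    tree = cKDTree(coords)
    raw = np.array(sorted(tree.query_pairs(cutoff)), dtype=int).reshape(-1, 2)
    if len(raw):
        i, j = heavy[raw[:, 0]], heavy[raw[:, 1]]
        same_chain = ref.chain_ids[i] == ref.chain_ids[j]
        if mode == "fold":
            keep = same_chain & (np.abs(ref.resids[i] - ref.resids[j]) >= min_sep + 1)
        else:
            keep = ~same_chain
            if chain_pair is not None:
                ga = set(chain_pair[0])
                gb = set(chain_pair[1])
                ci = ref.chain_ids[i]
                cj = ref.chain_ids[j]
                in_a = np.isin(ci, list(ga))
                in_b = np.isin(cj, list(gb))
                in_a_rev = np.isin(cj, list(ga))
                in_b_rev = np.isin(ci, list(gb))
                keep &= (in_a & in_b) | (in_a_rev & in_b_rev)
        i, j = i[keep], j[keep]
    else:
        i = j = np.array([], dtype=int)

    pairs = np.column_stack([np.minimum(i, j), np.maximum(i, j)])
    r0 = np.linalg.norm(ref.coords[pairs[:, 0]] - ref.coords[pairs[:, 1]], axis=1)
    if len(pairs) == 0:
        warnings.warn(f"no {mode} contacts found", stacklevel=2)
    return ContactSet(pairs, r0, mode)


def q_value(coords: np.ndarray, contacts: ContactSet,
            beta: float = DEFAULT_BETA, lam: float = DEFAULT_LAMBDA) -> float:
    """Fraction of native contacts of a single configuration."""
    if len(contacts) == 0:
        raise ValueError("Q is undefined for an empty contact set")
    coords = np.asarray(coords, dtype=float)
    d = coords[contacts.pairs[:, 0]] - coords[contacts.pairs[:, 1]]
    r = np.linalg.norm(d, axis=1)
    return float(np.mean(_sigmoid(r, contacts.r0, beta, lam)))


def _sigmoid(r, r0, beta, lam):
    # exp argument clipped: far-broken contacts saturate at 0 without overflow
    x = np.clip(beta * (r - lam * r0), -500, 500)
    return 1.0 / (1.0 + np.exp(x))


def q_timeseries(frames: np.ndarray, contacts_by_unit: dict,
                 beta: float = DEFAULT_BETA, lam: float = DEFAULT_LAMBDA) -> QSeries:
    """Q per frame for each tracked unit, evaluated independently."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n_frames, n_atoms = frames.shape[0], frames.shape[1]
    out = {}
    for unit, cs in contacts_by_unit.items():
        if len(cs) and cs.pairs.max() >= n_atoms:
            raise ValueError(
                f"unit {unit!r}: contact atom index {int(cs.pairs.max())} out of "
                f"range for frames with {n_atoms} atoms (frame 0)")
        di = frames[:, cs.pairs[:, 0]] - frames[:, cs.pairs[:, 1]]
        r = np.linalg.norm(di, axis=2)
        out[unit] = np.mean(_sigmoid(r, cs.r0[None], beta, lam), axis=1)
    return QSeries(np.arange(n_frames), out)


def q_by_region(frames: np.ndarray, contacts: ContactSet, ref: Structure,
                regions: dict, beta: float = DEFAULT_BETA,
                lam: float = DEFAULT_LAMBDA) -> QSeries:
    """Q restricted to region-wise contact subsets (e.g. per β-strand).

    ``regions`` maps a label to a set of residue ids; a contact belongs to a
    region when either of its residues does, so regions are subsets that may
    overlap, not a partition. Regions with no contacts are omitted with a
    warning.
    """
    subsets = {}
    resid_i = ref.resids[contacts.pairs[:, 0]]
    resid_j = ref.resids[contacts.pairs[:, 1]]
    for label, resids in regions.items():
        members = np.array(sorted(int(r) for r in resids))
        mask = np.isin(resid_i, members) | np.isin(resid_j, members)
        if not mask.any():
            warnings.warn(f"region {label!r} has no contacts; omitted", stacklevel=2)
            continue
        subsets[label] = contacts.subset(mask)
    return q_timeseries(frames, subsets, beta=beta, lam=lam)
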