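"""Structure-geometry measurements: atom distances and hydrogen bonds.

Built for the CD-loop diagnostics of tetrameric transthyretin: the distance
from Ser50 Cα to the amide nitrogen of residue 52 (4.2 Å in WT/T119M, 0.4 Å
wider in the destabilised S52P loop) and the serine hydrogen-bond pair that
the S52P mutation removes. Works on PDB/mmCIF models, including neutron
structures where exchangeable positions carry deuterium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Structure, read_structure

__all__ = ["AtomSelector", "atom_distance", "find_hbonds", "fetch_structure",
           "HBond"]

_DONOR_ELEMENTS = {"N", "O"}
_ACCEPTOR_ELEMENTS = {"N", "O"}
_H_ELEMENTS = {"H", "D"}
_COVALENT_H = 1.25  # Å, X–H bond detection cutoff


@dataclass(frozen=True)
class AtomSelector:
    """Identifies exactly one atom: chain / residue number / atom name.

    ``resname`` optionally asserts the residue type. When alternate
    conformations are present the highest-occupancy one is taken (ties broken
    alphabetically by altloc).
    """

    chain: str
    resid: int
    atom: str
    resname: str | None = None

    def __str__(self):
        rn = f"({self.resname})" if self.resname else ""
        return f"{self.chain}/{self.resid}{rn}/{self.atom}"

    def resolve(self, st: Structure) -> int:
        mask = ((st.chain_ids == self.chain) & (st.resids == self.resid)
                & (st.atom_names == self.atom))
        if self.resname is not None:
            mask &= st.resnames == self.resname
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise LookupError(f"selector {self} matches no atom")
        if len(idx) > 1:
            alts = st.altlocs[idx]
            if all(a == "" for a in alts):
                raise LookupError(f"selector {self} is ambiguous "
                                  f"({len(idx)} atoms, no altlocs)")
            order = sorted(range(len(idx)),
                           key=lambda k: (-st.occupancies[idx[k]], str(alts[k])))
            return int(idx[order[0]])
        return int(idx[0])


def _as_structure(structure) -> Structure:
    if isinstance(structure, Structure):
        return structure
    return read_structure(structure)


def atom_distance(structure, a: AtomSelector, b: AtomSelector) -> float:
    """Euclidean distance (Å) between two uniquely selected atoms.

    Report to 0.1 Å (``round(d, 1)``) when quoting crystallographic values.
    """
    st = _as_structure(structure)
    i, j = a.resolve(st), b.resolve(st)
    return float(np.linalg.norm(st.coords[i] - st.coords[j]))


@dataclass
class HBond:
    donor: tuple  # (chain, resid, atom)
    hydrogen: tuple | None
    acceptor: tuple
    distance: float  # donor–acceptor, Å
    angle: float | None  # donor–H–acceptor, degrees


def find_hbonds(structure, cutoff: float = 3.5, angle_min: float = 120.0,
                chains=None) -> list:
    """Hydrogen bonds by distance + angle criteria.

    A bond is a donor heavy atom (N/O carrying a covalently bound H or D),
    its hydrogen, and an acceptor (N/O on a different residue) with
    donor–acceptor distance <= ``cutoff`` Å and donor–H–acceptor angle >=
    ``angle_min`` degrees. Deuterium plays the hydrogen role, as in neutron
    structures. If the model carries no H/D at all, the angle test is
    dropped and donor–acceptor distance alone decides (heavy-atom fallback).
    ``chains`` optionally restricts both partners to a set of chain ids.
    """
    st = _as_structure(structure)
    if chains is not None:
        st = st.select_chains(list(chains))
    elements = np.asarray([str(e).upper() for e in st.elements])
    h_idx = np.flatnonzero(np.isin(elements, list(_H_ELEMENTS)))
    has_h = len(h_idx) > 0

    res_key = [(str(c), int(r)) for c, r in zip(st.chain_ids, st.resids)]
    donors = []  # (heavy_idx, h_idx or None)
    if has_h:
        heavy_idx = np.flatnonzero(np.isin(elements, list(_DONOR_ELEMENTS)))
        for h in h_idx:
            if len(heavy_idx) == 0:
                break
            d = np.linalg.norm(st.coords[heavy_idx] - st.coords[h], axis=1)
            near = heavy_idx[(d <= _COVALENT_H)
                             & np.array([res_key[i] == res_key[h] for i in heavy_idx])]
            if len(near):
                donors.append((int(near[np.argmin(
                    np.linalg.norm(st.coords[near] - st.coords[h], axis=1))]), int(h)))
    else:
        donors = [(int(i), None) for i in
                  np.flatnonzero(np.isin(elements, list(_DONOR_ELEMENTS)))]

    acceptors = np.flatnonzero(np.isin(elements, list(_ACCEPTOR_ELEMENTS)))
    bonds = []
    for d_idx, hh in donors:
        for a_idx in acceptors:
            if a_idx == d_idx or res_key[a_idx] == res_key[d_idx]:
                continue
            if hh is None and a_idx < d_idx:
                continue  # heavy-only mode: report each unordered pair once
            dist = float(np.linalg.norm(st.coords[d_idx] - st.coords[a_idx]))
            if dist > cutoff:
                continue
            angle = None
            if hh is not None:
                v1 = st.coords[d_idx] - st.coords[hh]
                v2 = st.coords[a_idx] - st.coords[hh]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle < angle_min:
                    continue
            bonds.append(HBond(
                donor=(str(st.chain_ids[d_idx]), int(st.resids[d_idx]),
                       str(st.atom_names[d_idx])),
                hydrogen=None if hh is None else (
                    str(st.chain_ids[hh]), int(st.resids[hh]),
                    str(st.atom_names[hh])),
                acceptor=(str(st.chain_ids[a_idx]), int(st.resids[a_idx]),
                          str(st.atom_names[a_idx])),
                distance=dist, angle=angle))
    return bonds


def fetch_structure(pdb_id: str, dest_dir: str = ".", timeout: float = 30.0) -> str:
    """Download a PDB entry from RCSB (requires network). Returns the path."""
    import pathlib
    import urllib.request

    pdb_id = pdb_id.upper()
    path = pathlib.Path(dest_dir) / f"{pdb_id.lower()}.pdb"
    if path.exists():
        return str(path)
    url = f"https://files.rcsb.org/download/{pdb_id}.pdb"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_bytes(data)
    return str(path)
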