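"""Lightweight array-based protein structure container with PDB I/O.

The analysis modules (contacts, fma, geometry, synth) operate on flat numpy
arrays rather than a hierarchical model; gemmi does the parsing/writing so the
on-disk formats (PDB, mmCIF, multi-model trajectories) stay standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = ["Structure", "read_structure", "read_trajectory", "write_trajectory"]

_HYDROGEN = {"H", "D"}


@dataclass
class Structure:
    """Flat per-atom representation of one model.

    All arrays share the atom axis. ``elements`` are upper-case element
    symbols; deuterium is kept as ``"D"`` so neutron structures round-trip.
    """

    chain_ids: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    occupancies: np.ndarray = None  # type: ignore[assignment]
    altlocs: np.ndarray = None  # type: ignore[assignment]
    regions: dict = field(default_factory=dict)  # label -> set of resids

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        if self.occupancies is None:
            self.occupancies = np.ones(n)
        if self.altlocs is None:
            self.altlocs = np.array([""] * n, dtype=object)
        for name in ("chain_ids", "resids", "resnames", "atom_names", "elements"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != {n} atoms")
            setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def heavy_mask(self) -> np.ndarray:
        """Boolean mask of heavy (non-H, non-D) atoms."""
        return ~np.isin(self.elements, list(_HYDROGEN))

    def subset(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return Structure(
            chain_ids=self.chain_ids[idx],
            resids=self.resids[idx],
            resnames=self.resnames[idx],
            atom_names=self.atom_names[idx],
            elements=self.elements[idx],
            coords=self.coords[idx],
            occupancies=self.occupancies[idx],
            altlocs=self.altlocs[idx],
            regions=dict(self.regions),
        )

    def select_chains(self, chains) -> "Structure":
        return self.subset(np.isin(self.chain_ids, list(chains)))

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    # -- I/O -------------------------------------------------------------

    def to_gemmi(self, frames: np.ndarray | None = None) -> gemmi.Structure:
        """Build a gemmi Structure; ``frames`` adds one model per frame."""
        st = gemmi.Structure()
        st.name = "ttrkit"
        coord_sets = [self.coords] if frames is None else list(frames)
        for imodel, xyz in enumerate(coord_sets, start=1):
            model = gemmi.Model(imodel)
            chain = None
            residue = None
            for i in range(self.n_atoms):
                cid = str(self.chain_ids[i])
                if chain is None or chain.name != cid:
                    chain = gemmi.Chain(cid)
                    model.add_chain(chain)
                    chain = model[-1]
                    residue = None
                rid = int(self.resids[i])
                if residue is None or residue.seqid.num != rid:
                    residue = gemmi.Residue()
                    residue.name = str(self.resnames[i])
                    residue.seqid = gemmi.SeqId(rid, " ")
                    chain.add_residue(residue)
                    residue = chain[-1]
                atom = gemmi.Atom()
                atom.name = str(self.atom_names[i])
                atom.element = gemmi.Element(str(self.elements[i]))
                atom.occ = float(self.occupancies[i])
                atom.altloc = str(self.altlocs[i]) if self.altlocs[i] else "\0"
                atom.pos = gemmi.Position(*xyz[i])
                residue.add_atom(atom)
            st.add_model(model)
        st.setup_entities()
        return st

    def write_pdb(self, path: str) -> None:
        self.to_gemmi().write_pdb(str(path))

    @classmethod
    def from_gemmi_model(cls, model: gemmi.Model) -> "Structure":
        chain_ids, resids, resnames, names, elements = [], [], [], [], []
        occ, alt, xyz = [], [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    chain_ids.append(chain.name)
                    resids.append(res.seqid.num)
                    resnames.append(res.name)
                    names.append(atom.name)
                    elements.append(atom.element.name.upper())
                    occ.append(atom.occ)
                    alt.append(atom.altloc if atom.has_altloc() else "")
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        return cls(
            chain_ids=np.array(chain_ids, dtype=object),
            resids=np.array(resids, dtype=int),
            resnames=np.array(resnames, dtype=object),
            atom_names=np.array(names, dtype=object),
            elements=np.array(elements, dtype=object),
            coords=np.array(xyz, dtype=float),
            occupancies=np.array(occ, dtype=float),
            altlocs=np.array(alt, dtype=object),
        )


def read_structure(path: str, model_index: int = 0) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure` (one model)."""
    st = gemmi.read_structure(str(path))
    return Structure.from_gemmi_model(st[model_index])


def read_trajectory(path: str):
    """Read a multi-model PDB: returns (reference Structure, frames array).

    The first model defines the topology; every model supplies one frame of
    coordinates, shape ``(n_frames, n_atoms, 3)``.
    """
    st = gemmi.read_structure(str(path))
    ref = Structure.from_gemmi_model(st[0])
    frames = np.empty((len(st), ref.n_atoms, 3))
    for k, model in enumerate(st):
        i = 0
        for chain in model:
            for res in chain:
                for atom in res:
                    frames[k, i] = (atom.pos.x, atom.pos.y, atom.pos.z)
                    i += 1
        if i != ref.n_atoms:
            raise ValueError(f"model {k} has {i} atoms, reference has {ref.n_atoms}")
    return ref, frames


def write_trajectory(structure: Structure, frames: np.ndarray, path: str) -> None:
    """Write frames as a multi-model PDB consumable by standard MD tooling."""
    structure.to_gemmi(frames=np.asarray(frames)).write_pdb(str(path))
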