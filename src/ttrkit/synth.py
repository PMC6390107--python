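"""Synthetic toy structures and unfolding trajectories.

These generators provide ground-truth inputs for the native-contact (Q),
PLS-FMA and geometry modules without any external downloads. The toy fold is
a compact serpentine lattice (3.8 Å pitch) rather than a β-sandwich: Q and
PLS-FMA depend only on the contact topology and on which atoms move, not on
fold class, so a lattice with a realistic contact density is sufficient to
emulate the phenomenology of high-temperature unfolding runs — a designated
"strand" region loses its native contacts progressively while the rest of the
structure only jitters thermally.

Residues are labelled with eight equal sequence segments A–H, mimicking the
eight-strand topology of a transthyretin monomer; the "C"/"D" segments play
the role of the C and D strands where unfolding initiates.
"""

from __future__ import annotations

import numpy as np

from .structure import Structure

__all__ = [
    "make_toy_oligomer",
    "make_unfolding_trajectory",
    "make_hierarchy_series",
    "linear_schedule",
]

_LATTICE = 4.3  # Å, pseudo-Cα pitch (lattice neighbours are native contacts)
_ROW = 4  # residues per lattice row
# tetrahedral intra-residue offsets (Å): every intra-residue atom pair is
# >= 1.55 Å apart (self-avoidance) and worst-case inter-residue approach on
# the 4.3 Å lattice stays ~2.5 Å while neighbours remain within the 4.5 Å
# contact criterion
_TET_R = 1.6 / np.sqrt(3.0)
_ATOM_OFFSETS = {
    "CA": np.array([0.0, 0.0, 0.0]),
    "N": np.array([1.0, 1.0, 1.0]) * _TET_R,
    "C": np.array([1.0, -1.0, -1.0]) * _TET_R,
    "O": np.array([-1.0, 1.0, -1.0]) * _TET_R,
    "CB": np.array([-1.0, -1.0, 1.0]) * _TET_R,
}
_STRANDS = list("ABCDEFGH")


def _chain_path(n_res: int):
    """Two-layer, eight-strand sandwich on a lattice.

    Strand k (A..H) is a straight run of residues in row k%4, layer k//4;
    consecutive strands run antiparallel. Returns (points, strand index per
    residue). Residues left over after dividing by 8 extend the last strand.
    """
    per = n_res // 8
    counts = [per] * 8
    counts[-1] += n_res - 8 * per
    pts, strand_of = [], []
    for k, cnt in enumerate(counts):
        row, layer = k % 4, k // 4
        xs = range(cnt) if k % 2 == 0 else range(cnt - 1, -1, -1)
        for x in xs:
            pts.append([x, row, layer])
            strand_of.append(k)
    return np.array(pts, dtype=float) * _LATTICE, np.array(strand_of)


def make_toy_oligomer(n_chains: int = 4, residues_per_chain: int = 96,
                      seed: int = 0) -> Structure:
    """Build a compact toy monomer/dimer/tetramer.

    Chains are packed on a 2x2 grid with inter-block gaps tuned so that every
    interface carries contacts at the 4.5 Å native-contact criterion: the
    A–B / C–D gaps stand in for the monomer–monomer interfaces and the
    (A,B)–(C,D) gap for the dimer–dimer interface. Deterministic for a given
    seed (the seed only perturbs coordinates by a reproducible <0.05 Å dither
    so distinct seeds give distinct but equivalent structures).

    Parameters
    ----------
    n_chains : {1, 2, 4}
    residues_per_chain : >= 8 (eight strand segments A–H need one residue each)
    """
    if n_chains not in (1, 2, 4):
        raise ValueError("n_chains must be 1, 2 or 4")
    if residues_per_chain < 8:
        raise ValueError("residues_per_chain must be >= 8")
    rng = np.random.default_rng(seed)
    path, strand_of = _chain_path(residues_per_chain)
    # monomer-monomer gap slightly tighter than dimer-dimer gap
    dx = path[:, 0].max() + 4.15
    dy = path[:, 1].max() + 4.35
    chain_shift = {
        "A": np.zeros(3),
        "B": np.array([dx, 0.0, 0.0]),
        "C": np.array([0.0, dy, 0.0]),
        "D": np.array([dx, dy, 0.0]),
    }
    chains = "ABCD"[:n_chains]

    chain_ids, resids, resnames, names, elements, coords = [], [], [], [], [], []
    for cid in chains:
        for ires in range(residues_per_chain):
            ca = path[ires] + chain_shift[cid]
            for aname, off in _ATOM_OFFSETS.items():
                chain_ids.append(cid)
                resids.append(ires + 1)
                resnames.append("ALA")
                names.append(aname)
                elements.append(aname[0])
                coords.append(ca + off)
    coords = np.array(coords)
    coords += rng.normal(scale=0.015, size=coords.shape)

    regions = {lab: set(int(r) + 1 for r in np.flatnonzero(strand_of == k))
               for k, lab in enumerate(_STRANDS)}

    st = Structure(
        chain_ids=np.array(chain_ids, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        coords=coords,
        regions=regions,
    )
    _check_self_avoiding(st)
    return st


def _check_self_avoiding(st: Structure, min_dist: float = 1.5) -> None:
    from scipy.spatial import cKDTree

    pairs = cKDTree(st.coords).query_pairs(min_dist)
    if pairs:
        raise AssertionError(f"toy structure has {len(pairs)} clashes < {min_dist} Å")


def linear_schedule(n_frames: int, max_amplitude: float = 8.0) -> np.ndarray:
    """Default unfolding schedule: amplitude rising linearly from 0 to max (Å)."""
    return np.linspace(0.0, max_amplitude, n_frames)


#: per-atom escape-rate factors span this log-uniform range; the lower bound
#: keeps the slowest atom's final displacement at the contact-breaking scale
#: 3.6 Å (0.8 x 4.5 Å) for the default 8 Å schedule
VELOCITY_RANGE = (0.45, 3.0)
#: Brownian wiggle amplitude as a fraction of the peak schedule amplitude
WIGGLE_FRACTION = 0.1


def make_unfolding_trajectory(toy: Structure, region, n_frames: int = 1000,
                              schedule: np.ndarray | None = None,
                              jitter: float = 0.2, seed: int = 0,
                              chain: str = "A") -> np.ndarray:
    """Frames where a residue region progressively unfolds.

    Every atom receives thermal jitter (Gaussian, ``jitter`` Å per
    coordinate). Atoms of ``region`` (a region label like ``"C"``, an
    iterable of labels, or an explicit set of residue ids, restricted to
    ``chain``) additionally escape along fixed random per-atom directions
    with displacement ``x_a * schedule[f]``, where the dimensionless rate
    factors ``x_a`` are spread log-uniformly over :data:`VELOCITY_RANGE`
    (stratified over atoms) — mimicking the heterogeneous pace at which
    native contacts are lost during thermal unfolding, so the region's Q
    declines steadily over the whole trajectory rather than in one step —
    plus a cumulative Brownian wiggle. Expected region Q is monotone
    non-increasing along the monotone ``schedule``.

    Returns an array of shape ``(n_frames, n_atoms, 3)``.
    """
    if schedule is None:
        schedule = linear_schedule(n_frames)
    schedule = np.asarray(schedule, dtype=float)
    if len(schedule) != n_frames:
        raise ValueError("schedule length must equal n_frames")
    if np.any(np.diff(schedule) < -1e-12):
        raise ValueError("schedule amplitudes must be non-decreasing")

    resids = _region_resids(toy, region)
    mask = np.isin(toy.resids, sorted(resids)) & (toy.chain_ids == chain)
    if not mask.any():
        raise ValueError(f"region {region!r} matches no atoms on chain {chain!r}")

    rng = np.random.default_rng(seed)
    frames = np.repeat(toy.coords[None], n_frames, axis=0)
    frames += rng.normal(scale=jitter, size=frames.shape)

    n_reg = int(mask.sum())
    lo, hi = VELOCITY_RANGE
    quantiles = (np.arange(n_reg) + 0.5) / n_reg
    x = np.exp(np.log(lo) + (np.log(hi) - np.log(lo)) * rng.permutation(quantiles))
    u = rng.normal(size=(n_reg, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    wiggle_sd = WIGGLE_FRACTION * max(schedule[-1], 1.0) / np.sqrt(max(n_frames, 1))
    wiggle = np.cumsum(rng.normal(scale=wiggle_sd, size=(n_frames, n_reg, 3)), axis=0)
    frames[:, mask, :] += schedule[:, None, None] * (x[:, None] * u)[None] + wiggle
    return frames


def _region_resids(toy: Structure, region) -> set:
    if isinstance(region, str):
        region = [region]
    resids: set = set()
    for item in region:
        if isinstance(item, str):
            if item not in toy.regions:
                raise ValueError(f"unknown region label {item!r}")
            resids |= set(toy.regions[item])
        else:
            resids.add(int(item))
    unknown = resids - set(int(r) for r in np.unique(toy.resids))
    if unknown:
        raise ValueError(f"residues {sorted(unknown)} not in structure")
    return resids


def make_hierarchy_series(toy_tetramer: Structure, n_frames: int = 300,
                          amplitudes: dict | None = None, seed: int = 0):
    """Monomer/dimer/tetramer-context unfolding trajectories for one monomer.

    Emulates the quaternary-structure protection effect: the same chain-A
    C/D-analogue region unfolds with the largest amplitude when the chain is
    isolated, less as part of a dimer and least inside the tetramer. Returns
    ``{context: (Structure, frames)}`` for contexts monomer/dimer/tetramer.
    """
    if amplitudes is None:
        amplitudes = {"monomer": 8.0, "dimer": 5.0, "tetramer": 3.0}
    if not (amplitudes["monomer"] >= amplitudes["dimer"] >= amplitudes["tetramer"]):
        raise ValueError("amplitudes must be ordered monomer >= dimer >= tetramer")
    contexts = {"monomer": "A", "dimer": "AB", "tetramer": "ABCD"}
    out = {}
    for k, (name, chains) in enumerate(contexts.items()):
        sub = toy_tetramer.select_chains(chains)
        sub.regions = dict(toy_tetramer.regions)
        sched = linear_schedule(n_frames, amplitudes[name])
        frames = make_unfolding_trajectory(sub, ["C", "D"], n_frames,
                                           schedule=sched, seed=seed + k)
        out[name] = (sub, frames)
    return out
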