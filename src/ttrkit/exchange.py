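"""Stochastic/deterministic simulation of H/D tetramer subunit exchange.

Transthyretin subunit-exchange experiments mix hydrogenated (4H) and
deuterated (4D) tetramers in equal parts; dissociation and reassembly via
dimers and monomers scrambles the labels and produces the hybrid species
3H1D, 2H2D and 1H3D whose relative abundances native MS follows over days.

The reaction network modelled here is the mass-action scheme

    tetramer{d1,d2}  ⇌  d1 + d2          (k_tet_diss / k_tet_assoc)
    dimer{m1,m2}     ⇌  m1 + m2          (k_dim_diss / k_dim_assoc)

with composition-agnostic rate constants and combinatorial factors, i.e. a
tetramer is an unordered pair of dimers and dissociates into exactly those
dimers. The two structurally distinct 2H2D assemblies ({HH,DD} and {HD,HD})
are tracked separately internally but pooled in the reported abundances,
because native MS cannot tell them apart. An optional isotope effect scales
dissociation rates by ``isotope_factor`` per deuterated subunit of the
dissociating species.

Deterministic (ODE) and exact stochastic (direct Gillespie, numba-compiled)
integrators share one reaction table, so their means agree at large copy
number and monomer-equivalent mass is conserved by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = ["RateSet", "ExchangeSystem", "AbundanceTimeSeries",
           "simulate_exchange", "simulate_counts", "render_peak_areas",
           "SPECIES", "monomer_equivalents"]

SPECIES = ("4H", "3H1D", "2H2D", "1H3D", "4D")

# internal state layout: 6 tetramers (unordered dimer pairs), 3 dimers, 2 monomers
_TET = (("HH", "HH"), ("HH", "HD"), ("HH", "DD"),
        ("HD", "HD"), ("HD", "DD"), ("DD", "DD"))
_DIM = ("HH", "HD", "DD")
_MON = ("H", "D")
_NSTATE = 11
_DIM_IDX = {d: 6 + k for k, d in enumerate(_DIM)}
_MON_IDX = {m: 9 + k for k, m in enumerate(_MON)}
_TET_IDX = {frozenset_pair: k for k, frozenset_pair in enumerate(_TET)}
# pooled observable per internal tetramer index
_POOL = {0: "4H", 1: "3H1D", 2: "2H2D", 3: "2H2D", 4: "1H3D", 5: "4D"}
_ND_TET = (0, 1, 2, 2, 3, 4)  # deuterated subunits per tetramer species
_ND_DIM = (0, 1, 2)


@dataclass
class RateSet:
    """Mass-action rate constants (per day; association per day per copy)."""

    k_tet_diss: float = 0.2
    k_tet_assoc: float = 1e-3
    k_dim_diss: float = 50.0
    k_dim_assoc: float = 1e-2
    isotope_factor: float = 1.0

    def __post_init__(self):
        for name in ("k_tet_diss", "k_tet_assoc", "k_dim_diss", "k_dim_assoc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.isotope_factor <= 0:
            raise ValueError("isotope_factor must be > 0")


@dataclass
class ExchangeSystem:
    """Copy numbers of every species plus the rate constants.

    ``tetramer_counts`` uses the five MS-observable labels; a pooled 2H2D
    input count is split 1/3 {HH,DD} : 2/3 {HD,HD} (the random-assembly
    ratio) when the internal state is built.
    """

    tetramer_counts: dict = field(default_factory=dict)
    dimer_counts: dict = field(default_factory=dict)
    monomer_counts: dict = field(default_factory=dict)
    rates: RateSet = field(default_factory=RateSet)

    def __post_init__(self):
        for d, allowed in ((self.tetramer_counts, SPECIES),
                           (self.dimer_counts, _DIM),
                           (self.monomer_counts, _MON)):
            for key, val in d.items():
                if key not in allowed:
                    raise ValueError(f"unknown species {key!r}")
                if val < 0:
                    raise ValueError(f"negative count for {key!r}")

    @classmethod
    def equimolar(cls, total_tetramers: float = 1e5,
                  rates: RateSet | None = None) -> "ExchangeSystem":
        """The experiment's starting condition: equal parts 4H and 4D."""
        half = total_tetramers / 2
        return cls(tetramer_counts={"4H": half, "4D": half},
                   rates=rates or RateSet())

    def state_vector(self) -> np.ndarray:
        y = np.zeros(_NSTATE)
        tc = self.tetramer_counts
        y[0] = tc.get("4H", 0.0)
        y[1] = tc.get("3H1D", 0.0)
        y[2] = tc.get("2H2D", 0.0) / 3.0
        y[3] = tc.get("2H2D", 0.0) * 2.0 / 3.0
        y[4] = tc.get("1H3D", 0.0)
        y[5] = tc.get("4D", 0.0)
        for d, k in _DIM_IDX.items():
            y[k] = self.dimer_counts.get(d, 0.0)
        for m, k in _MON_IDX.items():
            y[k] = self.monomer_counts.get(m, 0.0)
        return y


@dataclass
class AbundanceTimeSeries:
    """Percent abundance of the five tetramer species over time (days)."""

    times: np.ndarray
    species: tuple = SPECIES
    abundances: np.ndarray = None  # (n_times, 5), rows sum to 100

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.abundances.shape != (len(self.times), len(self.species)):
            raise ValueError("abundances shape mismatch")

    def __getitem__(self, species: str) -> np.ndarray:
        return self.abundances[:, self.species.index(species)]

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, sp, self.abundances[i, j])
                for i, t in enumerate(self.times)
                for j, sp in enumerate(self.species)]
        return pd.DataFrame(rows, columns=["time_days", "species", "abundance_pct"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceTimeSeries":
        wide = df.pivot(index="time_days", columns="species", values="abundance_pct")
        return cls(times=wide.index.to_numpy(),
                   abundances=wide[list(SPECIES)].to_numpy())


def monomer_equivalents(state: np.ndarray) -> float:
    """Conserved total: 4·tetramers + 2·dimers + monomers."""
    state = np.asarray(state)
    return float(4 * state[..., :6].sum(-1) + 2 * state[..., 6:9].sum(-1)
                 + state[..., 9:].sum(-1))


# -- reaction table ------------------------------------------------------

def _reaction_table(rates: RateSet):
    """Shared reaction encoding: (rtype, c, r1, r2, stoich).

    rtype 0: unimolecular, propensity c·n;  1: bimolecular distinct, c·n1·n2
    (ODE flux c·y1·y2);  2: bimolecular identical, c·n(n−1)/2 (ODE c·y²/2).
    """
    f = rates.isotope_factor
    rtype, c, r1, r2, stoich = [], [], [], [], []

    def add(kind, rate, a, b, dvec):
        rtype.append(kind)
        c.append(rate)
        r1.append(a)
        r2.append(b)
        stoich.append(dvec)

    for k, (d1, d2) in enumerate(_TET):
        dv = np.zeros(_NSTATE, dtype=np.int64)
        dv[k] -= 1
        dv[_DIM_IDX[d1]] += 1
        dv[_DIM_IDX[d2]] += 1
        add(0, rates.k_tet_diss * f ** _ND_TET[k], k, -1, dv)
        add(2 if d1 == d2 else 1, rates.k_tet_assoc,
            _DIM_IDX[d1], _DIM_IDX[d2], -dv)
    for k, dim in enumerate(_DIM):
        m1, m2 = dim[0], dim[1]
        dv = np.zeros(_NSTATE, dtype=np.int64)
        dv[6 + k] -= 1
        dv[_MON_IDX[m1]] += 1
        dv[_MON_IDX[m2]] += 1
        add(0, rates.k_dim_diss * f ** _ND_DIM[k], 6 + k, -1, dv)
        add(2 if m1 == m2 else 1, rates.k_dim_assoc,
            _MON_IDX[m1], _MON_IDX[m2], -dv)

    return (np.array(rtype, dtype=np.int64), np.array(c, dtype=np.float64),
            np.array(r1, dtype=np.int64), np.array(r2, dtype=np.int64),
            np.array(stoich, dtype=np.int64))


def _ode_rhs(table):
    rtype, c, r1, r2, stoich = table
    stoich_f = stoich.astype(float)

    def rhs(_t, y):
        flux = np.where(rtype == 0, c * y[r1],
                        np.where(rtype == 1, c * y[r1] * y[r2],
                                 0.5 * c * y[r1] ** 2))
        return flux @ stoich_f

    return rhs


def simulate_counts(system: ExchangeSystem, t_grid, method: str = "ode",
                    seed: int | None = None) -> np.ndarray:
    """Full internal state (11 species) at each grid time.

    ``method='ode'`` integrates the deterministic mass-action equations;
    ``method='ssa'`` runs one exact direct-Gillespie realisation (counts are
    rounded to integers; reproducible for a given seed).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_grid must be non-empty")
    if t_grid.size > 1 and np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    y0 = system.state_vector()
    table = _reaction_table(system.rates)

    if method == "ode":
        if t_grid.size == 1:
            return y0[None].copy()
        total = monomer_equivalents(y0)
        sol = solve_ivp(_ode_rhs(table), (t_grid[0], t_grid[-1]), y0,
                        t_eval=t_grid, method="LSODA",
                        rtol=1e-10, atol=max(total, 1.0) * 1e-12)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        return sol.y.T
    if method == "ssa":
        from ._ssa import run_ssa

        if seed is None:
            seed = 0
        state0 = np.round(y0).astype(np.int64)
        return run_ssa(state0, t_grid, *table, int(seed) & 0x7FFFFFFF).astype(float)
    raise ValueError(f"unknown method {method!r}")


def simulate_exchange(system: ExchangeSystem, t_grid, method: str = "ode",
                      seed: int | None = None) -> AbundanceTimeSeries:
    """Percent abundance of the five MS-observable tetramer species.

    The two internal 2H2D forms are pooled. Abundances at each time point are
    percentages of the total tetramer signal.
    """
    counts = simulate_counts(system, t_grid, method=method, seed=seed)
    pooled = np.zeros((len(counts), 5))
    for internal, label in _POOL.items():
        pooled[:, SPECIES.index(label)] += counts[:, internal]
    totals = pooled.sum(axis=1)
    if np.any(totals <= 0):
        bad = np.asarray(t_grid, dtype=float)[totals <= 0][0]
        raise ValueError(f"no tetramers present at t={bad} d; abundances undefined")
    return AbundanceTimeSeries(times=np.asarray(t_grid, dtype=float),
                               abundances=100.0 * pooled / totals[:, None])


def render_peak_areas(ts: AbundanceTimeSeries, charge_states,
                      noise_sd: float = 0.0, seed: int | None = None,
                      charge_weights=None, total_signal: float = 1000.0
                      ) -> pd.DataFrame:
    """Synthetic Q-TOF-style peak-area table for an abundance time course.

    Each species' signal is spread over the given charge states with fixed
    intensity weights (uniform by default); Gaussian noise with standard
    deviation ``noise_sd`` percent of the per-peak signal scale is added and
    areas truncated at zero. Columns: time_days, species, charge, area.
    """
    charge_states = list(charge_states)
    if not charge_states:
        raise ValueError("charge-state list must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if charge_weights is None:
        charge_weights = np.ones(len(charge_states))
    w = np.asarray(charge_weights, dtype=float)
    w = w / w.sum()
    rng = np.random.default_rng(seed)

    rows = []
    for i, t in enumerate(ts.times):
        for j, sp in enumerate(ts.species):
            for z, wz in zip(charge_states, w):
                area = ts.abundances[i, j] / 100.0 * wz * total_signal
                if noise_sd > 0:
                    area += rng.normal(0.0, noise_sd / 100.0 * wz * total_signal)
                rows.append((t, sp, int(z), max(area, 0.0)))
    return pd.DataFrame(rows, columns=["time_days", "species", "charge", "area"])
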