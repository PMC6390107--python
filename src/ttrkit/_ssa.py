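"""Numba-compiled direct Gillespie kernel for the exchange network."""

import numpy as np
from numba import njit


@njit(cache=True)
def run_ssa(state0, t_grid, rtype, c, r1, r2, stoich, seed):  # pragma: no cover
    np.random.seed(seed)
    n_grid = t_grid.shape[0]
    n_rxn = rtype.shape[0]
    state = state0.copy()
    out = np.zeros((n_grid, state0.shape[0]), dtype=np.int64)
    t = t_grid[0]
    gi = 0
    a = np.zeros(n_rxn)
    while gi < n_grid:
        atot = 0.0
        for j in range(n_rxn):
            if rtype[j] == 0:
                a[j] = c[j] * state[r1[j]]
            elif rtype[j] == 1:
                a[j] = c[j] * state[r1[j]] * state[r2[j]]
            else:
                n = state[r1[j]]
                a[j] = c[j] * n * (n - 1) * 0.5
            atot += a[j]
        if atot <= 0.0:
            # nothing can fire: state is constant for all remaining grid times
            while gi < n_grid:
                out[gi] = state
                gi += 1
            break
        t_next = t + np.random.exponential(1.0 / atot)
        while gi < n_grid and t_grid[gi] < t_next:
            out[gi] = state
            gi += 1
        t = t_next
        u = np.random.random() * atot
        acc = 0.0
        j = 0
        for jj in range(n_rxn):
            acc += a[jj]
            if u < acc:
                j = jj
                break
        for s in range(state.shape[0]):
            state[s] += stoich[j, s]
    return out
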