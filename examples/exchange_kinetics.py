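"""Simulate an H/D subunit-exchange experiment and fit its kinetics.

Mixes deuterated and hydrogenated tetramers 1:1, lets the mass-action
network scramble subunits over 11 days, renders noisy native-MS-style peak
areas, recomputes relative abundances from the 13+..15+ charge states and
fits the three kinetic groups with the Bayesian one-phase model.
"""

import numpy as np

from ttrkit import exchange, kinetics

rates = exchange.RateSet(k_tet_diss=0.2,   # WT-like homo-tetramer decay, per day
                         k_tet_assoc=1e-3, k_dim_diss=50.0, k_dim_assoc=1e-2)
system = exchange.ExchangeSystem.equimolar(1e5, rates)
grid = np.linspace(0, 11, 12)

ts = exchange.simulate_exchange(system, grid)
peaks = exchange.render_peak_areas(ts, [13, 14, 15], noise_sd=2.0, seed=1)
observed = kinetics.relative_abundance(peaks, charge_range=(13, 15))

print("abundances at day 11 (%):",
      {sp: round(float(observed[sp][-1]), 1) for sp in observed.species})

fits = kinetics.fit_experiment(observed, draws=10000, tune=5000, seed=1)
for group, fit in fits.items():
    print(f"{group:>18}: k = {kinetics.format_rate(fit)}"
          f"  (converged: {fit.converged})")

print("\nThe homo group is the pooled 4H/4D dissociation rate; the hetero")
print("groups are the formation rates of the mixed species. The fitted homo")
print("k is the effective exchange rate — slightly below the microscopic")
print("0.2/day because homo-tetramers also re-form from the scrambled pool.")
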