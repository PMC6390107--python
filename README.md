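# ttrkit

Analysis toolkit for the stability and dissociation of tetrameric
transthyretin (TTR), the transport protein whose dissociation into dimers
and monomers — and subsequent monomer misfolding — seeds amyloid fibrils.
The package re-implements, as a tested and reusable library, the
computational core of a combined native-MS / crystallography / simulation
study design:

- **Subunit-exchange kinetics** (`ttrkit.exchange`, `ttrkit.kinetics`).
  Hydrogenated (4H) and deuterated (4D) tetramers mixed 1:1 exchange
  subunits through the reversible network
  `tetramer ⇌ dimer + dimer`, `dimer ⇌ monomer + monomer`, producing the
  hybrid species 3H1D, 2H2D, 1H3D that native MS resolves. The simulator
  integrates the mass-action ODEs or runs an exact Gillespie realisation;
  the fitting side recomputes relative abundances from charge-state peak
  areas and fits the one-phase model `y(t) = c + (y0 − c)·e^(−kt)` by
  Bayesian MCMC (normal/uniform/half-normal priors, MAP-initialised),
  reporting posterior mean ± sd of `k` in day⁻¹.
- **Fraction of native contacts** (`ttrkit.contacts`).
  `Q(x) = (1/N) Σ 1/(1 + exp[β(r_ij(x) − λ·r⁰_ij)])` with β = 5 Å⁻¹,
  λ = 1.8 over heavy-atom pairs within 4.5 Å of the native structure —
  intra-chain (fold) or inter-chain (interface) — evaluated per frame,
  per unit, and per strand region.
- **PLS functional mode analysis** (`ttrkit.fma`). Partial-least-squares
  regression of Q on superposed main-chain coordinates (20 components,
  75/25 train/validation split); the maximally correlated mode ranks
  residues by their contribution to unfolding.
- **Free-energy cycle** (`ttrkit.thermo`). Bennett-acceptance-ratio
  estimation from forward/reverse nonequilibrium work samples, per-state
  ΔΔG versus a tripeptide reference, the per-tetramer combination
  `ΔΔG_unf = ΔΔG_tetr + 2·ΔΔG_dime + 4·ΔΔG_mono`, equilibrium fold-changes
  `exp(|ΔΔG|/RT)`, `Kd → ΔG`, and double-mutant additivity.
- **Structure geometry** (`ttrkit.geometry`). Atom-pair distances (the
  CD-loop Ser50 Cα – residue-52 N diagnostic) and hydrogen-bond detection
  with deuterium-aware donors, on PDB/mmCIF models.
- **Synthetic ground truth** (`ttrkit.synth`). A toy lattice oligomer with
  labelled strand regions and unfolding trajectories with a known
  perturbed region, used throughout the tests.

## Worked example

`python examples/free_energy_cycle.py` prints:

```
BAR estimate: +5.01 ± 0.03 kcal/mol  (exact 5.00 kcal/mol)
ddG_unf destabilising mutant: +8.40 ± 0.64 kcal/mol
ddG_unf stabilising mutant:   -12.90 ± 0.64 kcal/mol
    monomer +2.1 kcal/mol -> equilibrium shift x35 (destabilising)
   tetramer -8.9 kcal/mol -> equilibrium shift x3,370,544 (stabilising)
tafamidis Kd = 2 nM -> binding dG 11.9 kcal/mol
double mutant (additivity): -4.50 ± 0.91 kcal/mol  [net stabilising]
```

The BAR line recovers a known free-energy difference from synthetic
Gaussian work distributions (10 replicate groups × 50 trajectories). The
ΔΔG_unf lines combine per-state stabilities into the overall shift of the
tetramer-dissociation-and-unfolding equilibrium: a monomer destabilised by
+2.1 kcal/mol shifts the whole equilibrium by +8.4 kcal/mol toward the
unfolded side (~9·10⁵-fold), while a −8.9 kcal/mol tetramer plus −1.0
kcal/mol monomer stabilisation shifts it by −12.9 kcal/mol (~10⁹-fold) —
comparable in magnitude to the ~12 kcal/mol binding energy of a 2 nM
tetramer stabiliser. Their sum is negative: the stabilising mutation is
predicted to dominate in a double mutant.

`python examples/pls_fma.py` runs the structural pipeline end to end
(synthetic unfolding trajectory → per-frame Q → PLS-FMA) and prints

```
Pearson r: training 1.000, validation 0.984
top-10 residues by mode amplitude: [26, 27, 29, 31, 32, 34, 36, 37, 44, 48]
C/D-analogue region: residues 25..48
```

— the collective mode explains the loss of native contacts on held-out
frames and localises on the strands that actually unfold.

The other examples cover the exchange experiment (`exchange_kinetics.py`),
Q time series and per-strand analysis (`native_contacts.py`) and CD-loop
geometry (`loop_geometry.py`).

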