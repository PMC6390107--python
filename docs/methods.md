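# Methods

This note documents the models, defaults and numerical choices behind
`ttrkit`, and what its synthetic benchmarks do and do not demonstrate.

## Subunit-exchange model

The exchange of H- and D-labelled subunits between tetramers is modelled
as mass-action kinetics on the reversible network

    tetramer{d1,d2} ⇌ d1 + d2        k_tet_diss / k_tet_assoc
    dimer{m1,m2}    ⇌ m1 + m2        k_dim_diss / k_dim_assoc

where a tetramer is an unordered pair of dimers and a dimer an unordered
pair of monomers. Dissociation therefore has a single, composition-defined
product channel, and association uses the symmetric convention (flux
`k·c_a·c_b` for distinct partners, `k·c²/2` for identical ones; propensity
`k·n(n−1)/2` in the stochastic integrator). With these conventions the
equilibrium tetramer composition from an equimolar scrambled monomer pool
is exactly Binomial(4, ½) — {6.25, 25, 37.5, 25, 6.25}% for
{4H, 3H1D, 2H2D, 1H3D, 4D} — and freezing dimer dissociation yields the
random-pairing distribution {25, 50, 25}% for {4H, 2H2D, 4D}; both serve
as closed-form oracles in the tests.

Assumptions and choices:

- **Dimer-mediated route only.** Tetramers dissociate to dimers, dimers to
  monomers; a direct tetramer→monomer channel is not modelled.
- **Internal species resolution.** The two structurally distinct 2H2D
  assemblies ({HH,DD} and {HD,HD}) are tracked separately so dissociation
  is well defined, and pooled only in the reported abundances, since MS
  cannot separate them. A pooled 2H2D input count is split 1:2 between the
  two forms (their random-assembly ratio).
- **Isotope effect.** A multiplicative factor per deuterated subunit is
  applied to dissociation rates of D-containing species; factor 1 makes
  the H/D labels exactly exchangeable (tested by mirror symmetry).
- **Units.** Rates are per day; association constants are per day per
  copy, so equilibrium constants depend on the simulated copy number.
- **Default copy number 10⁵ tetramers**: relative stochastic fluctuations
  below 1%, matching the smoothness of measured abundance curves. The
  stochastic path is an exact direct Gillespie simulation (numba-compiled);
  monomer-equivalent mass (4·tetramers + 2·dimers + monomers) is conserved
  exactly there and to integrator precision (LSODA, rtol 1e-10) in the ODE
  path.
- Default rate constants (0.2/day tetramer dissociation, fast dimer
  kinetics, association constants placing ~98% of the material in
  tetramers at equilibrium) give homo-tetramer decay on the multi-day
  scale of the 11-day experiment.

Synthetic "peak areas" spread each species' signal over user-chosen charge
states with fixed intensity weights and additive truncated-Gaussian noise;
they exist so the abundance computation has realistic input, not as an
instrument model (no m/z axis, no peak shapes).

## One-phase Bayesian fitting

Relative abundances are the species' summed peak areas over an inclusive
charge-state window (default 13+..15+) as a percentage of the total
tetramer signal. Each kinetic group is fitted with
`y(t) = c + (y0 − c)·e^(−kt)`, t in minutes, under the priors: y0 ~
Normal(50, 15) truncated to [0, 100] for dissociating series or
Normal(0, 5) truncated likewise for associating ones; c ~ Uniform(0, y0)
or Uniform(y0, 100) respectively; k ~ HalfNormal(scale 10 min⁻¹)
("mean 0, sd 10" read as location/scale); observation noise ~ HalfNormal
(scale 10%). Groups: 4H/4D pooled by averaging and fitted as dissociating,
2H2D associating, 3H1D/1H3D pooled and fitted as associating — pooling by
averaging because a single rate is reported per group. Noise is per-series,
not shared.

Sampling uses emcee's ensemble sampler (32 walkers, differential-evolution
moves) rather than NUTS; the posterior is low-dimensional and the
likelihood cheap, so ensemble MCMC reaches the same posterior. Details:

- MAP initialisation by bounded SLSQP from several heuristic starts;
  walkers start in a small ball around the MAP.
- `draws`/`tune` are total ensemble draws (default 10000/5000); a floor of
  1000 sampling and 500 warm-up steps per walker is enforced because
  ensemble chains need a minimum length regardless of the nominal budget.
  Summary statistics use exactly `draws` samples (step-major truncation).
- Convergence: split-chain R-hat < 1.01, computed on 4 chains formed by
  pooling 8 walkers each; failure attaches a warning, it does not raise.
- `k` is fitted in min⁻¹ and reported in both min⁻¹ and day⁻¹ (×1440),
  rounded to two decimals in formatted reports ("0.20 ± 0.03 day⁻¹").

For data with no decay signal (flat series), `k` is unidentifiable — the
posterior trades k against amplitude y0 − c ≈ 0 — so "no exchange" should
be read off the posterior-predictive abundance change, which is what the
tests assert.

## Fraction of native contacts

Contacts are heavy-atom pairs (all non-H, non-D atoms, side chains
included) within 4.5 Å in the reference structure; fold mode additionally
requires |Δresid| ≥ 4 on the same chain ("separated by at least three
other residues"), interface mode requires different chains (optionally a
specific chain pairing, including grouped pairings like (AB, CD) for the
dimer–dimer interface). The reference state is the starting structure.
Q uses β = 5 Å⁻¹ and λ = 1.8; the sigmoid argument is clipped at ±500
before exponentiation so fully broken contacts underflow to zero rather
than overflow. Per-region Q assigns a contact to a region when either
residue belongs to it — regions are subsets that may overlap, not a
partition, unless the caller constructs a partition of the contact list
(the weighted-mean identity then recovers global Q, which is tested).
Q of an empty contact list is an error, not zero.

## PLS functional mode analysis

Frames are superposed on the reference by least-squares (Kabsch SVD with
a proper-rotation correction; degenerate collinear selections are
rejected), then the property is regressed on flattened main-chain
(N, Cα, C, O) coordinates with PLS. Choices:

- Coordinates are centred on the training mean; the property is
  standardised; features are not variance-scaled (coordinates share units).
- Split: the leading 75% of frames train, the rest validate — a time-block
  split, since snapshots are autocorrelated; a shuffled split is available
  by flag and yields higher validation correlations on the synthetic data
  (no extrapolation in time).
- The mode is the normalised regression-coefficient direction in
  coordinate space. This is a practical stand-in for the ensemble-weighted
  maximally correlated mode of the FMA literature; it is documented as an
  approximation, not asserted as equivalent.
- Per-residue amplitude is the root-sum-square of the residue's atomic
  mode components, so squared amplitudes partition the unit mode norm.
  (A root-mean-square per residue would break that identity; the
  root-sum-square convention was chosen for it.)

## Free energies

BAR solves `Σ_F [1+(n_F/n_R)e^{β(W_F−ΔG)}]⁻¹ = Σ_R [1+(n_R/n_F)e^{β(W_R+ΔG)}]⁻¹`
by bracketed Brent root-finding (xtol 1e-10 kcal/mol) on the pooled works;
the left side minus right is monotone in ΔG so the root is unique. The
logistic terms are evaluated with `scipy.special.expit` for overflow
safety. Uncertainty is the standard error of per-replicate-group BAR
estimates (the 10-groups-of-50 design); non-overlapping work distributions
set a warning flag. Synthetic benchmarks draw Gaussian works satisfying
the Crooks relation (σ² = 2·W_diss·RT), for which ΔG is known in closed
form; BAR antisymmetry under direction swap is exact and tested.

Cycle conventions: ΔΔG(state) = ΔG(mutation in state) − ΔG(mutation in a
capped tripeptide reference); positive values shift the equilibrium toward
the dissociated/unfolded side. The per-tetramer combination is
ΔΔG_unf = ΔΔG_tetr + 2·ΔΔG_dime + 4·ΔΔG_mono (one tetramer → two dimers →
four monomers → unfolded), errors propagated with the same weights in
quadrature. This stoichiometry reproduces both published ΔΔG_unf totals
within 0.6 kcal/mol of the printed values (computed +8.4 vs printed +8.1;
−12.9 vs −12.4); whether the printed totals were computed this way or
estimated independently is not documented, so the residual ~0.3–0.5
kcal/mol pattern is noted rather than resolved. All conversions use
R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ and T = 298 K; reported "~" factors are
matched at 25% relative tolerance.

## Geometry

Atom selectors are (chain, residue number, atom name, optional residue
name) and must resolve uniquely; alternate locations resolve to the
highest occupancy, ties broken alphabetically. Distances are Euclidean,
quoted to 0.1 Å. Hydrogen bonds require a donor N/O with a covalently
bound H or D (≤ 1.25 Å, same residue), an acceptor N/O on a different
residue, donor–acceptor ≤ 3.5 Å and donor–H–acceptor angle ≥ 120° (a
common crystallographic criterion; none is prescribed by the source
data). Deuterium fills the hydrogen role, as in neutron structures.
Models without any H/D fall back to the distance criterion alone, with
each unordered pair reported once.

## Synthetic structures and trajectories

The toy oligomer is an eight-strand, two-layer lattice "sandwich"
(4.3 Å pitch, tetrahedral intra-residue atom offsets of 1.6 Å) rather
than a β-sandwich: Q and PLS-FMA respond to contact topology and to which
atoms move, not to fold class. Strand labels A–H are literal rows of the
lattice, so the C/D-analogue region is spatially contiguous, residues are
self-avoiding (≥ 1.5 Å), every lattice neighbour pair is a native contact,
and chains pack on a 2×2 grid with slightly tighter monomer–monomer than
dimer–dimer gaps. Default size: 96 residues per chain (desk-scale analogue
of the 127-residue monomer), four chains.

Unfolding trajectories displace the atoms of a chosen region along fixed
random per-atom directions with amplitude `x_a · s(f)`, where `s(f)` is a
monotone schedule (default linear 0 → 8 Å over 1000 frames) and the
dimensionless rate factors `x_a` are stratified log-uniform over
[0.45, 3.0]. The heterogeneity mirrors how real thermal unfolding loses
contacts at staggered paces, and it keeps Q declining steadily across the
whole trajectory instead of collapsing in one step; the lower bound keeps
the slowest atom's final displacement at the contact-breaking scale
3.6 Å = 0.8 × 4.5 Å. On top of the drift, region atoms carry a cumulative
Brownian wiggle (10% of the peak amplitude) and every atom receives 0.2 Å
thermal jitter. The hierarchy generator reuses this machinery with peak
amplitudes 8/5/3 Å for the monomer/dimer/tetramer contexts, reproducing
the qualitative ordering that isolated monomers unfold fastest.

What the synthetic benchmarks show — and do not. They verify that the
estimators are implemented correctly: Q against brute force, equilibria
against combinatorics, BAR against Crooks, the Bayesian fitter by CI
coverage, PLS-FMA by planted-signal recovery and by reaching validation
r ≥ 0.97 at the published analysis settings on a trajectory whose
coordinate-to-Q relationship is, by construction, low-dimensional and
approximately linear. They do not emulate force-field physics, solvent,
or the specific experimental rate constants and ΔΔG values, which require
instrument data and microsecond-scale simulation campaigns outside the
scope of this package.

## Problem sizes in the test suite

Stochastic-vs-deterministic agreement uses 200 Gillespie replicates at
10⁴ tetramers over 5 grid points with one excursion to (3, 4] standard
errors tolerated across the 25 comparison cells (per-cell 3-se criteria
applied to 25 cells produce a ~12% family-wise false-alarm rate
otherwise). MCMC tests run 8000 draws / 8000 tune; the 20-dataset CI
coverage check asserts ≥ 17/20 as specified for a 95% interval. The full
suite runs in a few minutes on one CPU; the only network-dependent test
is the measurement of the two deposited PDB entries.
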