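# Methods

This note records the models implemented in `plexscreen`, the defaults and
why they were chosen, the numerical conventions, and the limitations a user
should know before trusting a result.

## 1. From plate reads to the signal matrix

A multiplexed bead immunoassay reports one MFI per (well, bead region).
With one prey per well and one bait per bead region, a screen of N proteins
occupies N wells per replicate; the assembled signal matrix **X** is N×N
with rows as prey and columns as bait.

**Replicates.** Reactions are run in duplicate. Replicate MFIs are combined
by the arithmetic mean — the standard reduction for duplicate immunoassay
wells; the rule is recorded in the matrix metadata. No background well is
subtracted before analysis (the Z-score step estimates background per
row/column instead).

**Bead filter.** A replicate is used only if at least `min_beads = 35`
beads of that region were counted in the well; fewer beads make the median
fluorescence unreliable. The filter applies per replicate *before*
averaging, so one failed replicate does not drag down a good one. A cell
whose every replicate fails is **masked**.

**Missing data.** Masked cells propagate as missing everywhere: they are
excluded from resampling pools, carry no Z-score, and make any pair that
touches them uncallable. Missingness is never imputed — a failed
measurement must not fabricate or suppress signal quantitatively.

## 2. Bootstrap-median Z-scoring

For each row (and symmetrically each column) with n unmasked values:
draw n values with replacement, take the median; repeat B times (default
**B = 300**); let (μ, σ) be the mean and *population* SD of the B medians
(at B = 300 the population/sample distinction is negligible). Then
Z(i,j) = (X(i,j) − μ)/σ, and the row- and column-based Z are averaged into
X_zrc. The median's resistance means genuine hits barely perturb (μ, σ),
so — unlike the outlier-trimmed Z-scoring used for large sparse
interactomes — no signal has to be excluded up front. That matters for
small matrices of preselected proteins in which a large fraction of pairs
truly interact.

Numerical conventions:

* **Degenerate rows/columns** (bootstrap-median SD at floating-point level,
  e.g. a constant row, or a fully masked one) get Z = 0 rather than ±∞ and
  are recorded. A constant row carries no evidence of specific binding, and
  Z = 0 makes every geometric mean involving it undefined, which correctly
  suppresses calls. The zero test is scale-aware (σ ≤ 1e-12·max(1, |μ|)).
* **RNG streams.** One root seed; each row and column gets a child stream
  keyed by (seed, role, protein name). Results are therefore bitwise
  reproducible, independent of evaluation order, and *exactly* equivariant
  under protein permutations — the stream follows the protein, not the
  matrix position. For the same reason the resampled vector is sorted
  first: the bootstrap law depends only on the multiset of values, and the
  canonical ordering makes the realised draws independent of storage order.
* Both properties together make Z matrices invariant (to float rounding)
  under affine rescaling X → aX + c (a > 0) of the raw signals.

## 3. Combination, calling, quantization

Each unordered pair has two orientation scores z_ab = X_zrc(i,j) and
z_ba = X_zrc(j,i); the orientations genuinely differ (expression levels,
binding geometry), so both are required to agree that signal is present:
G = √(z_ab·z_ba), defined only when both are strictly positive. Undefined G
is a value, not an error; such pairs are never callable by score.

* **Threshold.** G > 5, strict inequality; G = 5.0 is not called.
* **Diagonal (homophilic) pairs** are scored like any other pair, using the
  single matrix value for both orientations.
* **Overrides** are explicit (pair + justification), flagged in the calls
  table, the network attributes and the manifest. They exist because a
  curator sometimes preserves a borderline pair known from prior evidence;
  hiding that decision would misrepresent the screen.
* **Quantization.** Categories low/mid/high at the 80th/90th empirical
  percentiles (linear interpolation between order statistics) of all
  *defined* G values in the scored set. The population is the pair set the
  caller supplies — restrict to a family submatrix (e.g. 14 Beats × 8
  Sides) before quantizing to reproduce a family heat map; the convention
  and population are recorded in the run manifest.

## 4. Equilibrium SPR fitting

Steady-state responses R_eq(C) at analyte concentrations C (µM) are fit by
unweighted least squares to R_eq = R_max·C/(K_D + C), with K_D, R_max
constrained positive. Dissociation kinetics of these weak adhesion
interactions are too fast to resolve, so only equilibrium plateaus are
modelled and no rate constants are reported.

* **Self-start.** R_max⁰ = 1.1 × max observed response; K_D⁰ = the
  concentration whose response is nearest R_max⁰/2. Robust for saturating
  and non-saturating series.
* **Standard errors** are asymptotic, from the parameter covariance at the
  optimum. Replicate series pool into mean K_D ± SEM (sample SD/√n; ≥ 2
  converged fits of the same pair required).
* **Refusals and failures.** Fewer than 4 points is refused (2-parameter
  fit); a fit whose K_D lands outside [min C/100, max C×100] or whose
  optimiser fails is flagged not-converged with diagnostics rather than
  reported as a number.
* A fit is checked in tests against an exhaustive (K_D, R_max) grid-search
  oracle, and recovery is exact (≤ 1e-6 relative) on noiseless data.

## 5. The synthetic-data generator

No raw plate reads of the original screens are publicly deposited, so the
generator defines the study conditions under which the pipeline is tested.

**Truth.** A bipartite edge set between families (default 14 × 8-or-9
proteins) sampled at density 0.10 (or an exact edge count), with per-edge
monomeric K_D log-uniform in 0.5–50 µM — the range actually measured for
this class of interactions. Expression factors are log-normal (median 1,
log-SD 0.5 ≈ a typical ~3-fold protein-prep spread), drawn independently
per protein *and per role*, so the two orientations of a pair differ as in
real data. Each (protein, role) fails outright with probability
`fail_prob`.

**Signals.** Cell (prey i, bait j) reads

    b0·ε_bg  +  e_bait(j)·e_prey(i) · S_max·C_eff/(C_eff + K_D) · ε_mult

with the second term only for planted edges. The saturation form with a
single effective prey concentration C_eff (default 1 µM) is a deliberate
stand-in for avidity-amplified multivalent binding: it is the simplest
model that makes expected signal strictly decreasing in K_D, matching the
observed rank relation between bead signal and measured affinity. It is a
modelling choice, not an asserted mechanism. Defaults: b0 = 100 a.u.,
S_max = 20,000 a.u. (strong binders read >20,000 against <100 background),
noise CVs 10%, log-normal (MFI is positive and heteroscedastic). Failed
roles read at `failed_floor = 0.2 × b0`: much of a cell's nonspecific
background comes from the protein layer itself, so an empty bead reads
below normal background. This drives the failed orientation's Z strongly
negative and guarantees the observed failed-bait phenomenology (pair
uncallable, never fabricated). Optional plate output adds duplicate wells
and Poisson(150) bead counts.

**Titrations.** R(C) = R_max·C/(K_D+C)·(1+cv·ξ), ξ ~ N(0,1) per point,
clamped at 0; the default concentration design is a 12-point two-fold
dilution from 0.02× to ~41× K_D.

**What the generator does not emulate** — and therefore what passing tests
do *not* demonstrate about real data: plate-position effects, carry-over
between wells, bead aggregation, prey-specific stickiness (shared
nonspecific binding that correlates cells within a row), detector
saturation, and bait jumping between bead regions (shown experimentally
not to occur). Cell noise is independent across cells given the expression
factors; real screens likely have correlated structure that this model's
clean separation of background and signal understates.

## 6. Null behaviour of the threshold on sparse matrices (known limitation)

The bootstrap-median SD of a row of N values is ≈ 1.25·σ_bg/√N, so a
background cell's Z is its noise deviation in units ~4.8× smaller than
σ_bg: null Z values scale like √N·t regardless of the background *scale*
(only the shape matters), reaching ±8 for N = 23 under log-normal noise.
Two independent orientations both exceed G = 5 with probability ≈ 2–3% per
background pair, i.e. ~6 of the ~240 null pairs per sparse 23×23 screen —
exactly what `analysis/05_benchmark_recovery.py` measures (sensitivity
1.000, mean ~6 background calls per run). No realistic noise shape removes
this: even strictly bounded (uniform) background puts the maximum null Z at
√N ≈ 4.8, just below the threshold, and estimator noise in σ at B = 300
still pushes occasional pairs over. The fixed threshold therefore controls
false positives only when the matrix is dense with genuine interactions
(which widens the bootstrap-median spread) or when calls are vetted against
a prior network and orthogonal affinity measurements — which is the
intended workflow, and why the network report separates `new` edges for
follow-up rather than treating calls as final. For de-novo sparse screens a
resampling-calibrated per-matrix threshold would be needed; that is outside
the present scope.

## 7. Problem sizes and determinism

Defaults used by the shipped analyses and tests: 23-protein matrices,
B = 300 bootstrap repetitions, 100-seed recovery benchmarks, 100-seed
affinity-recovery (12-point titrations, 2% noise, mean fitted K_D reported
per target), 3-replicate SPR pooling. Every stochastic step takes an
explicit seed; identical inputs and seeds give bitwise-identical outputs,
including the full pipeline driver (`run_bpia`), whose manifest records
every parameter, seed, and convention needed to reproduce a run.
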