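# Methods

## Model and loss convention

`predrigid` treats a model as an additive linear readout: a structure's
global prediction is `w · Σⱼ fⱼ` over its environment feature rows
`fⱼ` (descriptor vectors or the last-layer latent features of a deep
model).  The loss is

```
L(w) = Σᵢ λᵢ (gᵢ·w − yᵢ)² + ς² |w|²
```

with **no** factor of 1/2.  Under this convention the generalized
Gauss–Newton curvature is `H = Σᵢ λᵢ gᵢgᵢᵀ + ς²I`, the constrained-refit
identity `ΔL = R Δε²` holds with prefactor exactly 1, and adding a row
with weight λ raises that row's own rigidity by exactly λ.  A loss with
a global prefactor `c` (e.g. a mean rather than a sum, or a 1/2) simply
rescales every rigidity by `c`; relative comparisons, rankings and
enhancement percentages are unaffected.  Force rows follow
`force = −∂E/∂x`; stress-like targets are accepted as opaque
precomputed gradient rows with a weight, since nothing downstream
depends on how a virial was assembled.

## Rigidity definitions and numerics

`R = 1/(gᵀH⁻¹g)` is evaluated through a solve, never an explicit
inverse.  With `ς² > 0` the solve is a symmetric positive-definite
Cholesky factorization, cached per state and rebuilt after updates.
With `ς² = 0`, degenerate `H` is the *expected* case in the
partitioning problems this package diagnoses, so behaviour there is
deliberate: when the condition number exceeds 1e12 the solve switches
to an eigenvalue-clipped pseudo-solve (eigenvalues below `max/1e12`
dropped), and a right-hand side outside the numerical range of `H`
raises `SingularHessianError` advising `ς² > 0` rather than returning a
garbage number.  Zero query gradients raise `ZeroQueryError` — a zero
`g` means the quantity is not represented by the model at all, which
the caller must learn explicitly, not as an infinite rigidity.

Default regularization when the user sets none: `ς² = 1e-8 ×` the mean
diagonal of the data term — scale-aware and negligible for well-posed
systems.

CPR uses hard column masks: the component query is the global row with
zeros outside the block, leaving other blocks' weights untouched; this
matches the additive-component reading of the decomposition.

Rank-one updates add `λggᵀ` to the stored matrix and refresh the
factor; hypothetical (non-mutating) candidate scoring in the selection
module uses the Woodbury identity on the candidate block, and every
low-rank path is required by test to agree with a from-scratch rebuild.
Downdating (negative λ) is supported for bookkeeping but is numerically
risky near singularity.

`curvature_probe` is an honest measurement, not a restatement of the
identity: it computes the KKT displacement for the constraint
`g·w = g·w₀ + δ` and evaluates the loss at both points directly, so
the test `ΔL = R δ²` genuinely certifies the formalism (an independent
penalty-method minimizer is used as a second oracle in the tests).

Trajectory monitoring divides per-frame PR by the mean reference PR
(e.g. a test-set average) and reports a *trailing* moving average
(default window 200 frames, shorter prefixes averaged over what is
available) — trailing rather than centered so the series is usable
on-line during a running simulation.

The predictive-variance scale σ² in `variance_from_pr` is a
user-supplied calibration constant defaulting to 1; empirical
recalibration of error bars is out of scope, and for coarse-grained or
otherwise noise-dominated reference data the inverse rigidity should be
read as a qualitative robustness indicator, not a calibrated error bar.

## Selection

The greedy augmenter maximizes, at each iteration, an aggregate of the
target PRs after hypothetically adding each candidate.  The aggregate
over multiple targets is ambiguous in principle; the default is the
mean, with `min` and `sum` offered.  Ties break toward the lowest
candidate id, for determinism.  Candidate evaluation is non-mutating
(Woodbury), so one iteration costs `O(pool × targets)` solves against a
fixed factorization; the state is updated only on selection.
Strategies for *constructing* candidate structures (cluster carving,
periodic or high-symmetry embedding, buffer-atom jitter) are geometry
operations outside this package's scope: the API accepts arbitrary
user-built candidate rows per strategy label and scores their LPR
enhancement, including repeated addition of the same set.

## Synthetic study systems

The generators define the study conditions; all are seed-deterministic
(bit-identical regeneration) and emulate real data only in structure
(blocks, scales, correlations), not in chemistry.

**Linear systems** (`gen_linear_system`): 200 structures × 4
environments, 8 standard-normal features, energies from a known weight
vector plus N(0, 0.1²) noise.  Each environment's row is scaled by a
uniform factor in [0.5, 2]; the scale spread emulates the dense-vs-rare
regions of feature space that give real datasets their LPR range —
without it every environment would be equally rigid and calibration
studies would be degenerate.

**Committees** (`committee_variances`): 10 ridge models on 10 disjoint
folds (fraction 0.1 each) by default, bootstrap optional; the variance
of each environment's local prediction about the committee mean is the
empirical counterpart of the inverse LPR.  With a fraction of 1 and no
noise all members coincide and variances vanish.

**Body-ordered blocks** (`gen_body_ordered`): four blocks of width 4
(correlation orders ν = 1..4).  A class-c cluster (pair → c=1 ...
quint → c=4) has one shared latent geometry vector u; its genuine
content in block k ≤ c is `Rₖu` for fixed orthogonal maps — all blocks
are functions of the *same* geometry, which is why training on
high-order clusters alone leaves the energy partition degenerate.  The
overlap parameter κ adds self-interaction leakage `2κ·Lₖu` into blocks
k > c along fixed fresh directions: low-order content counted again in
high-order blocks.  At κ = 0 rows are strictly block-supported (the
purified analogue) and 50 two-body samples raise the ν=1 CPR of test
pentamers by many orders of magnitude; at κ = 0.5 the same samples
excite all blocks at once and resolve almost nothing (< 2× change).
The study sizes follow the emulated protocol: 500 pentamers, 50 added
dimers, 20 held-out test pentamers, ς² = 1e-6.

**Two-scale systems** (`gen_two_scale`): dimer-like samples with a
short-range block holding the summed internal descriptor `s = z₁+z₂`
and a long-range block whose genuine interaction excites a
2-dimensional subspace with amplitude `(3/r)³` for separations r
drawn from [3, 10] length units (the tail is referenced to the 3-unit
short-range boundary and vanishes as the units separate).  Without
range separation the LR block additionally carries `1.0·Ms`: each unit
recounts its own atoms (0.7) and its partner's (0.3; a
reciprocal-space evaluation picks up every atom in the cell without
real-space attenuation).  An isolated monomer recounts only itself
(0.7·Mz) — this dimer/monomer mismatch is what breaks extrapolation
when the partition is arbitrary.  The learning-curve driver uses
nested training subsets (25..400 dimers), so curvature monotonicity
guarantees noise-free CPR trends: separated CPRs grow roughly linearly
in n while double-counted CPRs stay pinned at the ridge floor
(~8 orders of magnitude lower at n = 400), and the monomer RMSE of the
double-counted model plateaus ~3 orders above the separated one.

**Two-domain augmentation task** (`gen_two_domain`): 12 features;
a source domain excites columns 0–7, the held-out target domain
columns 4–11, so a third of the target directions are absent from the
60-structure base set.  The 50-candidate pool hides 10 target-domain
rows among 40 source-domain ones; targets are 8 structures, evaluation
is energy RMSE on 30 held-out target structures, noise σ = 0.05.
Greedy PR-guided selection reliably finds the informative minority;
at small budgets (before the unshared directions are fully resolved)
its RMSE advantage over random selection can be within sampling noise,
and becomes decisive (ratios ~0.03–0.05) once enough rows are chosen.

**Toy clusters** (`gen_toy_clusters` / `radial_descriptor`): random
point clusters and a Gaussian radial-basis pair descriptor (6 centers
up to a cosine cutoff, default 2.8 length units — a familiar
short-range cutoff scale — width 0.4) with analytic gradients, so
force-row assembly and finite-difference oracles run end to end.  The
descriptor is translation- and permutation-invariant and deliberately
minimal: no species channels, no periodic boundaries, no angular terms.

## What the synthetic tests do and do not show

Passing these suites certifies the algebraic identities (increment
theorem, curvature identity, last-layer equivalence, monotonicity)
exactly, and the qualitative phenomenology (calibration,
degeneracy resolution, range separation, guided augmentation) on
linear-Gaussian analogues whose block structure and correlations — not
their chemistry — mimic real datasets.  They do not show that a
particular real descriptor's blocks are orthogonal, that real committee
variances are Gaussian, or that last-layer features of a given network
are expressive enough for its uncertainty to be well approximated; for
real models those remain empirical questions the same metrics are
designed to probe.

## Problem sizes

The study sizes above (500+50 clusters, 400 dimers, 200-structure
linear systems, 50-candidate pools, 20 000 posterior samples, 1000
monotonicity trials) were chosen as the smallest systems on which each
phenomenon is unambiguous — ratios of 10× or more, correlations beyond
−0.8 — while keeping every suite and the acceptance script within
seconds on a single CPU.

## File formats

The feature container is HDF5 (bit-exact round trips, timestamps
disabled for byte-reproducible writes) with a plain-text CSV fallback
(features.csv / envmap.csv / targets.csv, plus blocks.csv when
components are declared).  Structures use extended XYZ with
`Lattice`/`Properties` comment conventions.  All indices everywhere are
0-based and recorded in the container metadata; readers check the
format version and name the missing dataset in schema errors.
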