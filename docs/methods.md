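# Methods

## The problem and the strategy

Conserved charged residues that surround an active site without contacting
the catalytic machinery can influence catalysis in two distinct ways: through
the electrostatic field their net charge creates at the reacting center, and
through their local interactions (hydrogen bonds, packing). Substitution
experiments cannot separate the two. The computational intervention this
package implements removes *only* the net charge: the residue's partial
charges are rescaled to sum to zero while restraints preserve its geometry
and hydrogen-bond profile, and the consequence is read off reaction
free-energy profiles obtained by enhanced sampling along a learned
collective variable (CV).

Everything downstream of the electronic-structure engine is implemented and
tested here. The engine itself is replaced by a surrogate reactive system
with a known free-energy surface, so the estimation machinery — CV training,
adaptive biasing, reweighting, uncertainty, auditing — can be validated
quantitatively, which is impossible on the real system.

## Charge-neutralization schemes

Input is a residue topology (atoms, partial charges, backbone flags, a
neutral-form reference charge per backbone atom). Both schemes first restore
the backbone to its neutral-form reference charges, then operate on the side
chain:

* **polar** — each side-chain charge q → q/2 + δ with one uniform additive
  shift δ chosen so the residue sums to exactly zero. Halving keeps the side
  chain polar without putting unrealistic charges on aliphatic groups; the
  shift is applied per atom uniformly (the minimal-assumption reading; an
  alternative would distribute it proportionally to |q|). Ordering of
  side-chain charges is preserved.
* **apolar** — side-chain charges are multiplied by the single factor that
  zeroes the residue sum; because the factor is small in realistic cases
  this nearly zeroes the side chain, modeling an apolar substitution. When
  the required side-chain sum is exactly zero, the charges are set to zero
  (the limiting convention); a zero side-chain sum with a nonzero target is
  reported as infeasible rather than silently scaled.

Both schemes guarantee |Σq| < 10⁻¹² e (property-tested on randomized
residues).

Restraints that keep the perturbed system in the reference configuration:
positional restraints (default k = 10 kcal/mol/Å²) on backbone atoms more
than 7 Å from the active-site center, and one-sided harmonic upper walls
(default k = 20 kcal/mol/Å²) on hydrogen-bond distances at the 90th
percentile of their unbiased distributions. Percentiles use linear
interpolation between order statistics throughout the package. Which atom
pairs form the walls is configuration, not code. Restraints serialize to
YAML and to a PLUMED-dialect text block for cross-checking against external
inputs.

## Features and the training hull

The CV input is the full set of pairwise distances among a small group of
reactive atoms — 9 atoms (36 distances) for the first reaction stage, 8
(28) for the second — each normalized by the rational switch
s(r) = (1−(r/r₀)ⁿ)/(1−(r/r₀)ᵐ) with defaults (n, m) = (6, 12) and r₀
configurable per pair (default 4 Å). The removable singularity at r = r₀ is
filled with the limit n/m, using a first-order expansion within 10⁻⁸ of the
singular point for numerical continuity. s is strictly decreasing, bounded
in (0, 1].

Because networks extrapolate poorly, production sampling is confined to the
training-data hull: per raw distance, harmonic walls at the 0.5% and 99.5%
percentiles of the training distribution (k = 20). Degenerate (constant)
features yield coinciding walls and a warning, not an error.

## The discriminant CV

A feed-forward network (architectures (36, 72, 36, 1) and (28, 56, 28, 1);
tanh hidden units) maps features to one scalar. Training drives the
per-class CV distribution toward Gaussian targets via

  L = Σ_c (μ_c − μ̃_c)² + α (σ_c − σ̃_c)²,

with batch mean μ_c and population (ddof = 0) standard deviation σ_c per
class, targets μ̃ = (−10, 0, 10) and σ̃ = (0.4, 0.3, 0.4), and α = 1 by
default. Only stable states enter the training set; transition states are
never seen. Implementation is plain numpy with manual backpropagation and
Adam (lr 10⁻², full batch) — deliberately dependency-free so a trained model
is a single JSON bundle of arrays (weights, input standardization constants,
targets, history, termination status). The data are shuffled and split 80/20
with the model seed; training stops when the validation loss drops below
0.02 (the convergence level the protocol treats as converged), with a
patience-based early stop (warning) and an epoch cap as fallbacks. Training
is exactly reproducible for a fixed seed. Gradients of the loss are verified
against finite differences in the test suite.

## Adaptive-bias sampling

Sampling along the CV uses the exploration-oriented variant of on-the-fly
probability-enhanced sampling. Every `pace` = 200 steps each of the
`n_walkers` = 8 walkers deposits one unit-weight Gaussian kernel at its CV
value; the kernel density p(s) estimates the *sampled* distribution and the
shared bias is

  V(s) = (γ − 1) kT [ log(p(s)/Z + ε) − log ε ],  γ = barrier/kT.

The fixed point of this update is the well-tempered target: sampled density
∝ exp(−F/(γkT)), bias → const − (1 − 1/γ) F. Conventions chosen here and
recorded because the variant leaves them open:

* **Normalization Z** is the running supremum of p over kernel centers and a
  fixed probe grid, so p/Z ≤ 1 and with ε = 1/(e − 1) the bias is bounded in
  [0, (γ−1)kT] = [0, (1 − 1/γ)·barrier] exactly (identity: (γ−1)kT·
  log((1+ε)/ε) = (γ−1)kT). The empty-bias baseline is V = 0. A saturation
  guard at the cap absorbs the sliver by which p/Z can exceed 1 between
  probe points.
* **Kernel widths**: Silverman-shrunk running spread of all deposited CV
  values (std · n⁻¹ᐟ⁵), floored at `sigma_min` = 0.3 CV units.
* **Merging**: a new kernel closer than its own width (configurable) to an
  existing one is merged — weighted mean center, pooled width, summed
  weight — keeping the kernel count bounded (tens, not thousands).
* **Walkers** share one bias; deposits are synchronous at pace boundaries
  and see all walkers' current CV values. No other concurrency semantics
  are promised.

The propagator is underdamped Langevin in the BAOAB splitting (mass 1,
default friction 1, timestep 0.005 reduced units), chosen for its accurate
configurational sampling at moderate steps; a domain guard at 10× the
outermost basin center aborts divergent trajectories with the offending
step named. The reweighting offset c(t) = kT·log⟨e^{V/kT}⟩_p is recomputed
at every deposit on the probe grid; frames carry (CV, V, c) so unbiased
expectations use weights exp((V − c)/kT).

Default surrogate budget: 10⁵ steps per walker — enough for hundreds of
recrossings of a 10 kT barrier under a barrier parameter of 40 kT.

## Free-energy analysis

* **Burn-in**: the first frames are discarded based on stabilization of
  c(t): the first index where the trailing-window slope falls below 5% of
  the maximum slope, capped at 25% of the run. On a saturating series
  1 − e^(−t/τ) this retains from ≈ 3τ; with τ = T/60 it reproduces the
  discard-first-5% convention.
* **Profiles**: per replicate, a weighted histogram → −kT log → min-shift;
  the profile is the per-bin mean over replicates with the SEM of that mean
  (between-replicate SEM, not block averaging — both conventions exist; the
  between-replicate choice matches how the 5-replicate protocol reports
  uncertainty). Bins unoccupied in every replicate are NaN-flagged, never
  zero. Default grid: 200 bins wall-to-wall.
* **State energetics**: basin windows contribute interior minima, barrier
  windows (TS1/TS2) interior maxima, all relative to the reactant-state
  minimum, SEMs propagated as root-sum-squares. A window whose extremum
  sits on its edge (e.g. a flat profile) is an extraction error, not a
  silent answer. ΔΔG tables between two runs carry pooled SEMs and are
  exactly antisymmetric under swapping the runs.
* **Degeneracy audit**: a 1-D profile along a CV is kinetically meaningful
  only if the transition-state region of the CV is occupied exclusively by
  transition-state-like configurations. The audit builds the reweighted 2-D
  free-energy surface over (CV, rational variable — an interpretable
  observable such as a forming-bond distance), and inside the TS CV window
  requires (a) the minimum-free-energy rational value to lie in the expected
  TS range and (b) no outside bin to undercut it by more than a tolerance
  (default 0.5 kT). An unvisited TS window yields "inconclusive", distinct
  from "fail". A planted two-basin degeneracy (a 2 kT-deeper alternative
  family at the same CV value) is reliably flagged.

## The surrogate reactive system

What it emulates: a two-step reaction stage RS → TS1 → INT → TS2 → PS as
(i) Gaussian per-state feature ensembles standing in for unbiased per-state
sampling (three stable states = the three CV classes), and (ii) a 1-D
multi-basin potential (Gaussian wells/barriers, or the quartic double well
whose barrier is exact by construction) sampled by Langevin dynamics. In
one dimension the free energy along x equals U(x) up to a constant, so
per-bin Gauss–Legendre quadrature of the Boltzmann weight is an exact
oracle. A spectator charge couples as q·φ(x) with φ a Gaussian peaked at
the transition state: it shifts the barrier by ≈ q·(φ(x_TS) − φ(x_RS))
without moving the wells — the surrogate analogue of a remote net charge
acting on the transition state, with the true shift computable by
quadrature.

Default study conditions (deliberately fixed): 10 kT double-well barrier,
barrier parameter 4× the true barrier, 8 walkers × 10⁵ steps, 5 replicates,
imposed spectator shifts +2.3 and −0.8 reduced units (recovered within
2 pooled SEM). Feature ensembles: baseline distances spanning 2.5–8 Å,
state offsets ±0.8 Å in an alternating pattern, spread 0.15 Å, 2000 samples
per state — separable classes with overlapping feature ranges, as for real
pre-reaction distance distributions. Reduced units (kT = 1) throughout; the
real system's kcal/mol numbers are not targets of the surrogate.

What the surrogate does **not** capture: real geometry (features are
generated per state, or interpolated along x, rather than measured from a
3-D trajectory), solvent, multidimensional reaction mechanisms, and any
chemistry. Passing tests certify the *estimation machinery* — that biases
reweight exactly, uncertainties are honest, and imposed perturbations are
recovered — not that the real system's energetics would be reproduced.

One structural caveat surfaced by the end-to-end test: a discriminant CV
pins the stable states to its targets but leaves the location of the
transition *in feature space* unconstrained, so a CV that discriminates
perfectly may still place its steep region away from the dynamical
bottleneck (the audit then fails, correctly). The end-to-end pipeline test
makes the pass case explicit by aligning the surrogate's barriers with the
CV's transition midpoints — the analogue of choosing reactive-atom
distances that actually change at the barrier crossing.

## Conservation mapping

Structures are superposed on the catalytic His side chain (default anchor
CB + imidazole ring atoms; configurable) by the Kabsch algorithm (SVD with
determinant correction, always a proper rotation), implemented directly for
full double precision; the test suite cross-checks against an independent
quaternion (Horn) oracle. Charged residues reduce to single proxy atoms
(Lys NZ, Arg CZ → +; Asp CG, Glu CD → −); proxies cluster per sign by
single-linkage radius clustering (connected components of the radius graph,
verified against a graph oracle), reporting centroid, member count and
occupancy (fraction of structures contributing). Alignment-column
conservation maps 1-based ungapped reference positions gap-aware to columns
and reports percent residue frequencies over non-gap rows (gap rows can be
counted via a flag); columns with fewer counted rows than a support
threshold are flagged. Redundancy filtering is a greedy identity-threshold
filter on aligned sequences — a deliberate, self-contained replacement for
external clustering servers that preserves the pipeline stage; the
threshold (default 90%) is configurable. Database-dependent conservation
percentages are not reproduced here; the toy-alignment arithmetic is exact.

## Numerical choices and limitations

* Percentiles: linear interpolation, everywhere.
* Switch singularity handled by series expansion within |r/r₀ − 1| < 10⁻⁸.
* FES min-shift: every emitted profile has minimum exactly 0.
* The bias force is the analytic gradient of the unclipped bias; in the
  (tiny) saturated sliver the force is not zeroed — the discrepancy is
  below 10⁻³ kT/unit and only at the most-sampled point.
* Adam hyperparameters and the 80/20 split are fixed defaults echoed in the
  model file; epoch counts to convergence depend on them and are not
  contractual.
* `langevin_sample` is a single-particle reference propagator; the sampler
  uses its own walker-vectorized loop. Both are BAOAB with the same
  constants.
* The per-replica ensemble mode exposes pooled vs per-replica training-set
  assembly without asserting which matches any external protocol.
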