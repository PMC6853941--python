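# Methods

This note documents the models and procedures implemented in
`perturbome`, the parameters that matter, the design choices made where
the design was genuinely open, and the limitations we know about. It
states no empirical result that the test suite does not itself compute.

## 1. The perturbation-vector model

A treatment's phenotype is a point in an n-dimensional feature space
(here: per-well medians of cell-morphology features, normalised to
[0, 1]). A perturbation is the displacement vector from the DMSO control
centroid of the batch to that point. Single drugs are measured in
replicate (six wells plated at successive time points); their vector is
the arithmetic mean of the replicate vectors. Combinations are measured
once.

**Assumptions.** (i) Additivity under independence: two non-interfering
perturbations superpose, c = a + b. (ii) The feature space is meaningful
as a Euclidean space after per-feature normalisation — distances mix all
features with equal weight. (iii) Control wells sample the null
variability of the system.

## 2. Decomposition and taxonomy

For single vectors a, b and combination c, the in-plane coefficients
(α, β) solve the normal equations

    [[a·a, a·b], [a·b, b·b]] (α, β)ᵀ = (a·c, b·c)ᵀ,

i.e. the least-squares projection of c onto span(a, b). The residual
r = c − αa − βb is orthogonal to both a and b; γ = ‖r‖ ≥ 0 and
n̂ = r/γ. Both signs of the residual describe the same emergent
phenotype, hence γ is non-negative by convention. Degenerate geometry
(Gram-matrix condition number > 1e8, i.e. numerically collinear singles)
raises an error carrying the 1-D projection as a diagnostic — the plane,
and with it the α/β split, is undefined.

Sign patterns of (α−1, β−1, γ) over {−, 0, +}³ give 27 subspaces
(1 point, 6 lines, 12 surfaces, 8 volumes); merging the two γ signs
leaves 18 interaction classes: 2 undirected (none / emergent-only),
8 uni-directional, 8 bi-directional. `enumerate_interaction_classes`
generates this taxonomy by direct enumeration rather than hard-coding
it.

## 3. Statistical calling

**Perturbation strength D_P.** The control displacement vectors of a
batch are reduced by PCA to the fewest components explaining 90% of
their variance; D_P is the Mahalanobis distance of a treatment vector
from the reduced control distribution (a multi-dimensional z-score). A
drug is *strong* if D_P > 7 in at least one batch. The PCA is fitted on
control wells only: the perturbation is measured against control
variation, not against treatment variation.

**Non-interaction cloud.** For a pair (A, B), all replicate-pair sums
aᵢ + bⱼ are combined with every control well of the combination's
plate. The control enters multiplicatively by default: each sum is
multiplied element-wise by the control well's feature row expressed as a
ratio to the plate control median (ratios ≈ 1), so the cloud inherits
intra-plate well-to-well variation; an additive variant (adding the
control's deviation from the plate median) is available via
`InteractionParams(cloud_mode="additive")` and behaves very similarly in
our benchmarks. Features whose plate median is numerically zero get a
neutral ratio.

**Interaction significance D_I.** The cloud is reduced by PCA to 90% of
its own variance and D_I is the Mahalanobis distance of the observed
combination vector from the reduced cloud; D_I > 3 flags a candidate
interaction. Two properties of this construction are worth knowing:

* *Finite-replicate calibration.* The cloud has (reps_A × reps_B ×
  controls) points but only reps_A + reps_B + controls independent
  sources, so its covariance has a small effective sample size. Under
  the superposition null with a large i.i.d. cloud, D_I² follows a
  chi-square law with the retained degrees of freedom (verified in the
  test suite); with six replicates the estimate is noisy and the null
  distribution has heavier tails. Together with the fact that the
  observation is a single well while the cloud mixes two wells' noise,
  the practical false-positive rate of the absolute D_I > 3 cutoff on
  truly non-interacting pairs is a few percent per pair at our synthetic
  screen conditions — a property of the published decision rule, not of
  the implementation.
* *Basis choice.* By default the PCA is fitted per cloud. A screen-level
  basis (components of all treatment vectors) is available via the
  `basis` argument of `interaction_significance`; it guarantees that a
  deviation is never discarded because one pair's cloud happens to be
  flat along it, but it also makes the metric exactly calibrated — and
  an exactly calibrated D then *typically* exceeds 3 whenever more than
  ~9 components are retained (E[D²] ≈ d.o.f.), defeating the absolute
  cutoff. The default therefore stays per-cloud, which over-covers and
  keeps calls sparse, consistent with the decision rule it serves.

**Effect-size gates.** From all non-significant pairs (D_I ≤ 3), each
drug gets a band median ± 2·MAD of its own-scaling coefficients (its α
in pairs where it is the first drug, its β otherwise) and a γ threshold
equal to the largest non-significant γ. A pair uses A's band for α, B's
band for β, and the larger of the two γ thresholds (the emergent
component is shared). Drugs with fewer than `min_nonsig_pairs = 12`
non-significant pairs fall back to global pooled thresholds — a MAD from
fewer points is too unstable to gate on (a full screen has hundreds of
pairs per drug, so this floor only matters for small screens). A pair
is an interaction only if D_I > 3 *and* at least one gate trips;
significant pairs with all gates quiet are conservatively called
non-interactions.

Note an irreducible consequence of the 2-MAD rule: for a Gaussian
coefficient, ±2 MAD ≈ ±1.35 σ, so an *unchanged* coefficient of a
significant pair trips its gate with probability ≈ 18%. Exact 18-class
agreement on pairs with unchanged coefficients is therefore bounded away
from 1 no matter how clean the data; per-component recovery (did every
truly changed component get its correct state?) is the meaningful
sensitivity measure and is what the recovery benchmark scores.

## 4. Preprocessing

* **Aggregation**: per-well median over cells — robust to outlier cells;
  wells without cells are excluded with a recorded reason.
* **Median polish** (per plate and feature): iterative row/column median
  sweeps (row first), tolerance 1e-6, at most 100 iterations, midpoint
  convention for ties; value = overall median + row + column + residual,
  polished value = overall + residual. Single-row/column plates polish
  the other dimension only, with a warning. Verified against planted
  additive effects and idempotent on its own residuals. Caveat: on
  plates dominated by strongly perturbed wells the row/column medians
  absorb real treatment signal; the polish is designed for screens where
  most wells are near-control (as real screens are).
* **Scaling** (per batch and feature): clip at the 0.5th/99.5th
  percentiles, min–max map so the clip bounds hit exactly 0 and 1;
  zero-variance features map to 0.5 and are flagged. The printed
  percentile pair "99.5/0.05" in common protocols is asymmetric; we read
  it as the symmetric (0.5, 99.5) pair, both configurable. Note that
  per-feature scaling is an anisotropic transformation: it changes
  vector geometry (e.g. the planted orthogonality of an emergent
  component), which is why the decomposition coefficients recovered from
  a scaled screen carry extra scatter relative to the raw planting.
* **Feature filter** (stages i–iii per batch, a feature must pass in
  all batches; stage iv pooled): (i) intra-/inter-plate control CV
  < 0.2 — intra is the per-plate sd/|mean| over control wells averaged
  over plates, inter is the sd/|mean| of per-plate control means;
  (ii) mean between-replicate Pearson correlation ≥ 0.2 — computed per
  feature across drugs between replicate columns of the drug × replicate
  matrix, averaged over replicate pairs (the natural reproducibility
  statistic for scalar per-well values); (iii) at least one perturbation
  with Bonferroni-significant control z-score (α = 0.05, corrected over
  all feature × perturbation tests in the batch); (iv) while any
  retained pair has |ρ| > 0.8, drop the member with the smaller maximal
  |z| (lexicographic tie-break). Every removal records its stage.
* **Drug validity**: wells need ≥ 30 cells; drugs need ≥ 3 valid wells;
  stability is a least-squares line of the cell count (normalised by the
  same-plate control median count, making the slope dimensionless)
  against the temporal replicate order — a drug fails when the slope
  exceeds 0.05 *and* the largest-to-smallest well count differs by
  ≥ 30%. One time point: not assessed.

## 5. Network analysis

Directed edges point at the modulated drug and are only admissible when
that drug is strong — modulation of an effect indistinguishable from
control cannot be detected — giving 1/2/3 admissible link types for
weak–weak / weak–strong / strong–strong pairs and the maximal count
M_max = w(w−1)/2 + 2ws + 3s(s−1)/2. Sparseness is observed/maximal,
also broken down within core, within periphery and between.

**Core–periphery (MINRES).** Nodes are scored by the dominant singular
vector of the (undirected, simple) adjacency — the principal eigenvector
of the rank-1 approximation A ≈ w wᵀ. Binarisation: candidate cores are
prefixes of the score ordering; the split maximising the Pearson
correlation between the adjacency and the idealized pattern (ties
present exactly on pairs touching the core) is kept. Graphs without
core–periphery contrast at any split (cliques, cycles) assign every node
to the core. Significance: the same correlation quality is recomputed on
degree-preserving configuration-model graphs (default 1000); the p-value
is the fraction of nulls scoring at least as high.

**Label-swap randomization.** Each iteration draws one global
permutation of drug labels, repaired so that no drug maps to itself or
to any of its combination partners (equivalently: every combination is
decomposed against singles outside the combination), reruns
decomposition, D_I and classification with the *original* thresholds,
and accumulates per-type edge counts; z = (observed − null mean)/null
s.d. On screens where combinations are exact superpositions of their own
singles, the swapped nulls produce more calls than the true labelling
(verified in the test suite).

## 6. Interactome metrics

Localization: ⟨d_s⟩ is the mean shortest-path distance of each target to
its nearest same-set target; Glass' Δ = (⟨d_s⟩ − μ_random)/σ_random
against 10,000 uniformly sampled node sets of the same size (Δ < −1:
strongly localized). A degree-binned sampler is available since drug
targets skew high-degree; the uniform null is the default. LCC size and
its z-score use the same null. Separation s_AB = ⟨d_AB⟩ −
(⟨d_AA⟩+⟨d_BB⟩)/2, with ⟨d_AB⟩ the mean over all proteins of either set
of the distance to the closest protein of the other set (shared proteins
contribute 0); ⟨d_MeanAB⟩ and ⟨d_MinAB⟩ are the mean and minimum over
all cross-pairs. Targets unreachable from the rest of their module are
excluded from means with a warning and count (rare when the graph is
restricted to its largest connected component, the default on loading).
Annotation similarity S(a,b) = 2/min nᵢ over shared terms (0 if none);
⟨S⟩ averages over all unordered pairs. Tanimoto = |∩|/|∪| of set bits,
0/0 ↦ 0.

## 7. The synthetic screen generator

`simulate_screen` emulates the screen layout end to end: 384-well
(16×24) plates with DMSO controls, six single-drug replicates plated at
successive time points, once-measured combinations realising planted
(α, β, γ) with n̂ drawn uniformly on the unit sphere of the orthogonal
complement of span(a, b), additive plate row/column artefacts, well
noise, and per-cell noise around the well mean (Student-t with 3 d.o.f.
optionally, to exercise the median's robustness). Planted γ is expressed
relative to the pair's own mean effect magnitude. Layout is randomized:
wells fill a compact shuffled block of rows (a half-empty scattered
plate makes median polish needlessly noisy) and singles/combinations
interleave (a plate dominated by strongly perturbed wells contaminates
the polish medians). Identical seeds give identical outputs.

Defaults (chosen to emulate a well-behaved morphological screen, on the
[0, 1] feature scale): 12 drugs of which 3 strong, displacement 0.10
(strong; near the D_P = 7 cutoff at default noise) / 0.03 (weak, clearly
below), feature dimension 10, 48 DMSO wells per plate (standing in for
the batch-wide DMSO pool a many-plate screen accumulates), well noise
0.004, cell noise 0.02 with 100 cells/well, plate effects 0.01.

What the generator does *not* emulate: correlated feature blocks,
feature-specific noise, heteroscedasticity between treatments,
cell-population substructure, batch-specific feature behaviour, edge
effects beyond additive row/column terms, or any image-level artefact.
Passing tests on these synthetics therefore validate the statistical
machinery and its calibration, not robustness to every failure mode of
real imaging data.

`simulate_interactome` grows target modules on a preferential-attachment
background graph: with probability λ the next member is a neighbor of
the current module, else a uniform node — λ = 1 gives a connected
module, λ = 0 a null module; a fraction of members can be shared with an
earlier module to plant overlap. Glass' Δ is monotone in λ (verified).

## 8. The recovery benchmark

`perturbome.experiments.interaction_recovery_experiment` plants
interactions of every directional/emergent pattern and scores the full
pipeline (aggregation → polish → scaling → vectors → cloud → D_I →
gates → classes) against the ground truth. Conditions: 35 drugs per
screen (15 strong at 0.15, 20 weak at 0.03), 105 pairs among the strong
drugs of which 70% are planted non-interacting (interactions among weak
drugs are undetectable by construction — their modulation is inside
control noise, which is also why directed edges require a strong
target); planted α, β ∈ {0.1, 1, 1.9} and γ = 1.5× the pair effect
scale; well noise 0.002 with 100 cells/well. Twenty screens with derived
sub-seeds contribute 620 interacting pairs.

Scores: *sensitivity* — a planted interacting pair counts as recovered
when every planted changed component is called with its planted state
(a spurious extra state on an unchanged coefficient is scored under
exact-class agreement instead; see the 2-MAD note in §3);
*NI specificity* — planted non-interactions called clean; *exact-class
agreement* — strict 18-class match over all pairs. The first is the
benchmark's pass criterion (≥ 95% in the acceptance suite); the other
two are reported because they are bounded by the decision rule itself:
specificity by the D_I false-positive channel and exact agreement by the
2-MAD false-trip rate.

`coefficient_noise_sweep` reruns one screen at decreasing well noise and
reports the RMSE of recovered (α, β) against the planted values plus the
RMS of γ over planted non-interactions (whose true γ is 0; the planted γ
of interacting pairs lives on the raw feature scale, which the per-
feature scaling distorts, so it is not directly comparable). Both
measures shrink with noise.

## 9. Numerical details and limitations

* PCA via full SVD (deterministic); reduced covariances get a 1e-8
  ridge; component counts are the smallest prefix reaching the variance
  target.
* All randomness flows through `numpy.random.default_rng` seeds; same
  seed, same result, including the label-swap nulls and bootstrap.
* Median polish convergence criterion: largest absolute effect change
  < 1e-6, max 100 iterations.
* The multiplicative cloud's variance is aligned with the sum vector,
  which partially masks in-plane deviations parallel to it; the
  additive mode avoids this particular alignment but loses the
  proportionality of well variation to signal. Both are exposed.
* Multiple-testing behaviour of the per-feature association tests
  follows the raw α = 0.05 convention of screen-era analyses; an FDR
  switch is not applied by default.
* The 18-class taxonomy is exposed as-is; any coarser grouping (e.g.
  into a 12-type summary) is left to downstream configuration.
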