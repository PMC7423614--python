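# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer would want to know.

## Synthetic data

**Species trees** come from a coalescent-style sampler: lineages start at
the present and merge pairwise at exponential waiting times with rate
k(k−1)/2 for k open lineages. Any shape would do for the downstream
algorithms; this one is ultrametric by construction, which gives a free
invariant to test (all root-to-leaf path lengths equal).

**Gene families** evolve by a continuous-time birth–death process along
the species tree: a single gene enters at the root; on each branch a
lineage duplicates at rate `dup_rate` and dies at rate `loss_rate` (events
per unit branch length, exponential waiting times); surviving lineages
speciate at internal species-tree nodes. The emitted gene tree contains
only surviving leaves; each retained internal node carries its true event
label. Consequences used by the tests: children of a true speciation node
always carry disjoint species sets (nothing horizontally transfers), so
the species-overlap rule can never call a false duplication; and losses
can erase the overlap evidence of a true duplication, so overlap recall is
exactly 1 only at `loss_rate = 0`. Default rates for recovery experiments
are `dup_rate = 0.3`, `loss_rate = 0.2` — enough events per family on an
11-species tree to exercise both labels without collapsing most families.

**Proteomes.** Each surviving gene yields one protein: random flanks
(15–60 residues each side) around one copy of its family's domain
template, mutated at per-position substitution probability
`domain_divergence` (default 0.1; no indels, matching the ungapped
scanner). `decoys_per_proteome` (default 15–20) unrelated
background-composition sequences are added per species. The residue
background is uniform (1/20) throughout — generator, profile log-odds and
null calibration all use the same background, so the decoy false-positive
rate of the screen is exactly the calibrated quantity.

**Luminescence traces** are forward-simulated by algebraically inverting
the calibration equation: the active fraction is
x = (1 + K_R·Ca)/(1 + K_TR + K_R·Ca), the fractional consumption rate
R = xⁿ/λ per second, expected counts per bin R·A·dt with A the remaining
reporter pool. The pool is decremented by its *expected* consumption even
when counts are Poisson-sampled; this keeps the forward model exactly
invertible, so the noise-free round trip through
`fractional_rate` + `calibrate` is exact to machine precision, and
reporter conservation (Σcounts + lysis residual = total) holds exactly
(noise-free) or in expectation (Poisson). Default transients peak at
2–20 µM over a 120 s record at dt = 0.5 s with 10⁵ total counts. The peak
range matters physically: a much larger/longer transient consumes
essentially the entire pool, the lysis residual → 0, and the late-time
rate estimate leaves the invertible domain (R·λ ≥ 1); the defaults keep a
substantial residual at lysis, the regime the assay protocol itself
operates in.

Not emulated: indels, across-site rate heterogeneity, horizontal
transfer, incomplete lineage sorting, gene conversion, instrument
dead-time or background luminescence. Passing recovery tests therefore
show correctness of the algorithms under the stated generative model, not
robustness to alignment error or annotation noise in real proteomes.

## Homolog screen

Domain models are ungapped PSSMs rather than profile HMMs: the decisions
downstream depend only on domain presence/absence, and an ungapped
log-odds window keeps the stage self-contained and exactly testable
(scanning provably equals exhaustive window enumeration). Choices:

- **Match states:** alignment columns with >50 % gaps are excluded —
  conventional profile construction.
- **Pseudocounts:** background-proportional with weight w (default 1.0),
  avoiding −∞ log-odds. With w = 0 an unobserved residue is floored at
  the one-extra-count probability to keep scores finite.
- **Acceptance threshold:** the (1−FPR) upper order statistic of
  max-window scores over `n_null` random background sequences (defaults
  FPR = 10⁻³, n_null = 10⁴, null length 200). This is a *per-sequence*
  false-positive rate, the empirical-null analog of a family gathering
  cutoff / E-value threshold. `n_null·FPR < 10` triggers an instability
  warning.
- **Overlaps:** greedy best-score-first non-overlapping selection, ties
  to the smaller start — deterministic.
- **Iterative search:** each iteration past the first stacks the ungapped
  windows of all hits so far into a new (trivially gap-free) alignment,
  rebuilds the profile, recalibrates the threshold, and rescans. The hit
  set only grows; each hit is tagged with the iteration that first found
  it; the loop stops early at a fixpoint. Rebuilding from hit windows
  mirrors retrieve-and-realign without bundling an aligner.
- **Classification:** rule-based on domain composition (see README). On
  multi-profile conflicts the highest bit-score wins and the assignment
  is flagged AMBIGUOUS in its rule trace; similarity-candidate sets for
  the MICU and NCLX families are explicit inputs, since
  similarity-search-scale databases are outside this package's scope.
- **Trimming:** a column is removed iff its gap fraction is strictly
  greater than the cutoff (default 0.99); exactly-at-cutoff columns are
  kept. Idempotent by construction.

The two-iteration demonstration fixture emulates the hardest case: a
short (24-residue), compositionally biased domain. With a biased
background (90 % of mass on six residues) the null and homolog score
distributions compress toward each other, so an intermediate homolog
passes iteration 1 while relatives that diverged further *through* it do
not; once the intermediate joins the rebuilt profile, the relatives score
above the recalibrated cutoff. The fixture generator draws the distant
relatives by rejection against these two precomputed search states (with
a 1-bit margin), so the two-stage discovery is a deterministic property
of the dataset for any seed.

## Orthology

The species-overlap rule is parameter-free and needs no species-tree
reconciliation; multifurcations are handled pairwise (any intersecting
child pair ⇒ duplication — the conservative reading). Rooting: outgroup
when one is supplied (root on the edge above the outgroup's MRCA), else
midpoint with ties broken by the lexicographically smallest leaf-name
pair; midpoint rooting provably minimizes the maximum root-to-leaf depth,
which the tests check by exhaustive re-rooting. Relation types count
same-species co-orthologs on each side of the speciation LCA. Ortholog
pairs (speciation LCA) and paralog pairs (duplication LCA) partition all
leaf pairs — asserted, not assumed.

## Profiling

Strain-to-species collapsing is OR over strains: a presence call anywhere
outweighs absence calls, which are fragile to assembly/annotation gaps.
The co-occurrence statistic for the permutation test is the match count
(both-present + both-absent), symmetric in presence and absence, with
p = (1 + #{null ≥ observed})/(n_perm + 1) under independent row shuffles
of the second column, seeded. Two calibration facts shape the tests: the
p-value is exactly 1/(n_perm+1) for identical non-constant columns only
when the number of distinguishable row permutations is ≫ n_perm, and the
discrete statistic makes the p-value tie-conservative (super-uniform).
At 1000 rows the tie mass is ~2 % and the null distribution of p is
uniform to within KS sampling noise; at a few dozen rows conservatism is
visible, which is the expected behaviour of a valid permutation test, not
an error. Constant columns give p = 1 with a warning. The loss report
lists, per family, the *maximal* named taxonomy clades in which every
species lacks the family (subclades of a reported clade are suppressed).

## Clade-contrast scan

Column divergence is base-2 Jensen–Shannon divergence between the two
groups' residue distributions over 21 symbols — the 20 amino acids plus
gap, because a group-specific deletion is a group-specific signal. The
pseudocount (default 0.5) is a *total* prior mass spread uniformly over
the symbols, not a per-symbol count: this keeps small groups able to
produce concentrated distributions, so the default thresholds
(divergence ≥ 0.5 AND group-A conservation ≥ 0.7) remain meaningful for
alignments with a handful of sequences per clade. Within-group
conservation is the raw max symbol frequency. JSD is symmetric in the
groups, bounded in [0,1], zero iff the pseudocounted distributions
coincide, and invariant to alphabet relabeling — all property-tested.
Thresholds are exposed as parameters since no canonical cutoff exists for
this family of scores.

## Aequorin quantification

- **Smoothing** uses the penalized natural cubic spline minimizing
  p·Σ(yᵢ−f(xᵢ))² + (1−p)·∫(f″)², p ∈ [0,1], default 0.5. This is solved
  via `scipy.interpolate.make_smoothing_spline` with λ = (1−p)/p, the
  same minimizer. p = 1 interpolates exactly; p = 0 is handled as the
  explicit least-squares line (the λ → ∞ limit).
- **Lmax accounting:** Lmax at sample i is the total *remaining*
  discharge — future counts plus the post-lysis residual — making Rᵢ a
  per-second fractional consumption rate; λ = 1 is consistent with this
  per-second normalization. Counts arrays are never mutated.
- **Calibration** is monotone non-decreasing in R on its domain
  (R·λ < 1); rates whose calibrated value is negative (below the
  Ca²⁺-independent luminescence floor, x < 1/(1+K_TR)) are clamped to 0,
  with the raw value available for diagnostics. R·λ ≥ 1 raises a domain
  error. Near the zero crossing the numerator x(1+K_TR)−1 suffers
  catastrophic cancellation; accuracy there is meaningful in absolute
  terms (~10⁻¹⁸ M) rather than relative ones.
- **Order of operations:** smoothing is applied to the luminescence
  counts before rate computation and calibration (closest to the assay's
  processing); `calibrate_trace(smoothing=None)` skips it, and
  `parametrize_kinetics(smoothing_p=...)` can re-smooth the calibrated
  trace instead.
- **Parametrization:** peak is the maximum of the (spline-represented)
  trace after the stimulus on a 10× oversampled grid, first index on
  ties; left slope is the maximum of the analytic spline derivative on
  [stimulus, peak]; a secant slope over the rising phase is reported
  alongside, since "left slope" admits both readings. Both the peak of
  the calibrated Ca²⁺ trace and the rising-phase slope are reported
  per well; groups aggregate as mean ± SEM (sd/√n), with SEM = NaN for
  single-well groups. Uniform sampling is required; non-uniform input is
  rejected rather than silently resampled.

## Problem sizes

Recovery experiments use 8-species trees with 100–200 replicate families;
screen fidelity uses 200 planted domains and 1000 decoys against a
20 000-sequence null; the permutation-test calibration uses 200
repetitions of 1000-species profiles at 199 permutations; the plate
simulations use 9–18 wells of 120–240 samples at 10⁵ counts. These sizes
give Monte-Carlo standard errors comfortably below every tolerance used
in the tests while keeping the full suite fast.

## Known limitations

- The screen is ungapped: a domain split by a long insertion scores as
  two partial windows and may be missed at tight thresholds.
- Species-overlap orthology under heavy loss underestimates duplications
  (no reconciliation-based loss inference is attempted).
- The co-occurrence permutation test treats species as exchangeable rows;
  it does not model phylogenetic autocorrelation (no tree-aware
  correlated-evolution model).
- Calibration constants are taken as given (wild-type aequorin, native
  coelenterazine); no refitting from data.
- The clade-contrast scan is a two-group score; it does not reimplement
  multi-group harmony/relief-style algorithms.
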