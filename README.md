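# mcukit

Phylogenomic co-evolution analysis of the mitochondrial calcium uniporter
complex, plus aequorin-based quantification of mitochondrial Ca²⁺ uptake.

The mitochondrial Ca²⁺ uniporter is a multimeric inner-membrane channel:
the pore subunit MCU, the EF-hand gatekeeper family MICU, and — in
opisthokonts — the short, poorly conserved single-pass regulator EMRE.
Reading presence/absence of these families across many genomes is
complicated by an ancestral opisthokont duplication of MCU: most fungi
retained only a fungal-specific paralog (MCUP), while animals kept the
other copy, so naive family-level profiling conflates two subfamilies with
very different biology. `mcukit` provides the computational workflow for
resolving this: domain-rule homolog detection with iterative profile
search (how very divergent EMREs become detectable in a second pass),
duplication-aware orthology splitting, presence/absence co-occurrence
profiling on a taxonomy, clade-contrast residue scanning (MCU vs MCUP),
and calibration of aequorin luminescence kinetics into molar Ca²⁺ with
peak/slope parametrization. A synthetic-data generator with full ground
truth (birth–death gene families, planted domains, forward-simulated
luminescence) makes every stage verifiable without any genome downloads.

Intended users: molecular evolution / comparative genomics researchers
studying protein-complex co-evolution, and anyone quantifying
aequorin-based Ca²⁺ measurements.

## The methods in brief

**Homolog screen.** Domains are modelled as ungapped position-specific
log-odds profiles: for match column c (columns with ≤50 % gaps) and
residue a,

    score[c][a] = log₂( (n_a + w·b_a) / (n_c + w) / b_a )   [bits]

with background b and pseudocount weight w. A sequence is scanned with a
sliding window; windows scoring at or above the family's acceptance
threshold are hits (greedy non-overlapping selection). The threshold — the
analog of a family gathering cutoff — is calibrated as the (1−FPR)
quantile of max-window scores over random background sequences. The
iterative search rebuilds the profile from all hits found so far and
rescans, which recovers family members too diverged for the seed profile.

**Orthology.** Gene-tree internal nodes are labelled by the
species-overlap rule: a node is a duplication iff its child subtrees share
at least one species, else a speciation. Two genes are orthologs iff their
LCA is a speciation; co-ortholog counts on each side give the
one-to-one / one-to-many / many-to-many relation type. A duplication node
splits its subtree into two paralog clades (animal-like MCU vs MCUP).

**Profiling.** Strain rows collapse to species by OR; co-occurrence of two
families is the 2×2 presence tally plus Jaccard, with significance from a
permutation test on the match count (both-present + both-absent) under
row shuffles: p = (1 + #{null ≥ observed}) / (n_perm + 1).

**Clade-contrast scan.** Each alignment column gets the base-2
Jensen–Shannon divergence between the two groups' pseudocounted residue
distributions (gap = 21st symbol) and the within-group max residue
frequency; columns conserved in group A but divergent between groups are
flagged and ranked.

**Aequorin quantification.** Counts are smoothed by the penalized cubic
spline minimizing p·Σ(yᵢ−f(xᵢ))² + (1−p)·∫(f″)² (default p = 0.5); the
fractional consumption rate at sample i is Rᵢ = (countsᵢ/dt) / Lmaxᵢ with
Lmaxᵢ the total remaining discharge (future counts + post-lysis residual);
and Ca²⁺ follows the wild-type aequorin / native coelenterazine
calibration

    [Ca²⁺](M) = (x + x·K_TR − 1) / (K_R − x·K_R),   x = (R·λ)^(1/n)

with λ = 1, K_R = 7.23×10⁶, K_TR = 120, n = 2.99. Kinetics are summarized
as peak amplitude, peak time, and left slope (max analytic spline
derivative on the rising phase), aggregated per group as mean ± SEM.

## Worked example

Generate the bundled synthetic dataset (11 species: 4 holozoa-like, 3
chytrid-like, 4 dikarya-like; 6 gene families; a 9-well aequorin plate)
and run the whole pipeline:

```bash
mcukit simulate --out demo --seed 1 --scale demo
mcukit run-all --fixtures demo --seed 1 --out demo_run
```

`demo_run/coevolution/cooccurrence.json` then contains

```json
"MCU:MICU":  {"n_both": 7, "n_only_a": 0, "n_only_b": 0, "n_neither": 4,
              "jaccard": 1.0, "p_value": 0.004}
"MCUP:MICU": {"n_both": 3, "n_only_a": 4, "n_only_b": 4, "n_neither": 0,
              "jaccard": 0.273, "p_value": 1.0}
```

— the animal-like MCU clade co-occurs perfectly with MICU (present
together in 7 species, absent together in 4; permutation p = 0.004),
while the fungal paralog MCUP does not co-evolve with MICU (p = 1.0).
That contrast is the analysis' central readout: only the duplication-aware
split reveals the co-evolution. `clades.json` shows the three
chytrid-like species (`c1`–`c3`) in *both* the MCU and MCUP clades, and
`specificity.tsv` ranks the alignment columns that separate MCUP from the
animal-like MCUs (10 flagged columns in the demo, divergence up to 0.90
with group-A conservation 1.0).

`demo_run/quantify/groups.tsv` summarizes the plate (true simulated peaks
were 20, 14 and 2 µM):

```
group          n  peak_mean_M  peak_sem_M  slope_mean_M_per_s
HsMCU+HsEMRE   3    2.014e-05    3.65e-08            3.88e-06
SpMCU+SpEMRE   3    1.406e-05    4.14e-08            3.05e-06
empty-vector   3    2.037e-06    1.02e-08            7.68e-07
```

i.e. group peaks recovered within ~2 % under Poisson counting noise at
10⁵ total counts per well.

The same stages are available as a library:

```python
from mcukit import aequorin, simulate

ca = simulate.bell_transient(peak_ca=2e-5)            # 20 µM transient
trace, _ = simulate.simulate_luminescence(ca, aequorin.CalibrationConstants(),
                                          total_counts=1e5, dt=0.5)
recovered = aequorin.calibrate(aequorin.fractional_rate(trace))
# max relative error vs the input transient: ~1e-15 (noise-free)
```

## Layout

```
src/mcukit/
  simulate.py      species trees, birth–death gene families, planted
                   domains, forward luminescence simulation
  screen.py        PSSM profiles, window scanning, threshold calibration,
                   iterative search, family classification, trimming
  orthology.py     species-overlap events, rooting, paralog clades,
                   ortholog pairs
  profiling.py     strain collapsing, co-occurrence, permutation test,
                   taxonomy report
  conservation.py  clade-contrast (JSD) column scanning
  aequorin.py      smoothing, fractional rate, calibration, kinetics
  io.py            FASTA / newick / TSV / CSV / JSON round-trips, manifests
  pipeline.py      fixture generation and end-to-end orchestration
  cli.py           `mcukit` subcommands (simulate, screen, orthology,
                   profile, conserve, quantify, run-all)
docs/methods.md    model assumptions, parameter choices, limitations
```
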