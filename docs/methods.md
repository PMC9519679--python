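# Methods

This note documents the models behind `svharvest`, the assumptions of the
synthetic-data generator, and the numerical choices made where the design
was genuinely open. It states no empirical result beyond what the test
suite and `scripts/acceptance.py` compute.

## 1. Coordinates and domain types

All internal coordinates are 0-based half-open; VCF/GFF3 I/O converts at
the boundary. An SV record carries sample, caller, type (DEL, INS, DUP,
INV, TRA, INDEL), interval, length, genotype, filter status and — for
translocations — a mate breakpoint. Insertions are point variants whose
length is the inserted size and may be unknown. Length categories are
INDEL 2–49 bp, A 50–300 bp, B 0.3–5 kb, C 5–50 kb, D 50–250 kb,
E 0.25–1 Mb; the A/B boundary at 300 bp is resolved A-inclusive so the
bins tile [2 bp, 1 Mb] deterministically. Translocations have no length
and form one pooled class.

## 2. Synthetic data

The generator replaces read simulation and external caller execution with
a call-level error model; nothing downstream needs nucleotides, so only
coordinates, an N-mask and a pericentromere track are generated.

**Truth sets.** Event counts per (type, category) are Poisson with mean
`rate × genome length`; defaults are 1.9·10⁻⁶ events/bp for categories
A–C and INDELs, 3.8·10⁻⁶ for D and 1.9·10⁻⁷ for E. Lengths are uniform
within the category bounds (the within-category distribution is not
otherwise constrained; uniform is the least-informative choice). Positions
are uniform with rejection of overlaps within a sample; events that cannot
be placed after 50 tries (small toy genomes saturate in categories D/E)
are skipped with one summary warning.

**Caller profiles.** Each caller is a per-(type, category) sensitivity and
precision target plus Gaussian breakpoint jitter (start and end jittered
independently, rounded to bp), length jitter for insertions, a heterozygous
miscall rate and a filter-failure rate. False positives are placed
uniformly with expected count `n_emitted · (1−p)/p`, which makes the
measured precision converge to the target `p` — the property the
benchmark tests close the loop on.

**Cohort.** A shared pool of SV events is genotyped over n = 23 inbreds.
An event is a singleton with probability 0.5 (half of real SV clusters are
private to one line); otherwise its cohort frequency is Beta(0.6, 2) —
a rare-skewed spectrum — and carriers follow a founder-haplotype model:
the cohort descends from 6 ancestral lineages and each sample inherits its
founder's carrier state, flipped with probability 0.05. The founder model
is essential, not cosmetic: with i.i.d. samples the realised kinship is
≈ 0 and no kernel method can predict an unseen sample at any heritability,
whereas real diversity panels carry exactly this block relatedness (it is
what structure PCs and kinship matrices estimate). Six lineages and 5 %
divergence give off-diagonal kinship values in the 0.3–0.7 range typical
of crop panels; the values were chosen once and are exposed on
`CohortSpec`.

**Expression.** Per-gene baselines on log2 scale (N(3, 2) across genes,
N(0, 0.25) sample noise), exponentiated to an FPKM-like non-negative
matrix. A configurable fraction (default 0.3) of gene-associated events
adds `effect_sd · N(0,1)` to the carrier samples of their gene — the
planted signal the association tests must recover.

**Phenotypes.** `y_ijk = μ + E_j + G_i + (G×E)_ij + ε_ijk` with the
genetic values a sparse linear combination (default 50 causal events) of
SV presence, standardised so the **plot-level** heritability is h²; the
non-genetic variance is split evenly between G×E and residual. Replication
across environments and replicates therefore sharpens the adjusted entry
means towards the true genetic values, and h² = 0 yields pure noise.
Causal events are drawn among events with ≥ 3 carriers: singleton effects
cannot be cross-validated (the carrier is absent from every training
fold), and heritable trait variance in real panels rides on shared
variation.

## 3. Benchmarking and ensemble selection

Matching is one-to-one: candidate (truth, call) pairs within the class
tolerances are accepted greedily by increasing breakpoint distance
(max over compared breakpoints), ties broken by leftmost call. INDELs and
insertions are anchored at one breakpoint — the second end is implied by
the length, which has its own tolerance — otherwise the two tolerances
would double-count a length difference. Greedy matching equals the exact
maximum matching on instances whose truth events are separated by more
than the tolerance (the regime SV benchmarking operates in); the test
suite verifies this against a bitmask-DP oracle.

Undefined metrics (zero denominators) propagate as missing, never as 0 —
in particular a caller with no calls in a category does not spuriously
fail the precision floor.

OR-combination is the union in expression order with cross-caller
deduplication (two calls are duplicates if they tolerance-match each
other; the earlier caller's record survives). AND keeps the first
caller's calls that have a match in every other member. Selection: step 1
ORs every caller with precision ≥ floor (default 0.95) in all categories;
step 2 ANDs the rest and admits the consensus only if its measured
precision clears the floor everywhere; if nothing qualifies the best
single caller by mean F1 is returned with a warning.

## 4. Merging and clustering

Per-sample filtering keeps PASS, 1/1, non-RPL calls outside all-N regions
and below 1 Mb; overlapping same-sample footprints are resolved by keeping
the smallest record (greedy by size, ties leftmost then caller priority).
Clustering scans each (type, chromosome) track in coordinate order; a
record joins an open cluster when the distance to the nearest member start
is < 20 bp (A/INDEL) or < 50 bp (B–E) **and** both breakpoints differ from
the running representative (member-wise median) by < 10 / < 50 bp. The
conjunction prevents unbounded transitive chaining. Unknown-length
insertions cluster on start alone (10 bp); translocations need both
breakpoints within 50 bp. Presence/absence genotypes and
MAF = min(f, 1−f) follow directly.

## 5. Annotation

Gene context uses any-overlap against strand-aware features: up5k/down5k
are the 5 kb windows off the 5′/3′ gene ends, exon/intron partition the
gene body; "intergenic" applies exactly when nothing else does, and
multiple labels are allowed. TE overlap is reciprocal ≥ 80 % for
length-resolved clusters (known-length insertions are anchored at their
breakpoint), breakpoint-inside-TE for unknown-length insertions, and
either-breakpoint for translocations. Hotspots: per chromosome, cluster
counts in non-overlapping 1 Mb windows; λ is the chromosome mean; a window
is a hotspot when its count exceeds the smallest k with Poisson
CDF(k; λ) ≥ 0.99, which bounds the false-flag rate below 1 % under a
uniform distribution. TSS profiles count SV interval coverage (one
increment per covered offset) and exact SNV positions over strand-oriented
offsets in ±5 kb.

## 6. Population genetics

Inbred lines are coded as haploids. r² is computed from haplotype
frequencies, `D²/(p_A q_A p_B q_B)`, identical to the squared Pearson
correlation on complete data; monomorphic input is undefined (missing),
never 0. π uses the unbiased per-site estimator `n/(n−1) · 2p(1−p)`
summed per 100 kb window and divided by the window length. In the linkage
summary, focal variants with no SNV within 1 kb are excluded from the
denominator; an SV cluster is represented by its representative start.

## 7. Expression association

PCA centres genes (no scaling — expression variance is informative) and
reports sample scores and variance fractions. The genome-wide test
correlates presence vectors (MAF > 0.15, i.e. ≥ 4 minor carriers of 23)
with one PC's loadings; the statistic is the mean |r| over clusters and
the null permutes each cluster's presence independently per iteration
(default 1,000; a joint-permutation mode is available since the choice is
not canonical). `p = (1 + #{null ≥ obs})/(n_perm + 1)`, bounded below by
1/(n_perm+1).

Kinship is `K = ZZᵀ / Σ p_k(1−p_k)` with Z the column-centred marker
matrix — the realised-relationship estimator for haploid coding, mean
diagonal ≈ 1, invariant to duplicated markers. The PK model
`y = μ + Qβ + x·β_SV + u + ε`, `u ~ N(0, σ²_g K)`, is fitted per gene by
exact REML: K is eigendecomposed once and the restricted likelihood is
profiled to a 1-D bounded search over log δ (δ = σ²_e/σ²_g, tolerance
1e-8, boundaries probed). The Wald t for β_SV uses **Satterthwaite
denominator degrees of freedom**: treating the REML variance ratio as
known makes the naive t (df = n−p) anticonservative at n = 23 (measured
≈ 7.4 % at nominal 5 %), while the Satterthwaite adjustment restores
calibration (≈ 3.4 %) and reduces exactly to the OLS df when K = I.
Gene-level significance is unadjusted P < 0.05 by default, matching the
field's reporting; a Benjamini–Hochberg flag is trivial to apply on the
returned p-values.

## 8. Prediction

Adjusted entry means solve the two-way additive model on genotype ×
environment cell means by least squares (minimum-norm solution of the
rank-deficient dummy design, genotype effect plus the average environment
effect). This is a deliberate fixed-effects approximation of the
mixed-model formulation: with heavy replication and only 23 genotypes it
reproduces balanced-design answers exactly and leaves genotype contrasts
invariant to environment shifts, without a mixed-model dependency.
Estimability requires a connected genotype–environment incidence graph.

`build_G` drops monomorphic columns, columns with > 20 % missing values
and exact duplicates (after mean imputation of remaining gaps), then
centres and scales to unit variance (population SD, so mean diag(G) = 1)
and forms `G = W*W*ᵀ/m`. GBLUP estimates (σ²_g, σ²_e) by REML on the
training block and predicts
`μ̂ + G[test,train](G[train,train] + δI)⁻¹(y_train − μ̂)` — algebraically
kernel ridge regression with shrinkage δ on the centred response, which
the tests verify to 1e-6 against scikit-learn. The joined weighted matrix
is `Σ wᵢ Gᵢ` over the 0.1-step simplex grid (66 triples for three
kernels); grid-search ties resolve toward a larger weight on the
first-listed kernel for determinism. Cross-validation partitions samples
uniformly into k folds (sizes differing by ≤ 1; replicate r seeded with
`seed + r`), scores Pearson r(y, ŷ) per validation fold, and summarises
as the median over folds then the median over replicates; folds below 3
samples are rejected as a configuration error.

## 9. What a green test does and does not establish

The generator emulates statistical structure — caller error scales,
allele-frequency spectrum, founder relatedness, planted expression and
phenotype effects — not sequence context: no mappability gradients, no
caller-specific systematic biases (all simulated callers err
independently, so OR-combinations look better than correlated real
callers would), no LD decay along a recombination map, and expression
noise is homoscedastic on the log scale. Green acceptance tests therefore
establish that the algorithms are implemented correctly and are calibrated
under their stated models, not that the published biological numbers are
reproduced; published table arithmetic (totals, percentages, grid sizes)
is checked directly on the printed values.

## 10. Known limitations

* Cluster genotypes are presence/absence only; heterozygous cluster calls
  are out of scope (real inbreds are ≈ 99 % homozygous).
* The AND-combination uses the first caller's coordinates; no coordinate
  averaging across consensus members.
* The hotspot λ is per chromosome; sub-chromosomal rate variation (e.g.
  pericentromeric enrichment) inflates hotspot counts by design.
* The PK model fits one variance component; dominance or epistatic
  kernels are not modelled.
* The fixed-effects entry means understate shrinkage relative to a true
  mixed model in very unbalanced designs.
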