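# Methods

`pqtlkit` implements a complete protein-QTL inference chain — discovery
scan, locus definition, replication meta-analysis, trans-locus mediator
evidence, pleiotropy clustering, and disease risk scoring — together with
a synthetic-data generator that plants recoverable truth at every stage.
This note describes the models, the defaults and why they are set where
they are, what the generator does and does not emulate, and the design
choices made where the protocol left the design open.

## Discovery model

Protein levels are analysed on the log10 scale. For each assay, an
ordinary-least-squares model removes age, sex, recruitment centre, assay
batch, smoking, diabetes and hypertension (categoricals expanded to
indicator contrasts); the residuals are standardized to mean 0, sd 1.
Association of each standardized residual *y* with each coded-allele
dosage *g* is the simple-regression Wald test:

    beta = cov(g, y) / var(g),   se^2 = RSS / ((n-2) var(g) n-scale),
    t = beta / se  ~  t(n-2),    r^2 = cor(g, y)^2

Two-step residualization (covariates projected out once, then marginal
scans) rather than a joint per-variant model mirrors the standard pQTL
protocol and is what the recovery tests calibrate against. The *t*
reference with n−2 df matters only at the small n used in unit fixtures;
at n ≈ 3,394 it is indistinguishable from the normal. P-values that
underflow are clamped at the smallest positive normal double and flagged,
so extreme associations (−log10 p > 300) remain representable and ordered.

Assay QC removes assays with more than 20% of samples below the lower
detection limit or inter-plate CV above 25% (both strict). Variant QC
removes call rate < 95% and Hardy–Weinberg exact p < 1e-6, the HWE test
computed on hard calls from rounded dosages (the protocol filtered
genotyped calls before imputation). The HWE p is the exact conditional
test: the sum of probabilities of all heterozygote counts no more likely
than the observed one, given the allele counts.

Genome-wide significant records (p < 5e-8, strict) are merged per trait by
greedy blocking: the strongest remaining record becomes an index and
absorbs records with LD r² > 0.1 **and** distance ≤ 250 kb (the merge
condition is read as a conjunction). Loci are classed *cis* when the index
SNP lies within 500 kb of the trait gene body (distance 0 inside the gene;
signed negative 5′ of the gene in reference orientation), *trans* when on
another chromosome or ≥ 100 Mb away. Same-chromosome distances between
500 kb and 100 Mb — which the reference data never produced — get an
explicit `ambiguous` class with a warning rather than a silent call. A
per-locus override list allows the documented cis exception just outside
the window (the 530.7 kb case).

## Replication

Index SNPs are matched into replication cohorts directly by id, else by
the best LD proxy with r² > 0.8 within ±500 kb on the same chromosome
(the search radius is this package's choice; proxies further away are not
plausible). Proxy effect alleles are harmonized by the sign of the dosage
correlation in the LD reference. Per-cohort estimates combine by
fixed-effects inverse-variance weighting (pooled betas require the
beta/se scheme, not sample-size z-weighting):

    w_i = 1/se_i^2,  beta_pool = sum(w_i beta_i)/sum(w_i),
    se_pool = sum(w_i)^(-1/2)

The Bonferroni replication threshold is 0.05 divided by the number of
measurable pQTLs, rounded to one significant figure — 0.05/71 → 0.0007,
with 71 = 79 − 8 unmeasured as the documented default divisor. A
replicated call additionally requires the pooled sign to agree with
discovery.

## Mediator evidence for trans loci

Candidate mediators of a trans locus are all genes within 500 kb of the
index SNP, ranked by absolute distance. Five evidence tracks:

1. **Coding proxy** — a missense variant in LD (r² > 0.6) with the index
   SNP, attributed to the candidate gene harboring it.
2. **Cis-eQTL** — per expression dataset, simple regression of log2
   expression on dosage; reported when p < 5e-4 (≈ FDR 5%), uncorrected
   p shown.
3. **Unweighted network path** — shortest path (edge count) from the
   candidate to the trait gene in the interaction network (STRING-style
   edges kept at combined score > 400), tested against a permutation null.
4. **eQTL-weighted path** — each gene entered along a path costs its
   trans-eQTL score: 1 by default, 0.8 if the gene's best eQTL p for the
   index SNP (minimum across datasets) is < 0.05, 0.6 if < 0.005. The
   weighted length excludes the source's own score, so a direct edge costs
   score(target) and a two-hop path score(mediator) + score(target).
5. **Literature** — a provided abstract co-occurrence count > 50.

A pair appears in the headline table when at least one track fires; the
full unfiltered table is always available.

**Permutation null.** The null randomizes both topology and scores:
degree-preserving double-edge swaps (10·|E| attempted swaps per replicate,
the standard configuration-model burn-in; edge confidences ride along by
slot) plus an independent permutation of the score map over nodes. The
p-value is the plain fraction of replicates whose shortest length is
strictly smaller than the observed one; disconnected replicates count as
not-shorter. A `(k+1)/(B+1)` estimator is available by configuration.
1000 replicates is the default; the calibration and recovery experiments
in this package run at 200 replicates (p resolution 0.005, ample for
decisions at alpha 0.05).

**A structural property of this estimator worth knowing.** Because node
scores lie in [0.6, 1], any permuted network in which the source–target
pair is directly adjacent has weighted length ≤ 1, which is strictly
shorter than any observed two-hop path (≥ 1.2). The weighted permutation
p of a mediated two-hop path is therefore never smaller than the
unweighted one: whenever hub degrees make direct edges common enough under
rewiring that the unweighted test cannot call a two-hop path significant,
the weighted test cannot either. The weighted statistic still separates
candidate mediators *at equal hop count* (a 0.6-scored mediator shortens
the observed path and is reported with the path), but with this null it
cannot be strictly more sensitive than hop counting for mediated paths.
The package implements the estimator as defined and reports measured
detection rates; see the calibration section of `scripts/acceptance.py`
output.

**Calibration experiment.** Path lengths are small integers, so a
strict-inequality permutation p is discrete and mildly anti-conservative:
pairs at distance L become false positives exactly when the null mass
below L sits under alpha. The null calibration therefore uses
Erdős–Rényi graphs of 120 nodes with mean degree 3 — a regime where the
distance-2 shell carries ≈ 5% mass and the distance-≤2 mass clears alpha —
with 5 independent graphs × 100 non-adjacent connected pairs and 200
permutations shared across a graph's pairs. Measured false-positive rate
at alpha 0.05 is ≈ 0.06–0.08.

## Pleiotropy and disease scores

Index SNPs with ≥ 2 protein associations below 0.05/(n_proteins × n_snps)
(= 7.6e-6 for 83 × 79; the protocol prints 7.7e-6) form a −log10 p matrix;
rows and columns are ordered by complete-linkage hierarchical clustering
with 1 − Pearson r as distance (zero-variance profiles get distance 1).

For disease scoring, each index SNP's disease-GWAS record is aligned to
the pQTL allele pair (a swap flips the beta), strand-ambiguous A/T and C/G
pairs are excluded, and the coded allele is flipped where needed so every
disease beta is risk-increasing. Per-protein records pool by the same IVW
formulas; pooled p-values are flagged by Benjamini–Hochberg FDR at 5%
across all scored proteins in a run (the FDR family is configurable). A
formal Mendelian-randomization estimator is deliberately out of scope; the
pooled score is a causal *screen*, not an effect estimate.

## Synthetic data

Every generator is a pure function of its specification and a seed, and
all planted structure is recorded in a `TruthTable` keyed by the same
identifiers the pipeline emits, so recovery tests are joins, not string
matching.

* **Genotypes** — dosages are sums of two Bernoulli haplotypes. LD comes
  from a latent AR(1) Gaussian per haplotype thresholded at the MAF
  quantile; a `block` key restarts the chain, giving haplotype blocks
  with high internal LD and independence between blocks. The default
  cohort uses 13 blocks of 3 variants per chromosome (50 kb inside a
  block, 300 kb between blocks), latent rho 0.8, with a shared MAF per
  block — pairwise r² within a block is then well above the 0.1 merge
  threshold, as real block structure requires, while cross-block leakage
  is negligible.
* **Protein panel** — 3,394 samples × 92 assays; each planted effect
  contributes a standardized dosage component scaled to its variance
  fraction; covariates jointly explain 15%; plate intercepts are random
  per 88-sample plate with sd calibrated to a target inter-plate CV via
  the lognormal relation CV = sqrt(exp(sigma_ln²) − 1); the residual takes
  the remaining variance. The lowest `lod_censor_frac` quantile of each
  assay is set to the LOD value (censored, not dropped, the way PEA panels
  present data), and `frac_below_lod`/`cv_interplate` are recorded from
  the realized data — the CV from a pooled control measured once per
  plate. Nine assays are planted as QC violators (six by LOD at 25%
  censoring, three by CV with target 0.50, far enough from the 0.25
  cutoff that sampling noise in ~39 plates cannot blur the violation), so
  83 of 92 survive.
* **Expression** — 11 datasets of n = 89–367 (mean exactly 223), subjects
  subsampled independently per dataset, planted additive effects on log2
  expression, independent noise across datasets.
* **Network** — preferential attachment (m = 2) over 200 genes, random
  confidences in [401, 1000], planted edges added afterwards. The default
  study plants cis-gene → mediator → trait-gene with the mediator a
  trans-eQTL target (10% variance in every dataset, so its best p is
  < 0.005 and its score 0.6) and removes any accidental direct
  cis-gene–trait-gene edge so the mediated route is the shortest.
* **Disease summary statistics** — variants of causal proteins get a
  disease beta proportional (factor 0.5) to the protein beta plus
  N(0, se) sampling noise; everything else is null; se is constant (0.01)
  and p the two-sided normal tail.

**What the generator does not emulate:** realistic human LD maps and
allele-frequency spectra, imputation error, case–control disease data,
population stratification, assay-specific standard curves, or networks
with STRING's size and hub structure. Passing recovery tests therefore
demonstrate that the *threshold logic and inference chain* behave as
specified under controlled conditions, not that the pipeline's power
numbers transfer to real cohorts.

## Numerical choices

* Missing dosages are NaN (out-of-band); no numeric missing codes.
* Coordinates are 1-based inclusive internally; BED input is converted on
  ingest. The coded allele is VCF ALT (or the declared allele), and all
  betas are per coded-allele copy.
* P-value underflow clamps at the smallest positive normal double
  (≈ 2.2e-308) with an explicit flag.
* The weighted shortest path is a hand-rolled Dijkstra over entered-node
  costs (ties broken by node order) because node-cost semantics through an
  undirected edge-weight callable are not guaranteed by graph libraries;
  it is property-tested against exhaustive path enumeration.
* Rewiring seeds: replicate *b* uses independent streams `[seed+b, 1]`
  (topology) and `[seed+b, 2]` (scores), making every replicate
  reproducible in isolation.
* Monomorphic variants are skipped in scans and treated as r² = 0 in LD
  queries, with logging, never as exceptions.
* Merge and proxy ties break deterministically (p, then id; |Δpos|, then
  id).

## Problem sizes used by the shipped experiments

The calibration run uses 500 pairs at 200 permutations; mediator-recovery
runs 20 seeds at 200 permutations; pQTL/disease recovery runs the full
n = 3,394 cohort across 20 seeds (tests) or 10 seeds (acceptance script).
These sizes give the binomial resolution the assertions need — e.g. 20
seeds resolves a 95% criterion to ±1 seed — while each experiment
completes in minutes on one core.

## Known limitations

* The permutation estimator's discreteness makes it anti-conservative at
  small alpha on short-path pairs (see the calibration section); the
  `add_one` estimator is strictly valid but still discrete.
* The weighted path test inherits the structural ceiling described above;
  a null that compares within hop-count strata would be needed for the
  weighted test to dominate hop counting, and is not part of the
  specified protocol.
* LD in the generator is block-diagonal; proxy search and locus merging
  are exercised, but long-range LD pathologies (e.g. MHC-scale) are not.
* The pooled disease score assumes independent instruments (loci are
  LD-pruned by construction) and makes no pleiotropy correction.
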