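# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where conventions
diverge.

## 1. Workflow model

The pipeline treats post-GWAS gene prioritization as a funnel of set-valued
filters:

1. **SNP stage.** Genome-wide significant SNPs (p strictly < `p_sig`,
   default 1e-8) are expanded against a reference genotype panel: a partner
   qualifies if it lies on the same chromosome within `window_bp`
   (default ±500 kb, inclusive) of a query and its dosage r² with the query
   is strictly greater than `r2_min` (default 0.9). r² is the squared
   Pearson correlation of unphased dosage vectors (the standard composite
   estimator; phased input is collapsed to dosages, and samples with a
   missing dosage at either variant are dropped pairwise). The union of
   queries and partners, deduplicated by variant id (query records win, a
   provenance column records which rule admitted each SNP), is chained into
   loci per chromosome by single linkage: consecutive sorted SNPs with gap
   strictly below `locus_gap_bp` (500 kb) share a locus, so a gap of
   exactly 500 kb splits. Coordinates are 1-based inclusive as in VCF; the
   BED export is 0-based half-open.
2. **Evidence stage.** Three filters nominate genes: (a) SNPs in the
   regulatory category-1 family (1a–1f, the eQTL tier of the closed
   15-category vocabulary) that survive the SNP stage, mapped to genes via
   the eQTL link table; (b) genes upregulated (`direction == up`) in a
   target brain tissue at adjusted p strictly < `deg_alpha` (0.05) — the
   default target list is the five tissues with the strongest upregulation
   signal (cortex, frontal cortex BA9, cerebellum, cerebellar hemisphere,
   anterior cingulate cortex BA24); (c) TWAS hits for an obesity-defining
   phenotype (BMI, fat mass, waist circumference, weight) in one of nine
   brain tissues. Gene identity is the uppercased, whitespace-stripped
   symbol; synonym resolution across resources is out of scope (a known
   limitation). The merge reports the union plus all pairwise and triple
   overlaps and verifies inclusion–exclusion.
3. **Network stage.** The prioritized genes are induced on the scored
   interaction network. Methods conventions for "medium confidence" differ
   between ≥ 0.4 and > 0.4; we use inclusive ≥ 0.4 (the database's own
   convention), with `strict=True` available. Duplicate undirected edges
   collapse to the maximum score; self-loops drop; isolated candidates stay
   as nodes. Centralities on the unweighted graph: degree; *harmonic*
   closeness Σ 1/d (chosen because a confidence-filtered network is always
   disconnected and the harmonic form is well defined there — it is also
   the reciprocal-distance sum that network-analysis plugins report);
   betweenness unnormalized with endpoints excluded (rankings are invariant
   to the usual normalizations). Key genes are the intersection of the
   three top-k lists; ties at the k boundary break by symbol order for
   determinism, `keep_ties=True` keeps all tied nodes. Centralities are
   computed on the induced subgraph (not the full database graph),
   matching the "reconstruct the network for the gene set" reading.
4. **Enrichment stage.** One-sided hypergeometric upper tail per term
   (equivalent to one-sided Fisher on the 2×2 table) with the universe
   defaulting to the genes annotated in the library, not the genome.
   Adjustment is Benjamini–Hochberg per library; the source workflow says
   only "adjusted p-value", so BH is an explicit choice users should be
   aware of. Significance requires adj-p strictly < 0.05 *and* overlap ≥ 4
   ("more than 3 genes"). Service-specific combined scores (rank-deviation
   nulls) are deliberately not reproduced.
5. **Drug stage.** Interactions kept when the drug is approved, the gene is
   a key gene, ≥ `min_sources` (2) databases support it after removing a
   configurable cancer-specific source blocklist, and ≥ `min_pmids` (1)
   publications exist ("PubMed sources" is read as an additional
   requirement, the stricter interpretation; both knobs are configurable).
   Weight-effect classes are input annotations (derived from literature
   upstream); a drug with conflicting classes across rows is an input
   error. Side-effect burden counts distinct "very common" (MedDRA ≥ 10%)
   effects per drug. Repurposing triage flags drugs with burden ≤
   `max_effects` and ≥ 1 knockout-supported target; the source contrasts
   burdens of 1–8 against 52 without naming a cutoff, so the default of 10
   sits between those groups and is exposed as a parameter.
6. **Validation stage.** Three resampling schemes, `n_trials = 10` each,
   trial seeds `seed, seed+1, ...`, sampling uniform without replacement:
   `stage1_random` draws prioritized-set-sized samples from the annotated
   universe and reruns hub selection on each; `stage2_random` draws
   key-set-sized samples from the prioritized genes; `stage2_low_degree`
   restricts that pool to genes with induced-network degree < 2. Overlap
   rates against the knockout-flagged and drug-related gene references are
   summarized as median and sample SD (n−1).

### The t test, and why there are two of them

The comparison of one observed rate against 10 trial rates is a t test with
9 df. The natural "one-sample" form, t = (mean − observed)/(s/√n), treats
the observed value as a fixed hypothesized mean; it is what a comparison of
"our workflow vs ten controls" usually means and is very powerful. It is
not, however, a calibrated outlier test: when the observed rate is
exchangeable with the trials (a true null), the numerator carries the
observed value's own sampling noise, which the denominator ignores, and the
test rejects far above its nominal level. The "prediction" form divides by
s·√(1 + 1/n) instead — the standard error of a new observation — and holds
the nominal level under exchangeability. `compare_observed_to_null`
defaults to the one-sample form (the conventional reading) and exposes the
prediction form; the calibration property test uses the latter, the power
property test the former, and reports record which form produced them.
Two-sided p-values are reported; directional claims read the sign of t.

## 2. Synthetic-knowledgebase generator

`synthio` generates every input the pipeline consumes, deterministically
from `(scenario, seed)` (each table draws from its own fixed RNG stream, so
tables regenerate independently and byte-identically).

* **Panel.** Haplotypes are built block by block (`ld_block_size_bp`,
  50 kb): the first SNP of a block draws a fresh allele frequency from
  U(0.15, 0.5); each later SNP copies the previous column and flips alleles
  with probability `mutation_rate` (0.02). Within-block adjacent pairs are
  therefore tightly correlated while blocks recombine freely. Monomorphic
  columns are repaired by single-genotype flips so pairwise LD is always
  defined.
* **Association p-values.** Planted causal SNPs get p = 10^(−8 − Exp(1)),
  background uniform on (1e-6, 1]: deterministic separation, no false
  significants at the 1e-8 cut.
* **Enrichment model.** Inclusion probabilities are boosted on the odds
  scale, p' = m·q/(1 − q + m·q): identity at m = 1 (the null scenario) and
  saturating at 1. True genes get m = `enrichment_strength`; planted hubs —
  standing in for the core causal genes, which in real data accumulate
  evidence in several resources at once — get m = strength², which still
  reduces to 1 at strength 1 so null calibration is preserved. eQTL links
  for boosted genes preferentially attach to causal SNPs (same odds boost
  on a 0.15 base), which is what lets the SNP-level filters recover true
  genes downstream.
* **Interaction network.** Preferential attachment (Barabási–Albert,
  m = `ppi_attachment`) over a random `ppi_coverage` fraction of the
  universe; the rest stay isolated, mirroring the many proteins real
  databases leave unconnected at medium confidence (the isolated fraction
  also supplies the degree<2 pool the low-degree control needs — it must
  exceed the key-set size for that scheme to resample). Node labels are
  shuffled so structural hubs are independent of gene identity; planted
  hubs then receive extra high-score (0.7–1.0) edges until their degree
  reaches twice the 90th percentile of non-hub degree.
* **Knowledge tables.** The GMT library holds one planted term — the
  planted hubs topped up with true genes to 15 of 20 members — plus random
  terms; drug interactions and knockout flags use the same odds-boost
  model on 0.12 base rates.

### Desk-scale study conditions

The scenario defaults mirror the proportions of a full-scale human
workflow at roughly one-twelfth size, chosen once from a pre-implementation
power analysis: a 1,200-gene universe (standing in for ~15k annotated
genes), 10% true genes, 15 planted hubs, enrichment strength 8, evidence
base rates 0.05 (giving a prioritized union of ~220 genes ≈ 18% of the
universe, vs ~9% at full scale), 4 chromosomes × 5 Mb with 1,000 SNPs and
99 samples (a reference-panel-sized cohort), 60 causal SNPs. Desk-scale
runs use top_k = 50 (scaling the full-scale 100 against the smaller
prioritized set); `PipelineConfig` defaults keep the full-scale settings.
At these conditions the key set is ~40 genes with knockout overlap ≈ 30–40%
and drug overlap ≈ 40–60%, the same order as the full-scale workflow's
~28%/~31%.

### What the generator does *not* emulate

Realistic allele-frequency spectra and coalescent genealogies; real genome
coordinates or gene structures; eQTL effect sizes (links are binary);
correlated evidence layers beyond the shared truth set; literature-derived
weight-effect directions (labels are random per drug); database-specific
biases (study-skew in publication counts, ascertainment in interaction
databases). Passing tests therefore demonstrate that the *procedures* are
correct and that the workflow concentrates a planted signal under the
stated enrichment model — not that real knowledgebases satisfy that model.

## 3. Numerical choices and degenerate inputs

* Hypergeometric tails go through scipy's log-gamma survival function
  (checked against exact rational enumeration for all N ≤ 25); BH through
  statsmodels (checked against a naive O(m²) oracle); centralities through
  igraph's C implementations (checked against an all-pairs BFS
  pair-counting oracle, which is an independent method, not Brandes).
* r² is clipped to [0, 1]; monomorphic variants raise a dedicated error
  for direct queries and are skipped as expansion partners (they cannot
  satisfy an r² threshold).
* Trial-rate standard deviations below 1e-12 are treated as zero variance
  (degenerate test) — this also catches exactly-repeated rates up to
  float rounding, e.g. when a resampling pool equals the sample size.
* A single trial yields median = the value, SD = 0 with a degenerate flag.
* All outputs are sorted deterministically (variants by chrom/pos/id,
  genes by symbol, terms by adjusted p then id); every random draw flows
  from the configured seed.

## 4. Open choices made here

* Whether the full SNP list or only the significant SNPs feed locus
  clustering: the full list (configurable by passing either table).
* The 14,937-gene resampling pool is not purged of the prioritized genes
  (no exclusion), matching the plain reading of the control design.
* TWAS hits are taken as-is with no association-strength cutoff before the
  phenotype/tissue filter.
* The eQTL/DEG pairwise overlap is reported (it is implied by
  inclusion–exclusion) but never asserted against external counts.
* Numeric-rank regulatory annotations are supported by passing a custom
  category set to `filter_regulatory_snps`.

## 5. Known limitations

Symbol-string gene identity (no synonym resolution); binary evidence
(no per-link weights or colocalization probabilities); unweighted shortest
paths (scores gate edges but do not weight them); no conditional/joint
association analysis (the significant-SNP list is an input); enrichment
limited to the hypergeometric ORA family; validation limited to the
resampling schemes above (benchmarking against external historical studies
requires their summary statistics and is out of scope).
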