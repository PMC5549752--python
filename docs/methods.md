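# Methods

## Analysis model

The pipeline treats a paired metabarcoding experiment as an OTU ×
(sample, fraction) count matrix in which each biological sample
contributes a DNA-derived column (rRNA genes; the standing community)
and an RNA-derived column (rRNA; ribosome content, a proxy for
metabolic activity), plus procedural-blank control columns. The
analysis makes the standard assumptions of the RNA:DNA-ratio approach:
sequencing reads are a multinomial sample of the underlying relative
abundances; rRNA content scales with activity within a taxon; and
ratios of *relative* abundances are meaningful even though neither
fraction is an absolute measurement. No correction is applied for 16S
copy-number or rRNA-operon variation between taxa — ratios compare a
taxon with itself across fractions, where copy number largely cancels,
but cross-taxon ratio comparisons inherit that caveat (especially for
eukaryotes, whose rDNA copy number is highly variable).

## Read cleaning

A read passes QC iff, in order: both primers match degeneracy-aware
with at most `max_primer_mismatches` (default 0) mismatches and are
trimmed (reverse primer as reverse complement at the 3' end); the
trimmed read is ≥ `min_length_bp` (default 200 bp); it has ≤
`max_ambiguous` (default 0) 'N' bases; and its mean PHRED quality is ≥
`min_mean_phred` (default 25). Two readings were open: a single PHRED
threshold can be per-base or per-read; the mean-per-read reading was
chosen as the common read-level interpretation of a single threshold.
Length is measured after primer trimming because the amplicon insert is
the biological quantity. Rejections are attributed to the first failing
rule, making reports reproducible, and rule order is fixed for the same
reason.

## Clustering

Greedy centroid clustering processes sequences by decreasing length
(ties: decreasing abundance, then id) and assigns each to the *first*
centroid reaching the identity threshold (0.97 prokaryotes, 0.95
eukaryotes), else founds a new cluster. First-match (not best-match)
assignment mirrors the greedy length-sorted tool family and is part of
the contract, since it changes partitions. Identity is matched columns
over internal columns of an optimal global alignment with free terminal
gaps (biotite `align_optimal`, gap penalty −10, terminal gaps free);
external clusterers differ in dialect here, so the definition is
localized in `pairwise_identity` and the implementation is certified in
tests against a brute-force all-vs-all oracle rather than against any
particular tool. This is a reference implementation: it is quadratic in
the number of sequences and not meant beyond ~10⁴ sequences.

## Filtering

Order: minimum-count → decontamination → phantom removal, as the
conservative reading of the protocol lists them; order matters (a
2-read contaminant is attributed to the artefact stage). Choices made
where the procedure was ambiguous:

* **min-count scope** — an OTU is an artefact when its *total* across
  every column of the table is < 3 (the conservative, dataset-wide
  reading consistent with "sequencing artefacts").
* **decontamination** — binary presence: any OTU with ≥ 1 read in any
  control column is removed from all columns; controls are pooled
  rather than matched per sampling occasion. No frequency/prevalence
  model is offered; for low-biomass work the presence rule is the
  conservative default.
* **phantom scope** — an OTU detected in RNA with zero DNA in the same
  sample has its RNA count zeroed *in that sample only* (default),
  because the same OTU may be legitimately DNA-backed in another
  sample; `scope="global"` removes the OTU outright for users who read
  the rule strictly.
* **fixed point** — phantom zeroing can push an OTU's total back below
  the min-count threshold, so the chain re-applies min-count + phantom
  until stable; the returned table is a fixed point and re-running the
  chain (with `controls="none"`, the explicit no-control configuration,
  since control columns are consumed) removes nothing.

The ledger records per-stage OTU and read removals; reads are conserved
exactly (input = output + removed) and removal sets are disjoint across
stages.

Normalization is to proportions per column, not rarefaction, to avoid
discarding reads; rarefaction utilities are provided for
depth-standardized richness comparisons only.

## Diversity statistics

Implemented from closed forms (and cross-checked against scikit-bio in
the test suite):

* **Shannon H** in natural log. The log base is a genuine choice;
  nats were chosen because published H values near 9 for ~2×10⁴
  observed OTUs sit close to the ln-maximum (ln 20432 ≈ 9.9), which is
  the "extreme diversity" regime these data occupy, whereas log₂ or
  log₁₀ would place them nowhere near their bounds.
* **ACE** with the classic rare cutoff of 10; when every rare read is a
  singleton C_ace = 0 and Chao1 is returned instead. γ² uses the
  max(·, 0) clamp.
* **Coverage** = observed / ACE, the definition that reproduces the
  published 72%–98% range from the bundled table values; Good's
  coverage 1 − F₁/N is provided as a secondary definition.
* **Gini** over observed OTUs only (unobserved taxa are unknowable),
  sample formula without small-n correction, so the upper bound is
  1 − 1/n; the Lorenz curve is built from the same ascending-sorted
  cumulative sums and starts at (0,0).
* **Exact rarefaction** via log-gamma arithmetic, so binomial
  coefficients at 10⁶-read scale do not overflow; subsampled
  rarefaction is a multivariate hypergeometric draw with an explicit
  seed (never global RNG state).

## Activity

Ratios are computed on column-normalized proportions (robust to unequal
sequencing depth between fractions), after aggregation to the analysis
rank (genus for prokaryotes, order for eukaryotes; OTUs unassigned at
that rank pool into "unclassified"). Banding partitions [0, ∞) at
0.1, 1 and 10; a ratio of exactly 1 is counted active (the boundary
between "> 1 is active" prose and banding at 1 is ambiguous; inclusive
was chosen and is tested). The top-n taxon selection ranks taxa within
each sample by decreasing DNA relative abundance (rank basis exposed as
`rank_by={"dna","rna","mean"}` since the convention varies), assigns
absent taxa rank n_taxa + 1, averages across samples, and breaks ties
by total abundance then name. `activity_table` also reports the
Spearman correlation between DNA abundance and ratio as a diagnostic
for the rare-taxa-high-ratio pattern.

## Synthetic data generator

`generate_community` emulates, per sample: base abundances drawn
log-normal(0, σ²) and normalized (σ default 2.0, which yields Gini
≈ 0.8–0.9 at these richnesses — the unevenness regime of environmental
communities); DNA counts multinomial at `depth_dna`; RNA expected
proportions = base × per-OTU multiplier, renormalized, multinomial at
`depth_rna`. Multipliers: a designated active set (default 10% of OTUs,
multiplier uniform in [3, 10]), a designated inactive set (default 10%,
uniform in [0.05, 1/3]; the spec'd config names no size for this set,
so `inactive_fraction` mirrors `active_fraction`), and a neutral
remainder at exactly 1. Optional rare-ratio inflation multiplies each
OTU's multiplier by 1 + `rare_ratio_inflation`/percentile, with
percentile the OTU's ascending-abundance percentile in that sample, so
the rarest OTUs get the largest inflation — reproducing the negative
abundance-ratio trend qualitatively, not quantitatively.

Contaminants are extra OTUs with guaranteed presence in the blank
column (Poisson(`contaminant_control_rate`), floored at 1 read) and
moderate expected abundance in sample columns
(`contaminant_sample_rate` expected reads — the worst case for
presence-based removal is a contaminant abundant in samples, and these
survive the min-count filter so removal is attributable to
decontamination). Phantoms are extra OTUs with RNA-only expectation
(`phantom_rate` expected reads) and structurally zero DNA counts. Both
are folded into the per-column multinomial, so column sums equal
configured depths exactly. When `contaminant_count` is 0 no blank
column is emitted (an all-zero control is degenerate). All draws come
from one `numpy` generator seeded by `seed`; outputs are byte-identical
per seed.

**What passing tests do and do not show.** The generator reproduces
unevenness, rare tails, depth effects, contamination and phantom
structure, and a controllable activity contrast — so the tests certify
the *procedures* (filters remove exactly what they define, statistics
match closed forms, the ratio rule separates a 3× activity contrast at
5×10⁴-read depth). It does not model PCR/chimera error, realistic
quality profiles, copy-number variation, phylogenetically structured
taxonomies, or between-sample source structure; recovery on synthetic
data therefore bounds what the method can do under its own assumptions,
not its accuracy on real communities.

**Recovery scoring.** `active_set_recovery` calls an OTU active when
its mean ratio over DNA-supported samples is ≥ 1, and scores
precision/recall over the designated active ∪ inactive candidates.
Neutral OTUs (true multiplier exactly 1) sit on the decision boundary,
so sampling noise classifies about half of them "active" by
construction; they are therefore not part of the scored contrast, which
measures separation of truly active from truly inactive taxa.

## Pipeline and determinism

`run_all` enters at OTU-table level (primary), FASTQ level, or from the
generator; stages never mutate inputs; the manifest records the config
snapshot, seed, version and per-stage counts, which chain exactly.
Problem sizes in the bundled experiments (500 OTUs, 5×10⁴ reads per
fraction, 3 samples; clustering demonstrations at ≤ 10² sequences of
100–150 bp) were chosen as the smallest scales at which the targeted
effects — uneven tails, a 3× activity contrast, contaminant/phantom
structure — are comfortably resolved; the full-scale published datasets
(~10⁷ reads) and external clustering/annotation pipelines are out of
scope, and partitions at that scale are not expected to match any
specific external tool.

## Known limitations

* Identity dialect and greedy options of external clusterers vary; only
  the documented definition is implemented.
* Presence-based decontamination over-removes genuinely shared taxa
  that also contaminate reagents; that is the accepted cost of the
  conservative design.
* ACE variance is not reported; richness estimates at very low coverage
  are point estimates only.
* The RNA:DNA ratio is a relative-activity proxy; it supports no
  growth-rate or absolute-activity inference, and eukaryote rDNA
  copy-number variability blurs cross-taxon comparisons.
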