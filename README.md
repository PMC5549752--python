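# cloudotu

Paired DNA/RNA amplicon community analysis, built for the question *which
members of a microbial community are metabolically active?* — as asked of
cloud water, one of the most dilute and contamination-prone habitats that
gets sequenced. The package takes paired 16S/18S amplicon data (rRNA genes
from DNA extracts = the *total* community; rRNA from RNA extracts = the
putatively *active* community) through read QC, OTU clustering,
conservative filtering, diversity statistics and RNA:DNA activity ratios,
and ships a ground-truthed synthetic-community generator so every stage is
testable without any sequence download.

It is aimed at microbial ecologists working with low-biomass environmental
samples (atmospheric, glacial, subsurface), where negative-control
decontamination and artefact filtering are not optional extras but the
heart of the analysis.

## What it computes

**Filtering.** Three conservative filters applied in order, with a ledger:
OTUs with < 3 reads total (likely artefacts); OTUs detected in procedural
blanks (contaminants — presence-based: one control read condemns the OTU
everywhere); and *phantom* OTUs, detected in a sample's RNA fraction with
no DNA support in the same sample (no template organism, so biologically
implausible). After the chain, every RNA-positive OTU has DNA backing, so
all ratios below are finite. Counts are then normalized to proportions
rather than rarefied.

**Diversity.** For a count vector *N₁…N_S* with total *N*:
Shannon–Wiener *H* = −Σ pᵢ ln pᵢ (nats); the abundance-based coverage
estimator ACE = S_abund + S_rare/C_ace + (F₁/C_ace)·γ² with rare cutoff 10
and Chao1 fallback; sample coverage = S_obs/ACE; the Gini coefficient
G = 2Σᵢ i·x₍ᵢ₎/(n Σx) − (n+1)/n with its Lorenz curve; exact rarefaction
E[S_m] = Σᵢ [1 − C(N−Nᵢ, m)/C(N, m)] and seeded subsampling without
replacement.

**Activity.** Per taxon and sample, the RNA:DNA ratio = relative abundance
in the RNA fraction / relative abundance in the DNA fraction, banded at
0.1 / 1 / 10; ratio ≥ 1 flags potentially active taxa. Taxa are aggregated
to genus (prokaryotes) or order (eukaryotes), and the "top n by average
abundance rank across samples" selection reproduces the usual DNA-vs-RNA
scatter panels.

**Comparison.** Shared-OTU (Venn) partitions with per-region read
fractions, Bray–Curtis similarity 1 − Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ), and the
conversion cells·mL⁻¹ × water volume / equivalent air volume → cells·m⁻³
of cloudy air.

**Clustering (reference scale).** Greedy length-sorted centroid clustering
at a configurable identity threshold (0.97 for 16S, 0.95 for 18S), with
identity = matched columns / internal columns of an optimal global
alignment with free terminal gaps. Intended for 10²–10⁴ sequences and
verifiable against a brute-force all-vs-all oracle, not for production
throughput.

## Worked example

```python
from cloudotu import (SyntheticConfig, generate_community, run_filter_chain,
                      activity_table, active_set_recovery)

cfg = SyntheticConfig(seed=17)          # 500 OTUs, 5e4 reads per fraction
table, truth = generate_community(cfg)  # paired DNA/RNA + blank control
filtered, ledger = run_filter_chain(table)
records, rho = activity_table(filtered, rank="genus")
recall, precision = active_set_recovery(filtered, truth)
print(recall, precision)
```

Running `python examples/05_activity.py` prints:

```
activity bands over (genus, sample) records:
  zero     : 0
  lt_0.1   : 0
  0.1_to_1 : 25
  1_to_10  : 23
  gt_10    : 0
abundance-vs-ratio Spearman rho: -0.26
top genera by average DNA-abundance rank: ['Pseudomonas', 'Deinococcus', ...]
active-set recovery (ratio >= 1 rule): recall 1.00, precision 1.00
```

meaning: of the genus × sample records, 23 fall in the "active" 1–10
ratio band; the mild negative Spearman correlation reflects rarer taxa
carrying noisier, higher ratios; and the ratio ≥ 1 rule recovers the
generator's designated active OTU set perfectly under these conditions.
The other scripts in `examples/` walk through QC, clustering, filtering,
diversity, comparison and the one-call pipeline (also available as the
`cloudotu` command: `synth`, `qc`, `cluster`, `filter`, `diversity`,
`activity`, `compare`, `airconc`, `run-all`).

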