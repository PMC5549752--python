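"""RNA:DNA activity ratios, banding, and top-taxon selection.

The relative abundance of a taxon in the RNA-derived fraction divided by
its relative abundance in the DNA-derived fraction of the same sample
(the RNA:DNA ratio) is a standard proxy for relative metabolic activity:
ratios >= 1 flag potentially active taxa, and the 0.1 / 1 / 10 bands
structure the DNA-vs-RNA scatter plots. Ratios are computed on
column-normalized proportions, which makes them robust to unequal
sequencing depth between the two fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core import OtuTable, rank_vocabulary
from .filters import normalize_proportions

__all__ = [
    "UNCLASSIFIED",
    "BANDS",
    "ActivityRecord",
    "aggregate_to_rank",
    "rna_dna_ratio",
    "classify_band",
    "is_active",
    "top_taxa_by_average_rank",
    "activity_table",
]

UNCLASSIFIED = "unclassified"

#: Activity bands partitioning [0, inf): zero, then (0, 0.1), [0.1, 1),
#: [1, 10), [10, inf).
BANDS = ("zero", "lt_0.1", "0.1_to_1", "1_to_10", "gt_10")


@dataclass(frozen=True)
class ActivityRecord:
    """DNA/RNA relative abundances and activity call for one (taxon, sample)."""

    taxon: str
    sample_id: str
    dna_rel: float
    rna_rel: float
    ratio: float
    band: str


def aggregate_to_rank(table: OtuTable, rank: str) -> pd.DataFrame:
    """Sum OTU counts over taxa at ``rank``.

    Returns a DataFrame indexed by taxon name with MultiIndex columns
    (sample_id, fraction); OTUs unassigned at ``rank`` are pooled into a
    reserved "unclassified" taxon. Column totals are conserved.
    """
    rank_vocabulary(table.domain)  # domain sanity
    vocab = rank_vocabulary(table.domain)
    if rank not in vocab:
        raise ValueError(f"unknown rank {rank!r} for domain {table.domain!r}")
    taxa = [
        table.taxonomy[o].name_at(rank) or UNCLASSIFIED for o in table.otu_ids
    ]
    cols = pd.MultiIndex.from_tuples(
        [(c.sample_id, c.fraction) for c in table.columns],
        names=["sample_id", "fraction"],
    )
    df = pd.DataFrame(table.counts, index=taxa, columns=cols)
    agg = df.groupby(level=0, sort=True).sum()
    agg.index.name = "taxon"
    return agg


def rna_dna_ratio(dna_rel: float, rna_rel: float) -> float:
    """RNA:DNA ratio for one taxon in one sample.

    Zero RNA gives ratio 0 regardless of DNA; positive RNA with zero DNA
    is a phantom that must have been filtered upstream and raises.
    """
    if dna_rel < 0 or rna_rel < 0:
        raise ValueError("relative abundances must be non-negative")
    if rna_rel == 0:
        return 0.0
    if dna_rel == 0:
        raise ValueError(
            "RNA abundance without DNA abundance: phantom OTU leaked through "
            "filtering"
        )
    return rna_rel / dna_rel


def classify_band(ratio: float) -> str:
    """Assign a ratio to its activity band; bands partition [0, inf)."""
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if ratio == 0:
        return "zero"
    if ratio < 0.1:
        return "lt_0.1"
    if ratio < 1:
        return "0.1_to_1"
    if ratio < 10:
        return "1_to_10"
    return "gt_10"


def is_active(ratio: float) -> bool:
    """Activity call: ratio >= 1 (boundary counted active)."""
    return ratio >= 1.0


def top_taxa_by_average_rank(
    agg: pd.DataFrame, n: int = 20, rank_by: str = "dna"
) -> list[str]:
    """Select the ``n`` taxa with the best average abundance rank.

    Within each sample's ranking fraction (DNA by default) taxa are
    ranked by decreasing relative abundance (rank 1 = most abundant;
    taxa absent from a sample get rank = number of taxa + 1); ranks are
    averaged across samples and the ``n`` smallest win, ties broken by
    total abundance then name. ``rank_by`` is one of "dna", "rna",
    "mean".
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rank_by not in ("dna", "rna", "mean"):
        raise ValueError("rank_by must be 'dna', 'rna' or 'mean'")
    fractions = {"dna": ["DNA"], "rna": ["RNA"], "mean": ["DNA", "RNA"]}[rank_by]
    cols = [
        c for c in agg.columns if c[1] in fractions
    ]
    if not cols:
        raise ValueError(f"no {fractions} columns to rank on")
    n_taxa = len(agg.index)
    ranks = pd.DataFrame(index=agg.index, dtype=float)
    for col in cols:
        v = agg[col]
        # decreasing-abundance rank; absent taxa pushed past the end
        r = v.rank(ascending=False, method="min")
        r[v == 0] = n_taxa + 1
        ranks[str(col)] = r
    avg_rank = ranks.mean(axis=1)
    total = agg.sum(axis=1)
    order = sorted(
        agg.index, key=lambda t: (avg_rank[t], -total[t], t)
    )
    return order[: min(n, n_taxa)]


def activity_table(
    table: OtuTable, rank: str
) -> tuple[list[ActivityRecord], float]:
    """Per-(taxon, sample) activity records at ``rank``, plus a diagnostic.

    The table must be filtered (phantom-free); proportions are computed
    per column after aggregation. Returns the records and the Spearman
    correlation between DNA relative abundance and ratio over RNA-positive
    records (negative when rare taxa carry inflated ratios, the pattern
    seen in uneven environmental communities).
    """
    normalize_proportions(table)  # validates no zero-total column
    agg = aggregate_to_rank(table, rank)
    props = agg / agg.sum(axis=0)
    samples = sorted({s for s, f in agg.columns if f == "RNA"})
    records: list[ActivityRecord] = []
    for sample in samples:
        if (sample, "DNA") not in agg.columns:
            raise ValueError(f"sample {sample!r} has RNA but no DNA column")
        for taxon in agg.index:
            dna_rel = float(props[(sample, "DNA")][taxon])
            rna_rel = float(props[(sample, "RNA")][taxon])
            if dna_rel == 0 and rna_rel == 0:
                continue
            if dna_rel == 0 and rna_rel > 0:
                # aggregation cannot create phantoms if filtering ran, but
                # guard against unfiltered input
                raise ValueError(
                    f"phantom taxon {taxon!r} in sample {sample!r}: run the "
                    "filter chain before computing activity"
                )
            ratio = rna_dna_ratio(dna_rel, rna_rel)
            records.append(
                ActivityRecord(
                    taxon=taxon,
                    sample_id=sample,
                    dna_rel=dna_rel,
                    rna_rel=rna_rel,
                    ratio=ratio,
                    band=classify_band(ratio),
                )
            )
    pos = [(r.dna_rel, r.ratio) for r in records if r.ratio > 0]
    if len(pos) >= 3:
        rho = float(spearmanr([p[0] for p in pos], [p[1] for p in pos]).statistic)
    else:
        rho = float("nan")
    return records, rho
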