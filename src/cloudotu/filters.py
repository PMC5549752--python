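"""Conservative OTU filtering and normalization for paired DNA/RNA tables.

Three filters are applied in a fixed order, each recorded in a ledger:

1. **minimum-count** — OTUs totalling fewer than ``min_reads`` reads
   across every column of the table are treated as likely sequencing
   artefacts and dropped;
2. **decontamination** — any OTU *detected* (count > 0, presence not
   abundance) in a procedural-blank control column is removed from all
   columns, and the control columns are then dropped;
3. **phantom removal** — an OTU observed in a sample's RNA fraction but
   absent from the same sample's DNA fraction is biologically
   implausible (no template organism) and has its RNA count zeroed for
   that sample; OTUs left with zero total count are dropped.

After the chain every RNA-positive (OTU, sample) pair has a positive DNA
count, so all downstream RNA:DNA ratios are finite. The order matters and
is part of the contract: a 2-read contaminant is attributed to the
artefact stage, not the contaminant stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import OtuTable, SampleFraction

__all__ = [
    "LedgerEntry",
    "FilterLedger",
    "FilterConfig",
    "min_count_filter",
    "decontaminate",
    "phantom_filter",
    "normalize_proportions",
    "run_filter_chain",
]


@dataclass(frozen=True)
class LedgerEntry:
    stage: str
    otus_removed: int
    reads_removed: int
    otu_ids: tuple[str, ...]


@dataclass
class FilterLedger:
    """Ordered per-stage record of what was removed and why."""

    entries: list[LedgerEntry] = field(default_factory=list)

    def add(self, entry: LedgerEntry) -> None:
        self.entries.append(entry)

    @property
    def total_reads_removed(self) -> int:
        return sum(e.reads_removed for e in self.entries)

    @property
    def total_otus_removed(self) -> int:
        return sum(e.otus_removed for e in self.entries)

    def validate_disjoint(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            overlap = seen & set(e.otu_ids)
            if overlap:
                raise AssertionError(
                    f"OTUs removed twice across stages: {sorted(overlap)}"
                )
            seen |= set(e.otu_ids)

    def to_rows(self) -> list[dict]:
        return [
            {
                "stage": e.stage,
                "otus_removed": e.otus_removed,
                "reads_removed": e.reads_removed,
                "otu_ids": ",".join(e.otu_ids),
            }
            for e in self.entries
        ]


def min_count_filter(
    table: OtuTable, min_reads: int = 3
) -> tuple[OtuTable, LedgerEntry]:
    """Drop OTUs with total count < ``min_reads`` across all columns."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    totals = table.counts.sum(axis=1)
    keep = totals >= min_reads
    removed_ids = tuple(o for o, k in zip(table.otu_ids, keep) if not k)
    entry = LedgerEntry(
        stage="min_count",
        otus_removed=len(removed_ids),
        reads_removed=int(totals[~keep].sum()),
        otu_ids=removed_ids,
    )
    return table.subset_otus(keep), entry


def decontaminate(
    table: OtuTable,
    control_fractions: Sequence[SampleFraction] | None = None,
) -> tuple[OtuTable, LedgerEntry]:
    """Remove OTUs present in any control column; drop the control columns.

    Presence-based, exactly: one control read condemns the OTU in every
    sample. Raises if no control column exists, forcing an explicit
    no-control configuration upstream.
    """
    controls = (
        list(control_fractions)
        if control_fractions is not None
        else table.control_columns()
    )
    if not controls:
        raise ValueError(
            "no control sample-fractions found; decontamination requires "
            "controls (or an explicit no-control configuration)"
        )
    for c in controls:
        if not table.has_column(c):
            raise ValueError(f"control column {c.label!r} not in table")
    ctrl_idx = [table.column_index(c) for c in controls]
    contaminated = (table.counts[:, ctrl_idx] > 0).any(axis=1)
    removed_ids = tuple(o for o, bad in zip(table.otu_ids, contaminated) if bad)
    sample_idx = [i for i in range(table.n_columns) if i not in set(ctrl_idx)]
    reads_removed = int(
        table.counts[contaminated].sum() + table.counts[~contaminated][:, ctrl_idx].sum()
    )
    out = table.subset_otus(~contaminated).drop_columns(controls)
    entry = LedgerEntry(
        stage="decontaminate",
        otus_removed=len(removed_ids),
        reads_removed=reads_removed,
        otu_ids=removed_ids,
    )
    return out, entry


def phantom_filter(
    table: OtuTable, scope: str = "sample"
) -> tuple[OtuTable, LedgerEntry]:
    """Zero RNA counts with no matching DNA support, per sample.

    ``scope="sample"`` (default) zeroes the RNA count only in the sample
    where the phantom is observed — an OTU may be legitimately DNA-backed
    elsewhere. ``scope="global"`` removes an OTU entirely if it is a
    phantom in any sample. OTUs reduced to zero total count are dropped.
    """
    if scope not in ("sample", "global"):
        raise ValueError(f"scope must be 'sample' or 'global', got {scope!r}")
    rna_cols = [c for c in table.columns if c.fraction == "RNA" and not c.is_control]
    for rc in rna_cols:
        if table.find(rc.sample_id, "DNA") is None:
            raise ValueError(
                f"sample {rc.sample_id!r} has an RNA fraction but no DNA fraction"
            )
    counts = table.counts.copy()
    reads_zeroed = 0
    phantom_any = np.zeros(table.n_otus, dtype=bool)
    for rc in rna_cols:
        ri = table.column_index(rc)
        di = table.column_index(table.find(rc.sample_id, "DNA"))
        phantom = (counts[:, ri] > 0) & (counts[:, di] == 0)
        reads_zeroed += int(counts[phantom, ri].sum())
        counts[phantom, ri] = 0
        phantom_any |= phantom
    if scope == "global":
        # condemn the whole OTU row wherever a phantom was seen
        reads_zeroed += int(counts[phantom_any].sum())
        counts[phantom_any] = 0
    out = table.with_counts(counts)
    empty = counts.sum(axis=1) == 0
    removed_ids = tuple(o for o, e in zip(table.otu_ids, empty) if e)
    out = out.subset_otus(~empty)
    entry = LedgerEntry(
        stage="phantom",
        otus_removed=len(removed_ids),
        reads_removed=reads_zeroed,
        otu_ids=removed_ids,
    )
    return out, entry


def normalize_proportions(table: OtuTable) -> np.ndarray:
    """Column-wise proportions; each column sums to 1. Zero-total -> error."""
    totals = table.counts.sum(axis=0)
    zero = [c.label for c, t in zip(table.columns, totals) if t == 0]
    if zero:
        raise ValueError(f"cannot normalize zero-total column(s): {zero}")
    return table.counts / totals


@dataclass(frozen=True)
class FilterConfig:
    """Configuration for the full filter chain.

    ``controls="auto"`` uses the table's flagged control columns and
    errors when there are none; ``controls="none"`` skips the
    decontamination stage explicitly.
    """

    min_reads: int = 3
    controls: str = "auto"
    phantom_scope: str = "sample"

    def __post_init__(self) -> None:
        if self.controls not in ("auto", "none"):
            raise ValueError("controls must be 'auto' or 'none'")


def run_filter_chain(
    table: OtuTable, config: FilterConfig | None = None
) -> tuple[OtuTable, FilterLedger]:
    """min_count -> decontaminate -> phantom, with a per-stage ledger.

    Phantom zeroing can drop an OTU's total back below ``min_reads``, so
    the min_count and phantom stages are re-applied until nothing
    changes; the chain therefore returns a fixed point and re-running it
    on its own output (with ``controls="none"``, since control columns
    are consumed by the first pass) removes nothing.
    """
    config = config or FilterConfig()
    ledger = FilterLedger()
    reads_in = table.total_reads

    table, entry = min_count_filter(table, config.min_reads)
    ledger.add(entry)

    if config.controls == "auto":
        table, entry = decontaminate(table)
        ledger.add(entry)
    else:
        ledger.add(LedgerEntry("decontaminate", 0, 0, ()))

    table, entry = phantom_filter(table, scope=config.phantom_scope)
    ledger.add(entry)

    # iterate min_count + phantom to a fixed point
    while True:
        table, e_min = min_count_filter(table, config.min_reads)
        table, e_ph = phantom_filter(table, scope=config.phantom_scope)
        if e_min.otus_removed == 0 and e_ph.reads_removed == 0:
            break
        if e_min.otus_removed:
            ledger.add(e_min)
        if e_ph.otus_removed or e_ph.reads_removed:
            ledger.add(e_ph)

    ledger.validate_disjoint()
    if reads_in != table.total_reads + ledger.total_reads_removed:
        raise AssertionError("filter ledger does not conserve reads")
    return table, ledger
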