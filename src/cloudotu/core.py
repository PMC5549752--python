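"""Core domain types for paired DNA/RNA amplicon community analysis.

The central object is the :class:`OtuTable`: an OTU x (sample, fraction)
count matrix with taxonomy, where each biological sample contributes up to
two columns — a DNA-derived fraction (rRNA genes, the "total" community)
and an RNA-derived fraction (rRNA, the putatively active community) —
plus procedural-blank control columns used for decontamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SequenceRead",
    "TaxonomyLineage",
    "SampleFraction",
    "OtuTable",
    "SampleMetadata",
    "PROKARYOTE_RANKS",
    "EUKARYOTE_RANKS",
    "rank_vocabulary",
]

#: Rank vocabulary used for prokaryotic lineages (16S analyses).
PROKARYOTE_RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus")

#: Rank vocabulary used for eukaryotic lineages (18S analyses).
EUKARYOTE_RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
)


def rank_vocabulary(domain: str) -> tuple[str, ...]:
    """Return the ordered rank names for ``domain`` ("prokaryote"/"eukaryote")."""
    if domain == "prokaryote":
        return PROKARYOTE_RANKS
    if domain == "eukaryote":
        return EUKARYOTE_RANKS
    raise ValueError(f"unknown domain: {domain!r}")


@dataclass(frozen=True)
class SequenceRead:
    """A single amplicon read with per-base PHRED qualities."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id!r}: negative PHRED score")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_quality(self) -> float:
        if not self.quals:
            return 0.0
        return float(np.mean(self.quals))


@dataclass(frozen=True)
class TaxonomyLineage:
    """An ordered taxonomic lineage, possibly unassigned below some rank.

    ``names`` holds taxon names aligned with the rank vocabulary of the
    domain (phylum..genus for prokaryotes, kingdom..genus for eukaryotes)
    and may terminate early; internal gaps (an empty name followed by a
    non-empty one) are invalid.
    """

    names: tuple[str, ...]
    ranks: tuple[str, ...] = PROKARYOTE_RANKS

    def __post_init__(self) -> None:
        if len(self.names) > len(self.ranks):
            raise ValueError(
                f"lineage has {len(self.names)} names for {len(self.ranks)} ranks"
            )
        seen_empty = False
        for name in self.names:
            if name == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(
                    f"lineage {';'.join(self.names)!r}: assigned rank after an "
                    "unassigned one (internal gap)"
                )

    @classmethod
    def from_string(
        cls, lineage: str, ranks: tuple[str, ...] = PROKARYOTE_RANKS
    ) -> "TaxonomyLineage":
        """Parse a semicolon-delimited lineage string; "" is fully unassigned."""
        if lineage == "":
            return cls(names=(), ranks=ranks)
        names = tuple(part.strip() for part in lineage.split(";"))
        # trailing empties are "unassigned below", not gaps: trim them
        while names and names[-1] == "":
            names = names[:-1]
        return cls(names=names, ranks=ranks)

    def to_string(self) -> str:
        return ";".join(self.names)

    def name_at(self, rank: str) -> str | None:
        """Taxon name at ``rank``, or None if unassigned at that depth."""
        try:
            i = self.ranks.index(rank)
        except ValueError:
            raise ValueError(f"unknown rank {rank!r}; expected one of {self.ranks}")
        if i < len(self.names) and self.names[i] != "":
            return self.names[i]
        return None


@dataclass(frozen=True, order=True)
class SampleFraction:
    """One column of an OtuTable: a sample's DNA or RNA fraction."""

    sample_id: str
    fraction: str  # "DNA" or "RNA"
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.fraction not in ("DNA", "RNA"):
            raise ValueError(f"fraction must be 'DNA' or 'RNA', got {self.fraction!r}")

    @property
    def label(self) -> str:
        return f"{self.sample_id}_{self.fraction}"

    @classmethod
    def from_label(cls, label: str, control_prefix: str = "CTRL") -> "SampleFraction":
        sample_id, sep, fraction = label.rpartition("_")
        if not sep or fraction not in ("DNA", "RNA"):
            raise ValueError(
                f"column label {label!r} does not end in '_DNA' or '_RNA'"
            )
        return cls(
            sample_id=sample_id,
            fraction=fraction,
            is_control=sample_id.startswith(control_prefix),
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample physical metadata linking water- and air-volume scales."""

    sample_id: str
    water_volume_mL: float
    air_volume_m3: float
    prok_conc_per_mL: float = 0.0
    euk_conc_per_mL: float = 0.0
    lwc_g_m3: float | None = None

    def __post_init__(self) -> None:
        if self.water_volume_mL <= 0:
            raise ValueError(f"{self.sample_id}: water_volume_mL must be positive")
        if self.air_volume_m3 <= 0:
            raise ValueError(f"{self.sample_id}: air_volume_m3 must be positive")
        if self.prok_conc_per_mL < 0 or self.euk_conc_per_mL < 0:
            raise ValueError(f"{self.sample_id}: concentrations must be >= 0")


class OtuTable:
    """OTU x sample-fraction count matrix with taxonomy.

    Parameters
    ----------
    otu_ids:
        Row identifiers, unique, order-stable under filtering.
    counts:
        Non-negative integer matrix of shape (n_otus, n_columns).
    columns:
        One :class:`SampleFraction` per column; (sample_id, fraction)
        pairs must be unique.
    taxonomy:
        Mapping otu_id -> :class:`TaxonomyLineage`. Missing entries are
        treated as fully unassigned.
    domain:
        "prokaryote" or "eukaryote"; fixes the rank vocabulary.
    """

    def __init__(
        self,
        otu_ids: Sequence[str],
        counts: np.ndarray,
        columns: Sequence[SampleFraction],
        taxonomy: Mapping[str, TaxonomyLineage] | None = None,
        domain: str = "prokaryote",
    ) -> None:
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape != (len(otu_ids), len(columns)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(otu_ids)} OTUs x {len(columns)} columns"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(otu_ids)) != len(otu_ids):
            dupes = pd.Index(otu_ids)[pd.Index(otu_ids).duplicated()].tolist()
            raise ValueError(f"duplicate OTU ids: {dupes}")
        keys = [(c.sample_id, c.fraction) for c in columns]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (sample_id, fraction) columns")
        rank_vocabulary(domain)  # validates domain

        self.otu_ids: list[str] = list(otu_ids)
        self.counts: np.ndarray = counts.astype(np.int64)
        self.columns: list[SampleFraction] = list(columns)
        tax = dict(taxonomy or {})
        ranks = rank_vocabulary(domain)
        for oid in self.otu_ids:
            tax.setdefault(oid, TaxonomyLineage(names=(), ranks=ranks))
        self.taxonomy: dict[str, TaxonomyLineage] = tax
        self.domain = domain
        self._col_index = {c: i for i, c in enumerate(self.columns)}
        self._row_index = {o: i for i, o in enumerate(self.otu_ids)}

    # -- basic introspection -------------------------------------------------

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def column_labels(self) -> list[str]:
        return [c.label for c in self.columns]

    def column_index(self, sf: SampleFraction) -> int:
        try:
            return self._col_index[sf]
        except KeyError:
            raise KeyError(f"no column {sf.label!r} in table")

    def has_column(self, sf: SampleFraction) -> bool:
        return sf in self._col_index

    def get_column(self, sf: SampleFraction) -> np.ndarray:
        return self.counts[:, self.column_index(sf)]

    def control_columns(self) -> list[SampleFraction]:
        return [c for c in self.columns if c.is_control]

    def sample_ids(self, fraction: str | None = None, controls: bool = False) -> list[str]:
        """Distinct non-control (or control) sample ids, in column order."""
        seen: dict[str, None] = {}
        for c in self.columns:
            if c.is_control != controls:
                continue
            if fraction is not None and c.fraction != fraction:
                continue
            seen.setdefault(c.sample_id, None)
        return list(seen)

    def find(self, sample_id: str, fraction: str) -> SampleFraction | None:
        for c in self.columns:
            if c.sample_id == sample_id and c.fraction == fraction:
                return c
        return None

    # -- subsetting ----------------------------------------------------------

    def subset_otus(self, keep: Sequence[str] | np.ndarray) -> "OtuTable":
        """Rows restricted to ``keep`` (ids or boolean mask), order preserved."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            mask = keep
        else:
            wanted = set(keep)
            mask = np.array([o in wanted for o in self.otu_ids])
        ids = [o for o, m in zip(self.otu_ids, mask) if m]
        return OtuTable(
            otu_ids=ids,
            counts=self.counts[mask],
            columns=self.columns,
            taxonomy={o: self.taxonomy[o] for o in ids},
            domain=self.domain,
        )

    def drop_columns(self, drop: Iterable[SampleFraction]) -> "OtuTable":
        dropset = set(drop)
        keep = [i for i, c in enumerate(self.columns) if c not in dropset]
        return OtuTable(
            otu_ids=self.otu_ids,
            counts=self.counts[:, keep],
            columns=[self.columns[i] for i in keep],
            taxonomy=self.taxonomy,
            domain=self.domain,
        )

    def with_counts(self, counts: np.ndarray) -> "OtuTable":
        return OtuTable(
            otu_ids=self.otu_ids,
            counts=counts,
            columns=self.columns,
            taxonomy=self.taxonomy,
            domain=self.domain,
        )

    # -- conversion ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.otu_ids, name="otu_id"),
            columns=self.column_labels(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.otu_ids == other.otu_ids
            and self.columns == other.columns
            and np.array_equal(self.counts, other.counts)
            and self.taxonomy == other.taxonomy
            and self.domain == other.domain
        )

    def __repr__(self) -> str:
        return (
            f"OtuTable({self.n_otus} OTUs x {self.n_columns} sample-fractions, "
            f"{self.total_reads} reads, domain={self.domain!r})"
        )
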