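"""Readers and writers: FASTQ, FASTA, OTU table TSV, taxonomy TSV, metadata YAML.

Conventions (the field has no single standard for OTU-table interchange):

* OTU table: tab-separated, first column ``otu_id``, one column per
  sample-fraction labelled ``<sample>_<DNA|RNA>``; control samples are
  recognised by an id prefix (default ``CTRL``).
* Taxonomy: two tab-separated columns, ``otu_id`` and a semicolon-joined
  lineage with a fixed rank order; an empty string means fully unassigned,
  trailing empties mean unassigned below that rank.
* FASTQ qualities are Sanger PHRED+33, no autodetection.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np
import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import (
    OtuTable,
    SampleFraction,
    SampleMetadata,
    SequenceRead,
    TaxonomyLineage,
    rank_vocabulary,
)

__all__ = [
    "FastqParseError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
]

PHRED_OFFSET = 33


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records, naming the record index."""


def read_fastq(path: str | Path | TextIO) -> Iterator[SequenceRead]:
    """Yield :class:`SequenceRead` from a Sanger FASTQ file, in file order."""
    handle: TextIO
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
    else:
        handle = path
    try:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqParseError(f"record {index}: {exc}") from exc
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"record {index} ({title.split()[0] if title else '?'}): "
                    f"{len(seq)} bases but {len(qual)} quality characters"
                )
            quals = tuple(ord(c) - PHRED_OFFSET for c in qual)
            if any(q < 0 for q in quals):
                raise FastqParseError(
                    f"record {index}: quality character below PHRED+33 offset"
                )
            yield SequenceRead(id=title.split()[0], bases=seq.upper(), quals=quals)
            index += 1
    finally:
        if close:
            handle.close()


def write_fastq(reads: Iterable[SequenceRead], path: str | Path | TextIO) -> int:
    """Write reads as Sanger FASTQ; returns the number of records written."""
    handle, close = _open_w(path)
    n = 0
    try:
        for read in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.quals)
            handle.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")
            n += 1
    finally:
        if close:
            handle.close()
    return n


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs."""
    out: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    out.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
        if name is not None:
            out.append((name, "".join(chunks)))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path | TextIO) -> int:
    handle, close = _open_w(path)
    n = 0
    try:
        for name, seq in records:
            handle.write(f">{name}\n{seq}\n")
            n += 1
    finally:
        if close:
            handle.close()
    return n


def _open_w(path: str | Path | TextIO) -> tuple[TextIO, bool]:
    if isinstance(path, (str, Path)):
        return open(path, "w"), True
    return path, False


# -- OTU tables --------------------------------------------------------------


def read_otu_table(
    path: str | Path | TextIO,
    taxonomy_path: str | Path | None = None,
    control_prefix: str = "CTRL",
    domain: str = "prokaryote",
) -> OtuTable:
    """Read a tab-separated OTU x sample-fraction count table.

    Raises on duplicate OTU ids, non-integer or negative counts, and
    column labels that do not follow the ``<sample>_<DNA|RNA>`` convention.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate OTU id(s) in table: {dupes}")
    try:
        counts = df.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-integer count in OTU table: {exc}") from exc
    if (counts.values < 0).any():
        raise ValueError("negative count in OTU table")
    columns = [SampleFraction.from_label(c, control_prefix) for c in df.columns]
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = read_taxonomy(taxonomy_path, domain=domain)
    return OtuTable(
        otu_ids=[str(i) for i in df.index],
        counts=counts.values,
        columns=columns,
        taxonomy=taxonomy,
        domain=domain,
    )


def write_otu_table(
    table: OtuTable,
    path: str | Path | TextIO,
    taxonomy_path: str | Path | None = None,
) -> None:
    """Write a table (and optionally its taxonomy) so that reading it back
    reproduces the original."""
    table.to_frame().to_csv(path, sep="\t")
    if taxonomy_path is not None:
        write_taxonomy(table.taxonomy, taxonomy_path, otu_order=table.otu_ids)


def read_taxonomy(
    path: str | Path, domain: str = "prokaryote"
) -> dict[str, TaxonomyLineage]:
    """Read a two-column otu_id <TAB> lineage file."""
    ranks = rank_vocabulary(domain)
    out: dict[str, TaxonomyLineage] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                otu_id, lineage = parts[0], ""
            elif len(parts) == 2:
                otu_id, lineage = parts
            else:
                raise ValueError(f"taxonomy line {ln}: expected 2 columns")
            if otu_id in out:
                raise ValueError(f"duplicate OTU id in taxonomy: {otu_id!r}")
            out[otu_id] = TaxonomyLineage.from_string(lineage, ranks=ranks)
    return out


def write_taxonomy(
    taxonomy: dict[str, TaxonomyLineage],
    path: str | Path | TextIO,
    otu_order: Iterable[str] | None = None,
) -> None:
    handle, close = _open_w(path)
    try:
        order = list(otu_order) if otu_order is not None else list(taxonomy)
        for otu_id in order:
            handle.write(f"{otu_id}\t{taxonomy[otu_id].to_string()}\n")
    finally:
        if close:
            handle.close()


# -- sample metadata ---------------------------------------------------------

_META_FIELDS = (
    "water_volume_mL",
    "air_volume_m3",
    "prok_conc_per_mL",
    "euk_conc_per_mL",
    "lwc_g_m3",
)


def read_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    """Read per-sample metadata from a YAML mapping keyed by sample id."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, SampleMetadata] = {}
    for sample_id, fields in raw.items():
        unknown = set(fields) - set(_META_FIELDS)
        if unknown:
            raise ValueError(f"sample {sample_id!r}: unknown metadata {sorted(unknown)}")
        out[sample_id] = SampleMetadata(sample_id=sample_id, **fields)
    return out


def write_metadata(meta: dict[str, SampleMetadata], path: str | Path) -> None:
    raw = {}
    for sample_id, m in meta.items():
        entry = {
            "water_volume_mL": float(m.water_volume_mL),
            "air_volume_m3": float(m.air_volume_m3),
            "prok_conc_per_mL": float(m.prok_conc_per_mL),
            "euk_conc_per_mL": float(m.euk_conc_per_mL),
        }
        if m.lwc_g_m3 is not None:
            entry["lwc_g_m3"] = float(m.lwc_g_m3)
        raw[sample_id] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
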