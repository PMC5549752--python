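"""Reference greedy centroid clustering of amplicons into OTUs.

Sequences are processed in decreasing length order (ties broken by
decreasing abundance, then lexicographic id) and each joins the *first*
existing centroid whose identity to it reaches the threshold, else founds
a new cluster — the behaviour of the greedy length-sorted tool family.
Identity is computed from an optimal global alignment with free terminal
gaps as matched columns / internal alignment columns; this dialect choice
is localized in :func:`pairwise_identity`.

This is a reference implementation meant for 10^2–10^4 sequences, with a
partition that can be certified against a brute-force all-vs-all oracle;
it does not aim at the throughput of production clusterers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import biotite.sequence as _seq
import biotite.sequence.align as _align

from .core import OtuTable, SampleFraction

__all__ = ["Cluster", "pairwise_identity", "greedy_cluster", "cluster_counts"]

_NUC_MATRIX = _align.SubstitutionMatrix.std_nucleotide_matrix()


@dataclass
class Cluster:
    """One OTU: a centroid and the member sequences assigned to it."""

    centroid_id: str
    member_ids: list[str]
    threshold: float

    def __post_init__(self) -> None:
        if self.centroid_id not in self.member_ids:
            raise ValueError("centroid must be one of its members")

    @property
    def size(self) -> int:
        return len(self.member_ids)


def pairwise_identity(a: str, b: str) -> float:
    """Sequence identity in [0, 1] under free terminal gaps.

    Matched columns divided by the columns of the optimal global
    alignment, excluding terminal-gap columns; symmetric in its
    arguments.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    sa = _seq.NucleotideSequence(a.upper(), ambiguous=True)
    sb = _seq.NucleotideSequence(b.upper(), ambiguous=True)
    matrix = _NUC_MATRIX
    if sa.alphabet != matrix.get_alphabet1():
        matrix = _align.SubstitutionMatrix.std_nucleotide_matrix()
    alignment = _align.align_optimal(
        sa, sb, matrix, gap_penalty=-10, terminal_penalty=False, max_number=1
    )[0]
    return float(_align.get_sequence_identity(alignment, mode="not_terminal"))


def _greedy_order(
    seqs: Sequence[tuple[str, str, int]]
) -> list[tuple[str, str, int]]:
    """Decreasing length, then decreasing abundance, then id."""
    return sorted(seqs, key=lambda t: (-len(t[1]), -t[2], t[0]))


def greedy_cluster(
    seqs: Sequence[tuple[str, str, int]], threshold: float
) -> list[Cluster]:
    """Cluster ``(id, sequence, abundance)`` triples at ``threshold``.

    Deterministic for a given input set; clusters are returned in
    founding order. Every member has identity >= threshold to its
    centroid (first-match, not best-match, assignment).
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ids = [t[0] for t in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    clusters: list[Cluster] = []
    centroid_seqs: list[str] = []
    for sid, sequence, _abund in _greedy_order(seqs):
        assigned = False
        for cluster, cseq in zip(clusters, centroid_seqs):
            if pairwise_identity(sequence, cseq) >= threshold:
                cluster.member_ids.append(sid)
                assigned = True
                break
        if not assigned:
            clusters.append(
                Cluster(centroid_id=sid, member_ids=[sid], threshold=threshold)
            )
            centroid_seqs.append(sequence)
    return clusters


def cluster_counts(
    clusters: Sequence[Cluster],
    read_map: Mapping[str, SampleFraction],
    domain: str = "prokaryote",
) -> OtuTable:
    """Materialize the OTU x sample-fraction count matrix.

    Each cluster becomes one row (OTU id = centroid id); column order is
    the sorted set of sample-fractions seen in ``read_map``. Total counts
    equal the number of clustered reads.
    """
    for cluster in clusters:
        for mid in cluster.member_ids:
            if mid not in read_map:
                raise KeyError(f"read {mid!r} has no sample-fraction mapping")
    columns = sorted(set(read_map.values()))
    col_index = {c: i for i, c in enumerate(columns)}
    counts = np.zeros((len(clusters), len(columns)), dtype=np.int64)
    for i, cluster in enumerate(clusters):
        for mid in cluster.member_ids:
            counts[i, col_index[read_map[mid]]] += 1
    return OtuTable(
        otu_ids=[c.centroid_id for c in clusters],
        counts=counts,
        columns=columns,
        domain=domain,
    )
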