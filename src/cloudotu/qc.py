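"""Amplicon read cleaning.

A read passes QC iff, applied in this order:

1. the forward primer matches (degeneracy-aware) at the 5' end and the
   reverse primer (as reverse complement) at the 3' end — both are trimmed;
2. the trimmed read is at least ``min_length_bp`` long;
3. it contains at most ``max_ambiguous`` 'N' bases;
4. its mean PHRED quality is at least ``min_mean_phred``.

Rejections are attributed to the first failing rule, so the per-rule
counts in the report are reproducible and sum to the rejected total.
The single quality threshold is applied to the mean per-read quality;
length is measured after primer trimming (the amplicon insert is the
biological quantity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .core import SequenceRead

__all__ = ["QcConfig", "QcReport", "primer_match", "qc_filter", "reverse_complement"]

#: IUPAC nucleotide degeneracy expansions.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")

RULE_PRIMER = "primer"
RULE_LENGTH = "length"
RULE_AMBIGUOUS = "ambiguous"
RULE_QUALITY = "quality"
RULES = (RULE_PRIMER, RULE_LENGTH, RULE_AMBIGUOUS, RULE_QUALITY)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class QcConfig:
    """Cleaning thresholds; primers ``None`` disables the primer stage."""

    min_length_bp: int = 200
    forward_primer: str | None = None
    reverse_primer: str | None = None
    max_ambiguous: int = 0
    min_mean_phred: float = 25.0
    max_primer_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be positive")
        if self.forward_primer == "" or self.reverse_primer == "":
            raise ValueError("primers must be non-empty when provided")
        if self.max_primer_mismatches < 0:
            raise ValueError("max_primer_mismatches must be >= 0")


@dataclass
class QcReport:
    """Per-rule rejection counts; input = passed + sum(rejected)."""

    input_reads: int = 0
    passed: int = 0
    rejected_by_rule: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in RULES}
    )

    def validate(self) -> None:
        if self.input_reads != self.passed + sum(self.rejected_by_rule.values()):
            raise AssertionError("QcReport counts do not conserve input")


def _iupac_match(primer: str, window: str) -> int:
    """Number of mismatching positions, degeneracy-aware on the primer side."""
    mism = 0
    for p, b in zip(primer, window):
        if b not in IUPAC.get(p, frozenset()):
            mism += 1
    return mism


def primer_match(
    read: SequenceRead,
    primer: str,
    end: str = "five_prime",
    max_mismatches: int = 0,
) -> tuple[bool, SequenceRead]:
    """Match (and trim) ``primer`` against the read's terminal window.

    The primer is compared position-by-position against the first
    (``five_prime``) or last (``three_prime``) ``len(primer)`` bases;
    an IUPAC degeneracy code on the primer matches any base of its
    expansion. On a match the window is removed and the qualities are
    sliced consistently. A primer longer than the read never matches.
    """
    if end not in ("five_prime", "three_prime"):
        raise ValueError(f"end must be 'five_prime' or 'three_prime', got {end!r}")
    k = len(primer)
    if k == 0:
        raise ValueError("primer must be non-empty")
    if k > len(read):
        return False, read
    primer = primer.upper()
    if end == "five_prime":
        window = read.bases[:k]
    else:
        window = read.bases[-k:]
    if _iupac_match(primer, window) > max_mismatches:
        return False, read
    if end == "five_prime":
        trimmed = SequenceRead(id=read.id, bases=read.bases[k:], quals=read.quals[k:])
    else:
        trimmed = SequenceRead(id=read.id, bases=read.bases[:-k], quals=read.quals[:-k])
    return True, trimmed


def qc_filter(
    reads: Iterable[SequenceRead], cfg: QcConfig
) -> tuple[list[SequenceRead], QcReport]:
    """Apply the cleaning rules to a read stream.

    Returns the passing (primer-trimmed) reads and a :class:`QcReport`
    attributing every rejection to its first failing rule. The filter is
    a pure per-read predicate: read order never changes the outcome.
    """
    report = QcReport()
    passed: list[SequenceRead] = []
    rev_rc = (
        reverse_complement(cfg.reverse_primer) if cfg.reverse_primer else None
    )
    for read in reads:
        report.input_reads += 1
        r = read
        if cfg.forward_primer is not None:
            ok, r = primer_match(
                r, cfg.forward_primer, "five_prime", cfg.max_primer_mismatches
            )
            if not ok:
                report.rejected_by_rule[RULE_PRIMER] += 1
                continue
        if rev_rc is not None:
            ok, r = primer_match(r, rev_rc, "three_prime", cfg.max_primer_mismatches)
            if not ok:
                report.rejected_by_rule[RULE_PRIMER] += 1
                continue
        if len(r) < cfg.min_length_bp:
            report.rejected_by_rule[RULE_LENGTH] += 1
            continue
        if r.bases.count("N") > cfg.max_ambiguous:
            report.rejected_by_rule[RULE_AMBIGUOUS] += 1
            continue
        if r.mean_quality < cfg.min_mean_phred:
            report.rejected_by_rule[RULE_QUALITY] += 1
            continue
        report.passed += 1
        passed.append(r)
    report.validate()
    return passed, report
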