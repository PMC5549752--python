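"""Clean a batch of amplicon reads and inspect the per-rule report.

Builds a small synthetic read set around two centroid sequences with
primers attached, degrades some reads, and applies the cleaning rules
(primer match/trim, length, ambiguous bases, mean quality).
"""

from cloudotu import QcConfig, qc_filter
from cloudotu.qc import reverse_complement
from cloudotu.synth import generate_reads, random_centroids
from cloudotu.core import SequenceRead

FWD, REV = "GTGYCAGCMGCCGCGGTAA", "GGACTACNVGGGTWTCTAAT"  # 515F / 806R

centroids = random_centroids(2, 250, rng=1)
reads, _ = generate_reads(centroids, {c: 10 for c, _ in centroids}, divergence=0.01, qual=35, seed=1)

# attach primers, then damage a few reads
flanked = [
    SequenceRead(r.id, "GTGTCAGCAGCCGCGGTAA" + r.bases + reverse_complement("GGACTACAAGGGTTTCTAAT"),
                 tuple([35] * (len(r.bases) + 39)))
    for r in reads
]
flanked[0] = SequenceRead("short", flanked[0].bases[:150], flanked[0].quals[:150])
flanked[1] = SequenceRead("noisy", flanked[1].bases, tuple([15] * len(flanked[1].bases)))

cfg = QcConfig(min_length_bp=200, forward_primer=FWD, reverse_primer=REV, min_mean_phred=25)
passed, report = qc_filter(flanked, cfg)

print(f"input reads      : {report.input_reads}")
for rule, count in report.rejected_by_rule.items():
    print(f"rejected ({rule:9s}): {count}")
print(f"passed           : {report.passed}")
# The short read fails the primer rule (its 3' primer was truncated away);
# the low-quality read fails the mean-PHRED threshold; the rest pass with
# primers trimmed off.
print(f"example passed read length (primers removed): {len(passed[0])}")
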