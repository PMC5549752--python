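"""End-to-end orchestration with a run manifest.

The pipeline can enter at read level (FASTQ -> QC -> clustering -> table)
or, the primary path, directly at OTU-table level; it then applies the
conservative filter chain and computes diversity, activity and
between-sample comparison outputs into a directory, together with a
manifest recording the configuration snapshot, seeds, per-stage record
counts and package version. A re-run with the same configuration and
seed reproduces the outputs; input files are never mutated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .activity import activity_table, aggregate_to_rank, top_taxa_by_average_rank
from .clustering import cluster_counts, greedy_cluster
from .comparison import bray_curtis_matrix, venn_partition
from .core import OtuTable, SampleFraction
from .diversity import diversity_report, rarefaction_exact
from .filters import FilterConfig, normalize_proportions, run_filter_chain
from .io import read_fastq, read_otu_table, write_otu_table
from .qc import QcConfig, qc_filter
from .synth import SyntheticConfig, generate_community

__all__ = ["PipelineConfig", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_all`.

    Exactly one of ``otu_table``, ``fastq`` or ``synthetic`` provides the
    input; ``synthetic`` holds :class:`SyntheticConfig` keyword overrides.
    """

    out_dir: str = "cloudotu_out"
    otu_table: str | None = None
    taxonomy: str | None = None
    fastq: str | None = None
    synthetic: dict[str, Any] | None = None
    domain: str = "prokaryote"
    control_prefix: str = "CTRL"
    min_reads: int = 3
    controls: str = "auto"
    phantom_scope: str = "sample"
    activity_rank: str = "genus"
    top_n: int = 20
    cluster_threshold: float = 0.97
    qc: dict[str, Any] = field(default_factory=dict)
    rarefaction_points: int = 8
    seed: int = 0


def _load_table(cfg: PipelineConfig, manifest: dict) -> OtuTable:
    sources = [cfg.otu_table is not None, cfg.fastq is not None, cfg.synthetic is not None]
    if sum(sources) != 1:
        raise StageError("input", "exactly one of otu_table, fastq, synthetic required")
    if cfg.otu_table is not None:
        table = read_otu_table(
            cfg.otu_table,
            taxonomy_path=cfg.taxonomy,
            control_prefix=cfg.control_prefix,
            domain=cfg.domain,
        )
        manifest["stages"].append(
            {"stage": "load", "otus": table.n_otus, "reads": table.total_reads}
        )
        return table
    if cfg.synthetic is not None:
        synth_cfg = SyntheticConfig(**{"seed": cfg.seed, **cfg.synthetic})
        table, _truth = generate_community(synth_cfg)
        manifest["stages"].append(
            {"stage": "synth", "otus": table.n_otus, "reads": table.total_reads}
        )
        return table
    # FASTQ entry: QC then clustering; reads are assigned to sample-fractions
    # by the id prefix before the first '.', label convention <sample>_<frac>.
    reads = list(read_fastq(cfg.fastq))
    passed, report = qc_filter(reads, QcConfig(**cfg.qc))
    manifest["stages"].append(
        {
            "stage": "qc",
            "input_reads": report.input_reads,
            "passed": report.passed,
            "rejected": dict(report.rejected_by_rule),
        }
    )
    seqs = [(r.id, r.bases, 1) for r in passed]
    clusters = greedy_cluster(seqs, cfg.cluster_threshold)
    read_map = {}
    for r in passed:
        label = r.id.split(".", 1)[0]
        try:
            read_map[r.id] = SampleFraction.from_label(label, cfg.control_prefix)
        except ValueError as exc:
            raise StageError("cluster", str(exc))
    table = cluster_counts(clusters, read_map, domain=cfg.domain)
    manifest["stages"].append(
        {"stage": "cluster", "otus": table.n_otus, "reads": table.total_reads}
    )
    return table


def run_all(cfg: PipelineConfig) -> Path:
    """Run the full pipeline; returns the output directory path."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in asdict(cfg).items()},
        "stages": [],
    }

    table = _load_table(cfg, manifest)

    # filtering
    try:
        filtered, ledger = run_filter_chain(
            table,
            FilterConfig(
                min_reads=cfg.min_reads,
                controls=cfg.controls,
                phantom_scope=cfg.phantom_scope,
            ),
        )
    except (ValueError, AssertionError) as exc:
        raise StageError("filter", str(exc))
    write_otu_table(filtered, out / "filtered.tsv", out / "taxonomy.tsv")
    pd.DataFrame(ledger.to_rows()).to_csv(out / "ledger.tsv", sep="\t", index=False)
    manifest["stages"].append(
        {
            "stage": "filter",
            "otus": filtered.n_otus,
            "reads": filtered.total_reads,
            "removed": [
                {"stage": e.stage, "otus": e.otus_removed, "reads": e.reads_removed}
                for e in ledger.entries
            ],
        }
    )

    # diversity per column + rarefaction curves
    try:
        reports = []
        curves = []
        for col in filtered.columns:
            counts = filtered.get_column(col)
            rep = diversity_report(counts, label=col.label)
            reports.append(asdict(rep))
            total = int(counts.sum())
            depths = np.unique(
                np.linspace(1, total, cfg.rarefaction_points, dtype=int)
            )
            curve = rarefaction_exact(counts, depths.tolist())
            for d, s in zip(curve.depths, curve.expected_richness):
                curves.append({"label": col.label, "depth": d, "expected_richness": s})
        pd.DataFrame(reports).to_csv(out / "diversity.tsv", sep="\t", index=False)
        pd.DataFrame(curves).to_csv(out / "rarefaction.tsv", sep="\t", index=False)
    except ValueError as exc:
        raise StageError("diversity", str(exc))
    manifest["stages"].append({"stage": "diversity", "columns": filtered.n_columns})

    # activity
    try:
        records, rho = activity_table(filtered, cfg.activity_rank)
        agg = aggregate_to_rank(filtered, cfg.activity_rank)
        top = top_taxa_by_average_rank(agg, n=cfg.top_n)
        act = pd.DataFrame([asdict(r) for r in records])
        act.to_csv(out / "activity.tsv", sep="\t", index=False)
        (out / "top_taxa.txt").write_text("\n".join(top) + "\n")
    except ValueError as exc:
        raise StageError("activity", str(exc))
    manifest["stages"].append(
        {"stage": "activity", "records": len(records), "abundance_ratio_spearman": rho}
    )

    # comparison
    try:
        props = normalize_proportions(filtered)
        sim = bray_curtis_matrix(props)
        labels = filtered.column_labels()
        pd.DataFrame(sim, index=labels, columns=labels).to_csv(
            out / "braycurtis.tsv", sep="\t"
        )
        dna_samples = filtered.sample_ids(fraction="DNA")
        if len(dna_samples) >= 2:
            venn = venn_partition(filtered, "DNA")
            pd.DataFrame(
                [
                    {
                        "region": "&".join(sorted(p.region)) or "(absent)",
                        "otu_count": p.otu_count,
                        **{
                            f"read_fraction_{s}": f
                            for s, f in sorted(p.read_fraction_per_sample.items())
                        },
                    }
                    for p in venn
                ]
            ).to_csv(out / "venn.tsv", sep="\t", index=False)
    except ValueError as exc:
        raise StageError("compare", str(exc))
    manifest["stages"].append({"stage": "compare", "columns": filtered.n_columns})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
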