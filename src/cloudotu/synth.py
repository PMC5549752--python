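"""Synthetic paired DNA/RNA communities with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes in real cloud-water amplicon data:

* heavy-tailed, highly uneven OTU abundances (log-normal, sigma ~ 2
  gives Gini near 0.9) with a long rare tail;
* a DNA fraction sampled multinomially at a configured depth, and an RNA
  fraction whose expected proportions are the DNA proportions scaled by
  per-OTU activity multipliers — a designated *active* subset (multiplier
  drawn >= 1, typically >= 3), a designated *inactive* subset
  (multiplier <= 1), and a neutral remainder at 1;
* optional inflation of rare-OTU multipliers, reproducing the negative
  abundance-vs-ratio trend seen in environmental data;
* contaminant OTUs present in the procedural-blank control column (and
  moderately in samples), and phantom OTUs present in RNA only;
* full ground truth for recovery scoring.

Each column is a single multinomial draw at its configured depth, so
generated column sums equal the configured depths exactly; all
randomness flows from one seeded generator, making outputs byte-identical
for a given seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .core import OtuTable, SampleFraction, SequenceRead, TaxonomyLineage, rank_vocabulary
from .filters import normalize_proportions

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_community",
    "generate_reads",
    "random_centroids",
    "active_set_recovery",
    "DEFAULT_TAXONOMY_POOL",
]

#: Plausible cloud-microbiota lineages (phylum;class;order;family;genus)
#: used when no taxonomy pool is configured.
DEFAULT_TAXONOMY_POOL: tuple[str, ...] = (
    "Proteobacteria;Alphaproteobacteria;Sphingomonadales;Sphingomonadaceae;Sphingomonas",
    "Proteobacteria;Alphaproteobacteria;Rhizobiales;Methylobacteriaceae;Methylobacterium",
    "Proteobacteria;Alphaproteobacteria;Rhodospirillales;Acetobacteraceae;Acidiphilium",
    "Proteobacteria;Alphaproteobacteria;Rickettsiales;Rickettsiaceae;Rickettsia",
    "Proteobacteria;Gammaproteobacteria;Pseudomonadales;Pseudomonadaceae;Pseudomonas",
    "Proteobacteria;Gammaproteobacteria;Pseudomonadales;Moraxellaceae;Enhydrobacter",
    "Proteobacteria;Gammaproteobacteria;Pseudomonadales;Moraxellaceae;Psychrobacter",
    "Proteobacteria;Betaproteobacteria;Burkholderiales;Comamonadaceae;Comamonas",
    "Proteobacteria;Betaproteobacteria;Burkholderiales;Oxalobacteraceae;Janthinobacterium",
    "Bacteroidetes;Cytophagia;Cytophagales;Spirosomaceae;Spirosoma",
    "Bacteroidetes;Flavobacteriia;Flavobacteriales;Flavobacteriaceae;Capnocytophaga",
    "Actinobacteria;Actinobacteria;Corynebacteriales;Corynebacteriaceae;Corynebacterium",
    "Actinobacteria;Actinobacteria;Micrococcales;Microbacteriaceae;Curtobacterium",
    "Firmicutes;Bacilli;Lactobacillales;Carnobacteriaceae;Dolosigranulum",
    "Firmicutes;Bacilli;Bacillales;Staphylococcaceae;Staphylococcus",
    "Deinococcus-Thermus;Deinococci;Deinococcales;Deinococcaceae;Deinococcus",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator; defaults are the conditions the
    recovery experiments are stated at."""

    n_otus: int = 500
    n_samples: int = 3
    lognormal_sigma: float = 2.0
    depth_dna: int = 50_000
    depth_rna: int = 50_000
    active_fraction: float = 0.1
    inactive_fraction: float = 0.1
    active_multiplier_range: tuple[float, float] = (3.0, 10.0)
    inactive_multiplier_range: tuple[float, float] = (0.05, 1.0 / 3.0)
    rare_ratio_inflation: float = 0.0
    contaminant_count: int = 5
    contaminant_control_rate: float = 20.0
    contaminant_sample_rate: float = 25.0
    phantom_count: int = 10
    phantom_rate: float = 15.0
    taxonomy_pool: tuple[str, ...] = DEFAULT_TAXONOMY_POOL
    domain: str = "prokaryote"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 1:
            raise ValueError("n_otus must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.depth_dna <= 0 or self.depth_rna <= 0:
            raise ValueError("depth_dna and depth_rna must be positive")
        if not 0 <= self.active_fraction <= 1:
            raise ValueError("active_fraction must be in [0, 1]")
        if not 0 <= self.inactive_fraction <= 1:
            raise ValueError("inactive_fraction must be in [0, 1]")
        if self.active_fraction + self.inactive_fraction > 1:
            raise ValueError("active_fraction + inactive_fraction must be <= 1")
        if self.active_multiplier_range[0] < 1:
            raise ValueError("active_multiplier_range low bound must be >= 1")
        if self.inactive_multiplier_range[1] > 1:
            raise ValueError("inactive_multiplier_range high bound must be <= 1")
        if self.rare_ratio_inflation < 0:
            raise ValueError("rare_ratio_inflation must be >= 0")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")
        if self.contaminant_count < 0 or self.phantom_count < 0:
            raise ValueError("contaminant_count and phantom_count must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth returned alongside a generated table."""

    active_set: frozenset[str]
    inactive_set: frozenset[str]
    contaminant_set: frozenset[str]
    phantom_set: frozenset[str]
    multipliers: dict[str, float]
    true_abundances: dict[str, np.ndarray]  # sample_id -> community proportions
    community_otus: tuple[str, ...]


def generate_community(cfg: SyntheticConfig) -> tuple[OtuTable, SyntheticTruth]:
    """Generate a paired DNA/RNA OTU table with controls and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    ranks = rank_vocabulary(cfg.domain)

    width = max(4, len(str(cfg.n_otus)))
    community = [f"OTU_{i + 1:0{width}d}" for i in range(cfg.n_otus)]
    contaminants = [f"CONTAM_{i + 1:03d}" for i in range(cfg.contaminant_count)]
    phantoms = [f"PHANTOM_{i + 1:03d}" for i in range(cfg.phantom_count)]
    otu_ids = community + contaminants + phantoms

    n_active = round(cfg.active_fraction * cfg.n_otus)
    n_inactive = round(cfg.inactive_fraction * cfg.n_otus)
    designated = rng.choice(cfg.n_otus, size=n_active + n_inactive, replace=False)
    active_idx = np.sort(designated[:n_active])
    inactive_idx = np.sort(designated[n_active:])

    multipliers = np.ones(cfg.n_otus)
    multipliers[active_idx] = rng.uniform(*cfg.active_multiplier_range, size=n_active)
    multipliers[inactive_idx] = rng.uniform(
        *cfg.inactive_multiplier_range, size=n_inactive
    )

    samples = [f"cloud{i + 1}" for i in range(cfg.n_samples)]
    columns: list[SampleFraction] = []
    for s in samples:
        columns.append(SampleFraction(s, "DNA"))
        columns.append(SampleFraction(s, "RNA"))
    # a procedural blank is only emitted when contamination is simulated;
    # an all-zero control column is degenerate for normalization
    control: SampleFraction | None = None
    if cfg.contaminant_count > 0:
        control = SampleFraction("CTRL1", "DNA", is_control=True)
        columns.append(control)

    n_rows = len(otu_ids)
    counts = np.zeros((n_rows, len(columns)), dtype=np.int64)
    col_of = {c: i for i, c in enumerate(columns)}
    n_cont, n_phan = cfg.contaminant_count, cfg.phantom_count

    true_abund: dict[str, np.ndarray] = {}
    for s in samples:
        base = rng.lognormal(mean=0.0, sigma=cfg.lognormal_sigma, size=cfg.n_otus)
        base /= base.sum()
        true_abund[s] = base

        # DNA expectation: community + contaminants (phantoms absent by design)
        dna_exp = np.zeros(n_rows)
        dna_exp[: cfg.n_otus] = base
        if n_cont:
            dna_exp[cfg.n_otus : cfg.n_otus + n_cont] = (
                cfg.contaminant_sample_rate / cfg.depth_dna
            )
        dna_exp /= dna_exp.sum()
        counts[:, col_of[SampleFraction(s, "DNA")]] = rng.multinomial(
            cfg.depth_dna, dna_exp
        )

        # rare-OTU ratio inflation: multiplier scaled by 1 + infl / percentile,
        # where percentile is the OTU's ascending abundance percentile in this
        # sample (rarest -> smallest percentile -> largest inflation)
        mult = multipliers.copy()
        if cfg.rare_ratio_inflation > 0:
            order = np.argsort(np.argsort(base))  # ascending ranks 0..n-1
            percentile = (order + 1) / cfg.n_otus
            mult = mult * (1.0 + cfg.rare_ratio_inflation / percentile)

        rna_exp = np.zeros(n_rows)
        rna_exp[: cfg.n_otus] = base * mult
        if n_cont:
            rna_exp[cfg.n_otus : cfg.n_otus + n_cont] = (
                cfg.contaminant_sample_rate / cfg.depth_rna
            )
        if n_phan:
            rna_exp[cfg.n_otus + n_cont :] = cfg.phantom_rate / cfg.depth_rna
        rna_exp /= rna_exp.sum()
        counts[:, col_of[SampleFraction(s, "RNA")]] = rng.multinomial(
            cfg.depth_rna, rna_exp
        )

    # control column: contaminants only, detection guaranteed
    if n_cont and control is not None:
        ctrl = rng.poisson(cfg.contaminant_control_rate, size=n_cont)
        counts[cfg.n_otus : cfg.n_otus + n_cont, col_of[control]] = np.maximum(ctrl, 1)

    pool = cfg.taxonomy_pool or ("",)
    taxonomy = {
        oid: TaxonomyLineage.from_string(pool[i % len(pool)], ranks=ranks)
        for i, oid in enumerate(otu_ids)
    }

    table = OtuTable(
        otu_ids=otu_ids,
        counts=counts,
        columns=columns,
        taxonomy=taxonomy,
        domain=cfg.domain,
    )
    truth = SyntheticTruth(
        active_set=frozenset(community[i] for i in active_idx),
        inactive_set=frozenset(community[i] for i in inactive_idx),
        contaminant_set=frozenset(contaminants),
        phantom_set=frozenset(phantoms),
        multipliers={community[i]: float(multipliers[i]) for i in range(cfg.n_otus)},
        true_abundances=true_abund,
        community_otus=tuple(community),
    )
    return table, truth


def active_set_recovery(
    filtered: OtuTable, truth: SyntheticTruth
) -> tuple[float, float]:
    """Score the "mean RNA:DNA ratio >= 1" rule against ground truth.

    An OTU is called active when its RNA:DNA ratio of column-normalized
    proportions, averaged over the samples where it has DNA support, is
    >= 1; OTUs removed by filtering are called inactive. Precision and
    recall are scored over the designated candidate set (true active +
    true inactive OTUs); contaminants, phantoms and the neutral remainder
    are excluded by construction. Returns (recall, precision).
    """
    props = normalize_proportions(filtered)
    row = {o: i for i, o in enumerate(filtered.otu_ids)}
    samples = filtered.sample_ids(fraction="RNA")
    predicted_active: set[str] = set()
    for otu in truth.active_set | truth.inactive_set:
        if otu not in row:
            continue
        ratios = []
        for s in samples:
            dcol = filtered.find(s, "DNA")
            rcol = filtered.find(s, "RNA")
            if dcol is None or rcol is None:
                continue
            d = props[row[otu], filtered.column_index(dcol)]
            r = props[row[otu], filtered.column_index(rcol)]
            if d > 0:
                ratios.append(r / d)
        if ratios and float(np.mean(ratios)) >= 1.0:
            predicted_active.add(otu)
    tp = len(predicted_active & truth.active_set)
    fn = len(truth.active_set - predicted_active)
    fp = len(predicted_active & truth.inactive_set)
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    return recall, precision


# -- read-level generation ---------------------------------------------------

_BASES = np.array(list("ACGT"))


def random_centroids(
    n: int, length: int, rng: int | np.random.Generator = 0
) -> list[tuple[str, str]]:
    """Random, mutually well-separated centroid sequences."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return [
        (f"SEED_{i + 1:03d}", "".join(rng.choice(_BASES, size=length)))
        for i in range(n)
    ]


def generate_reads(
    centroids: Sequence[tuple[str, str]],
    per_otu_counts: Mapping[str, int],
    divergence: float = 0.0,
    qual: int = 35,
    seed: int | np.random.Generator = 0,
    threshold: float | None = None,
) -> tuple[list[SequenceRead], dict[str, str]]:
    """Emit point-mutated reads per centroid, plus the read->OTU truth map.

    Each read is a copy of its centroid with substitutions at the given
    per-base divergence rate and constant quality. When ``threshold`` is
    given and two reads of one centroid could diverge past the clustering
    margin (2 x divergence >= 1 - threshold), a warning is raised since
    truth clusters may then split or merge.
    """
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    if threshold is not None and 2 * divergence >= (1 - threshold):
        warnings.warn(
            f"divergence {divergence} is not safely below the clustering "
            f"margin (1 - {threshold})/2; truth clusters may merge or split",
            stacklevel=2,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reads: list[SequenceRead] = []
    truth: dict[str, str] = {}
    for cid, seq in centroids:
        total = int(per_otu_counts.get(cid, 0))
        arr = np.array(list(seq))
        for i in range(total):
            bases = arr.copy()
            if divergence > 0:
                hit = rng.random(len(bases)) < divergence
                for j in np.flatnonzero(hit):
                    choices = [b for b in "ACGT" if b != bases[j]]
                    bases[j] = choices[rng.integers(3)]
            rid = f"{cid}_r{i + 1}"
            reads.append(
                SequenceRead(
                    id=rid, bases="".join(bases), quals=tuple([qual] * len(bases))
                )
            )
            truth[rid] = cid
    return reads, truth
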