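"""RNA:DNA ratios, banding, aggregation and top-taxon selection."""

import numpy as np
import pytest

from cloudotu.activity import (
    BANDS,
    activity_table,
    aggregate_to_rank,
    classify_band,
    is_active,
    rna_dna_ratio,
    top_taxa_by_average_rank,
)
from cloudotu.filters import run_filter_chain, FilterConfig
from cloudotu.synth import SyntheticConfig, generate_community
from conftest import make_table


LINEAGES = {
    "OTU1": "Proteobacteria;Alphaproteobacteria;Sphingomonadales;Sphingomonadaceae;Sphingomonas",
    "OTU2": "Proteobacteria;Alphaproteobacteria;Sphingomonadales;Sphingomonadaceae;Sphingomonas",
    "OTU3": "Proteobacteria;Gammaproteobacteria;Pseudomonadales;Pseudomonadaceae;Pseudomonas",
    "OTU4": "Proteobacteria;Gammaproteobacteria",  # unassigned at genus
}


class TestAggregate:
    def table(self):
        return make_table(
            [[3, 1], [4, 2], [5, 3], [6, 4]],
            ["s1_DNA", "s1_RNA"],
            taxonomy=LINEAGES,
        )

    def test_same_genus_summed(self):
        agg = aggregate_to_rank(self.table(), "genus")
        assert agg.loc["Sphingomonas", ("s1", "DNA")] == 7

    def test_unassigned_pooled(self):
        agg = aggregate_to_rank(self.table(), "genus")
        assert agg.loc["unclassified", ("s1", "DNA")] == 6

    def test_totals_conserved(self):
        t = self.table()
        agg = aggregate_to_rank(t, "genus")
        assert agg.sum(axis=0).tolist() == t.counts.sum(axis=0).tolist()

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            aggregate_to_rank(self.table(), "kingdom")  # not a prokaryote rank


class TestRatioAndBands:
    def test_equal_abundance_ratio_one(self):
        assert rna_dna_ratio(0.5, 0.5) == 1.0

    def test_direct_division(self):
        assert rna_dna_ratio(0.5, 0.8) == pytest.approx(1.6)
        assert rna_dna_ratio(0.5, 0.2) == pytest.approx(0.4)

    def test_zero_rna_gives_zero(self):
        assert rna_dna_ratio(0.3, 0.0) == 0.0

    def test_phantom_leak_rejected(self):
        with pytest.raises(ValueError, match="phantom"):
            rna_dna_ratio(0.0, 0.1)

    @pytest.mark.parametrize(
        "ratio,band",
        [
            (0.0, "zero"),
            (0.05, "lt_0.1"),
            (0.1, "0.1_to_1"),
            (0.5, "0.1_to_1"),
            (1.0, "1_to_10"),
            (9.99, "1_to_10"),
            (10.0, "gt_10"),
            (11_760.0, "gt_10"),
        ],
    )
    def test_band_assignment(self, ratio, band):
        assert classify_band(ratio) == band

    def test_bands_partition(self):
        rng = np.random.default_rng(1)
        for r in np.concatenate([[0.0], rng.lognormal(0, 3, size=200)]):
            assert classify_band(float(r)) in BANDS

    def test_boundary_one_is_active(self):
        assert is_active(1.0) and not is_active(0.999)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_band(-0.1)


class TestTopTaxa:
    def agg(self, counts, taxa, labels):
        t = make_table(counts, labels, taxonomy=taxa)
        return aggregate_to_rank(t, "genus")

    def test_rank_one_everywhere_selected_first(self):
        taxa = {
            "OTU1": "P;C;O;F;Big",
            "OTU2": "P;C;O;F;Small",
            "OTU3": "P;C;O;F;Mid",
        }
        agg = self.agg(
            [[90, 0, 80, 0], [1, 0, 2, 0], [9, 0, 18, 0]],
            taxa,
            ["s1_DNA", "s1_RNA", "s2_DNA", "s2_RNA"],
        )
        top = top_taxa_by_average_rank(agg, n=2)
        assert top == ["Big", "Mid"]

    def test_tie_broken_by_total_abundance(self):
        taxa = {"OTU1": "P;C;O;F;A", "OTU2": "P;C;O;F;B"}
        # ranks: A = (1, 2), B = (2, 1) -> tie at 1.5; B larger total
        agg = self.agg(
            [[60, 0, 10, 0], [40, 0, 90, 0]],
            taxa,
            ["s1_DNA", "s1_RNA", "s2_DNA", "s2_RNA"],
        )
        assert top_taxa_by_average_rank(agg, n=1) == ["B"]

    def test_absent_taxon_gets_worst_rank(self):
        taxa = {"OTU1": "P;C;O;F;A", "OTU2": "P;C;O;F;B"}
        agg = self.agg(
            [[10, 0, 0, 0], [5, 0, 50, 0]],
            taxa,
            ["s1_DNA", "s1_RNA", "s2_DNA", "s2_RNA"],
        )
        # A: ranks (1, 3); B: ranks (2, 1) -> B wins
        assert top_taxa_by_average_rank(agg, n=1) == ["B"]

    def test_n_larger_than_taxa_returns_all(self):
        taxa = {"OTU1": "P;C;O;F;A"}
        agg = self.agg([[10, 0]], taxa, ["s1_DNA", "s1_RNA"])
        assert top_taxa_by_average_rank(agg, n=20) == ["A"]

    def test_invalid_n(self):
        taxa = {"OTU1": "P;C;O;F;A"}
        agg = self.agg([[10, 0]], taxa, ["s1_DNA", "s1_RNA"])
        with pytest.raises(ValueError):
            top_taxa_by_average_rank(agg, n=0)


class TestActivityTable:
    def test_absent_from_rna_is_zero_band(self):
        t = make_table(
            [[10, 5], [10, 0]],
            ["s1_DNA", "s1_RNA"],
            taxonomy={"OTU1": "P;C;O;F;A", "OTU2": "P;C;O;F;B"},
        )
        records, _ = activity_table(t, "genus")
        by_taxon = {r.taxon: r for r in records}
        assert by_taxon["B"].ratio == 0.0 and by_taxon["B"].band == "zero"

    def test_unfiltered_phantom_rejected(self):
        t = make_table(
            [[10, 5], [0, 3]],
            ["s1_DNA", "s1_RNA"],
            taxonomy={"OTU1": "P;C;O;F;A", "OTU2": "P;C;O;F;B"},
        )
        with pytest.raises(ValueError, match="filter"):
            activity_table(t, "genus")

    def test_true_active_taxon_lands_in_active_band(self):
        # RNA proportions exactly 5x DNA proportions for taxon A
        t = make_table(
            [[100, 500], [900, 500]],
            ["s1_DNA", "s1_RNA"],
            taxonomy={"OTU1": "P;C;O;F;A", "OTU2": "P;C;O;F;B"},
        )
        records, _ = activity_table(t, "genus")
        by_taxon = {r.taxon: r for r in records}
        assert by_taxon["A"].ratio == pytest.approx(5.0)
        assert by_taxon["A"].band == "1_to_10"

    def test_ratios_invariant_to_rna_depth_rescaling(self):
        t1 = make_table(
            [[10, 6], [30, 18], [60, 12]], ["s1_DNA", "s1_RNA"],
            taxonomy={"OTU1": "P;C;O;F;A", "OTU2": "P;C;O;F;B", "OTU3": "P;C;O;F;C"},
        )
        t2 = t1.with_counts(t1.counts * np.array([1, 10]))
        r1, _ = activity_table(t1, "genus")
        r2, _ = activity_table(t2, "genus")
        for a, b in zip(r1, r2):
            assert a.ratio == pytest.approx(b.ratio)

    def test_rare_otus_show_inflated_ratios(self):
        """With rare-ratio inflation the abundance-vs-ratio Spearman
        correlation is negative, the trend seen in uneven communities."""
        pool = tuple(f"P;C;O;F;G{i:03d}" for i in range(300))  # one genus per OTU
        cfg = SyntheticConfig(
            n_otus=300,
            depth_dna=30_000,
            depth_rna=30_000,
            active_fraction=0.0,
            inactive_fraction=0.0,
            rare_ratio_inflation=0.5,
            contaminant_count=0,
            phantom_count=0,
            taxonomy_pool=pool,
            seed=13,
        )
        table, _ = generate_community(cfg)
        filtered, _ = run_filter_chain(table, FilterConfig(controls="none"))
        _, rho = activity_table(filtered, "genus")
        assert rho < 0
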