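"""Conservative filter chain: artefacts, contaminants, phantoms, proportions."""

import numpy as np
import pytest

from cloudotu.filters import (
    FilterConfig,
    decontaminate,
    min_count_filter,
    normalize_proportions,
    phantom_filter,
    run_filter_chain,
)
from cloudotu.synth import SyntheticConfig, generate_community
from conftest import make_table


class TestMinCount:
    def test_two_read_otu_removed(self):
        t = make_table([[1, 1], [3, 0]], ["s1_DNA", "s1_RNA"])
        out, entry = min_count_filter(t, 3)
        assert out.otu_ids == ["OTU2"]
        assert entry.otus_removed == 1 and entry.reads_removed == 2

    def test_boundary_retained(self):
        t = make_table([[3, 0]], ["s1_DNA", "s1_RNA"])
        out, _ = min_count_filter(t, 3)
        assert out.n_otus == 1

    def test_min_one_is_identity_without_empty_rows(self):
        t = make_table([[1, 0], [0, 2]], ["s1_DNA", "s1_RNA"])
        out, entry = min_count_filter(t, 1)
        assert out == t and entry.otus_removed == 0

    def test_invalid_threshold(self):
        t = make_table([[3]], ["s1_DNA"])
        with pytest.raises(ValueError):
            min_count_filter(t, 0)


class TestDecontaminate:
    def test_presence_not_abundance(self):
        t = make_table(
            [[500, 1], [200, 0]], ["s1_DNA", "CTRL1_DNA"], otu_ids=["bad", "good"]
        )
        out, entry = decontaminate(t)
        assert out.otu_ids == ["good"]
        assert entry.otu_ids == ("bad",)
        assert out.column_labels() == ["s1_DNA"]  # control column dropped

    def test_untouched_when_absent_from_controls(self):
        t = make_table([[10, 0], [20, 0]], ["s1_DNA", "CTRL1_DNA"])
        out, entry = decontaminate(t)
        assert out.n_otus == 2 and entry.otus_removed == 0

    def test_all_zero_control_is_identity_on_rows(self):
        t = make_table([[10, 0]], ["s1_DNA", "CTRL1_DNA"])
        out, _ = decontaminate(t)
        assert out.counts.tolist() == [[10]]

    def test_missing_controls_is_an_error(self):
        t = make_table([[10]], ["s1_DNA"])
        with pytest.raises(ValueError, match="control"):
            decontaminate(t)


class TestPhantomFilter:
    def test_rna_without_dna_zeroed_per_sample(self):
        # OTU B: phantom in s1 (DNA 0, RNA 7) but DNA-backed in s2
        t = make_table(
            [[5, 3, 2, 1], [0, 7, 4, 2]],
            ["s1_DNA", "s1_RNA", "s2_DNA", "s2_RNA"],
            otu_ids=["A", "B"],
        )
        out, entry = phantom_filter(t)
        assert out.counts.tolist() == [[5, 3, 2, 1], [0, 0, 4, 2]]
        assert entry.reads_removed == 7 and entry.otus_removed == 0

    def test_fully_phantom_otu_removed(self):
        t = make_table(
            [[5, 3], [0, 7]], ["s1_DNA", "s1_RNA"], otu_ids=["A", "B"]
        )
        out, entry = phantom_filter(t)
        assert out.otu_ids == ["A"] and entry.otu_ids == ("B",)

    def test_dna_only_untouched(self):
        t = make_table([[5, 0]], ["s1_DNA", "s1_RNA"])
        out, entry = phantom_filter(t)
        assert out.counts.tolist() == [[5, 0]] and entry.reads_removed == 0

    def test_global_scope_removes_everywhere(self):
        t = make_table(
            [[5, 3, 2, 1], [0, 7, 4, 2]],
            ["s1_DNA", "s1_RNA", "s2_DNA", "s2_RNA"],
            otu_ids=["A", "B"],
        )
        out, _ = phantom_filter(t, scope="global")
        assert out.otu_ids == ["A"]

    def test_rna_without_matching_dna_column_rejected(self):
        t = make_table([[5]], ["s1_RNA"])
        with pytest.raises(ValueError, match="no DNA fraction"):
            phantom_filter(t)

    def test_postcondition_no_phantoms_left(self):
        table, _ = generate_community(
            SyntheticConfig(n_otus=80, depth_dna=2000, depth_rna=2000, seed=5)
        )
        out, _ = phantom_filter(table)
        for s in out.sample_ids(fraction="RNA"):
            rna = out.get_column(out.find(s, "RNA"))
            dna = out.get_column(out.find(s, "DNA"))
            assert not np.any((rna > 0) & (dna == 0))


class TestNormalize:
    def test_columns_sum_to_one(self):
        t = make_table([[1, 5], [3, 0]], ["s1_DNA", "s1_RNA"])
        p = normalize_proportions(t)
        assert p[:, 0].tolist() == [0.25, 0.75]
        assert np.allclose(p.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_column_rejected(self):
        t = make_table([[1, 0]], ["s1_DNA", "s1_RNA"])
        with pytest.raises(ValueError, match="zero-total"):
            normalize_proportions(t)


class TestFilterChain:
    def test_constructed_fixture_one_of_each(self, paired_table):
        out, ledger = run_filter_chain(paired_table)
        by_stage = {e.stage: e for e in ledger.entries[:3]}
        assert by_stage["min_count"].otu_ids == ("artefact",)
        assert by_stage["decontaminate"].otu_ids == ("contam",)
        assert by_stage["phantom"].otu_ids == ("phantom",)
        assert set(out.otu_ids) == {"clean1", "clean2"}

    def test_clean_table_is_identity(self):
        t = make_table(
            [[50, 40, 0], [10, 5, 0]],
            ["s1_DNA", "s1_RNA", "CTRL1_DNA"],
        )
        out, ledger = run_filter_chain(t)
        assert ledger.total_otus_removed == 0
        assert out.counts.tolist() == [[50, 40], [10, 5]]

    def test_read_conservation(self, paired_table):
        out, ledger = run_filter_chain(paired_table)
        assert paired_table.total_reads == out.total_reads + ledger.total_reads_removed

    def test_stage_sets_disjoint(self, paired_table):
        _, ledger = run_filter_chain(paired_table)
        ledger.validate_disjoint()

    @pytest.mark.parametrize("seed", [0, 11])
    def test_idempotent_on_synthetic_tables(self, seed):
        table, _ = generate_community(
            SyntheticConfig(n_otus=120, depth_dna=4000, depth_rna=4000, seed=seed)
        )
        once, _ = run_filter_chain(table)
        twice, ledger2 = run_filter_chain(once, FilterConfig(controls="none"))
        assert twice == once
        assert ledger2.total_reads_removed == 0

    def test_monotone_read_totals(self, paired_table):
        out, ledger = run_filter_chain(paired_table)
        running = paired_table.total_reads
        for e in ledger.entries:
            assert e.reads_removed >= 0
            running -= e.reads_removed
        assert running == out.total_reads

    def test_missing_dna_fraction_aborts(self):
        t = make_table(
            [[5, 4, 3]], ["s1_DNA", "s1_RNA", "s2_RNA"]
        )
        with pytest.raises(ValueError, match="s2"):
            run_filter_chain(t, FilterConfig(controls="none"))
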