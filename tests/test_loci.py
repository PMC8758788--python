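"""Positional classes, knockdown dependence, DE filters, concordance."""

import pytest

from ladscape.damid import LadSet
from ladscape.intervals import GenomicInterval, LocusAnnotation
from ladscape.loci import (
    ExpressionRecord,
    apply_de_filters,
    assign_positional_class,
    concordance_table,
    kd_dependence,
    mirna_target_concordance,
    venn_positional_sets,
)
from ladscape.repositioning import DifferentialRegion

iv = GenomicInterval


def dr(s, e, direction):
    return DifferentialRegion(iv("chr1", s, e), direction)


def gene(lid, s, e):
    return LocusAnnotation(lid, iv("chr1", s, e), "gene")


class TestAssignPositionalClass:
    DRS = [dr(10_000, 30_000, "PI"), dr(50_000, 70_000, "IP")]

    def test_core_classes(self):
        calls = assign_positional_class(
            [gene("a", 12_000, 14_000), gene("b", 55_000, 60_000), gene("c", 90_000, 92_000)],
            self.DRS,
            proximity_window=0,
        )
        assert [c.positional_class for c in calls] == ["released", "recruited", "unchanged"]

    def test_proximal_within_window(self):
        # 2 kb from the IP DR with a 5 kb window
        calls = assign_positional_class([gene("a", 72_000, 74_000)], self.DRS, 5_000)
        assert calls[0].positional_class == "proximal_recruited"
        calls = assign_positional_class([gene("a", 72_000, 74_000)], self.DRS, 1_000)
        assert calls[0].positional_class == "unchanged"

    def test_tie_broken_by_larger_overlap(self):
        drs = [dr(0, 10_000, "PI"), dr(10_000, 30_000, "IP")]
        calls = assign_positional_class([gene("a", 8_000, 20_000)], drs, 0)
        assert calls[0].positional_class == "recruited" and calls[0].ambiguous

    def test_duplicate_ids_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            assign_positional_class([gene("a", 0, 10), gene("a", 20, 30)], self.DRS, 0)

    def test_classes_partition_loci(self, bundle, results):
        calls = results["gene_calls"]
        n_genes = sum(1 for l in bundle.loci if l.locus_kind == "gene")
        assert len(calls) == n_genes
        counts = {}
        for c in calls:
            counts[c.positional_class] = counts.get(c.positional_class, 0) + 1
        assert sum(counts.values()) == n_genes


class TestKdDependence:
    def test_released_inside_kd_lad_fails(self):
        calls = assign_positional_class([gene("a", 12_000, 14_000)],
                                        [dr(10_000, 30_000, "PI")], 0)
        kd = {"akd": LadSet("akd", [iv("chr1", 10_000, 30_000)])}
        calls = kd_dependence(calls, kd)
        assert calls[0].kd_flags == {"fails_to_release_akd": True}

    def test_released_outside_all_kd_lads_unflagged(self):
        calls = assign_positional_class([gene("a", 12_000, 14_000)],
                                        [dr(10_000, 30_000, "PI")], 0)
        calls = kd_dependence(calls, {"akd": LadSet("akd", [])})
        assert calls[0].kd_flags == {}

    def test_recruited_missing_from_kd_lads_fails(self):
        calls = assign_positional_class([gene("a", 55_000, 60_000)],
                                        [dr(50_000, 70_000, "IP")], 0)
        calls = kd_dependence(calls, {"akd": LadSet("akd", [iv("chr1", 0, 10_000)])})
        assert calls[0].kd_flags == {"fails_to_recruit_akd": True}

    def test_monotone_in_lad_superset(self):
        calls = assign_positional_class([gene("a", 12_000, 14_000)],
                                        [dr(10_000, 30_000, "PI")], 0)
        small = LadSet("k", [iv("chr1", 13_000, 20_000)])
        big = LadSet("k", [iv("chr1", 10_000, 40_000), iv("chr1", 50_000, 60_000)])
        flag_small = kd_dependence(list(calls), {"k": small})[0].kd_flags
        flag_big = kd_dependence(list(calls), {"k": big})[0].kd_flags
        assert flag_small.items() <= flag_big.items()

    def test_planted_fraction_exact_noise_free(self, bundle_nf, results_nf):
        assert results_nf["kd_dependent_released_fraction"] == pytest.approx(
            bundle_nf.truth["kd_dependent_released_fraction"]
        )


class TestDeFilters:
    def rec(self, fc, p, inten=8.0):
        return ExpressionRecord("x", fc, p, inten)

    def test_fold_change_boundary(self):
        assert apply_de_filters([self.rec(0.4, 0.01)]) == []
        kept = apply_de_filters([self.rec(0.5, 0.01)])
        assert len(kept) == 1 and kept[0].direction == "up"

    def test_intensity_filter(self):
        assert apply_de_filters([self.rec(2.0, 0.01, 6.0)]) == []
        assert len(apply_de_filters([self.rec(2.0, 0.01, 6.5)])) == 1
        # intensity absent: filter not applied
        assert len(apply_de_filters([ExpressionRecord("x", 2.0, 0.01)])) == 1

    def test_fdr_filter_and_direction(self):
        assert apply_de_filters([self.rec(-2.0, 0.05)]) == []
        kept = apply_de_filters([self.rec(-2.0, 0.049)])
        assert kept[0].direction == "down"

    def test_invalid_adj_p(self):
        with pytest.raises(ValueError, match="adj_p"):
            ExpressionRecord("x", 1.0, 1.5)


class TestConcordance:
    def test_ten_released_one_up(self):
        calls = assign_positional_class(
            [gene(f"g{i}", 10_500 + 600 * i, 11_000 + 600 * i) for i in range(10)],
            [dr(10_000, 30_000, "PI")],
            0,
        )
        records = [ExpressionRecord("g0", 2.0, 0.001, 8.0, direction="up")]
        out = concordance_table(calls, records)
        assert out["table"].loc["released", "up"] == 1
        assert out["fraction_changed"] == pytest.approx(0.10)
        assert out["n_missing_records"] == 9

    def test_empty_records_all_ns(self):
        calls = assign_positional_class([gene("a", 12_000, 14_000)],
                                        [dr(10_000, 30_000, "PI")], 0)
        out = concordance_table(calls, [])
        assert out["table"].to_numpy().sum() == out["table"].loc["released", "ns"] == 1

    def test_swapping_directions_transposes_columns(self):
        calls = assign_positional_class(
            [gene("a", 12_000, 14_000), gene("b", 55_000, 60_000)],
            [dr(10_000, 30_000, "PI"), dr(50_000, 70_000, "IP")],
            0,
        )
        rec = [ExpressionRecord("a", 2.0, 0.001, direction="up"),
               ExpressionRecord("b", -2.0, 0.001, direction="down")]
        flipped = [ExpressionRecord("a", -2.0, 0.001, direction="down"),
                   ExpressionRecord("b", 2.0, 0.001, direction="up")]
        t1 = concordance_table(calls, rec)["table"]
        t2 = concordance_table(calls, flipped)["table"]
        assert (t1["up"] == t2["down"]).all() and (t1["down"] == t2["up"]).all()

    def test_cells_sum_to_repositioned_calls(self, results):
        out = results["concordance"]
        assert out["table"].to_numpy().sum() == out["n_repositioned"]
        assert out["n_repositioned"] == results["n_genes_released"] + results["n_genes_recruited"]


class TestVennSets:
    def test_no_drs_all_empty(self):
        out = venn_positional_sets([gene("a", 0, 1_000)], [], {"akd": LadSet("akd", [])})
        assert out["normally_released"] == out["normally_recruited"] == 0

    def test_kd_identical_to_wt_no_failures(self):
        drs = [dr(50_000, 70_000, "IP")]
        kd = {"akd": LadSet("akd", [iv("chr1", 50_000, 70_000)])}
        out = venn_positional_sets([gene("a", 55_000, 56_000)], drs, kd)
        assert out["normally_recruited"] == 1 and out["fails_recruit_akd"] == 0

    def test_planted_enhancer_counts(self, bundle_nf, results_nf):
        venn = results_nf["enhancer_venn"]
        assert venn["normally_recruited"] == bundle_nf.truth["enhancers_recruited"]
        assert venn["fails_recruit_akd"] == bundle_nf.truth["enhancers_recruited_kd_dependent"]


class TestMirnaTargetConcordance:
    def test_two_thirds(self):
        rec = [ExpressionRecord("t1", -2, 0.001, direction="down"),
               ExpressionRecord("t2", -2, 0.001, direction="down"),
               ExpressionRecord("t3", 0.0, 0.9, direction="ns")]
        out = mirna_target_concordance([("m1", "up")], {"m1": ["t1", "t2", "t3"]}, rec)
        assert out["per_mirna"]["m1"]["concordant_fraction"] == pytest.approx(2 / 3)

    def test_empty_target_map_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = mirna_target_concordance([("m1", "up")], {}, [])
        assert out["per_mirna"] == {}

    def test_mirna_without_targets_excluded(self):
        out = mirna_target_concordance([("m1", "up"), ("m2", "down")],
                                       {"m1": ["t1"]},
                                       [ExpressionRecord("t1", -2, 0.001, direction="down")])
        assert out["no_target_mirnas"] == ["m2"]
        assert out["pooled_concordance"] == 1.0

    def test_planted_concordance_recovered(self, bundle, results):
        out = results["mirna_target_concordance"]
        assert out["pooled_concordance"] == pytest.approx(
            bundle.truth["mirna_target_concordance"], abs=1e-9
        )
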