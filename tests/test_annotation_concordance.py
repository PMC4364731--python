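"""Cutoff flags, Venn partition, prioritization, and lead-vs-proxy tests."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisprior.annotation_concordance import (
    CutoffFlags,
    apply_cutoffs,
    compare_lead_vs_ld,
    prioritize_concordant,
    venn_partition,
)
from cisprior.core_io import (
    AnnotationRecord,
    GeneMap,
    LDPair,
    PipelineConfig,
    ValidationError,
    VariantRecord,
    parse_reg_category,
)
from cisprior.ld_expansion import expand_loci, variant_universe


def _annot(rsid, cadd=None, gwava=None, regdb=None):
    cat = parse_reg_category(regdb) if regdb else None
    return AnnotationRecord(rsid, cadd, gwava, cat)


class TestApplyCutoffs:
    def test_triple_pass(self):
        (f,) = apply_cutoffs([_annot("rs6684375", 13.02, 0.44, "2b")])
        assert (f.pass_cadd, f.pass_gwava, f.pass_regdb) == (True, True, True)

    def test_boundary_values_inclusive(self):
        (f,) = apply_cutoffs([_annot("rs1", 10.0, 0.4, "2c")])
        assert (f.pass_cadd, f.pass_gwava, f.pass_regdb) == (True, True, True)

    def test_missing_scores_fail_only_their_own_cutoff(self):
        (f,) = apply_cutoffs([_annot("rs601338", 32.0)])
        assert (f.pass_cadd, f.pass_gwava, f.pass_regdb) == (True, False, False)

    def test_no_data_category_fails(self):
        (f,) = apply_cutoffs([_annot("rs1", 5.0, 0.9, "7")])
        assert f.pass_gwava and not f.pass_regdb

    def test_universe_retains_unannotated_variants(self):
        flags = apply_cutoffs([_annot("rs1", 15.0, 0.5, "1f")], universe=["rs1", "rs2"])
        assert [f.rsid for f in flags] == ["rs1", "rs2"]
        assert flags[1].region == "none"

    @settings(derandomize=True, max_examples=40)
    @given(
        cadd=st.floats(0, 40), gwava=st.floats(0, 1),
        delta=st.floats(0.1, 10), eps=st.floats(0.01, 0.5),
    )
    def test_tightening_cutoffs_never_grows_pass_sets(self, cadd, gwava, delta, eps):
        annot = [_annot("rs1", cadd, gwava, "2b")]
        loose = apply_cutoffs(annot, PipelineConfig())[0]
        tight = apply_cutoffs(
            annot,
            PipelineConfig(cadd_cut=10 + delta, gwava_cut=min(1.0, 0.4 + eps), regdb_cut_major=1),
        )[0]
        assert (not tight.pass_cadd) or loose.pass_cadd
        assert (not tight.pass_gwava) or loose.pass_gwava
        assert (not tight.pass_regdb) or loose.pass_regdb


class TestVennPartition:
    def test_single_triple_concordant(self):
        vp = venn_partition([CutoffFlags("rs1", True, True, True)])
        assert vp.counts["CGR"] == 1 and vp.counts["union"] == 1

    def test_all_false_goes_to_none(self):
        vp = venn_partition([CutoffFlags("rs1", False, False, False)])
        assert vp.counts["none"] == 1 and vp.counts["union"] == 0

    def test_duplicate_rsid_rejected(self):
        flags = [CutoffFlags("rs1", True, False, False)] * 2
        with pytest.raises(ValidationError):
            venn_partition(flags)

    def test_regions_partition_union(self, small_cohort):
        flags = apply_cutoffs(small_cohort.annotations)
        vp = venn_partition(flags)
        region_sum = sum(vp.counts[r] for r in ("C", "G", "R", "CG", "CR", "GR", "CGR"))
        assert region_sum == vp.counts["union"]
        assert vp.counts["union"] + vp.counts["none"] == len(flags)

    def test_pairwise_inclusive_contains_exclusive(self, small_cohort):
        vp = venn_partition(apply_cutoffs(small_cohort.annotations))
        assert vp.regions["CG"] <= vp.pairwise_inclusive["CG"]
        assert vp.regions["CGR"] <= vp.pairwise_inclusive["CG"]


class TestPrioritizeConcordant:
    def _loci(self):
        leads = [VariantRecord("rsL", "1", 50, role="lead")]
        pairs = [LDPair("rsL", "rsP", 0.9), LDPair("rsL", "rsQ", 0.85)]
        return expand_loci(leads, pairs)

    def test_matches_brute_force_triple_intersection(self, small_cohort):
        loci = expand_loci(small_cohort.leads, small_cohort.ld_pairs)
        universe, _ = variant_universe(loci)
        flags = apply_cutoffs(small_cohort.annotations, universe=[v.rsid for v in universe])
        table = prioritize_concordant(flags, loci, small_cohort.gene_map, small_cohort.annotations)
        expected = (
            {f.rsid for f in flags if f.pass_cadd}
            & {f.rsid for f in flags if f.pass_gwava}
            & {f.rsid for f in flags if f.pass_regdb}
        )
        assert set(table["rsid"]) == expected

    def test_row_order_invariance(self, small_cohort):
        loci = expand_loci(small_cohort.leads, small_cohort.ld_pairs)
        universe, _ = variant_universe(loci)
        rsids = [v.rsid for v in universe]
        fwd = prioritize_concordant(
            apply_cutoffs(small_cohort.annotations, universe=rsids), loci,
            small_cohort.gene_map, small_cohort.annotations,
        )
        rev = prioritize_concordant(
            apply_cutoffs(small_cohort.annotations[::-1], universe=rsids[::-1]), loci,
            small_cohort.gene_map, small_cohort.annotations,
        )
        assert fwd.equals(rev)

    def test_empty_concordant_set(self):
        flags = [CutoffFlags("rsP", True, True, False)]
        assert prioritize_concordant(flags, self._loci()).empty

    def test_orphan_prioritized_variant_rejected(self):
        flags = [CutoffFlags("rsX", True, True, True)]
        with pytest.raises(ValidationError, match="rsX"):
            prioritize_concordant(flags, self._loci())


class TestCompareLeadVsLd:
    def test_separated_groups_exact_p(self):
        annot = [_annot(f"rs{i}", cadd=v) for i, v in enumerate([4, 5, 6, 1, 2, 3])]
        roles = {"rs0": "lead", "rs1": "lead", "rs2": "lead",
                 "rs3": "proxy", "rs4": "proxy", "rs5": "proxy"}
        res, med_lead, med_proxy = compare_lead_vs_ld(annot, roles)
        assert res.p_two_sided == pytest.approx(0.1)
        assert med_lead == 5 and med_proxy == 2

    def test_identical_distributions_near_one(self):
        annot = [_annot(f"rs{i}", cadd=float(i % 10)) for i in range(40)]
        roles = {f"rs{i}": ("lead" if i < 20 else "proxy") for i in range(40)}
        res, *_ = compare_lead_vs_ld(annot, roles)
        assert res.p_two_sided > 0.5

    def test_empty_group_rejected(self):
        annot = [_annot("rs1", cadd=5.0)]
        with pytest.raises(ValidationError):
            compare_lead_vs_ld(annot, {"rs1": "lead"})
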