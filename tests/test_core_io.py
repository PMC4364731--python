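"""Domain types, the regulatory-category parser, and table round-trips."""

import pytest

from cisprior.core_io import (
    REG_CATEGORY_ORDER,
    AnnotationRecord,
    LDPair,
    PipelineConfig,
    RegCategoryParseError,
    SelectionRecord,
    ValidationError,
    VariantRecord,
    parse_reg_category,
    read_annotations,
    read_gene_map,
    read_gene_sets,
    read_ld_pairs,
    read_leads,
    read_selection,
    write_prioritized,
)


class TestRegCategory:
    @pytest.mark.parametrize("token", REG_CATEGORY_ORDER)
    def test_parse_format_roundtrip(self, token):
        assert parse_reg_category(token).token == token

    def test_rank_is_strict_total_order(self):
        ranks = [parse_reg_category(t).rank for t in REG_CATEGORY_ORDER]
        assert ranks == sorted(ranks) and len(set(ranks)) == len(ranks)

    def test_rank_consistent_with_major_minor_lexicographic(self):
        cats = [parse_reg_category(t) for t in REG_CATEGORY_ORDER]
        keys = [(c.major, c.minor or "") for c in cats]
        assert keys == sorted(keys)

    @pytest.mark.parametrize("token", ["7", "ND", "."])
    def test_no_data_aliases(self, token):
        cat = parse_reg_category(token)
        assert cat.is_no_data and cat.rank is None

    def test_strong_evidence_token(self):
        cat = parse_reg_category("1f")
        assert cat.major == 1 and cat.minor == "f" and cat.major <= 2

    @pytest.mark.parametrize("token", ["8x", "1z", "4a", "0", "", "2d"])
    def test_malformed_token_raises(self, token):
        with pytest.raises(RegCategoryParseError):
            parse_reg_category(token, row=3)


class TestRecordInvariants:
    def test_variant_requires_valid_position_and_class(self):
        with pytest.raises(ValidationError):
            VariantRecord("rs1", "1", 0)
        with pytest.raises(ValidationError):
            VariantRecord("rs1", "1", 5, var_class="inversion")

    def test_ld_pair_bounds_and_self_pair(self):
        with pytest.raises(ValidationError):
            LDPair("a", "b", 1.2)
        with pytest.raises(ValidationError):
            LDPair("a", "a", 1.0)

    def test_gwava_range_enforced(self):
        with pytest.raises(ValidationError):
            AnnotationRecord("rs1", gwava_like=1.2)

    def test_selection_rs_cannot_exceed_neutral_rate(self):
        with pytest.raises(ValidationError):
            SelectionRecord("rs1", rs_score=4.0, nr_score=3.0)

    def test_config_rejects_out_of_range_threshold(self):
        with pytest.raises(ValidationError):
            PipelineConfig(r2_min=1.01)


class TestReaders:
    def test_duplicate_rsid_collapses_risk_maximal(self, tmp_path):
        p = tmp_path / "annot.tsv"
        p.write_text(
            "rsid\tcadd\tgwava\tregdb\n"
            "rs1\t24.5\tNA\t5\n"
            "rs1\t11.0\t0.3\t2b\n"
        )
        (rec,) = read_annotations(p)
        assert rec.cadd_like == 24.5
        assert rec.gwava_like == 0.3
        assert rec.regdb_cat.token == "2b"

    def test_missing_encodings_equivalent(self, tmp_path):
        p = tmp_path / "annot.tsv"
        p.write_text(
            "rsid\tcadd\tgwava\tregdb\nrs1\t5.0\tNA\tND\nrs2\t5.0\t.\t.\nrs3\t5.0\t\t7\n"
        )
        recs = {r.rsid: r for r in read_annotations(p)}
        assert all(recs[r].gwava_like is None for r in recs)
        # '.' and empty read as absent; 'ND'/'7' as the explicit no-data class
        assert all(
            recs[r].regdb_cat is None or recs[r].regdb_cat.is_no_data for r in recs
        )

    def test_empty_ld_file_is_valid(self, tmp_path):
        p = tmp_path / "ld.tsv"
        p.write_text("lead_rsid\tproxy_rsid\tr2\n")
        assert read_ld_pairs(p) == []

    def test_self_ld_rows_dropped(self, tmp_path):
        p = tmp_path / "ld.tsv"
        p.write_text("lead_rsid\tproxy_rsid\tr2\nrsA\trsA\t1\nrsA\trsB\t0.9\n")
        pairs = read_ld_pairs(p)
        assert [(q.lead_rsid, q.proxy_rsid) for q in pairs] == [("rsA", "rsB")]

    def test_gene_map_dash_rows_parse_empty(self, tmp_path):
        p = tmp_path / "genemap.tsv"
        p.write_text("rsid\tgenes\nrs1\t-\nrs2\tFEN1, FADS1\n")
        gm = read_gene_map(p)
        assert gm.genes_for("rs1") == ()
        assert gm.genes_for("rs2") == ("FEN1", "FADS1")

    def test_gmt_reader(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("IBD\tdesc\tNOD2\tIL23R\nRA\tdesc\tPTPN22\n")
        gs = read_gene_sets(p, background_size=30000)
        assert gs.sets["IBD"] == {"NOD2", "IL23R"}
        assert gs.background_size == 30000


class TestRoundTrips:
    def test_tables_read_write_lossless(self, tmp_path, small_cohort):
        """Writing a generated bundle and re-reading preserves every record."""
        out = small_cohort.write(tmp_path / "bundle")
        assert read_leads(out / "leads.tsv") == small_cohort.leads
        assert read_ld_pairs(out / "ld.tsv") == small_cohort.ld_pairs
        assert sorted(read_annotations(out / "annot.tsv"), key=lambda a: a.rsid) == sorted(
            small_cohort.annotations, key=lambda a: a.rsid
        )
        assert read_selection(out / "selection.tsv") == small_cohort.selection
        assert read_gene_map(out / "genemap.tsv").mapping == small_cohort.gene_map.mapping

    def test_write_prioritized_tsv_and_bed(self, tmp_path):
        rows = [
            {
                "rsid": "rs6684375", "chrom": "1", "pos": 22706434,
                "lead_rsid": "rs12568930", "r2": 1.0,
                "cadd": 13.02, "gwava": 0.44, "regdb": "2b", "genes": (),
            }
        ]
        tsv = write_prioritized(rows, tmp_path / "p.tsv")
        lines = tsv.read_text().splitlines()
        assert len(lines) == 2 and lines[1].split("\t")[0] == "rs6684375"
        bed = write_prioritized(rows, tmp_path / "p.bed", format="bed")
        assert bed.read_text() == "1\t22706433\t22706434\trs6684375\n"

    def test_write_prioritized_empty_is_header_only(self, tmp_path):
        out = write_prioritized([], tmp_path / "p.tsv")
        assert out.read_text().count("\n") == 1

    def test_write_prioritized_vcf(self, tmp_path):
        rows = [{"rsid": "rs1", "chrom": "2", "pos": 100, "lead_rsid": "rs9"}]
        out = write_prioritized(rows, tmp_path / "p.vcf", format="vcf")
        body = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert body == ["2\t100\trs1\tN\tN\t.\tPASS\tLEAD=rs9"]
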