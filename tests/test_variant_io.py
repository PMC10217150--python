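"""VCF/PED ingestion, multiallelic splitting, HGVS parsing, report I/O."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trioforge.model import MISSING, Variant, normalize_chrom
from trioforge.variant_io import (
    HgvsError,
    PedigreeError,
    VcfParseError,
    format_hgvs_g,
    parse_hgvs_g,
    read_pedigree,
    read_vcf,
    write_pedigree,
    write_report,
    write_vcf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=AF_POP,Number=A,Type=Float,Description="af">\n'
    '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
    "##contig=<ID=11>\n##contig=<ID=2>\n##contig=<ID=chr4>\n"
)


def _write(tmp_path, body, samples=("S1",)):
    text = VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n" + body
    p = tmp_path / "t.vcf"
    p.write_text(text)
    return p


class TestReadVcf:
    def test_header_only_yields_empty_cohort(self, tmp_path):
        table = read_vcf(_write(tmp_path, ""))
        assert table.n_variants == 0
        assert table.samples == ["S1"]

    def test_substitution_record_matches_hgvs_key(self, tmp_path):
        table = read_vcf(_write(tmp_path, "11\t1238987\t.\tC\tT\t.\tPASS\t.\tGT:DP\t0/1:30\n"))
        v = table.variants[0]
        assert (v.chrom, v.pos, v.ref, v.alt) == parse_hgvs_g("NC_000011.10:g.1238987C > T")

    def test_chr_prefix_normalized(self, tmp_path):
        table = read_vcf(_write(tmp_path, "chr4\t100\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\n"))
        assert table.variants[0].chrom == "4"

    @pytest.mark.parametrize("gt_str", ["0/0", "0/1", "0/2", "1/1", "1/2", "2/2", "./."])
    def test_multiallelic_split_recoding(self, tmp_path, gt_str):
        # hand oracle: per-alt code is the count of that allele number in
        # the genotype; missing stays missing for every alt
        alleles = gt_str.replace("|", "/").split("/")
        if "." in alleles:
            expect = {1: MISSING, 2: MISSING}
        else:
            nums = [int(a) for a in alleles]
            expect = {a: sum(1 for x in nums if x == a) for a in (1, 2)}
        table = read_vcf(_write(tmp_path, f"2\t500\t.\tA\tC,G\t.\tPASS\t.\tGT\t{gt_str}\n"))
        assert table.n_variants == 2
        assert [v.alt for v in table.variants] == ["C", "G"]
        assert int(table.gt[0, 0]) == expect[1]
        assert int(table.gt[1, 0]) == expect[2]

    def test_multiallelic_split_conserves_dosage(self, tmp_path):
        # brute force over all diploid genotypes of a triallelic record
        combos = ["/".join(map(str, c)) for c in itertools.combinations_with_replacement("012", 2)]
        body = "".join(
            f"2\t{500 + i}\t.\tA\tC,G\t.\tPASS\t.\tGT\t{g}\n" for i, g in enumerate(combos)
        )
        table = read_vcf(_write(tmp_path, body))
        for i, g in enumerate(combos):
            nums = [int(x) for x in g.split("/")]
            total_alt = sum(1 for x in nums if x > 0)
            rows = [j for j, v in enumerate(table.variants) if v.pos == 500 + i]
            assert sum(int(table.gt[r, 0]) for r in rows) == total_alt

    def test_per_alt_info_split(self, tmp_path):
        table = read_vcf(_write(
            tmp_path, "2\t500\t.\tA\tC,G\t.\tPASS\tAF_POP=0.1,0.002;GENE=TAF1B\tGT\t0/1\n"))
        assert table.profiles[0].af_pop == pytest.approx(0.1)
        assert table.profiles[1].af_pop == pytest.approx(0.002)
        assert all(v.gene == "TAF1B" for v in table.variants)

    def test_absent_annotations_map_to_absent(self, tmp_path):
        table = read_vcf(_write(tmp_path, "2\t500\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\n"))
        p = table.profiles[0]
        assert p.af_pop is None and p.sift is None and p.consequence == "other"

    def test_unknown_contig_rejected(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text(VCF_HEADER + "##contig=<ID=weird>\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
                     "weird\t5\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(VcfParseError, match="record 1"):
            read_vcf(p)


class TestRoundTrip:
    def test_vcf_round_trip_identity(self, small_cohort, tmp_path):
        cohort, _, _ = small_cohort
        path = write_vcf(cohort, tmp_path / "c.vcf")
        back = read_vcf(path)
        back.families = cohort.families
        back._check_families()
        # align row order (writer sorts by position)
        idx = [back.variant_index(v.key) for v in cohort.variants]
        assert [back.variants[i] for i in idx] == cohort.variants
        assert np.array_equal(back.gt[idx], cohort.gt)
        assert np.array_equal(back.depth[idx], cohort.depth)
        for i, j in enumerate(idx):
            a, b = cohort.profiles[i], back.profiles[j]
            assert a.consequence == b.consequence and a.sift == b.sift
            # VCF INFO floats travel at single precision
            assert a.af_pop == pytest.approx(b.af_pop, rel=1e-6)

    def test_pedigree_round_trip(self, small_cohort, tmp_path):
        cohort, _, _ = small_cohort
        path = write_pedigree(cohort.families, tmp_path / "c.ped")
        fams = read_pedigree(path)
        assert fams == cohort.families


class TestHgvs:
    @pytest.mark.parametrize("text,key", [
        ("NC_000002.12:g.9904885C > T", ("2", 9904885, "C", "T")),
        ("NC_000004.12:g.189957414T > A", ("4", 189957414, "T", "A")),
        ("NC_000011.10:g.1238987C>T", ("11", 1238987, "C", "T")),
        ("NC_000023.11:g.500A > G", ("X", 500, "A", "G")),
    ])
    def test_substitutions_parse(self, text, key):
        assert parse_hgvs_g(text) == key

    @pytest.mark.parametrize("text", [
        "NC_000011.10:g.1238987del",
        "NC_000011.10:g.123_124insA",
        "not hgvs at all",
    ])
    def test_non_substitutions_rejected(self, text):
        with pytest.raises(HgvsError):
            parse_hgvs_g(text)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        chrom=st.sampled_from([str(i) for i in range(1, 23)] + ["X", "Y"]),
        pos=st.integers(min_value=1, max_value=3_000_000_000),
        ref=st.sampled_from("ACGT"),
        alt=st.sampled_from("ACGT"),
    )
    def test_parse_is_left_inverse_of_format(self, chrom, pos, ref, alt):
        if ref == alt:
            return
        v = Variant(chrom=chrom, pos=pos, ref=ref, alt=alt)
        assert parse_hgvs_g(format_hgvs_g(v)) == v.key


class TestPedigree:
    def test_three_line_trio(self, tmp_path):
        p = tmp_path / "t.ped"
        p.write_text("F1\tC\tFA\tMO\t1\t2\nF1\tFA\t0\t0\t1\t1\nF1\tMO\t0\t0\t2\t1\n")
        fams = read_pedigree(p)
        assert len(fams) == 1
        fam = fams[0]
        assert (fam.proband, fam.father, fam.mother, fam.siblings) == ("C", "FA", "MO", ())

    def test_quad_with_unaffected_sibling(self, tmp_path):
        p = tmp_path / "q.ped"
        p.write_text(
            "F1\tC\tFA\tMO\t1\t2\nF1\tS\tFA\tMO\t2\t1\nF1\tFA\t0\t0\t1\t1\nF1\tMO\t0\t0\t2\t1\n")
        fam = read_pedigree(p)[0]
        assert fam.siblings == ("S",)
        assert fam.sexes["S"] == "female"

    def test_missing_parent_id_is_error(self, tmp_path):
        p = tmp_path / "bad.ped"
        p.write_text("F1\tC\t0\tMO\t1\t2\nF1\tMO\t0\t0\t2\t1\n")
        with pytest.raises(PedigreeError, match="trio incomplete"):
            read_pedigree(p)

    def test_unknown_father_id_is_error(self, tmp_path):
        p = tmp_path / "bad.ped"
        p.write_text("F1\tC\tNOBODY\tMO\t1\t2\nF1\tMO\t0\t0\t2\t1\n")
        with pytest.raises(PedigreeError, match="father"):
            read_pedigree(p)

    def test_two_affected_children_unsupported(self, tmp_path):
        p = tmp_path / "bad.ped"
        p.write_text(
            "F1\tC1\tFA\tMO\t1\t2\nF1\tC2\tFA\tMO\t1\t2\nF1\tFA\t0\t0\t1\t1\nF1\tMO\t0\t0\t2\t1\n")
        with pytest.raises(PedigreeError, match="multiple affected"):
            read_pedigree(p)


class TestReportWriting:
    def test_tsv_round_trip_preserves_values(self, tmp_path):
        df = pd.DataFrame({"gene": ["FRG1", "TAF1B"], "af": [1.9e-5, 3.156e-4]})
        path = write_report(df, tmp_path / "r.tsv", "tsv")
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == ["gene", "af"]
        assert back["af"].tolist() == pytest.approx(df["af"].tolist())

    def test_json_records(self, tmp_path):
        import json
        df = pd.DataFrame({"a": [1], "b": ["x"]})
        path = write_report(df, tmp_path / "r.json", "json")
        assert json.loads(path.read_text()) == [{"a": 1, "b": "x"}]

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_report(pd.DataFrame({"a": [1]}), tmp_path / "r.xml", "xml")


def test_normalize_chrom_dialects():
    assert normalize_chrom("chr11") == "11"
    assert normalize_chrom("X") == "X"
    with pytest.raises(ValueError):
        normalize_chrom("contig_7")
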