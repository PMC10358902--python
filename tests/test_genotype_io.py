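"""Panel parsing, orientation normalization, and QC filtering."""

import pytest
from hypothesis import given, settings, strategies as st

from tgscore.genotype_io import (
    MISSING,
    AlleleCall,
    GenotypeParseError,
    filter_inconsistent,
    normalize_orientation,
    read_genotypes,
    remove_monomorphic,
    write_genotype_matrix,
)
from tests.conftest import make_panel, snp

META3 = {
    "rs1": snp("rs1", "C", "T"),
    "rs2": snp("rs2", "A", "G"),
    "rs3": snp("rs3", "G", "T"),
}


def write_matrix(tmp_path, text, name="geno.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestMatrixParsing:
    def test_toy_matrix_loads_all_calls(self, tmp_path):
        path = write_matrix(tmp_path, "rsid\tP1\tP2\nrs1\tCT\tCC\nrs2\tAG\tGG\nrs3\tGT\tTT\n")
        panel = read_genotypes(path, META3)
        assert len(panel.calls) == 6
        assert panel.participants == ["P1", "P2"]
        assert panel.genotype("P1", "rs1") == "CT"
        assert panel.genotype("P2", "rs2") == "GG"

    def test_comma_dialect_sniffed(self, tmp_path):
        path = write_matrix(tmp_path, "rsid,P1,P2\nrs1,CT,CC\n", name="geno.csv")
        panel = read_genotypes(path, META3)
        assert panel.genotype("P2", "rs1") == "CC"

    def test_missing_preserved_not_imputed(self, tmp_path):
        path = write_matrix(tmp_path, "rsid\tP1\tP2\nrs1\t--\tCC\n")
        panel = read_genotypes(path, META3)
        assert panel.genotype("P1", "rs1") == MISSING

    def test_malformed_genotype_names_the_cell(self, tmp_path):
        path = write_matrix(tmp_path, "rsid\tP1\tP2\nrs1\tCT\tCX\n")
        with pytest.raises(GenotypeParseError, match=r"rs1.*P2|P2.*rs1"):
            read_genotypes(path, META3)

    def test_unknown_rsid_is_hard_error(self, tmp_path):
        path = write_matrix(tmp_path, "rsid\tP1\nrs99\tCT\n")
        with pytest.raises(GenotypeParseError, match="rs99"):
            read_genotypes(path, META3)

    def test_vcf_matches_matrix_panel(self, tmp_path):
        """Cross-format oracle: the same calls via VCF GT fields give an identical panel."""
        matrix = write_matrix(tmp_path, "rsid\tP1\tP2\nrs1\tCT\tCC\nrs2\tAG\tGG\n")
        vcf = tmp_path / "geno.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\n"
            "1\t100\trs1\tC\tT\t.\t.\t.\tGT\t0/1\t0/0\n"
            "1\t200\trs2\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\n"
        )
        pm = read_genotypes(matrix, META3)
        pv = read_genotypes(vcf, META3, format="vcf")
        assert pm.to_frame().equals(pv.to_frame())

    def test_multiallelic_vcf_rejected(self, tmp_path):
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\n"
            "1\t100\trs1\tC\tT,G\t.\t.\t.\tGT\t0/1\n"
        )
        with pytest.raises(GenotypeParseError, match="biallelic"):
            read_genotypes(vcf, META3, format="vcf")

    def test_matrix_round_trip_bit_identical(self, tmp_path):
        path = write_matrix(tmp_path, "rsid\tP1\tP2\nrs1\tCT\t--\nrs2\tAG\tGG\nrs3\tGG\tTT\n")
        panel = read_genotypes(path, META3)
        out1 = tmp_path / "o1.tsv"
        out2 = tmp_path / "o2.tsv"
        write_genotype_matrix(panel, out1)
        write_genotype_matrix(read_genotypes(out1, META3), out2)
        assert out1.read_bytes() == out2.read_bytes()


class TestOrientation:
    def test_reverse_probe_complemented(self):
        meta = snp("rs1", "T", "C")
        call = AlleleCall("P1", "rs1", MISSING, probe_calls=(("GA", "R"),))
        assert normalize_orientation(call, meta).genotype == "CT"

    def test_forward_probe_unchanged(self):
        meta = snp("rs1", "C", "T")
        call = AlleleCall("P1", "rs1", MISSING, probe_calls=(("CT", "F"),))
        assert normalize_orientation(call, meta).genotype == "CT"

    @settings(derandomize=True)
    @given(
        geno=st.sampled_from(["CC", "CT", "TT"]),
        orients=st.lists(st.sampled_from(["F", "R"]), min_size=1, max_size=6),
    )
    def test_idempotent(self, geno, orients):
        meta = snp("rs1", "C", "T")
        comp = {"C": "G", "T": "A"}
        probes = tuple(
            (geno if o == "F" else "".join(sorted(comp[a] for a in geno)), o) for o in orients
        )
        call = AlleleCall("P1", "rs1", MISSING, probe_calls=probes)
        once = normalize_orientation(call, meta)
        twice = normalize_orientation(once, meta)
        assert once.genotype == twice.genotype == geno
        assert not once.inconsistent

    def test_complementing_all_probes_gives_same_forward_panel(self):
        """Swapping every reading's strand yields the same forward-forward call."""
        meta = snp("rs1", "A", "G")
        probes = (("AG", "F"), ("AG", "F"), ("CT", "R"))
        flipped = (("CT", "R"), ("CT", "R"), ("AG", "F"))
        c1 = normalize_orientation(AlleleCall("P1", "rs1", MISSING, probe_calls=probes), meta)
        c2 = normalize_orientation(AlleleCall("P1", "rs1", MISSING, probe_calls=flipped), meta)
        assert c1.genotype == c2.genotype == "AG"

    def test_palindromic_with_reverse_probes_warns(self):
        meta = snp("rs1", "A", "T")
        call = AlleleCall("P1", "rs1", MISSING, probe_calls=(("AT", "F"), ("AT", "R")))
        with pytest.warns(UserWarning, match="palindromic"):
            out = normalize_orientation(call, meta)
        assert out.genotype == "AT"


class TestConsistencyFilter:
    def _panel_with_probes(self, probes_by_pid):
        from tgscore.genotype_io import GenotypePanel

        meta = {"rs1": snp("rs1", "C", "T"), "rs2": snp("rs2", "A", "G")}
        calls = {}
        pids = list(probes_by_pid)
        for pid, probes in probes_by_pid.items():
            calls[(pid, "rs1")] = AlleleCall(pid, "rs1", MISSING, probe_calls=probes)
            calls[(pid, "rs2")] = AlleleCall(pid, "rs2", "AG")
        return GenotypePanel(calls=calls, meta=meta, participants=pids)

    def test_agreeing_probes_retained(self):
        panel = self._panel_with_probes({"P1": (("CT", "F"), ("CT", "F"), ("CT", "F"))})
        filtered, audit = filter_inconsistent(panel)
        assert filtered.genotype("P1", "rs1") == "CT"
        assert not audit.inconsistent_calls

    def test_disagreeing_probes_set_missing(self):
        panel = self._panel_with_probes({"P1": (("CT", "F"), ("CC", "F"), ("CT", "F"))})
        filtered, audit = filter_inconsistent(panel, missingness_ceiling=0.9)
        assert filtered.genotype("P1", "rs1") == MISSING
        assert ("P1", "rs1") in audit.inconsistent_calls

    def test_participant_above_ceiling_dropped_and_audited(self):
        panel = self._panel_with_probes({
            "P1": (("CT", "F"), ("CC", "F")),  # 1 of 2 SNPs missing = 50%
            "P2": (("CT", "F"), ("CT", "F")),
        })
        filtered, audit = filter_inconsistent(panel, missingness_ceiling=0.20)
        assert filtered.participants == ["P2"]
        assert "P1" in audit.dropped_participants
        assert "missingness" in audit.dropped_participants["P1"]


class TestMonomorphicRemoval:
    def _toy(self):
        meta = {f"rs{i}": snp(f"rs{i}", "C", "T") for i in range(1, 5)}
        genos = {
            "rs1": {"P1": "CC", "P2": "CC", "P3": "CC"},
            "rs2": {"P1": "CT", "P2": "CC", "P3": "TT"},
            "rs3": {"P1": "TT", "P2": "CT", "P3": "TT"},
            "rs4": {"P1": "CC", "P2": "CT", "P3": "CC"},
        }
        return make_panel(genos, meta)

    def test_all_homozygous_snp_removed(self):
        filtered, removed = remove_monomorphic(self._toy())
        assert removed == 1
        assert "rs1" not in filtered.meta
        assert filtered.n_snps == 3

    def test_monomorphic_among_nonmissing_still_removed(self):
        meta = {"rs1": snp("rs1", "C", "T")}
        panel = make_panel({"rs1": {"P1": "CC", "P2": MISSING, "P3": "CC"}}, meta)
        filtered, removed = remove_monomorphic(panel)
        assert removed == 1 and filtered.n_snps == 0

    def test_idempotent(self):
        once, n1 = remove_monomorphic(self._toy())
        twice, n2 = remove_monomorphic(once)
        assert n2 == 0
        assert once.to_frame().equals(twice.to_frame())

    def test_simulated_monomorphic_fraction(self, small_cohort):
        filtered, removed = remove_monomorphic(small_cohort.panel)
        assert removed == 30  # 25% of 120
        assert filtered.n_snps == 90
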