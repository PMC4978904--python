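import io

import pytest

import oracles
from conftest import random_dna
from pamscape.pam_scanner import (
    PAM_CLASSES,
    PamSpec,
    SiteTable,
    parse_bed_sites,
    scan_genome,
    scan_record,
    write_bed,
)
from pamscape.sequence_core import SeqRecord, reverse_complement


def as_tuples(sites):
    return sorted(
        (
            s.record_id,
            s.strand,
            s.protospacer_start,
            s.protospacer_end,
            s.pam_start,
            s.pam_end,
            s.protospacer_seq,
            s.pam_seq,
        )
        for s in sites
    )


NGG2 = PamSpec.from_name("NGG", spacer_length=2)


class TestScanRecord:
    def test_single_forward_site(self):
        [site] = scan_record(SeqRecord("t", "ATACGG"), NGG2)
        assert site.strand == "+"
        assert (site.pam_start, site.pam_end) == (3, 6)
        assert (site.protospacer_start, site.protospacer_end) == (1, 3)
        assert (site.protospacer_seq, site.pam_seq) == ("TA", "CGG")

    def test_single_reverse_site_mapped_to_forward_coords(self):
        # reverse complement of the forward example
        [site] = scan_record(SeqRecord("t", "CCGTAT"), NGG2)
        assert site.strand == "-"
        assert (site.pam_start, site.pam_end) == (0, 3)
        assert (site.protospacer_start, site.protospacer_end) == (3, 5)
        assert (site.protospacer_seq, site.pam_seq) == ("TA", "CGG")

    def test_empty_record(self):
        assert scan_record(SeqRecord("t", ""), NGG2) == []

    def test_no_spacer_room_site_dropped(self):
        # PAM at the very start: no room for a 2 bp protospacer
        assert scan_record(SeqRecord("t", "AGGT"), NGG2) == []

    def test_ambiguous_base_suppresses_site(self):
        # N in the protospacer kills the site even though the PAM matches
        assert scan_record(SeqRecord("t", "ANACGG"), NGG2) == []
        # N inside the PAM window kills the PAM match too
        assert scan_record(SeqRecord("t", "ATACNG"), NGG2) == []

    @pytest.mark.parametrize("pam_class", PAM_CLASSES)
    def test_oracle_equivalence_random_sequences(self, rng, pam_class):
        spec = PamSpec.from_name(pam_class, spacer_length=20)
        for _ in range(20):
            length = rng.randint(30, 800)
            seq = random_dna(rng, length, alphabet="ACGTACGTN")
            got = as_tuples(scan_record(SeqRecord("r", seq), spec))
            want = oracles.brute_force_scan("r", seq, pam_class, 20)
            assert got == want

    def test_strand_symmetry(self, rng):
        spec = PamSpec.from_name("NNGRRT", spacer_length=5)
        for _ in range(20):
            seq = random_dna(rng, rng.randint(40, 400))
            fwd = scan_record(SeqRecord("r", seq), spec)
            rev = scan_record(SeqRecord("r", reverse_complement(seq)), spec)
            assert len(fwd) == len(rev)
            plus = sum(1 for s in fwd if s.strand == "+")
            minus = sum(1 for s in fwd if s.strand == "-")
            assert sum(1 for s in rev if s.strand == "+") == minus
            assert sum(1 for s in rev if s.strand == "-") == plus


class TestScanGenome:
    def test_counts_match_oracle_on_repeated_motif(self):
        seq = "AGGT" * 250
        tables = scan_genome([SeqRecord("t", seq)], [PamSpec.from_name("NGG")])
        want = oracles.brute_force_scan("t", seq, "NGG", 20)
        assert len(tables["NGG"].sites) == len(want)
        assert tables["NGG"].scanned_bp == 1000

    def test_empty_genome(self):
        tables = scan_genome([], [PamSpec.from_name("NGG")])
        assert tables["NGG"].sites == []
        assert tables["NGG"].scanned_bp == 0

    def test_duplicate_class_names_rejected(self):
        with pytest.raises(ValueError):
            scan_genome([], [PamSpec.from_name("NGG"), PamSpec.from_name("NGG")])

    def test_subset_laws(self, rng):
        records = [SeqRecord("g", random_dna(rng, 3000))]
        specs = [PamSpec.from_name(c, 10) for c in PAM_CLASSES]
        tables = scan_genome(records, specs)
        keys = {
            c: {(s.record_id, s.strand, s.start, s.end) for s in tables[c].sites}
            for c in PAM_CLASSES
        }
        assert keys["NNGRRT"] <= keys["NNGRRN"] <= keys["NNNRRN"]
        assert keys["NNGRRT"] <= keys["NNNRRT"] <= keys["NNNRRN"]

    def test_scanned_bp_equal_across_classes(self, rng):
        records = [SeqRecord(f"g{i}", random_dna(rng, 500)) for i in range(3)]
        tables = scan_genome(records, [PamSpec.from_name(c) for c in PAM_CLASSES])
        assert {t.scanned_bp for t in tables.values()} == {1500}


class TestBedOutput:
    def test_forward_site_line(self):
        table = SiteTable(scan_record(SeqRecord("t", "ATACGG"), NGG2), scanned_bp=6)
        out = io.StringIO()
        write_bed(table, out)
        assert out.getvalue() == "t\t1\t6\tNGG|TA|CGG\t0\t+\n"

    def test_reverse_site_line(self):
        table = SiteTable(scan_record(SeqRecord("t", "CCGTAT"), NGG2), scanned_bp=6)
        out = io.StringIO()
        write_bed(table, out)
        assert out.getvalue() == "t\t0\t5\tNGG|TA|CGG\t0\t-\n"

    def test_pam_only_span(self):
        table = SiteTable(scan_record(SeqRecord("t", "ATACGG"), NGG2), scanned_bp=6)
        out = io.StringIO()
        write_bed(table, out, span="pam")
        assert out.getvalue() == "t\t3\t6\tNGG|TA|CGG\t0\t+\n"

    def test_empty_table_empty_file(self):
        out = io.StringIO()
        write_bed(SiteTable([], 0), out)
        assert out.getvalue() == ""

    def test_round_trip(self, rng):
        seq = random_dna(rng, 2000)
        spec = PamSpec.from_name("NNGRRT", 20)
        table = SiteTable(scan_record(SeqRecord("chr1", seq), spec), len(seq))
        out = io.StringIO()
        write_bed(table, out)
        rows = parse_bed_sites(io.StringIO(out.getvalue()))
        assert len(rows) == len(table.sites)
        for row, site in zip(rows, table.sites):
            assert row == (
                "chr1",
                site.start,
                site.end,
                f"{site.pam_class}|{site.protospacer_seq}|{site.pam_seq}",
                0,
                site.strand,
            )
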