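"""Degenerate-primer scanning, product enumeration and composition."""

import numpy as np
import pytest

from zwmarker.gene_structure import GeneModel
from zwmarker.insilico_pcr import (
    AmpliconHit,
    BindingSite,
    amplicons_to_bed,
    annotate_composition,
    enumerate_amplicons,
    iupac_match,
    scan_primer,
)
from zwmarker.sequence_io import IUPAC_SETS, SeqRecord, revcomp


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestIupacMatch:
    @pytest.mark.parametrize(
        "p,t,expected",
        [("R", "A", True), ("R", "G", True), ("R", "C", False), ("W", "N", False),
         ("N", "A", True), ("A", "A", True), ("A", "T", False), ("Y", "C", True)],
    )
    def test_expansion_semantics(self, p, t, expected):
        assert iupac_match(p, t) is expected

    def test_illegal_bases_raise(self):
        with pytest.raises(ValueError):
            iupac_match("X", "A")
        with pytest.raises(ValueError):
            iupac_match("A", "R")  # target may only be A/C/G/T/N


def brute_force_scan(seq: str, primer: str, max_mismatch: int, tpe: int):
    """Position-by-position reference scanner (independent oracle)."""
    out = []
    m = len(primer)
    for strand in "+-":
        pat = primer if strand == "+" else revcomp(primer)
        for i in range(len(seq) - m + 1):
            win = seq[i : i + m]
            ok = [t in "ACGT" and t in IUPAC_SETS[p] for p, t in zip(pat, win)]
            mm = m - sum(ok)
            if mm > max_mismatch:
                continue
            exact = ok[m - tpe :] if strand == "+" else ok[:tpe]
            if tpe and not all(exact):
                continue
            pos5 = i + 1 if strand == "+" else i + m
            out.append((strand, pos5, mm))
    return sorted(out, key=lambda s: (s[1], s[0]))


class TestScanPrimer:
    def test_planted_exact_site(self):
        rng = np.random.default_rng(0)
        primer = "TCTGCATCGCTAAATCCTTT"
        seq = _rand(rng, 100) + primer + _rand(rng, 100)
        seq = seq.replace(primer, primer, 1)
        sites = [s for s in scan_primer(SeqRecord("t", seq), primer) if s.strand == "+"]
        assert any(s.pos5 == 101 and s.mismatches == 0 for s in sites)

    def test_degenerate_primer_matches_realization(self):
        primer = "CTCCCAAGGATGAGRAAYTG"
        target = "ACGTACGT" + "CTCCCAAGGATGAGAAACTG" + "ACGTACGT"
        sites = scan_primer(SeqRecord("t", target), primer)
        assert any(s.strand == "+" and s.pos5 == 9 and s.mismatches == 0 for s in sites)

    def test_n_in_target_never_matches(self):
        primer = "ACGTACGTACGTACGTACGT"
        target = primer.replace("A", "N", 1) + "TTTT"
        sites = scan_primer(SeqRecord("t", target), primer, max_mismatch=0)
        assert sites == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = _rand(rng, 2000)
        primer = list(_rand(rng, 20))
        primer[7] = "R"
        primer[12] = "Y"
        primer = "".join(primer)
        # plant a couple of imperfect copies to make hits likely
        realization = primer.replace("R", "A").replace("Y", "C")
        mutated = "T" + realization[1:]
        seq = seq[:300] + realization + seq[320:900] + revcomp(mutated) + seq[920:]
        got = [
            (s.strand, s.pos5, s.mismatches)
            for s in scan_primer(SeqRecord("t", seq), primer, 2, 3)
        ]
        assert got == brute_force_scan(seq, primer, 2, 3)

    def test_sites_sorted_by_pos5(self):
        rng = np.random.default_rng(9)
        primer = _rand(rng, 18)
        seq = primer + _rand(rng, 50) + revcomp(primer) + _rand(rng, 50) + primer
        pos = [s.pos5 for s in scan_primer(SeqRecord("t", seq), primer)]
        assert pos == sorted(pos)


def _site(pos5, strand, role="fwd"):
    return BindingSite("s", strand, pos5, 0, role)


class TestEnumerateAmplicons:
    @pytest.mark.parametrize(
        "fwd,rev,length",
        [(43167, 43533, 367), (68920, 69842, 923), (1, 50, 50)],
    )
    def test_product_length_arithmetic(self, fwd, rev, length):
        hits = enumerate_amplicons([_site(fwd, "+")], [_site(rev, "-", "rev")])
        assert len(hits) == 1
        assert hits[0].length == length

    def test_divergent_sites_yield_nothing(self):
        assert enumerate_amplicons([_site(100, "+")], [_site(50, "-", "rev")]) == []

    def test_max_product_cap(self):
        hits = enumerate_amplicons(
            [_site(1, "+")], [_site(6000, "-", "rev")], max_product=5000
        )
        assert hits == []

    def test_all_combinations_reported_in_order(self):
        fwd = [_site(10, "+"), _site(60, "+")]
        rev = [_site(200, "-", "rev"), _site(400, "-", "rev")]
        hits = enumerate_amplicons(fwd, rev)
        assert [(h.start, h.end) for h in hits] == [
            (10, 200), (10, 400), (60, 200), (60, 400)
        ]


class TestComposition:
    @pytest.fixture()
    def model(self):
        # exon1 1-100, intron1 101-285 (185), exon2 286-500
        return GeneModel("g", "s", "+", ((1, 100), (286, 500)))

    def test_exon_intron_exon_breakdown(self, model):
        amp = AmpliconHit("M", "s", 71, 437, _site(71, "+"), _site(437, "-", "rev"))
        out = annotate_composition(amp, model)
        assert out.composition == (("E1", 30), ("I1", 185), ("E2", 152))
        assert sum(ln for _, ln in out.composition) == out.length == 367

    def test_amplicon_within_single_exon(self, model):
        amp = AmpliconHit("M", "s", 10, 59, _site(10, "+"), _site(59, "-", "rev"))
        out = annotate_composition(amp, model)
        assert out.composition == (("E1", 50),)

    def test_amplicon_outside_gene_flagged(self, model):
        amp = AmpliconHit("M", "s", 600, 700, _site(600, "+"), _site(700, "-", "rev"))
        out = annotate_composition(amp, model)
        assert out.composition == ()
        assert out.outside_gene


class TestWorkedExampleSurface:
    """The packaged worked-example genome reproduces the published panel."""

    EXPECTED = {
        "M1": (43167, 43533, 367, (("E22", 30), ("I22", 185), ("E23", 152))),
        "M2": (43178, 43435, 258, (("E22", 19), ("I22", 185), ("E23", 54))),
        "M3": (29350, 32346, 2997, (("E9", 43), ("I9", 2852), ("E10", 102))),
        "M4": (38324, 38827, 504, (("E16", 112), ("I16", 335), ("E17", 57))),
        "M5": (38358, 38821, 464, (("E16", 78), ("I16", 335), ("E17", 51))),
        "M7": (68920, 69842, 923, (("E17", 54), ("I17", 801), ("E18", 68))),
    }

    def test_positions_lengths_and_composition(self, worked_example_result):
        for marker, (start, end, length, comp) in self.EXPECTED.items():
            amp = worked_example_result.diagnostic_amplicons[marker]
            assert (amp.start, amp.end, amp.length) == (start, end, length)
            assert amp.composition == comp
            assert abs(amp.rev_site.pos5 - amp.fwd_site.pos5) + 1 == length

    def test_inner_variants_nested_in_outer(self, worked_example_result):
        d = worked_example_result.diagnostic_amplicons
        for inner, outer in (("M2", "M1"), ("M5", "M4")):
            hi, ho = d[inner], d[outer]
            assert ho.start <= hi.start and hi.end <= ho.end
            assert (hi.start, hi.end) != (ho.start, ho.end)
            # same intron: identical I-tag in both compositions
            itag = [t for t, _ in hi.composition if t.startswith("I")]
            assert itag == [t for t, _ in ho.composition if t.startswith("I")]

    def test_spin_marker_has_no_sites(self, worked_example_result):
        assert worked_example_result.amplicons["M6"] == []

    def test_composition_conservation_everywhere(self, worked_example_result):
        for amp in worked_example_result.diagnostic_amplicons.values():
            assert sum(ln for _, ln in amp.composition) == amp.length


class TestBedExport:
    def test_zero_based_half_open_conversion(self):
        amp = AmpliconHit("M1", "s", 101, 200, _site(101, "+"), _site(200, "-", "rev"))
        line = amplicons_to_bed([amp]).strip().split("\t")
        assert (line[1], line[2]) == ("100", "200")
        assert int(line[2]) - int(line[1]) == amp.length
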