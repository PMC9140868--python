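"""Seed-and-extend search vs an exhaustive Smith-Waterman oracle."""

import numpy as np
import pytest
from Bio import Align

from zwmarker._sw import sw_align
from zwmarker.homology_search import local_search, locate_gene, presence_matrix
from zwmarker.sequence_io import SeqRecord, revcomp


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _mutate(rng, s, rate):
    out = list(s)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = [b for b in "ACGT" if b != out[i]][int(rng.integers(0, 3))]
    return "".join(out)


def _oracle():
    # match +1, mismatch -2, gap of length L costs 5 + 2L
    return Align.PairwiseAligner(
        mode="local", match_score=1, mismatch_score=-2,
        open_gap_score=-7, extend_gap_score=-2,
    )


class TestKernel:
    @pytest.mark.parametrize("seed", range(6))
    def test_score_equals_exhaustive_dp(self, seed):
        rng = np.random.default_rng(seed)
        sub = _rand(rng, 1500)
        q = _rand(rng, 200)
        planted = _mutate(rng, q, 0.1)
        pos = int(rng.integers(0, 1200))
        sub = sub[:pos] + planted + sub[pos + 200 :]
        score, qs, qe, ss, se, matches, cols = sw_align(q, sub)
        assert score == _oracle().score(sub, q)

    def test_coordinates_of_unique_optimum(self):
        rng = np.random.default_rng(42)
        sub = _rand(rng, 800)
        q = _rand(rng, 120)
        sub = sub[:300] + q + sub[420:]
        score, qs, qe, ss, se, matches, cols = sw_align(q, sub)
        assert (qs, qe, ss, se) == (0, 119, 300, 419)
        assert matches == cols == 120
        aln = _oracle().align(sub, q)[0]
        t0, t1 = aln.aligned[0][0][0], aln.aligned[0][-1][1]
        assert (t0, t1) == (ss, se + 1)


class TestLocalSearch:
    def test_exact_copy_full_identity_and_cover(self):
        rng = np.random.default_rng(1)
        q = _rand(rng, 300)
        sub = _rand(rng, 400) + q + _rand(rng, 400)
        hits = local_search(SeqRecord("q", q), [SeqRecord("s", sub, "W")])
        assert hits[0].identity == 1.0
        assert hits[0].query_cover == 1.0
        assert hits[0].subject_copy_length == 300
        assert hits[0].subject_start == 401

    def test_diverged_copy_identity_close_to_planted(self):
        rng = np.random.default_rng(2)
        q = _rand(rng, 400)
        planted = _mutate(rng, q, 0.10)
        sub = _rand(rng, 200) + planted + _rand(rng, 200)
        hits = local_search(SeqRecord("q", q), [SeqRecord("s", sub, "W")])
        assert hits and not hits[0].partial
        assert hits[0].identity == pytest.approx(0.90, abs=0.04)

    def test_reverse_complement_copy_found_with_same_identity(self):
        rng = np.random.default_rng(3)
        q = _rand(rng, 300)
        planted = _mutate(rng, q, 0.05)
        fwd_sub = _rand(rng, 150) + planted + _rand(rng, 150)
        rev_sub = revcomp(fwd_sub)
        h_fwd = local_search(SeqRecord("q", q), [SeqRecord("s", fwd_sub, "W")])[0]
        h_rev = local_search(SeqRecord("q", q), [SeqRecord("s", rev_sub, "W")])[0]
        assert h_rev.strand == "-"
        assert h_rev.identity == h_fwd.identity
        assert h_rev.subject_copy_length == h_fwd.subject_copy_length

    def test_truncated_copy_flagged_partial(self):
        rng = np.random.default_rng(4)
        q = _rand(rng, 923)
        fragment = q[397:]  # query positions 398..923
        sub = fragment + _rand(rng, 1255 - len(fragment))
        hits = local_search(SeqRecord("q", q), [SeqRecord("s", sub, "scaffold")])
        h = hits[0]
        assert h.partial
        assert h.query_cover == pytest.approx(526 / 923, abs=0.01)
        assert h.query_start == 398 and h.query_end == 923
        assert h.subject_start == 1

    def test_internal_deletion_chained_into_full_span(self):
        rng = np.random.default_rng(5)
        q = _rand(rng, 2000)
        copy = q[:700] + q[1700:]  # 1000 bp deleted from the middle
        sub = _rand(rng, 100) + copy + _rand(rng, 100)
        hits = local_search(SeqRecord("q", q), [SeqRecord("s", sub, "W")])
        h = hits[0]
        assert h.n_hsps >= 2
        assert not h.partial  # spans the query end-to-end
        assert h.subject_copy_length == 1000
        assert h.query_cover == 1.0

    def test_min_identity_monotonicity(self):
        rng = np.random.default_rng(6)
        q = _rand(rng, 300)
        sub = _rand(rng, 100) + _mutate(rng, q, 0.12) + _rand(rng, 100)
        subs = [SeqRecord("s", sub, "W")]
        counts = [
            len(local_search(SeqRecord("q", q), subs, min_identity=t))
            for t in (0.5, 0.7, 0.85, 0.95)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_word_size_floor(self):
        with pytest.raises(ValueError):
            local_search(SeqRecord("q", "ACGT" * 30), [], word_size=4)

    @pytest.mark.parametrize("seed", range(4))
    def test_best_hit_matches_exhaustive_oracle(self, seed):
        """Substitution-only instances: top hit score == full Smith-Waterman."""
        rng = np.random.default_rng(seed + 50)
        q = _rand(rng, 350)
        sub = _rand(rng, 5000)
        planted = _mutate(rng, q, 0.08)
        pos = int(rng.integers(0, 4600))
        sub = sub[:pos] + planted + sub[pos + 350 :]
        hits = local_search(SeqRecord("q", q), [SeqRecord("s", sub, "W")])
        assert hits[0].score == _oracle().score(sub, q)


class TestGeneLocation:
    def _assembly(self, rng, gene_exons, diverged_decoy=False):
        z = _rand(rng, 300)
        for e in gene_exons:
            z += e + _rand(rng, 120)
        subs = [SeqRecord("zc", z, "Z"), SeqRecord("wc", _rand(rng, 600), "W")]
        if diverged_decoy:
            s = _rand(rng, 150)
            for e in gene_exons:
                s += _mutate(rng, e, 0.1) + _rand(rng, 60)
            subs.append(SeqRecord("sc", s, "scaffold"))
        return subs

    def test_gene_planted_on_z_labelled_z(self):
        rng = np.random.default_rng(11)
        exons = [SeqRecord(f"e{i}", _rand(rng, 180)) for i in range(2)]
        subs = self._assembly(rng, [e.seq for e in exons])
        loc = locate_gene({"geneA": exons}, subs)
        assert loc["geneA"][0]["label"] == "Z"

    def test_decoy_reported_best_first(self):
        rng = np.random.default_rng(12)
        exons = [SeqRecord(f"e{i}", _rand(rng, 180)) for i in range(2)]
        subs = self._assembly(rng, [e.seq for e in exons], diverged_decoy=True)
        rows = locate_gene({"geneA": exons}, subs)["geneA"]
        assert [r["label"] for r in rows[:2]] == ["Z", "scaffold"]
        assert rows[0]["identity"] >= rows[1]["identity"]

    def test_absent_gene(self):
        rng = np.random.default_rng(13)
        exons = [SeqRecord("e0", _rand(rng, 180))]
        subs = [SeqRecord("zc", _rand(rng, 800), "Z")]
        assert locate_gene({"geneA": exons}, subs)["geneA"] == []

    def test_presence_matrix_agrees_with_locate(self):
        rng = np.random.default_rng(14)
        genes = {}
        for g in range(3):
            genes[f"g{g}"] = [SeqRecord(f"g{g}e", _rand(rng, 200))]
        subs = self._assembly(rng, [genes["g0"][0].seq, genes["g1"][0].seq])
        present, annot = presence_matrix(genes, subs)
        located = locate_gene(genes, subs)
        for g, rows in located.items():
            labels = {r["label"] for r in rows}
            for lab in present.columns:
                assert present.loc[g, lab] == (lab in labels)

    def test_empty_gene_list(self):
        present, annot = presence_matrix({}, [SeqRecord("zc", "ACGT" * 100, "Z")])
        assert present.empty
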