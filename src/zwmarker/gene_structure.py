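"""Exon/intron structure inference by spliced mapping of an mRNA onto a genome.

The use case is same-species mapping (the mRNA was sequenced from the genome
being analyzed, or a very close relative), so matching is near-exact: exon
blocks are found by maximal-exact-match seeding and chained co-linearly;
small divergence (default up to 2% per exon) is absorbed when stitching
adjacent anchors. Exon/intron boundaries that are ambiguous (the same mRNA
letters match on both sides of the junction) are shifted to the leftmost
placement whose intron starts with GT and ends with AG if one exists in the
ambiguity window, else simply leftmost. This is a convention of this
package; it is deterministic and matches the canonical splice-site motif.

This is deliberately not a general splice-aware aligner: no trans-splicing,
no cross-species mapping beyond the mismatch tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .sequence_io import SeqRecord, revcomp

MIN_ANCHOR_DEFAULT = 20
MAX_MISMATCH_RATE_DEFAULT = 0.02
MIN_MRNA_COVERAGE = 0.95


class UnmappableError(ValueError):
    """No co-linear exon chain covers enough of the mRNA."""


class AmbiguityError(ValueError):
    """Several equally scoring exon chains exist."""

    def __init__(self, candidates):
        self.candidates = candidates
        super().__init__(f"{len(candidates)} equally scoring exon chains: {candidates}")


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron coordinates of one gene on one sequence.

    ``exons`` are (start, end) pairs, 1-based inclusive, strictly increasing
    along the genome. Intron i separates exon i from exon i+1 (1-based,
    numbered in gene order; for a minus-strand gene the gene order runs from
    the highest-coordinate exon downwards).
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("GeneModel needs at least one exon")
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end or end < start:
                raise ValueError(f"exons not strictly increasing: {self.exons}")
            prev_end = end
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 - e1 < 2:
                raise ValueError("zero-length intron")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exon_number(self, i: int) -> int:
        """Gene-order ordinal (1-based) of the i-th exon in genomic order."""
        return i + 1 if self.strand == "+" else self.n_exons - i

    @property
    def introns(self) -> tuple[tuple[int, int, int, int], ...]:
        """(index, start, end, length), index 1-based after the preceding exon."""
        out = []
        for i, ((_, e1), (s2, _)) in enumerate(zip(self.exons, self.exons[1:])):
            idx = self.exon_number(i) if self.strand == "+" else self.exon_number(i + 1)
            out.append((idx, e1 + 1, s2 - 1, s2 - e1 - 1))
        return tuple(out)

    def spliced_sequence(self, genome: SeqRecord) -> str:
        parts = [genome.seq[s - 1 : e] for s, e in self.exons]
        joined = "".join(parts)
        return joined if self.strand == "+" else revcomp(joined)


def intron_table(model: GeneModel) -> list[tuple[int, int, int, int]]:
    """Ordered (intron_index, start, end, length) rows for a gene model."""
    return list(model.introns)


# ---------------------------------------------------------------------------
# spliced mapping
# ---------------------------------------------------------------------------


@dataclass
class _Anchor:
    qs: int  # query (mRNA) start, 0-based inclusive
    qe: int  # query end, 0-based inclusive
    ss: int  # subject (genome) start, 0-based inclusive
    se: int  # subject end, 0-based inclusive

    @property
    def qlen(self) -> int:
        return self.qe - self.qs + 1


def _maximal_exact_matches(query: str, subject: str, k: int) -> list[_Anchor]:
    index: dict[str, list[int]] = {}
    for i in range(len(subject) - k + 1):
        index.setdefault(subject[i : i + k], []).append(i)
    seen: set[tuple[int, int]] = set()
    anchors: list[_Anchor] = []
    for q in range(len(query) - k + 1):
        for s in index.get(query[q : q + k], ()):
            diag = s - q
            qs, qe = q, q + k - 1
            # extend left then right, exactly
            while qs > 0 and qs + diag > 0 and query[qs - 1] == subject[qs + diag - 1]:
                qs -= 1
            while (
                qe + 1 < len(query)
                and qe + diag + 1 < len(subject)
                and query[qe + 1] == subject[qe + diag + 1]
            ):
                qe += 1
            key = (diag, qs)
            if key in seen:
                continue
            seen.add(key)
            anchors.append(_Anchor(qs, qe, qs + diag, qe + diag))
    return [a for a in anchors if a.qlen >= k]


def _chain(anchors: list[_Anchor]) -> tuple[list[_Anchor], int, bool]:
    """Best co-linear chain by total query coverage (overlaps discounted).

    Returns (chain, score, tied) where tied flags a second, coordinate-wise
    different chain of equal score.
    """
    anchors = sorted(anchors, key=lambda a: (a.qs, a.ss))
    n = len(anchors)
    best = [a.qlen for a in anchors]
    prev = [-1] * n
    for i in range(n):
        ai = anchors[i]
        for j in range(i):
            aj = anchors[j]
            if aj.ss >= ai.ss or aj.se >= ai.se or aj.qe >= ai.qe:
                continue
            overlap = max(0, aj.qe - ai.qs + 1)
            # genomic order must survive trimming the query overlap
            if ai.ss + overlap <= aj.se + 1:
                continue
            gain = ai.qlen - overlap
            if best[j] + gain > best[i]:
                best[i] = best[j] + gain
                prev[i] = j
    if not anchors:
        return [], 0, False
    top = max(best)
    ends = [i for i in range(n) if best[i] == top]

    def backtrack(i: int) -> list[_Anchor]:
        out = []
        while i != -1:
            out.append(anchors[i])
            i = prev[i]
        return out[::-1]

    chains = [backtrack(i) for i in ends]
    coords = {tuple((a.qs, a.qe, a.ss, a.se) for a in c) for c in chains}
    return chains[0], top, len(coords) > 1


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _stitch(
    chain: list[_Anchor], query: str, subject: str, budget_rate: float
) -> list[tuple[int, int, int, int]]:
    """Merge chained anchors into exon blocks (query+subject 0-based intervals).

    Anchors whose query/subject gaps are equal-length and nearly identical are
    the same exon (substitution noise); unequal gaps are splice junctions.
    """
    blocks: list[list[int]] = [[chain[0].qs, chain[0].qe, chain[0].ss, chain[0].se]]
    for a in chain[1:]:
        qs, qe, ss, se = blocks[-1]
        overlap = max(0, qe - a.qs + 1)
        aqs, ass = a.qs + overlap, a.ss + overlap
        qgap = aqs - qe - 1
        sgap = ass - se - 1
        if qgap == sgap and qgap >= 0:
            mid_mm = _mismatches(query[qe + 1 : aqs], subject[se + 1 : ass])
            length = (a.qe - qs + 1)
            if mid_mm <= max(1, int(budget_rate * length)):
                blocks[-1] = [qs, a.qe, ss, a.se]
                continue
        blocks.append([aqs, a.qe, ass, a.se])
    return [tuple(b) for b in blocks]


def _assign_junction_gaps(
    blocks: list[tuple[int, int, int, int]], query: str, subject: str, budget_rate: float
) -> list[list[int]]:
    """Attach query bases that fell between exon blocks (mismatch near a junction)."""
    out = [list(b) for b in blocks]
    for left, right in zip(out, out[1:]):
        gap = right[0] - left[1] - 1
        if gap <= 0:
            continue
        budget = max(1, int(budget_rate * len(query)))
        # greedily extend the left exon rightwards while genome keeps pace
        while gap > 0 and budget > 0 and left[3] + 1 < right[2]:
            left[1] += 1
            left[3] += 1
            if query[left[1]] != subject[left[3]]:
                budget -= 1
            gap -= 1
        # whatever remains goes to the start of the right exon
        while gap > 0 and right[2] - 1 > left[3]:
            right[0] -= 1
            right[2] -= 1
            gap -= 1
        if gap > 0:
            raise UnmappableError("cannot place mRNA bases at an exon junction")
    # terminal extension to the mRNA ends
    first, last = out[0], out[-1]
    while first[0] > 0 and first[2] > 0:
        first[0] -= 1
        first[2] -= 1
    while last[1] < len(query) - 1 and last[3] < len(subject) - 1:
        last[1] += 1
        last[3] += 1
    return out


def _shift_junctions(blocks: list[list[int]], query: str, subject: str) -> None:
    """Resolve boundary ambiguity: leftmost GT..AG intron if possible, else leftmost.

    A junction can shift left by one when the last exonic base of the left
    exon equals the base just before the right exon (the mRNA still matches),
    and right by one symmetrically.
    """
    for left, right in zip(blocks, blocks[1:]):
        shifts = [0]
        # leftward shifts
        d = 0
        while (
            left[1] - d > left[0]
            and query[left[1] - d] == subject[right[2] - 1 - d]
            and subject[left[3] - d] == subject[right[2] - 1 - d]
        ):
            d += 1
            shifts.append(-d)
        # rightward shifts
        d = 0
        while (
            right[0] + d < right[1]
            and query[right[0] + d] == subject[left[3] + 1 + d]
            and subject[right[2] + d] == subject[left[3] + 1 + d]
        ):
            d += 1
            shifts.append(d)
        shifts.sort()

        def intron_at(shift: int) -> str:
            a = left[3] + shift + 1
            b = right[2] + shift - 1
            return subject[a : b + 1]

        chosen = None
        for s in shifts:
            iv = intron_at(s)
            if len(iv) >= 4 and iv.startswith("GT") and iv.endswith("AG"):
                chosen = s
                break
        if chosen is None:
            chosen = shifts[0]
        left[1] += chosen
        left[3] += chosen
        right[0] += chosen
        right[2] += chosen


def map_exons(
    mrna: SeqRecord,
    genome: SeqRecord,
    min_anchor: int = MIN_ANCHOR_DEFAULT,
    max_mismatch_rate: float = MAX_MISMATCH_RATE_DEFAULT,
    gene_id: str | None = None,
) -> GeneModel:
    """Infer a gene model by spliced mapping of ``mrna`` onto ``genome``.

    Tries the plus strand first, then the reverse complement. Raises
    :class:`UnmappableError` when no co-linear chain covers at least 95% of
    the mRNA, and :class:`AmbiguityError` when several chains tie.
    """
    if len(mrna.seq) > len(genome.seq):
        raise UnmappableError("mRNA longer than genomic sequence")
    gene_id = gene_id or mrna.id

    attempts: list[tuple[str, str]] = [("+", mrna.seq), ("-", revcomp(mrna.seq))]
    errors = []
    for strand, qseq in attempts:
        try:
            exons = _map_plus(qseq, genome.seq, min_anchor, max_mismatch_rate)
        except (UnmappableError, AmbiguityError) as exc:
            errors.append(exc)
            continue
        return GeneModel(gene_id, genome.id, strand, tuple(exons))
    for exc in errors:
        if isinstance(exc, AmbiguityError):
            raise exc
    raise UnmappableError(f"unmappable mRNA {mrna.id!r} on {genome.id!r}")


def _map_plus(
    query: str, subject: str, min_anchor: int, rate: float
) -> list[tuple[int, int]]:
    anchors = _maximal_exact_matches(query, subject, min_anchor)
    if not anchors:
        raise UnmappableError("no anchors")
    chain, score, tied = _chain(anchors)
    if score < MIN_MRNA_COVERAGE * len(query):
        raise UnmappableError(f"best chain covers {score}/{len(query)} mRNA bases")
    if tied:
        raise AmbiguityError([(a.ss + 1, a.se + 1) for a in chain])
    blocks = _stitch(chain, query, subject, rate)
    blocks = _assign_junction_gaps(blocks, query, subject, rate)
    _shift_junctions(blocks, query, subject)
    # per-exon mismatch-rate validation
    for qs, qe, ss, se in blocks:
        if qe - qs != se - ss:
            raise UnmappableError("inconsistent exon block geometry")
        mm = _mismatches(query[qs : qe + 1], subject[ss : se + 1])
        if mm > max(1, int(rate * (qe - qs + 1))):
            raise UnmappableError(f"exon exceeds mismatch budget ({mm} mismatches)")
    covered = sum(qe - qs + 1 for qs, qe, ss, se in blocks)
    if covered < MIN_MRNA_COVERAGE * len(query):
        raise UnmappableError("exon blocks cover too little of the mRNA")
    return [(ss + 1, se + 1) for _, _, ss, se in blocks]


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def to_gff3(model: GeneModel, source: str = "zwmarker") -> str:
    """Render a gene model as GFF3 (gene + exon features, 1-based inclusive)."""
    lines = ["##gff-version 3"]
    start, end = model.span
    gid = model.gene_id
    lines.append(
        "\t".join(
            [model.seq_id, source, "gene", str(start), str(end), ".", model.strand, ".", f"ID={gid}"]
        )
    )
    for i, (s, e) in enumerate(model.exons):
        num = model.exon_number(i)
        lines.append(
            "\t".join(
                [
                    model.seq_id,
                    source,
                    "exon",
                    str(s),
                    str(e),
                    ".",
                    model.strand,
                    ".",
                    f"ID={gid}.exon{num};Parent={gid}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def intron_table_tsv(model: GeneModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("intron_index\tstart\tend\tlength\n")
        for idx, s, e, ln in intron_table(model):
            fh.write(f"{idx}\t{s}\t{e}\t{ln}\n")
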