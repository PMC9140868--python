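"""Degenerate-primer binding-site scanning and PCR product enumeration.

The scanner slides each primer over both strands of a template, counting
mismatches under IUPAC semantics (a degenerate primer base matches any base
in its expansion; an ``N`` in the *template* matches nothing — assembly gaps
never create binding sites). Sites must be exact over a configurable number
of bases at the primer's 3' end, where polymerase extension is intolerant of
mismatches. Products are then every convergent site pair within a maximum
product length — all of them, deliberately: real gels show multiple and
nonspecific bands, so no "shortest product wins" heuristic is applied.

Coordinates are 1-based inclusive throughout; a site's ``pos5`` is the
primer's 5'-most footprint base projected onto the plus strand, so a
product's length is ``rev.pos5 - fwd.pos5 + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .gene_structure import GeneModel
from .sequence_io import IUPAC_SETS, PrimerPair, SeqRecord, revcomp

MAX_MISMATCH_DEFAULT = 2
THREE_PRIME_EXACT_DEFAULT = 3
MAX_PRODUCT_DEFAULT = 5000

# 256x256 lookup: MATCH[ord(primer_base), ord(template_base)] — template N or
# any ambiguity code never matches (conservative).
_MATCH = np.zeros((256, 256), dtype=bool)
for _p, _expansion in IUPAC_SETS.items():
    for _t in "ACGT":
        if _t in _expansion:
            _MATCH[ord(_p), ord(_t)] = True


def iupac_match(primer_base: str, target_base: str) -> bool:
    """True iff ``target_base`` lies in the IUPAC expansion of ``primer_base``."""
    if primer_base not in IUPAC_SETS:
        raise ValueError(f"illegal primer base {primer_base!r}")
    if target_base not in "ACGTN":
        raise ValueError(f"illegal target base {target_base!r}")
    return bool(_MATCH[ord(primer_base), ord(target_base)])


@dataclass(frozen=True)
class BindingSite:
    """One primer footprint on a template sequence.

    ``pos5`` is the 5'-most base of the primer projected onto the plus
    strand: the leftmost footprint base for a plus-strand site, the rightmost
    for a minus-strand site. ``start``/``end`` give the full footprint.
    """

    seq_id: str
    strand: str
    pos5: int
    mismatches: int
    primer_role: str  # fwd | rev
    primer_name: str = ""
    start: int = 0
    end: int = 0


@dataclass(frozen=True)
class AmpliconHit:
    """One predicted PCR product.

    ``composition`` (filled by :func:`annotate_composition`) lists the exon
    and intron fragments the product spans in gene order, e.g.
    ``[("E22", 30), ("I22", 185), ("E23", 152)]``.
    """

    marker_id: str
    seq_id: str
    start: int
    end: int
    fwd_site: BindingSite
    rev_site: BindingSite
    sequence: str = ""
    composition: tuple[tuple[str, int], ...] = ()
    outside_gene: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("amplicon end before start")
        if self.sequence and len(self.sequence) != self.length:
            raise ValueError("amplicon sequence/coordinate mismatch")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan_oriented(
    target: np.ndarray, primer: str, max_mismatch: int, exact_tail: slice
) -> list[tuple[int, int]]:
    """(0-based footprint start, mismatches) for one footprint pattern.

    ``exact_tail`` selects the footprint positions that must match exactly
    (the primer's 3' end in footprint coordinates).
    """
    m = len(primer)
    n = len(target)
    if n < m:
        return []
    pat = _encode(primer)
    windows = np.lib.stride_tricks.sliding_window_view(target, m)
    ok = _MATCH[pat[None, :], windows]
    mm = (~ok).sum(axis=1)
    good = mm <= max_mismatch
    if exact_tail != slice(0, 0):
        good &= ok[:, exact_tail].all(axis=1)
    return [(int(i), int(mm[i])) for i in np.nonzero(good)[0]]


def scan_primer(
    seq: SeqRecord,
    primer: str,
    max_mismatch: int = MAX_MISMATCH_DEFAULT,
    three_prime_exact: int = THREE_PRIME_EXACT_DEFAULT,
    primer_role: str = "fwd",
    primer_name: str = "",
) -> list[BindingSite]:
    """All binding sites of a degenerate primer on both strands of ``seq``.

    A site has at most ``max_mismatch`` mismatches overall and none within
    the ``three_prime_exact`` bases at the primer's 3' end. Sites are
    returned in ascending ``pos5`` order.
    """
    if len(primer) < three_prime_exact:
        raise ValueError("primer shorter than the exact 3' window")
    target = _encode(seq.seq)
    m = len(primer)
    sites: list[BindingSite] = []
    # plus strand: footprint reads as the primer; 3' end = rightmost bases
    tail = slice(m - three_prime_exact, m) if three_prime_exact else slice(0, 0)
    for i, mm in _scan_oriented(target, primer, max_mismatch, tail):
        sites.append(
            BindingSite(seq.id, "+", i + 1, mm, primer_role, primer_name, i + 1, i + m)
        )
    # minus strand: footprint reads as revcomp(primer); 3' end = leftmost bases
    head = slice(0, three_prime_exact) if three_prime_exact else slice(0, 0)
    for i, mm in _scan_oriented(target, revcomp(primer), max_mismatch, head):
        sites.append(
            BindingSite(seq.id, "-", i + m, mm, primer_role, primer_name, i + 1, i + m)
        )
    sites.sort(key=lambda s: (s.pos5, s.strand))
    return sites


def enumerate_amplicons(
    fwd_sites: Sequence[BindingSite],
    rev_sites: Sequence[BindingSite],
    max_product: int = MAX_PRODUCT_DEFAULT,
    seq: SeqRecord | None = None,
    marker_id: str = "",
) -> list[AmpliconHit]:
    """Every convergent (plus-strand fwd, minus-strand rev) product.

    Products run from the forward site's 5' base to the reverse site's 5'
    base; only pairs with ``fwd.pos5 < rev.pos5`` and a product length of at
    most ``max_product`` are kept. Results are sorted by start, then length.
    """
    hits: list[AmpliconHit] = []
    for f in fwd_sites:
        if f.strand != "+":
            continue
        for r in rev_sites:
            if r.strand != "-" or r.pos5 <= f.pos5:
                continue
            if f.seq_id != r.seq_id:
                raise ValueError("sites from different sequences")
            length = r.pos5 - f.pos5 + 1
            if length > max_product:
                continue
            product = seq.seq[f.pos5 - 1 : r.pos5] if seq is not None else ""
            hits.append(
                AmpliconHit(marker_id, f.seq_id, f.pos5, r.pos5, f, r, product)
            )
    hits.sort(key=lambda h: (h.start, h.length))
    return hits


def predict_amplicons(
    seq: SeqRecord,
    pair: PrimerPair,
    max_mismatch: int = MAX_MISMATCH_DEFAULT,
    three_prime_exact: int = THREE_PRIME_EXACT_DEFAULT,
    max_product: int = MAX_PRODUCT_DEFAULT,
) -> list[AmpliconHit]:
    """In-silico PCR of one primer pair on one template, both orientations.

    Either member of the pair may act as the left (plus-strand-identical)
    primer, as in a real reaction; both orientations are enumerated.
    """
    fwd = scan_primer(seq, pair.fwd_seq, max_mismatch, three_prime_exact, "fwd", pair.fwd_name)
    rev = scan_primer(seq, pair.rev_seq, max_mismatch, three_prime_exact, "rev", pair.rev_name)
    hits = enumerate_amplicons(
        [s for s in fwd if s.strand == "+"],
        [s for s in rev if s.strand == "-"],
        max_product,
        seq,
        pair.marker_id,
    )
    hits += enumerate_amplicons(
        [s for s in rev if s.strand == "+"],
        [s for s in fwd if s.strand == "-"],
        max_product,
        seq,
        pair.marker_id,
    )
    hits.sort(key=lambda h: (h.start, h.length))
    return hits


def annotate_composition(amp: AmpliconHit, model: GeneModel) -> AmpliconHit:
    """Label the exon/intron fragments an amplicon spans, in gene order.

    Overlap lengths always sum to the amplicon length when the product lies
    inside the gene span; a product entirely outside the gene gets an empty
    composition and ``outside_gene=True``.
    """
    if amp.seq_id != model.seq_id:
        raise ValueError("amplicon and gene model on different sequences")
    features: list[tuple[str, int, int]] = []
    for i, (s, e) in enumerate(model.exons):
        features.append((f"E{model.exon_number(i)}", s, e))
    for idx, s, e, _ in model.introns:
        features.append((f"I{idx}", s, e))
    features.sort(key=lambda f: f[1])
    if model.strand == "-":
        features.reverse()
    segments: list[tuple[str, int]] = []
    for tag, s, e in features:
        ov = min(amp.end, e) - max(amp.start, s) + 1
        if ov > 0:
            segments.append((tag, ov))
    if not segments:
        return replace(amp, composition=(), outside_gene=True)
    return replace(amp, composition=tuple(segments), outside_gene=False)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def amplicons_to_bed(hits: Iterable[AmpliconHit]) -> str:
    """BED6 rendering (0-based half-open; conversion from 1-based inclusive)."""
    lines = []
    for h in hits:
        lines.append(
            f"{h.seq_id}\t{h.start - 1}\t{h.end}\t{h.marker_id}\t{h.length}\t+"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def composition_str(amp: AmpliconHit) -> str:
    return "/".join(f"{tag}({ln} bp)" for tag, ln in amp.composition)


def amplicons_to_tsv(hits: Iterable[AmpliconHit], path: str | Path | None = None) -> str:
    """TSV with marker, primer, position, length and composition columns."""
    lines = ["marker\tfwd_primer\tfwd_pos\trev_primer\trev_pos\tlength\tcomposition"]
    for h in hits:
        lines.append(
            "\t".join(
                [
                    h.marker_id,
                    h.fwd_site.primer_name,
                    str(h.fwd_site.pos5),
                    h.rev_site.primer_name,
                    str(h.rev_site.pos5),
                    str(h.length),
                    composition_str(h),
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
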