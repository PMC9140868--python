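"""Desk-scale seed-and-extend local-alignment search.

Finds second (gametolog or translocated) copies of a query sequence inside a
small set of subject sequences, BLAST-style: exact ``word_size``-mer seeds
are clustered by diagonal into candidate regions, each region is resolved by
an exact affine-gap Smith-Waterman (match +1, mismatch -2, gap 5+2L), and
additional local alignments are pulled out of the flanks of each solved
region so that a copy interrupted by a large insertion or deletion is
recovered as several HSPs. Co-linear HSPs on the same subject and strand
are then chained into one hit whose subject-side span *includes* the indel
— this is what makes the length of a second gametolog copy directly
measurable from the hit even when the indel is far too large for a single
gapped alignment to bridge.

No E-value statistics: at these problem sizes score, identity and query
cover are the useful quality measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._sw import sw_align
from .sequence_io import SeqRecord, revcomp

WORD_SIZE_DEFAULT = 11
MIN_IDENTITY_DEFAULT = 0.70
MIN_HIT_LEN_DEFAULT = 50
COMPLETENESS_DEFAULT = 0.90  # query_cover below this flags a partial copy
_MIN_HSP_SPAN = 20
_MIN_HSP_SCORE = 16
_MAX_JOIN_GAP = 6000  # largest indel a chained hit may absorb
_CHAIN_OVERLAP_TOL = 15


@dataclass(frozen=True)
class HomologyHit:
    """One (possibly chained) local-alignment hit.

    ``subject_copy_length`` is the subject-side span end-to-end, including
    any indel between chained HSPs. ``query_cover`` is the query-side span
    fraction (qend-qstart+1)/qlen: a copy with an internal deletion still
    covers the query end-to-end, a terminally truncated copy does not —
    only the latter is ``partial``.
    """

    query_id: str
    subject_id: str
    subject_label: str
    strand: str
    query_start: int  # 1-based inclusive, on the original query
    query_end: int
    subject_start: int  # 1-based inclusive, plus strand
    subject_end: int
    identity: float
    query_cover: float
    subject_copy_length: int
    partial: bool
    score: int
    n_hsps: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.identity <= 1.0):
            raise ValueError(f"identity out of range: {self.identity}")
        if not (0.0 < self.query_cover <= 1.0 + 1e-9):
            raise ValueError(f"query_cover out of range: {self.query_cover}")


@dataclass(frozen=True)
class _HSP:
    qs: int  # 0-based inclusive on oriented query
    qe: int
    ss: int  # 0-based inclusive on subject plus strand
    se: int
    score: int
    matches: int
    cols: int


def _seed_clusters(query: str, subject: str, word: int, pad: int) -> list[tuple[int, int]]:
    """Candidate subject windows from shared exact k-mers, merged when close."""
    index: dict[str, list[int]] = {}
    for i in range(len(query) - word + 1):
        index.setdefault(query[i : i + word], []).append(i)
    spans: list[tuple[int, int]] = []
    for j in range(len(subject) - word + 1):
        if subject[j : j + word] in index:
            spans.append((j, j + word - 1))
    if not spans:
        return []
    spans.sort()
    merged = [list(spans[0])]
    for a, b in spans[1:]:
        if a - merged[-1][1] <= pad:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    windows = []
    for a, b in merged:
        windows.append((max(0, a - pad), min(len(subject) - 1, b + pad)))
    # merging may have made neighbours overlap
    out = [list(windows[0])]
    for a, b in windows[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(w) for w in out]


def _extract_hsps(query: str, subject: str, lo: int, hi: int, depth: int = 0) -> list[_HSP]:
    """Best alignment in subject[lo..hi], then recurse into the flanks."""
    if hi - lo + 1 < _MIN_HSP_SPAN or depth > 8:
        return []
    res = sw_align(query, subject[lo : hi + 1])
    if res is None:
        return []
    score, qs, qe, ss, se, matches, cols = res
    if score < _MIN_HSP_SCORE or (qe - qs + 1) < _MIN_HSP_SPAN:
        return []
    hsp = _HSP(qs, qe, lo + ss, lo + se, score, matches, cols)
    out = [hsp]
    out += _extract_hsps(query, subject, lo, lo + ss - 1, depth + 1)
    out += _extract_hsps(query, subject, lo + se + 1, hi, depth + 1)
    return out


def _chain_hsps(hsps: list[_HSP]) -> list[list[_HSP]]:
    """Greedy co-linear chaining: HSPs in query order whose subject order agrees."""
    hsps = sorted(hsps, key=lambda h: (h.qs, h.ss))
    chains: list[list[_HSP]] = []
    used = [False] * len(hsps)
    order = sorted(range(len(hsps)), key=lambda i: -hsps[i].score)
    for start in order:
        if used[start]:
            continue
        chain = [hsps[start]]
        used[start] = True
        changed = True
        while changed:
            changed = False
            for i, h in enumerate(hsps):
                if used[i]:
                    continue
                head, tail = chain[0], chain[-1]
                if (
                    h.qs > tail.qe - _CHAIN_OVERLAP_TOL
                    and h.ss > tail.se - _CHAIN_OVERLAP_TOL
                    and h.qe > tail.qe
                    and h.se > tail.se
                    and h.ss - tail.se <= _MAX_JOIN_GAP
                    and h.qs - tail.qe <= _MAX_JOIN_GAP
                ):
                    chain.append(h)
                    used[i] = True
                    changed = True
                elif (
                    h.qe < head.qs + _CHAIN_OVERLAP_TOL
                    and h.se < head.ss + _CHAIN_OVERLAP_TOL
                    and h.qs < head.qs
                    and h.ss < head.ss
                    and head.ss - h.se <= _MAX_JOIN_GAP
                    and head.qs - h.qe <= _MAX_JOIN_GAP
                ):
                    chain.insert(0, h)
                    used[i] = True
                    changed = True
        chains.append(chain)
    return chains


def local_search(
    query: SeqRecord,
    subjects: Sequence[SeqRecord],
    min_identity: float = MIN_IDENTITY_DEFAULT,
    min_hit_len: int = MIN_HIT_LEN_DEFAULT,
    word_size: int = WORD_SIZE_DEFAULT,
    completeness: float = COMPLETENESS_DEFAULT,
) -> list[HomologyHit]:
    """Seed-and-extend search of ``query`` against every subject, both strands.

    Returns chained hits sorted by descending score. ``min_identity`` and
    ``min_hit_len`` filter the chained hits; raising ``min_identity`` can
    only remove hits, never add them.
    """
    if word_size < 8:
        raise ValueError("word_size must be >= 8")
    qlen = len(query.seq)
    pad = min(qlen + 200, 4000)
    hits: list[HomologyHit] = []
    for subject in subjects:
        for strand in "+-":
            oq = query.seq if strand == "+" else revcomp(query.seq)
            hsps: list[_HSP] = []
            for lo, hi in _seed_clusters(oq, subject.seq, word_size, pad):
                hsps.extend(_extract_hsps(oq, subject.seq, lo, hi))
            for chain in _chain_hsps(hsps):
                qs = min(h.qs for h in chain)
                qe = max(h.qe for h in chain)
                ss = min(h.ss for h in chain)
                se = max(h.se for h in chain)
                matches = sum(h.matches for h in chain)
                cols = sum(h.cols for h in chain)
                score = sum(h.score for h in chain)
                identity = matches / cols if cols else 0.0
                span = qe - qs + 1
                if span < min_hit_len or identity < min_identity:
                    continue
                if strand == "+":
                    q1, q2 = qs + 1, qe + 1
                else:
                    q1, q2 = qlen - qe, qlen - qs
                cover = span / qlen
                hits.append(
                    HomologyHit(
                        query_id=query.id,
                        subject_id=subject.id,
                        subject_label=subject.label,
                        strand=strand,
                        query_start=q1,
                        query_end=q2,
                        subject_start=ss + 1,
                        subject_end=se + 1,
                        identity=identity,
                        query_cover=min(cover, 1.0),
                        subject_copy_length=se - ss + 1,
                        partial=cover < completeness,
                        score=score,
                        n_hsps=len(chain),
                    )
                )
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.subject_start))
    return hits


# ---------------------------------------------------------------------------
# gene location scan
# ---------------------------------------------------------------------------


def locate_gene(
    exon_seqs: Mapping[str, Sequence[SeqRecord]],
    assembly: Sequence[SeqRecord],
    min_identity: float = MIN_IDENTITY_DEFAULT,
    min_query_cover: float = 0.5,
    word_size: int = WORD_SIZE_DEFAULT,
) -> dict[str, list[dict]]:
    """Best location label per gene from its exon sequences.

    Each gene is represented by one or more exon records; every exon is
    searched against every subject and per-subject aggregates (length-
    weighted identity, total query cover, summed score) are ranked. Genes
    with no subject above both thresholds map to an empty list ("absent").
    """
    out: dict[str, list[dict]] = {}
    for gene, exons in exon_seqs.items():
        per_subject: dict[str, dict] = {}
        total_len = sum(len(e.seq) for e in exons)
        for exon in exons:
            hits = local_search(
                exon, assembly, min_identity=0.0 + 1e-9, min_hit_len=1,
                word_size=word_size,
            )
            best_per_subject: dict[str, HomologyHit] = {}
            for h in hits:
                if h.subject_id not in best_per_subject:
                    best_per_subject[h.subject_id] = h
            for sid, h in best_per_subject.items():
                agg = per_subject.setdefault(
                    sid,
                    {"label": h.subject_label, "score": 0, "matches": 0, "cols": 0, "covered": 0},
                )
                agg["score"] += h.score
                agg["matches"] += round(h.identity * (h.query_end - h.query_start + 1))
                agg["cols"] += h.query_end - h.query_start + 1
                agg["covered"] += h.query_end - h.query_start + 1
        rows = []
        for sid, agg in per_subject.items():
            identity = agg["matches"] / agg["cols"] if agg["cols"] else 0.0
            cover = agg["covered"] / total_len if total_len else 0.0
            if identity >= min_identity and cover >= min_query_cover:
                rows.append(
                    {
                        "subject_id": sid,
                        "label": agg["label"],
                        "identity": identity,
                        "query_cover": min(cover, 1.0),
                        "score": agg["score"],
                    }
                )
        rows.sort(key=lambda r: (-r["score"], -r["identity"], r["subject_id"]))
        out[gene] = rows
    return out


def gene_label(locations: list[dict]) -> str:
    """Top location label for one gene, or "absent"."""
    return locations[0]["label"] if locations else "absent"


def presence_matrix(
    exon_seqs: Mapping[str, Sequence[SeqRecord]],
    assembly: Sequence[SeqRecord],
    min_identity: float = MIN_IDENTITY_DEFAULT,
    min_query_cover: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x role-label presence matrix plus identity/cover annotations."""
    labels = sorted({s.label for s in assembly})
    located = locate_gene(exon_seqs, assembly, min_identity, min_query_cover)
    genes = list(exon_seqs)
    present = pd.DataFrame(False, index=genes, columns=labels)
    annot = pd.DataFrame("", index=genes, columns=labels)
    for gene, rows in located.items():
        for row in rows:
            lab = row["label"]
            if not present.loc[gene, lab]:
                present.loc[gene, lab] = True
                annot.loc[gene, lab] = (
                    f"id={row['identity']:.3f},qcov={row['query_cover']:.3f}"
                )
    return present, annot


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

_OUTFMT6 = ("qseqid", "sseqid", "pident", "length", "qstart", "qend", "sstart", "send", "qcovs")


def hits_to_tsv(hits: Iterable[HomologyHit], path: str | Path | None = None) -> str:
    """BLAST-outfmt-6-style tabular rendering of hits."""
    lines = ["\t".join(_OUTFMT6)]
    for h in hits:
        lines.append(
            "\t".join(
                [
                    h.query_id,
                    h.subject_id,
                    f"{100 * h.identity:.2f}",
                    str(h.subject_copy_length),
                    str(h.query_start),
                    str(h.query_end),
                    str(h.subject_start),
                    str(h.subject_end),
                    f"{100 * h.query_cover:.1f}",
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
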