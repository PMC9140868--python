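"""Synthetic ZW genome generator with full ground truth.

Builds small paired Z/"second-copy" sequences containing multi-exon genes,
planted degenerate-primer binding sites, gametolog copies with configurable
substitution divergence and a mid-intron indel of chosen size (the intron
length polymorphism ΔL), optional translocated decoy copies on a scaffold
and optional terminally truncated partial copies. Every planted feature is
recorded in a :class:`TruthSet` so each pipeline stage can be checked for
exact recovery without any external data.

Design guarantees:

* backgrounds are i.i.d. uniform ACGT, rejection-corrected so that no
  primer has an unintended binding site at the scanner's own mismatch
  tolerance — planted truth is therefore unique;
* substitutions never land in primer footprints, splice-site dinucleotides
  or the junction-adjacent bases that would make an exon/intron boundary
  ambiguous, so planted coordinates are exactly recoverable;
* the random stream is partitioned per output sequence, so adding a
  scaffold does not change Z or W content at a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .gene_structure import GeneModel
from .insilico_pcr import (
    MAX_MISMATCH_DEFAULT,
    THREE_PRIME_EXACT_DEFAULT,
    scan_primer,
)
from .sequence_io import (
    IUPAC_SETS,
    PrimerPair,
    SeqRecord,
    revcomp,
    write_fasta,
    write_role_map,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STREAM = {"Z": 0, "W": 1, "scaffold": 2, "misc": 3}


class SizingError(ValueError):
    """The configured genes do not fit into the configured sequence lengths."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSpec:
    """One plus-strand gene: ordered exon and intron lengths and a start offset."""

    gene_id: str
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    start: int  # 1-based coordinate of the first exon base on Z

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly one intron fewer than exons")
        if any(x <= 0 for x in self.exon_lengths + self.intron_lengths):
            raise ValueError("exon/intron lengths must be positive")
        if any(x < 4 for x in self.intron_lengths):
            raise ValueError("introns must be >= 4 bp to carry GT..AG ends")

    def exon_coords(self) -> list[tuple[int, int]]:
        coords = []
        pos = self.start
        for i, elen in enumerate(self.exon_lengths):
            coords.append((pos, pos + elen - 1))
            pos += elen
            if i < len(self.intron_lengths):
                pos += self.intron_lengths[i]
        return coords

    @property
    def end(self) -> int:
        return self.exon_coords()[-1][1]


@dataclass(frozen=True)
class MarkerSpec:
    """One marker: primer pair around one intron of one gene.

    The forward footprint ends ``fwd_tail`` bases before the upstream exon's
    end; the reverse footprint starts ``rev_head`` bases after the
    downstream exon's start. ``delta`` is the signed planted indel: positive
    means the Z intron is longer than the second copy's.
    """

    marker_id: str
    gene_id: str
    intron_index: int  # 1-based; amplicon spans exon i .. exon i+1
    fwd_seq: str
    rev_seq: str
    fwd_tail: int = 5
    rev_head: int = 5
    delta: int = 0
    fwd_mismatches: int = 0
    rev_mismatches: int = 0
    second_host: str | None = "W"  # W | scaffold | None (no second copy)
    truncate_keep_tail: int | None = None  # keep only this many 3' bases of the copy
    nonspecific_product: int | None = None  # plant an extra off-gene product of this length
    fwd_realization: str | None = None  # pin the Z-side realization of degenerate bases
    rev_realization: str | None = None


@dataclass(frozen=True)
class SimConfig:
    seed: int
    z_length: int
    w_length: int
    scaffold_length: int
    genes: tuple[GeneSpec, ...]
    markers: tuple[MarkerSpec, ...]
    gametolog_divergence: float = 0.03
    flank: int = 80

    def __post_init__(self) -> None:
        if not (0.0 <= self.gametolog_divergence <= 0.2):
            raise ValueError("divergence must lie in [0, 0.2]")
        for m in self.markers:
            gene = self.gene(m.gene_id)
            if not (1 <= m.intron_index <= len(gene.intron_lengths)):
                raise ValueError(f"{m.marker_id}: intron index out of range")
            ilen = gene.intron_lengths[m.intron_index - 1]
            if m.delta > 0 and ilen - m.delta < 1:
                raise ValueError(f"{m.marker_id}: indel leaves intron shorter than 1 bp")

    def gene(self, gene_id: str) -> GeneSpec:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthAmplicon:
    marker_id: str
    seq_id: str
    start: int
    end: int
    length: int
    composition: tuple[tuple[str, int], ...]
    fwd_pos5: int
    rev_pos5: int


@dataclass(frozen=True)
class TruthSecondCopy:
    marker_id: str
    host_id: str
    host_label: str
    length: int | None  # None when absent
    partial: bool
    delta_l: int | None
    z_longer: bool | None


@dataclass
class TruthSet:
    gene_models: dict[str, GeneModel]
    z_amplicons: dict[str, TruthAmplicon]
    second_copies: dict[str, TruthSecondCopy]
    nonspecific: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def validate(self) -> None:
        for amp in self.z_amplicons.values():
            if sum(ln for _, ln in amp.composition) != amp.length:
                raise ValueError(f"{amp.marker_id}: composition does not sum to length")
            if amp.length != amp.end - amp.start + 1:
                raise ValueError(f"{amp.marker_id}: inconsistent coordinates")
        for sc in self.second_copies.values():
            if sc.delta_l is not None:
                amp = self.z_amplicons[sc.marker_id]
                if sc.length is None or sc.partial:
                    raise ValueError(f"{sc.marker_id}: ΔL defined without complete copy")
                if sc.delta_l != abs(amp.length - sc.length):
                    raise ValueError(f"{sc.marker_id}: ΔL inconsistent")

    def to_dict(self) -> dict:
        return {
            "gene_models": {
                g: {"seq_id": m.seq_id, "strand": m.strand, "exons": list(map(list, m.exons))}
                for g, m in self.gene_models.items()
            },
            "z_amplicons": {k: asdict(v) for k, v in self.z_amplicons.items()},
            "second_copies": {k: asdict(v) for k, v in self.second_copies.items()},
            "nonspecific": {k: list(v) for k, v in self.nonspecific.items()},
        }


@dataclass
class SimResult:
    records: list[SeqRecord]
    mrnas: list[SeqRecord]
    primer_pairs: list[PrimerPair]
    role_map: dict[str, str]
    truth: TruthSet
    config: SimConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "mrna": outdir / "mrna.fasta",
            "primers": outdir / "primers.tsv",
            "roles": outdir / "roles.yaml",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.records, paths["genome"])
        write_fasta(self.mrnas, paths["mrna"])
        with open(paths["primers"], "w") as fh:
            fh.write("marker\tfwd_name\tfwd_seq\trev_name\trev_seq\tgene\n")
            for p in self.primer_pairs:
                fh.write(
                    f"{p.marker_id}\t{p.fwd_name}\t{p.fwd_seq}\t{p.rev_name}\t{p.rev_seq}\t{p.source_gene}\n"
                )
        write_role_map(self.role_map, paths["roles"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth.to_dict(), fh, indent=1, sort_keys=True)
        return paths


# ---------------------------------------------------------------------------
# sequence assembly
# ---------------------------------------------------------------------------


class _Builder:
    """Mutable sequence under construction with a protected-position mask."""

    def __init__(self, seq_id: str, length: int, rng: np.random.Generator):
        self.seq_id = seq_id
        self.rng = rng
        self.arr = _BASES[rng.integers(0, 4, length)].copy()
        self.protected = np.zeros(length, dtype=bool)

    def plant(self, start0: int, text: str, protect: bool = True) -> None:
        b = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
        if start0 < 0 or start0 + len(b) > len(self.arr):
            raise SizingError(f"{self.seq_id}: plant at {start0} overruns sequence")
        seg = slice(start0, start0 + len(b))
        clash = self.protected[seg] & (self.arr[seg] != b)
        if clash.any():
            raise ValueError(f"{self.seq_id}: conflicting plant at {start0}")
        self.arr[seg] = b
        if protect:
            self.protected[seg] = True

    def set_base_avoiding(self, pos0: int, avoid: str) -> None:
        """Ensure the (unprotected) base at pos0 differs from ``avoid``."""
        if self.protected[pos0]:
            return
        if chr(self.arr[pos0]) == avoid:
            options = [b for b in "ACGT" if b != avoid]
            self.arr[pos0] = ord(options[int(self.rng.integers(0, 3))])

    def rerandomize_window(self, start0: int, end0: int) -> bool:
        idx = np.arange(max(0, start0), min(len(self.arr), end0 + 1))
        idx = idx[~self.protected[idx]]
        if idx.size == 0:
            return False
        self.arr[idx] = _BASES[self.rng.integers(0, 4, idx.size)]
        return True

    def text(self) -> str:
        return self.arr.tobytes().decode("ascii")


def _realize(primer: str, rng: np.random.Generator, differ_from: str | None = None) -> str:
    """Pick one concrete expansion of a degenerate primer.

    With ``differ_from`` (a previous realization), degenerate positions are
    realized to a *different* expansion member where one exists, so the
    second copy exercises the degeneracy.
    """
    out = []
    for i, base in enumerate(primer):
        opts = sorted(IUPAC_SETS[base])
        if len(opts) == 1:
            out.append(opts[0])
            continue
        if differ_from is not None:
            alt = [o for o in opts if o != differ_from[i]]
            out.append(alt[int(rng.integers(0, len(alt)))] if alt else differ_from[i])
        else:
            out.append(opts[int(rng.integers(0, len(opts)))])
    return "".join(out)


def _self_clean(realized: str, primer: str) -> bool:
    """True when the realized footprint only matches its primer on the plus strand.

    A quasi-palindromic realization (easy with self-complementary codes like
    S or W) would otherwise create an unremovable minus-strand site inside
    the protected footprint.
    """
    sites = scan_primer(SeqRecord("fp", realized), primer)
    return all(s.strand == "+" for s in sites)


def _realize_checked(primer: str, rng: np.random.Generator) -> str:
    for _ in range(12):
        realized = _realize(primer, rng)
        if _self_clean(realized, primer):
            return realized
    return realized


def _mutate_footprint(
    realized: str, n: int, rng: np.random.Generator, protect_three_prime: int
) -> str:
    """Introduce n mismatches, away from the primer's 3' end."""
    if n == 0:
        return realized
    allowed = list(range(0, len(realized) - protect_three_prime))
    pos = rng.choice(len(allowed), size=n, replace=False)
    out = list(realized)
    for p in pos:
        i = allowed[int(p)]
        out[i] = [b for b in "ACGT" if b != out[i]][int(rng.integers(0, 3))]
    return "".join(out)


def _diverge(
    text: str, rate: float, rng: np.random.Generator, protected: np.ndarray
) -> str:
    arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8).copy()
    hit = (rng.random(arr.size) < rate) & ~protected
    for i in np.nonzero(hit)[0]:
        cur = chr(arr[i])
        arr[i] = ord([b for b in "ACGT" if b != cur][int(rng.integers(0, 3))])
    return arr.tobytes().decode("ascii")


def _cleanup(
    builder: _Builder,
    primer_seqs: Sequence[str],
    expected: set[tuple[str, str, int]],
    max_mismatch: int = MAX_MISMATCH_DEFAULT,
    three_prime_exact: int = THREE_PRIME_EXACT_DEFAULT,
    max_iter: int = 40,
) -> None:
    """Remove unintended primer binding sites by re-randomizing background."""
    for _ in range(max_iter):
        rec = SeqRecord(builder.seq_id, builder.text())
        bad = []
        for p in set(primer_seqs):
            for site in scan_primer(rec, p, max_mismatch, three_prime_exact):
                if (p, site.strand, site.pos5) not in expected:
                    bad.append(site)
        if not bad:
            return
        progress = False
        for site in bad:
            progress |= builder.rerandomize_window(site.start - 1, site.end - 1)
        if not progress:
            raise RuntimeError(
                f"{builder.seq_id}: unintended primer site overlaps protected bases"
            )
    raise RuntimeError(f"{builder.seq_id}: primer-site cleanup did not converge")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _rng_for(cfg_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg_seed, _STREAM[stream]]))


def generate(cfg: SimConfig) -> SimResult:
    """Deterministically build the configured Z/W/scaffold sequences + truth."""
    for g in cfg.genes:
        if g.end + cfg.flank > cfg.z_length:
            raise SizingError(f"gene {g.gene_id} does not fit into z_length={cfg.z_length}")

    z = _Builder("Z_SYN", cfg.z_length, _rng_for(cfg.seed, "Z"))
    w = _Builder("W_SYN", cfg.w_length, _rng_for(cfg.seed, "W"))
    scaf = _Builder("SCAF_SYN", cfg.scaffold_length, _rng_for(cfg.seed, "scaffold"))
    misc_rng = _rng_for(cfg.seed, "misc")
    hosts = {"W": w, "scaffold": scaf}
    role_map = {"Z_SYN": "Z", "W_SYN": "W", "SCAF_SYN": "scaffold"}

    expected: dict[str, set[tuple[str, str, int]]] = {
        b.seq_id: set() for b in (z, w, scaf)
    }
    all_primers = [s for m in cfg.markers for s in (m.fwd_seq, m.rev_seq)]

    exon_coords: dict[str, list[tuple[int, int]]] = {
        g.gene_id: g.exon_coords() for g in cfg.genes
    }

    # --- primer planting on Z
    z_real: dict[str, tuple[str, str, int, int]] = {}  # marker -> (fwd_real, rev_real, fpos0, rpos0)
    truth_amp: dict[str, TruthAmplicon] = {}
    truth_ns: dict[str, tuple[int, ...]] = {}
    for m in cfg.markers:
        gene = cfg.gene(m.gene_id)
        coords = exon_coords[m.gene_id]
        e_up = coords[m.intron_index - 1]
        e_dn = coords[m.intron_index]
        ilen = gene.intron_lengths[m.intron_index - 1]
        flen, rlen = len(m.fwd_seq), len(m.rev_seq)
        if flen + m.fwd_tail > e_up[1] - e_up[0] + 1:
            raise SizingError(f"{m.marker_id}: upstream exon too short for primer+tail")
        if rlen + m.rev_head > e_dn[1] - e_dn[0] + 1:
            raise SizingError(f"{m.marker_id}: downstream exon too short for primer+head")
        fwd_real = m.fwd_realization or _realize_checked(m.fwd_seq, misc_rng)
        rev_real = m.rev_realization or _realize_checked(m.rev_seq, misc_rng)
        fwd_plant = _mutate_footprint(fwd_real, m.fwd_mismatches, misc_rng, THREE_PRIME_EXACT_DEFAULT)
        rev_plant = _mutate_footprint(rev_real, m.rev_mismatches, misc_rng, THREE_PRIME_EXACT_DEFAULT)
        fpos0 = e_up[1] - (flen + m.fwd_tail)  # 0-based footprint start
        rpos0 = e_dn[0] - 1 + m.rev_head  # 0-based footprint start
        z.plant(fpos0, fwd_plant)
        z.plant(rpos0, revcomp(rev_plant))
        expected["Z_SYN"].add((m.fwd_seq, "+", fpos0 + 1))
        expected["Z_SYN"].add((m.rev_seq, "-", rpos0 + rlen))
        z_real[m.marker_id] = (fwd_real, rev_real, fpos0, rpos0)
        start1 = fpos0 + 1
        end1 = rpos0 + rlen
        up_num = m.intron_index
        comp = (
            (f"E{up_num}", flen + m.fwd_tail),
            (f"I{up_num}", ilen),
            (f"E{up_num + 1}", rlen + m.rev_head),
        )
        truth_amp[m.marker_id] = TruthAmplicon(
            m.marker_id, "Z_SYN", start1, end1, end1 - start1 + 1, comp, start1, end1
        )
        if m.nonspecific_product is not None:
            _plant_nonspecific(z, m, fwd_real, rev_real, cfg, expected["Z_SYN"], misc_rng)
            truth_ns[m.marker_id] = (m.nonspecific_product,)

    # --- splice-site dinucleotides and unambiguous junction edges (after the
    # primers: a footprint flush with a junction keeps its own bases, and the
    # GT..AG preference then disambiguates the boundary)
    for g in cfg.genes:
        coords = exon_coords[g.gene_id]
        for (_, e1e), (e2s, _) in zip(coords, coords[1:]):
            z.plant(e1e, "GT")  # 0-based first intron base == 1-based exon end
            z.plant(e2s - 3, "AG")  # last two intron bases
            z.set_base_avoiding(e1e - 1, "G")  # exon's last base
            z.set_base_avoiding(e2s - 1, "G")  # next exon's first base
            z.protected[e1e - 1] = True
            z.protected[e2s - 1] = True

    _cleanup(z, all_primers, expected["Z_SYN"])
    z_text = z.text()

    # --- gene models + mRNAs from the finished Z
    models: dict[str, GeneModel] = {}
    mrnas: list[SeqRecord] = []
    for g in cfg.genes:
        model = GeneModel(g.gene_id, "Z_SYN", "+", tuple(exon_coords[g.gene_id]))
        models[g.gene_id] = model
        mrnas.append(SeqRecord(f"{g.gene_id}_mRNA", model.spliced_sequence(SeqRecord("Z_SYN", z_text))))

    # --- second copies, grouped per (gene, intron) so nested markers share one indel
    groups: dict[tuple[str, int], list[MarkerSpec]] = {}
    for m in cfg.markers:
        if m.second_host is not None:
            groups.setdefault((m.gene_id, m.intron_index), []).append(m)
    truth_second: dict[str, TruthSecondCopy] = {}
    cursor = {"W": 60, "scaffold": 60}
    w_rng = _rng_for(cfg.seed + 1, "W")
    for (gene_id, intron_idx), members in sorted(groups.items()):
        deltas = {m.delta for m in members}
        hosts_used = {m.second_host for m in members}
        if len(deltas) != 1 or len(hosts_used) != 1:
            raise ValueError("markers sharing an intron must share delta and host")
        delta = deltas.pop()
        host_name = hosts_used.pop()
        host = hosts[host_name]
        gene = cfg.gene(gene_id)
        coords = exon_coords[gene_id]
        ilen = gene.intron_lengths[intron_idx - 1]
        intron_start0 = coords[intron_idx - 1][1]  # 0-based first intron base
        outer_start0 = min(z_real[m.marker_id][2] for m in members)
        outer_end0 = max(z_real[m.marker_id][3] + len(m.rev_seq) - 1 for m in members)
        reg_start0 = max(0, outer_start0 - cfg.flank)
        reg_end0 = min(len(z_text) - 1, outer_end0 + cfg.flank)
        region = z_text[reg_start0 : reg_end0 + 1]
        cut = intron_start0 - reg_start0 + ilen // 2  # region-relative indel point
        if delta > 0:
            del_lo = cut - delta // 2
            copy = region[:del_lo] + region[cut + (delta - delta // 2) :]
            shift_after = -delta
        elif delta < 0:
            ins = _BASES[w_rng.integers(0, 4, -delta)].tobytes().decode()
            copy = region[:cut] + ins + region[cut:]
            del_lo = cut
            shift_after = -delta
        else:
            copy = region
            del_lo = cut
            shift_after = 0

        def in_copy(zpos0: int) -> int:
            rel = zpos0 - reg_start0
            return rel if rel < del_lo else rel + shift_after

        # protected footprint mask within the copy + re-realized degenerate bases
        mask = np.zeros(len(copy), dtype=bool)
        copy_arr = np.frombuffer(copy.encode("ascii"), dtype=np.uint8).copy()
        fp_info = []  # (marker, fstart_rel, rstart_rel)
        for m in members:
            fwd_real, rev_real, fpos0, rpos0 = z_real[m.marker_id]
            fwd2 = _protect_ends(_realize(m.fwd_seq, w_rng, differ_from=fwd_real), fwd_real)
            rev2 = _protect_ends(_realize(m.rev_seq, w_rng, differ_from=rev_real), rev_real)
            # a re-realization that self-matches on the minus strand would be
            # an unremovable spurious site: fall back to the Z realization
            if not _self_clean(fwd2, m.fwd_seq):
                fwd2 = fwd_real
            if not _self_clean(rev2, m.rev_seq):
                rev2 = rev_real
            f_rel = in_copy(fpos0)
            r_rel = in_copy(rpos0)
            copy_arr[f_rel : f_rel + len(fwd2)] = np.frombuffer(fwd2.encode(), np.uint8)
            rc = revcomp(rev2)
            copy_arr[r_rel : r_rel + len(rc)] = np.frombuffer(rc.encode(), np.uint8)
            mask[f_rel : f_rel + len(fwd2)] = True
            mask[r_rel : r_rel + len(rc)] = True
            fp_info.append((m, f_rel, r_rel))
        copy = _diverge(copy_arr.tobytes().decode("ascii"), cfg.gametolog_divergence, w_rng, mask)

        truncate_tail = {m.truncate_keep_tail for m in members}
        keep_tail = truncate_tail.pop() if len(truncate_tail) == 1 else None
        amp_start_rel = min(f for _, f, _ in fp_info)
        if keep_tail is not None:
            # keep only the 3' tail of the *amplicon* copy, placed at the host start
            amp_end_rel = max(r + len(mm.rev_seq) - 1 for mm, _, r in fp_info)
            kept_from = amp_end_rel - keep_tail + 1
            placed = copy[kept_from : amp_end_rel + 1]
            host.plant(0, placed, protect=False)
            host.protected[: len(placed)] |= mask[kept_from : amp_end_rel + 1]
            for mm, f_rel, r_rel in fp_info:
                # register footprints that survived the truncation
                if f_rel >= kept_from:
                    expected[host.seq_id].add((mm.fwd_seq, "+", f_rel - kept_from + 1))
                if r_rel >= kept_from:
                    expected[host.seq_id].add(
                        (mm.rev_seq, "-", r_rel - kept_from + len(mm.rev_seq))
                    )
                truth_second[mm.marker_id] = TruthSecondCopy(
                    mm.marker_id, host.seq_id, host_name, keep_tail, True, None, None
                )
        else:
            host_pos0 = cursor[host_name]
            if host_pos0 + len(copy) + 60 > len(host.arr):
                raise SizingError(f"{host.seq_id} too short for second copies")
            # protect only the footprints: cleanup may then repair any
            # divergence-created spurious primer site inside the copy body
            host.plant(host_pos0, copy, protect=False)
            host.protected[host_pos0 : host_pos0 + len(copy)] |= mask
            cursor[host_name] = host_pos0 + len(copy) + 60
            for m, f_rel, r_rel in fp_info:
                expected[host.seq_id].add((m.fwd_seq, "+", host_pos0 + f_rel + 1))
                expected[host.seq_id].add((m.rev_seq, "-", host_pos0 + r_rel + len(m.rev_seq)))
                zlen = truth_amp[m.marker_id].length
                clen = zlen - delta
                dl = abs(delta)
                truth_second[m.marker_id] = TruthSecondCopy(
                    m.marker_id, host.seq_id, host_name, clen, False,
                    dl if dl else 0, (delta > 0) if delta else None,
                )

    for m in cfg.markers:
        if m.second_host is None:
            truth_second[m.marker_id] = TruthSecondCopy(
                m.marker_id, "", "absent", None, False, None, None
            )

    _cleanup(w, all_primers, expected["W_SYN"])
    _cleanup(scaf, all_primers, expected["SCAF_SYN"])

    records = [
        SeqRecord("Z_SYN", z_text, "Z"),
        SeqRecord("W_SYN", w.text(), "W"),
        SeqRecord("SCAF_SYN", scaf.text(), "scaffold"),
    ]
    pairs = [
        PrimerPair(m.marker_id, f"{m.marker_id}-F", m.fwd_seq, f"{m.marker_id}-R", m.rev_seq, m.gene_id)
        for m in cfg.markers
    ]
    truth = TruthSet(models, truth_amp, truth_second, truth_ns)
    truth.validate()
    return SimResult(records, mrnas, pairs, role_map, truth, cfg)


def _protect_ends(realized: str, z_realized: str, guard: int = 8) -> str:
    """Keep the first/last ``guard`` bases identical to the Z realization.

    Alignment end-points define the measured copy length, so the copy's
    terminal footprint bases must match the query over a run long enough
    that local alignment never trims the ends (a mismatch within the last
    few bases would leave a non-positive suffix score and clip the span).
    """
    out = list(realized)
    out[:guard] = z_realized[:guard]
    out[len(out) - guard :] = z_realized[len(out) - guard :]
    return "".join(out)


def _plant_nonspecific(
    z: _Builder,
    m: MarkerSpec,
    fwd_real: str,
    rev_real: str,
    cfg: SimConfig,
    expected: set[tuple[str, str, int]],
    rng: np.random.Generator,
) -> int:
    """Plant an extra off-gene product of the configured length on Z."""
    length = m.nonspecific_product
    gene = cfg.gene(m.gene_id)
    assert length is not None
    if length < len(fwd_real) + len(rev_real) + 10:
        raise SizingError(f"{m.marker_id}: nonspecific product too short")
    start0 = gene.end + 3 * cfg.flank
    if start0 + length > cfg.z_length - 20:
        start0 = 10
        if start0 + length > min(gene.start - 20, cfg.z_length):
            raise SizingError(f"{m.marker_id}: no room for nonspecific product")
    z.plant(start0, fwd_real)
    rstart0 = start0 + length - len(rev_real)
    z.plant(rstart0, revcomp(rev_real))
    expected.add((m.fwd_seq, "+", start0 + 1))
    expected.add((m.rev_seq, "-", rstart0 + len(rev_real)))
    return start0


def sim_config_to_yaml(cfg: SimConfig, path: str | Path | None = None) -> str:
    """Serialize a simulation configuration as YAML."""
    import yaml

    data = asdict(cfg)
    text = yaml.safe_dump(json.loads(json.dumps(data)), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def sim_config_from_yaml(path: str | Path) -> SimConfig:
    import yaml

    with open(Path(path)) as fh:
        data = yaml.safe_load(fh)
    genes = tuple(
        GeneSpec(g["gene_id"], tuple(g["exon_lengths"]), tuple(g["intron_lengths"]), g["start"])
        for g in data.pop("genes")
    )
    markers = tuple(MarkerSpec(**m) for m in data.pop("markers"))
    return SimConfig(genes=genes, markers=markers, **data)


# ---------------------------------------------------------------------------
# random study-like configurations
# ---------------------------------------------------------------------------

_DEGEN = "RYSWKM"


def _random_primer(rng: np.random.Generator, n_degenerate: int) -> str:
    length = int(rng.integers(18, 25))
    primer = ["ACGT"[int(i)] for i in rng.integers(0, 4, length)]
    if n_degenerate:
        # keep position 0 and the exact 3' window concrete
        slots = rng.choice(
            np.arange(1, length - THREE_PRIME_EXACT_DEFAULT), size=n_degenerate, replace=False
        )
        for s in slots:
            primer[int(s)] = _DEGEN[int(rng.integers(0, len(_DEGEN)))]
    return "".join(primer)


def random_config(
    seed: int,
    delta: int | None = None,
    divergence: float | None = None,
    second_host: str = "W",
    truncate: bool = False,
    nonspecific_product: int | None = None,
) -> SimConfig:
    """A random single-gene, single-marker study condition.

    Genes have 3-6 exons; the amplified intron is sized to accommodate the
    planted signed ΔL (drawn from ±[1, 3000] when not given); divergence is
    uniform on [0, 0.05]; primers are planted exactly, with 0-2 degenerate
    positions each.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9]))
    n_exons = int(rng.integers(3, 7))
    target_intron = int(rng.integers(1, n_exons))
    if delta is None:
        delta = int(rng.integers(1, 3001)) * (1 if rng.random() < 0.5 else -1)
    if divergence is None:
        divergence = float(rng.uniform(0.0, 0.05))
    fwd = _random_primer(rng, int(rng.integers(0, 3)))
    rev = _random_primer(rng, int(rng.integers(0, 3)))
    fwd_tail = int(rng.integers(1, 26))
    rev_head = int(rng.integers(1, 26))
    exon_lengths = []
    for i in range(n_exons):
        base = int(rng.integers(40, 200))
        if i == target_intron - 1:
            base = max(base, len(fwd) + fwd_tail + 2)
        if i == target_intron:
            base = max(base, len(rev) + rev_head + 2)
        exon_lengths.append(base)
    intron_lengths = []
    for i in range(n_exons - 1):
        if i == target_intron - 1:
            intron_lengths.append(max(0, delta) + int(rng.integers(60, 300)))
        else:
            intron_lengths.append(int(rng.integers(80, 400)))
    start = int(rng.integers(150, 400))
    gene = GeneSpec("geneA", tuple(exon_lengths), tuple(intron_lengths), start)
    z_length = gene.end + int(rng.integers(200, 500))
    if nonspecific_product is not None:
        z_length += nonspecific_product + 400  # room for the off-gene plant
    marker = MarkerSpec(
        "MX",
        "geneA",
        target_intron,
        fwd,
        rev,
        fwd_tail=fwd_tail,
        rev_head=rev_head,
        delta=delta,
        second_host=second_host,
        truncate_keep_tail=None,
        nonspecific_product=nonspecific_product,
    )
    amp_len = len(fwd) + fwd_tail + intron_lengths[target_intron - 1] + rev_head + len(rev)
    copy_len = amp_len - delta
    w_length = copy_len + 2 * 80 + 300
    if truncate:
        keep = max(60, int(0.6 * amp_len))
        marker = MarkerSpec(
            "MX", "geneA", target_intron, fwd, rev,
            fwd_tail=fwd_tail, rev_head=rev_head, delta=delta,
            second_host="scaffold", truncate_keep_tail=keep,
        )
    return SimConfig(
        seed=seed,
        z_length=z_length,
        w_length=w_length,
        scaffold_length=max(1200, copy_len + 500),
        genes=(gene,),
        markers=(marker,),
        gametolog_divergence=divergence,
    )


# ---------------------------------------------------------------------------
# worked-example fixtures
# ---------------------------------------------------------------------------

_P8_REAL = "CTCCCAAGGATGAGAAACTG"  # R->A, Y->C realization of P8


def _panel() -> dict[str, PrimerPair]:
    from .sequence_io import read_primer_table

    return {p.marker_id: p for p in read_primer_table()}


@lru_cache(maxsize=1)
def paper_fixture() -> SimResult:
    """Deterministic worked-example fixture for the published marker panel.

    A 70.5 kb synthetic Z carries a 23-exon CHD1-like gene and an 18-exon
    NIPBL-like gene laid out so that the panel's primer footprints fall at
    the study's reported coordinates (e.g. the M1 product spans
    43,167-43,533 = 367 bp = E22 30 bp / I22 185 bp / E23 152 bp and the M7
    product spans 68,920-69,842 = 923 bp = E17 54 / I17 801 / E18 68).
    Second copies carry the reported female second-copy lengths: intron-22
    markers +11 bp and intron-9/16 markers −2374/−43 bp on a scaffold-37-like
    decoy, and the NIPBL marker −413 bp (510 bp copy) on the W. The SPIN
    marker has no planted site anywhere, mirroring its unknown location.
    """
    panel = _panel()
    chd1 = GeneSpec(
        "CHD1",
        exon_lengths=tuple([150] * 22 + [200]),
        intron_lengths=(
            200, 200, 200, 200, 200, 200, 200, 200,  # i1-i8
            2852,                                     # i9
            900, 900, 900, 900, 900,                  # i10-i14
            641,                                      # i15
            335,                                      # i16
            700, 700, 700, 700,                       # i17-i20
            726,                                      # i21
            185,                                      # i22
        ),
        start=26443,
    )
    nipbl = GeneSpec(
        "NIPBL",
        exon_lengths=tuple([120] * 17 + [150]),
        intron_lengths=tuple([150] * 16 + [801]),
        start=64534,
    )

    def mk(marker, gene, intron, fwd, rev, tail, head, delta, host, fwd_realization=None):
        p = panel[marker]
        fwd_seq = p.fwd_seq if fwd == "fwd" else p.rev_seq
        rev_seq = p.rev_seq if rev == "rev" else p.fwd_seq
        return MarkerSpec(
            marker, gene, intron, fwd_seq, rev_seq,
            fwd_tail=tail, rev_head=head, delta=delta, second_host=host,
            fwd_realization=fwd_realization,
        )

    markers = (
        # left primer on the plus strand is P8 (R/Y realized as A/C); right is P2
        mk("M1", "CHD1", 22, "rev", "fwd", 10, 132, -11, "scaffold", _P8_REAL),
        # left primer is the 19-mer 1237L, flush with the exon-22 end; right is 1272H
        mk("M2", "CHD1", 22, "rev", "fwd", 0, 34, -11, "scaffold"),
        mk("M3", "CHD1", 9, "fwd", "rev", 22, 79, 2374, "scaffold"),
        mk("M4", "CHD1", 16, "fwd", "rev", 91, 36, 43, "scaffold"),
        mk("M5", "CHD1", 16, "fwd", "rev", 56, 31, 43, "scaffold"),
        mk("M7", "NIPBL", 17, "fwd", "rev", 32, 45, 413, "W"),
    )
    cfg = SimConfig(
        seed=20220523,
        z_length=70500,
        w_length=2400,
        scaffold_length=9000,
        genes=(chd1, nipbl),
        markers=markers,
        gametolog_divergence=0.03,
        flank=80,
    )
    result = generate(cfg)
    # restore the published primer names and the never-located SPIN marker
    result.primer_pairs = [p for _, p in sorted(_panel().items())]
    return result


@lru_cache(maxsize=1)
def equal_copies_fixture() -> SimResult:
    """Two-scaffold fixture with equal-length (ΔL = 0) intron-22 copies.

    Emulates an assembly where both copies of the M1/M2 region are 364 and
    255 bp (intron 182 bp) on different scaffolds. The copy hosting the
    reference amplicon is labelled Z in the role map purely so the pairing
    machinery has a reference side.
    """
    panel = _panel()
    gene = GeneSpec("CHD1", (300, 300), (182,), 401)
    markers = (
        MarkerSpec("M1", "CHD1", 1, panel["M1"].rev_seq, panel["M1"].fwd_seq,
                   fwd_tail=10, rev_head=132, delta=0, second_host="scaffold",
                   fwd_realization=_P8_REAL),
        MarkerSpec("M2", "CHD1", 1, panel["M2"].rev_seq, panel["M2"].fwd_seq,
                   fwd_tail=0, rev_head=34, delta=0, second_host="scaffold"),
    )
    cfg = SimConfig(
        seed=13399495,
        z_length=1600,
        w_length=300,
        scaffold_length=1200,
        genes=(gene,),
        markers=markers,
        gametolog_divergence=0.02,
    )
    return generate(cfg)


@lru_cache(maxsize=1)
def truncated_copy_fixture() -> SimResult:
    """Fixture with a terminally truncated second copy of a 923 bp product.

    The scaffold carries only the last 526 bases of the 923 bp amplicon
    (query positions 398-923) at its very start — an incomplete longer
    version, not a shorter variant, so no ΔL can be measured from it.
    """
    panel = _panel()
    gene = GeneSpec("NIPBL", (400, 400), (801,), 301)
    markers = (
        MarkerSpec("M7", "NIPBL", 1, panel["M7"].fwd_seq, panel["M7"].rev_seq,
                   fwd_tail=32, rev_head=45, delta=0, second_host="scaffold",
                   truncate_keep_tail=526),
    )
    cfg = SimConfig(
        seed=13396815,
        z_length=2400,
        w_length=300,
        scaffold_length=1255,
        genes=(gene,),
        markers=markers,
        gametolog_divergence=0.03,
    )
    return generate(cfg)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


def recovery_report(pipeline_result, truth: TruthSet) -> dict:
    """Exact-match comparison of a pipeline run against planted truth.

    Checks gene models (exon coordinates), the diagnostic Z amplicon
    (coordinates, length, composition), ΔL with direction, partial flags
    and second-copy location labels. Returns per-stage counts plus an
    overall exact-recovery fraction.
    """
    checks: list[tuple[str, bool, str]] = []

    for gid, tmodel in truth.gene_models.items():
        omodel = pipeline_result.gene_models.get(gid)
        ok = omodel is not None and tuple(omodel.exons) == tuple(tmodel.exons)
        checks.append(("gene_model", ok, gid))

    for mid, tamp in truth.z_amplicons.items():
        oamp = pipeline_result.diagnostic_amplicons.get(mid)
        ok = (
            oamp is not None
            and (oamp.start, oamp.end, oamp.length) == (tamp.start, tamp.end, tamp.length)
            and tuple(oamp.composition) == tuple(tamp.composition)
        )
        checks.append(("z_amplicon", ok, mid))

    for mid, tsc in truth.second_copies.items():
        rep = pipeline_result.copy_reports.get(mid)
        if rep is None:
            checks.append(("copy_pair", tsc.host_label == "absent", mid))
            continue
        if tsc.host_label == "absent":
            ok = rep.second_location == "absent"
        elif tsc.partial:
            ok = rep.second_partial and rep.delta_l is None
        else:
            ok = (
                not rep.second_partial
                and rep.delta_l == tsc.delta_l
                and rep.z_longer == tsc.z_longer
                and rep.second_location == tsc.host_label
                and rep.second_length == tsc.length
            )
        checks.append(("copy_pair", ok, mid))

    stages: dict[str, dict[str, int]] = {}
    mismatches = []
    for stage, ok, label in checks:
        st = stages.setdefault(stage, {"n": 0, "exact": 0})
        st["n"] += 1
        st["exact"] += int(ok)
        if not ok:
            mismatches.append(f"{stage}:{label}")
    total = len(checks)
    exact = sum(1 for _, ok, _ in checks if ok)
    return {
        "stages": stages,
        "n_checks": total,
        "n_exact": exact,
        "recovery": exact / total if total else 1.0,
        "mismatches": mismatches,
    }
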