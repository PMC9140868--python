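"""Sequence and table I/O plus nucleotide-alphabet utilities.

Everything downstream (spliced mapping, in-silico PCR, homology search)
operates on plain uppercase DNA strings held in :class:`SeqRecord` objects.
Genome/mRNA sequences live on the {A,C,G,T,N} alphabet; primers may use the
full 15-letter IUPAC code. Sequence role labels (Z / W / scaffold) are never
taken from FASTA headers — assemblies disagree wildly on naming — but from a
sidecar YAML role map ``{accession: Z|W|scaffold}``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: Expansion of every IUPAC nucleotide code into the concrete bases it stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)
GENOME_ALPHABET = frozenset("ACGTN")

VALID_ROLES = ("Z", "W", "scaffold", "unknown")


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


def _check_alphabet(seq: str, alphabet: frozenset[str], what: str) -> None:
    bad = set(seq) - alphabet
    if bad:
        raise FormatError(f"{what}: illegal character(s) {sorted(bad)!r}")


@dataclass(frozen=True)
class SeqRecord:
    """One named DNA sequence with an optional chromosomal role label.

    ``label`` is one of ``Z``, ``W``, ``scaffold`` or ``unknown`` and is
    assigned from a role map, not parsed from the sequence id.
    """

    id: str
    seq: str
    label: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("SeqRecord id must be non-empty")
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.label not in VALID_ROLES:
            raise FormatError(f"record {self.id!r}: bad role label {self.label!r}")
        _check_alphabet(self.seq, IUPAC_ALPHABET, f"record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def with_label(self, label: str) -> "SeqRecord":
        return SeqRecord(self.id, self.seq, label)


@dataclass(frozen=True)
class PrimerPair:
    """A named marker with IUPAC-degenerate forward/reverse primers."""

    marker_id: str
    fwd_name: str
    fwd_seq: str
    rev_name: str
    rev_seq: str
    source_gene: str = ""

    def __post_init__(self) -> None:
        for name, seq in ((self.fwd_name, self.fwd_seq), (self.rev_name, self.rev_seq)):
            if not seq:
                raise FormatError(f"primer {name!r} ({self.marker_id}): empty sequence")
            _check_alphabet(seq, IUPAC_ALPHABET, f"primer {name!r} ({self.marker_id})")


def _normalize(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    _check_alphabet(seq, IUPAC_ALPHABET, f"record {record_id!r}")
    if not seq:
        raise FormatError(f"record {record_id!r}: empty sequence")
    return seq


def read_fasta(path: str | Path, role_map: Mapping[str, str] | None = None) -> list[SeqRecord]:
    """Read a multi-record FASTA file into :class:`SeqRecord` objects.

    Sequences are uppercased, ``U`` is mapped to ``T``, and any character
    outside the IUPAC nucleotide alphabet is rejected. Duplicate ids are an
    error. ``role_map`` optionally assigns Z/W/scaffold labels by id.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        label = (role_map or {}).get(rec.id, "unknown")
        records.append(SeqRecord(rec.id, _normalize(str(rec.seq), rec.id), label))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write records as FASTA with 60-column line wrapping."""
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


_PRIMER_COLUMNS = ("marker", "fwd_name", "fwd_seq", "rev_name", "rev_seq", "gene")


def read_primer_table(path: str | Path | None = None) -> list[PrimerPair]:
    """Read a primer table TSV; with no path, the packaged marker panel.

    The packaged panel is the seven-marker M1–M7 set (CHD1 introns 22, 9 and
    16, the SPIN W marker, and the NIPBL intron amplified by the i16 primer
    pair), fourteen primers in total.
    """
    if path is None:
        text = resources.files("zwmarker.data").joinpath("primers.tsv").read_text()
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_PRIMER_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"primer table: missing column(s) {sorted(missing)}")
    pairs: list[PrimerPair] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.marker in seen:
            raise FormatError(f"primer table: duplicate marker id {row.marker!r}")
        seen.add(row.marker)
        pairs.append(
            PrimerPair(
                marker_id=row.marker,
                fwd_name=row.fwd_name,
                fwd_seq=str(row.fwd_seq).upper(),
                rev_name=row.rev_name,
                rev_seq=str(row.rev_seq).upper(),
                source_gene=row.gene,
            )
        )
    return pairs


def load_role_map(path: str | Path) -> dict[str, str]:
    """Load a sequence-role YAML map ``{accession: Z|W|scaffold}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: role map must be a mapping")
    out: dict[str, str] = {}
    for key, val in raw.items():
        if val not in VALID_ROLES:
            raise FormatError(f"{path}: bad role {val!r} for {key!r}")
        out[str(key)] = str(val)
    return out


def write_role_map(role_map: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(role_map), fh, sort_keys=True)


def revcomp(seq: str) -> str:
    """Reverse complement honoring the full IUPAC alphabet (R<->Y, M<->K, ...)."""
    _check_alphabet(seq, IUPAC_ALPHABET, "revcomp input")
    return str(Seq(seq).reverse_complement())


def read_species_table() -> pd.DataFrame:
    """Packaged study-species metadata (designations S1-S14, sample counts)."""
    text = resources.files("zwmarker.data").joinpath("species.tsv").read_text()
    return pd.read_csv(io.StringIO(text), sep="\t", dtype={"designation": str})
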