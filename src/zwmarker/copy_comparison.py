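"""Pairing a Z-specific amplicon with its second genomic copy.

The second copy of a sexing amplicon — the gametolog on the W chromosome,
or a translocated/ambiguously assembled copy on a scaffold — is chosen from
homology hits on non-Z sequences. Its length is the subject-side alignment
span (indel-inclusive), because what matters for a gel is the full genomic
copy length, not the number of aligned columns. The intron length
polymorphism ΔL is the absolute length difference between the two copies;
it is undefined when the second copy is absent or only partially present
(a truncated fragment is an incomplete longer copy, not a short variant,
so extrapolating a ΔL from it would be wrong).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .homology_search import HomologyHit
from .insilico_pcr import AmpliconHit

_LOCATION_PRIORITY = {"W": 0, "scaffold": 1, "unknown": 2, "Z": 3}


@dataclass(frozen=True)
class CopyPairReport:
    """Z copy vs second copy of one marker in one genome/species."""

    marker_id: str
    species_id: str
    z_seq_id: str
    z_length: int
    second_seq_id: str | None  # None when absent
    second_length: int | None  # subject-side span; None when absent
    second_partial: bool
    second_location: str  # Z|W|scaffold|unknown|absent
    delta_l: int | None  # |z - second|, None when absent/partial
    z_longer: bool | None
    identity: float | None = None
    query_cover: float | None = None

    def __post_init__(self) -> None:
        if self.delta_l is not None:
            if self.second_length is None or self.second_partial:
                raise ValueError("delta_l defined without a complete second copy")
            if self.delta_l != abs(self.z_length - self.second_length):
                raise ValueError("delta_l inconsistent with copy lengths")


def pair_copies(
    z_amplicon: AmpliconHit,
    hits: Sequence[HomologyHit],
    role_map: Mapping[str, str] | None = None,
    species_id: str = "",
) -> CopyPairReport:
    """Build a copy-pair report from a Z amplicon and its homology hits.

    The best non-Z hit by identity x query_cover becomes the second copy;
    when several tie, a W-labeled subject is preferred over a scaffold, then
    higher identity. Partial hits are reported but excluded from ΔL.
    """
    role_map = dict(role_map or {})

    def role_of(hit: HomologyHit) -> str:
        return role_map.get(hit.subject_id, hit.subject_label)

    candidates = [h for h in hits if role_of(h) != "Z"]
    if not candidates:
        return CopyPairReport(
            marker_id=z_amplicon.marker_id,
            species_id=species_id,
            z_seq_id=z_amplicon.seq_id,
            z_length=z_amplicon.length,
            second_seq_id=None,
            second_length=None,
            second_partial=False,
            second_location="absent",
            delta_l=None,
            z_longer=None,
        )
    candidates.sort(
        key=lambda h: (
            -(h.identity * h.query_cover),
            _LOCATION_PRIORITY.get(role_of(h), 2),
            -h.identity,
            h.subject_id,
        )
    )
    best = candidates[0]
    location = role_of(best)
    if best.partial:
        delta = None
        z_longer = None
    else:
        delta = abs(z_amplicon.length - best.subject_copy_length)
        z_longer = z_amplicon.length > best.subject_copy_length if delta else None
    return CopyPairReport(
        marker_id=z_amplicon.marker_id,
        species_id=species_id,
        z_seq_id=z_amplicon.seq_id,
        z_length=z_amplicon.length,
        second_seq_id=best.subject_id,
        second_length=best.subject_copy_length,
        second_partial=best.partial,
        second_location=location,
        delta_l=delta,
        z_longer=z_longer,
        identity=best.identity,
        query_cover=best.query_cover,
    )


def species_summary(reports: Iterable[CopyPairReport]) -> pd.DataFrame:
    """One row per (species, marker, copy), stably ordered.

    Partial copies are rendered with a ``(p)`` flag on both accession and
    length, mirroring how incomplete fragments are customarily reported.
    """
    rows = []
    for rep in sorted(reports, key=lambda r: (r.species_id, r.marker_id)):
        rows.append(
            {
                "species": rep.species_id,
                "marker": rep.marker_id,
                "copy": "Z",
                "accession": rep.z_seq_id,
                "length": str(rep.z_length),
                "location": "Z",
            }
        )
        if rep.second_seq_id is None:
            acc, length = "-", "-"
        elif rep.second_partial:
            acc = f"{rep.second_seq_id}(p)"
            length = f"{rep.second_length}(p)"
        else:
            acc, length = rep.second_seq_id, str(rep.second_length)
        rows.append(
            {
                "species": rep.species_id,
                "marker": rep.marker_id,
                "copy": "second",
                "accession": acc,
                "length": length,
                "location": rep.second_location,
            }
        )
    return pd.DataFrame(rows, columns=["species", "marker", "copy", "accession", "length", "location"])


def report_to_dict(rep: CopyPairReport) -> dict:
    """JSON-friendly rendering of a report."""
    return {
        "marker": rep.marker_id,
        "species": rep.species_id,
        "z": {"seq_id": rep.z_seq_id, "length": rep.z_length},
        "second": None
        if rep.second_seq_id is None
        else {
            "seq_id": rep.second_seq_id,
            "length": rep.second_length,
            "partial": rep.second_partial,
            "location": rep.second_location,
            "identity": rep.identity,
            "query_cover": rep.query_cover,
        },
        "delta_l": rep.delta_l,
        "z_longer": rep.z_longer,
    }
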