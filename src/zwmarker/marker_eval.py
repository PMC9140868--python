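"""Per-marker sexing verdicts and per-individual sex calls.

A marker is *informative* for a species only when both copies exist in
full, their length difference is resolvable on some standard gel, and no
nonspecific product lands in the diagnostic band window. The sex-call rule
is deliberately asymmetric: two separable sex-linked bands always mean
female, but a single band means male only under an informative verdict —
otherwise a missing W band (absent gametolog, unresolvable polymorphism,
degraded template) would be indistinguishable from maleness and the call
must stay indeterminate rather than risk a false male.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .copy_comparison import CopyPairReport
from .gel_model import (
    DEFAULT_TIME_MIN,
    BandPattern,
    GelConfig,
    STANDARD_GEL_PCTS,
    min_gel_percent,
    resolvable,
    separation,
)

VERDICTS = (
    "informative",
    "z_only",
    "unresolvable_polymorphism",
    "not_found",
    "partial_copy_only",
    "confounded",
)

_BAND_MATCH_RTOL = 0.05


@dataclass(frozen=True)
class MarkerVerdict:
    """Usability of one marker for sexing one species."""

    marker_id: str
    species_id: str
    verdict: str
    gel_pct_required: float | None = None
    z_length: int | None = None
    second_length: int | None = None
    delta_l: int | None = None
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.verdict == "informative" and self.gel_pct_required not in STANDARD_GEL_PCTS:
            raise ValueError("informative verdict requires a standard gel percentage")
        if self.verdict == "z_only" and self.second_length is not None:
            raise ValueError("z_only verdict implies an absent second copy")


@dataclass(frozen=True)
class SexCall:
    individual_id: str
    marker_id: str
    call: str  # male | female | indeterminate
    band_count: int
    reason: str = ""

    def __post_init__(self) -> None:
        if self.call not in ("male", "female", "indeterminate"):
            raise ValueError(f"bad call {self.call!r}")


def evaluate_marker(
    pair: CopyPairReport | None,
    gel: GelConfig | None = None,
    time: float = DEFAULT_TIME_MIN,
    nonspecific_lengths: Sequence[int] = (),
    w_band_only: bool = False,
    has_positive_control: bool = False,
    marker_id: str = "",
    species_id: str = "",
) -> MarkerVerdict:
    """Map one copy-pair report to exactly one verdict.

    ``nonspecific_lengths`` are extra product lengths observed or planted
    for this marker/species; one falling into the diagnostic band window at
    the chosen gel percentage confounds the marker. ``w_band_only`` marks
    W-dominant single-primer-pair designs, which are confounded unless an
    internal positive control band is part of the assay.
    """
    cfg = gel or GelConfig()
    marker = pair.marker_id if pair is not None else marker_id
    species = pair.species_id if pair is not None else species_id
    if pair is None:
        return MarkerVerdict(marker, species, "not_found")
    if w_band_only:
        if has_positive_control:
            return MarkerVerdict(
                marker, species, "informative",
                gel_pct_required=min(STANDARD_GEL_PCTS),
                z_length=pair.z_length,
                notes=("W-dominant design with positive control",),
            )
        return MarkerVerdict(
            marker, species, "confounded",
            notes=("W-dominant design: absence of a band cannot distinguish male from failed PCR",),
        )
    if pair.second_location == "absent":
        return MarkerVerdict(marker, species, "z_only", z_length=pair.z_length)
    if pair.second_partial:
        return MarkerVerdict(
            marker, species, "partial_copy_only",
            z_length=pair.z_length, second_length=pair.second_length,
            notes=("second copy truncated; length difference not measurable",),
        )
    assert pair.delta_l is not None and pair.second_length is not None
    if pair.delta_l == 0:
        return MarkerVerdict(
            marker, species, "unresolvable_polymorphism",
            z_length=pair.z_length, second_length=pair.second_length, delta_l=0,
        )
    g = min_gel_percent(pair.z_length, pair.second_length, time, cfg)
    if g is None:
        notes = ()
        for pct in STANDARD_GEL_PCTS:
            if separation(pair.z_length, pair.second_length, cfg.at(pct), time) == "indistinct":
                notes = (f"bands indistinct even at {pct:g}% gel",)
                break
        return MarkerVerdict(
            marker, species, "unresolvable_polymorphism",
            z_length=pair.z_length, second_length=pair.second_length,
            delta_l=pair.delta_l, notes=notes,
        )
    notes = []
    run_cfg = cfg.at(g)
    confounded = False
    for ns in nonspecific_lengths:
        for diagnostic in (pair.z_length, pair.second_length):
            if separation(ns, diagnostic, run_cfg, time) != "separated":
                confounded = True
                notes.append(f"nonspecific ~{ns} bp product overlaps the {diagnostic} bp band")
            elif ns not in (pair.z_length, pair.second_length):
                note = f"nonspecific ~{ns} bp product (separable)"
                if note not in notes:
                    notes.append(note)
    if confounded:
        return MarkerVerdict(
            marker, species, "confounded",
            z_length=pair.z_length, second_length=pair.second_length,
            delta_l=pair.delta_l, notes=tuple(notes),
        )
    return MarkerVerdict(
        marker, species, "informative",
        gel_pct_required=g,
        z_length=pair.z_length, second_length=pair.second_length,
        delta_l=pair.delta_l, notes=tuple(notes),
    )


def _nearest_expected(length: int, expected: Sequence[int]) -> int | None:
    best = None
    for e in expected:
        if abs(length - e) <= _BAND_MATCH_RTOL * e:
            if best is None or abs(length - e) < abs(length - best):
                best = e
    return best


def sex_call(
    bands: BandPattern,
    verdict: MarkerVerdict,
    gel: GelConfig | None = None,
    time: float = DEFAULT_TIME_MIN,
) -> SexCall:
    """Call the sex of one individual from one lane under one marker verdict.

    Two separable diagnostic bands -> female; a single diagnostic band under
    an informative verdict -> male; anything else -> indeterminate with a
    reason (never a guessed sex).
    """
    lane = bands.lane_id
    marker = verdict.marker_id
    lengths = [bp for bp, _ in bands.bands]
    n = len(lengths)
    if verdict.verdict != "informative":
        return SexCall(lane, marker, "indeterminate", n, f"marker verdict is {verdict.verdict}")
    assert verdict.z_length is not None and verdict.second_length is not None
    cfg = (gel or GelConfig()).at(verdict.gel_pct_required)
    expected = (verdict.z_length, verdict.second_length)
    assigned: dict[int, list[int]] = {verdict.z_length: [], verdict.second_length: []}
    for bp in lengths:
        e = _nearest_expected(bp, expected)
        if e is not None:
            assigned[e].append(bp)
    z_hits, w_hits = assigned[verdict.z_length], assigned[verdict.second_length]
    for zb in z_hits:
        for wb in w_hits:
            if zb != wb and resolvable(zb, wb, cfg, time):
                return SexCall(lane, marker, "female", n)
    if z_hits and not w_hits:
        return SexCall(lane, marker, "male", n)
    if w_hits and not z_hits:
        return SexCall(lane, marker, "indeterminate", n, "second-copy band without a Z band")
    if z_hits and w_hits:
        return SexCall(lane, marker, "indeterminate", n, "diagnostic bands not separable")
    return SexCall(lane, marker, "indeterminate", n, "no diagnostic band")


def recommend_panel(verdicts: Iterable[MarkerVerdict]) -> dict[str, list[MarkerVerdict]]:
    """Per-species ranking of informative markers.

    Ranked by lowest required gel percentage, then largest ΔL, then fewest
    notes, then marker id — i.e. the easiest, most robust marker first. The
    result is invariant under permutation of the input.
    """
    by_species: dict[str, list[MarkerVerdict]] = {}
    for v in verdicts:
        by_species.setdefault(v.species_id, []).append(v)
    out: dict[str, list[MarkerVerdict]] = {}
    for sp, vs in sorted(by_species.items()):
        informative = [v for v in vs if v.verdict == "informative"]
        informative.sort(
            key=lambda v: (v.gel_pct_required, -(v.delta_l or 0), len(v.notes), v.marker_id)
        )
        out[sp] = informative
    return out


def verdicts_to_frame(verdicts: Iterable[MarkerVerdict]) -> pd.DataFrame:
    rows = [
        {
            "species": v.species_id,
            "marker": v.marker_id,
            "verdict": v.verdict,
            "gel_pct": v.gel_pct_required,
            "z_length": v.z_length,
            "second_length": v.second_length,
            "delta_l": v.delta_l,
            "notes": "; ".join(v.notes),
        }
        for v in sorted(verdicts, key=lambda v: (v.species_id, v.marker_id))
    ]
    return pd.DataFrame(
        rows,
        columns=["species", "marker", "verdict", "gel_pct", "z_length", "second_length", "delta_l", "notes"],
    )


def species_report_md(verdicts: Iterable[MarkerVerdict]) -> str:
    """Human-readable per-species markdown summary."""
    panel = recommend_panel(verdicts)
    frame = verdicts_to_frame(verdicts)
    lines = ["# Marker evaluation report", ""]
    for sp, grp in frame.groupby("species"):
        lines.append(f"## Species {sp}")
        lines.append("")
        for _, row in grp.iterrows():
            extra = f" ({row['notes']})" if row["notes"] else ""
            gel = f", {row.gel_pct:g}% gel" if pd.notna(row.gel_pct) else ""
            lines.append(f"- {row.marker}: {row.verdict}{gel}{extra}")
        picks = panel.get(sp, [])
        if picks:
            lines.append(f"- recommended: {', '.join(v.marker_id for v in picks)}")
        else:
            lines.append("- recommended: none (no informative marker for this species)")
        lines.append("")
    return "\n".join(lines)
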