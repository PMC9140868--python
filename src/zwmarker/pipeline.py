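"""End-to-end marker evaluation: genome + mRNAs + primers -> verdicts.

Stage order mirrors the marker-design workflow: infer gene structure on the
Z-labelled sequence, predict Z-specific amplicons per marker, search all
non-Z sequences for second copies, pair them into ΔL reports, and score
each marker's gel resolvability into a sexing verdict. The diagnostic
amplicon for a marker is the predicted product that overlaps its source
gene; any further products feed the verdict as nonspecific bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .copy_comparison import CopyPairReport, pair_copies
from .gel_model import DEFAULT_TIME_MIN, GelConfig
from .gene_structure import GeneModel, UnmappableError, map_exons
from .homology_search import HomologyHit, local_search
from .insilico_pcr import AmpliconHit, annotate_composition, predict_amplicons
from .marker_eval import MarkerVerdict, evaluate_marker
from .sequence_io import PrimerPair, SeqRecord


@dataclass
class PipelineResult:
    species_id: str
    gene_models: dict[str, GeneModel] = field(default_factory=dict)
    amplicons: dict[str, list[AmpliconHit]] = field(default_factory=dict)
    diagnostic_amplicons: dict[str, AmpliconHit] = field(default_factory=dict)
    homology_hits: dict[str, list[HomologyHit]] = field(default_factory=dict)
    copy_reports: dict[str, CopyPairReport] = field(default_factory=dict)
    verdicts: dict[str, MarkerVerdict] = field(default_factory=dict)


def run_pipeline(
    records: Sequence[SeqRecord],
    mrnas: Sequence[SeqRecord],
    primer_pairs: Sequence[PrimerPair],
    role_map: Mapping[str, str] | None = None,
    species_id: str = "",
    gel: GelConfig | None = None,
    time: float = DEFAULT_TIME_MIN,
    max_mismatch: int = 2,
    three_prime_exact: int = 3,
    max_product: int = 5000,
    min_identity: float = 0.70,
    min_hit_len: int = 50,
    word_size: int = 11,
) -> PipelineResult:
    """Run the full evaluation for one genome (one species/individual)."""
    role_map = dict(role_map or {})
    labelled = [
        r.with_label(role_map[r.id]) if r.id in role_map else r for r in records
    ]
    z_records = [r for r in labelled if r.label == "Z"]
    if not z_records:
        raise ValueError("no sequence labelled Z in the role map")
    z = z_records[0]
    others = [r for r in labelled if r.id != z.id]
    result = PipelineResult(species_id=species_id)

    for mrna in mrnas:
        gene_id = mrna.id[:-5] if mrna.id.endswith("_mRNA") else mrna.id
        try:
            result.gene_models[gene_id] = map_exons(mrna, z, gene_id=gene_id)
        except UnmappableError:
            pass

    for pair in primer_pairs:
        hits = predict_amplicons(z, pair, max_mismatch, three_prime_exact, max_product)
        model = result.gene_models.get(pair.source_gene)
        if model is not None:
            hits = [annotate_composition(h, model) for h in hits]
        result.amplicons[pair.marker_id] = hits
        if not hits:
            result.verdicts[pair.marker_id] = evaluate_marker(
                None, gel, time, marker_id=pair.marker_id, species_id=species_id
            )
            continue
        on_gene = [h for h in hits if h.composition]
        diag = on_gene[0] if on_gene else hits[0]
        nonspecific = [h.length for h in hits if h is not diag]
        result.diagnostic_amplicons[pair.marker_id] = diag
        query = SeqRecord(f"{pair.marker_id}_Zamp", diag.sequence, "Z")
        hom = local_search(
            query, others, min_identity=min_identity,
            min_hit_len=min_hit_len, word_size=word_size,
        )
        result.homology_hits[pair.marker_id] = hom
        report = pair_copies(diag, hom, role_map, species_id=species_id)
        result.copy_reports[pair.marker_id] = report
        result.verdicts[pair.marker_id] = evaluate_marker(
            report, gel, time, nonspecific_lengths=nonspecific
        )
    return result
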