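"""Noncoding filters, genomic-context classification and catalog comparison.

External coding-potential predictors are consumed as precomputed evidence
flags; they are never re-run here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genome_model_io import TranscriptModel, locus_span, transcript_length
from .reference_merge import ReferenceIndex, assign_class_code

__all__ = [
    "CodingEvidence",
    "LNC_CLASSES",
    "MIN_LNCRNA_LENGTH",
    "is_preliminary_noncoding",
    "passes_final_noncoding",
    "identify_lncrnas",
    "classify_context",
    "catalogs_overlap",
]

MIN_LNCRNA_LENGTH = 200  # retained transcripts must be strictly longer

LNC_CLASSES = ("intergenic", "sense", "antisense", "others")


@dataclass(frozen=True)
class CodingEvidence:
    """External predictor calls and hit flags for one transcript.

    All flags are mandatory: a missing call is an error, never a default.
    """

    transcript_id: str
    cpc_noncoding: bool
    cpat_noncoding: bool
    pfam_hit: bool
    ms_hit: bool
    riboseq_hit: bool


def is_preliminary_noncoding(ev: CodingEvidence) -> bool:
    """Noncoding when either predictor calls the transcript noncoding."""
    return ev.cpc_noncoding or ev.cpat_noncoding


def passes_final_noncoding(ev: CodingEvidence) -> bool:
    """No protein evidence from domain scans, mass spec or ribosome profiling.

    Only defined for transcripts that already passed the preliminary filter.
    """
    if not is_preliminary_noncoding(ev):
        raise ValueError(
            f"transcript {ev.transcript_id!r} failed the preliminary noncoding "
            "filter; the final filter does not apply"
        )
    return not (ev.pfam_hit or ev.ms_hit or ev.riboseq_hit)


def identify_lncrnas(
    candidates: Sequence[TranscriptModel],
    evidence: Mapping[str, CodingEvidence],
) -> set[str]:
    """Transcript ids passing length > 200 nt and both noncoding filters."""
    retained = set()
    for t in candidates:
        if t.transcript_id not in evidence:
            raise KeyError(f"no coding evidence for transcript {t.transcript_id!r}")
        ev = evidence[t.transcript_id]
        if transcript_length(t) <= MIN_LNCRNA_LENGTH:
            continue
        if not is_preliminary_noncoding(ev):
            continue
        if not passes_final_noncoding(ev):
            continue
        retained.add(t.transcript_id)
    return retained


def _same_strand_exonic_overlap(lnc: TranscriptModel, coding: TranscriptModel) -> bool:
    if lnc.strand != coding.strand:
        return False
    return any(le.overlap_length(ce) > 0 for le in lnc.exons for ce in coding.exons)


def classify_context(lnc: TranscriptModel, coding: ReferenceIndex) -> str:
    """Assign one of {intergenic, sense, antisense, others}.

    Order: intergenic (class code 'u' vs the coding set), then sense
    (>= 1 bp same-strand exonic overlap), then antisense (opposite-strand
    overlap with a coding locus span, introns included), else others.
    """
    if assign_class_code(lnc, coding).code == "u":
        return "intergenic"
    hits = coding.overlapping(lnc.chrom, lnc.start, lnc.end)
    if any(_same_strand_exonic_overlap(lnc, c) for c in hits):
        return "sense"
    span = locus_span(lnc)
    if any(
        c.strand != lnc.strand and span.overlap_length(locus_span(c)) > 0 for c in hits
    ):
        return "antisense"
    return "others"


def classify_all(
    lncs: Iterable[TranscriptModel], coding: ReferenceIndex
) -> dict[str, str]:
    return {t.transcript_id: classify_context(t, coding) for t in lncs}


def catalogs_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    """True iff any exon of a shares >= 1 bp with any exon of b, strand ignored."""
    return any(ea.overlap_length(eb) >= 1 for ea in a.exons for eb in b.exons)
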