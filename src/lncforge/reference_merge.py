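"""Merge reference catalogs by redundancy rules and call novelty via class codes.

Redundancy: multi-exon transcripts are redundant when their intron chains are
identical on the same strand (terminal exon ends free); single-exon
transcripts when their genomic overlap exceeds 80% of the shorter one on the
same strand. Within a redundancy class the highest-priority source survives.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genome_model_io import (
    GenomicInterval,
    TranscriptModel,
    intron_chain,
    locus_span,
    transcript_length,
)

__all__ = [
    "DEFAULT_SOURCE_PRIORITY",
    "SourcedTranscript",
    "ClassCode",
    "ReferenceIndex",
    "is_redundant",
    "merge_references",
    "assign_class_code",
    "flag_novel",
]

# higher number = preferred representative
DEFAULT_SOURCE_PRIORITY: Mapping[str, int] = {
    "GENCODE": 3,
    "RefSeq": 2,
    "lncRNAdb": 1,
    "assembled": 0,
}

SINGLE_EXON_OVERLAP_FRACTION = 0.8

CLASS_CODES = ("=", "c", "u", "x", "o", "i", "other")


@dataclass(frozen=True)
class SourcedTranscript:
    model: TranscriptModel
    source_priority: int

    @classmethod
    def from_source(
        cls,
        model: TranscriptModel,
        priority: Mapping[str, int] = DEFAULT_SOURCE_PRIORITY,
    ) -> "SourcedTranscript":
        if model.source not in priority:
            raise KeyError(f"no priority defined for source {model.source!r}")
        return cls(model, priority[model.source])


@dataclass(frozen=True)
class ClassCode:
    code: str

    def __post_init__(self) -> None:
        if self.code not in CLASS_CODES:
            raise ValueError(f"unknown class code {self.code!r}")


def _chain_key(t: TranscriptModel) -> tuple:
    return (t.chrom, t.strand, tuple((i.start, i.end) for i in intron_chain(t)))


def _single_exon_overlap_fraction(a: TranscriptModel, b: TranscriptModel) -> float:
    ov = a.exons[0].overlap_length(b.exons[0])
    shorter = min(transcript_length(a), transcript_length(b))
    return ov / shorter


def is_redundant(a: TranscriptModel, b: TranscriptModel) -> bool:
    """True when a and b count as one transcript under the merging rules."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    a_multi = len(a.exons) > 1
    b_multi = len(b.exons) > 1
    if a_multi != b_multi:
        return False
    if a_multi:
        return _chain_key(a) == _chain_key(b)
    return _single_exon_overlap_fraction(a, b) > SINGLE_EXON_OVERLAP_FRACTION


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_references(refs: Sequence[SourcedTranscript]) -> list[TranscriptModel]:
    """Collapse redundancy classes, keeping the highest-priority representative.

    Redundancy classes are the transitive closure of :func:`is_redundant`.
    Ties in priority break toward the lexicographically smallest
    transcript_id, so the merge is deterministic and idempotent.
    """
    models = [st.model for st in refs]
    uf = _UnionFind(len(models))
    # bucket by chrom to avoid the full quadratic sweep across chromosomes
    by_chrom: dict[str, list[int]] = {}
    for i, m in enumerate(models):
        by_chrom.setdefault(m.chrom, []).append(i)
    for idxs in by_chrom.values():
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                i, j = idxs[ai], idxs[bi]
                if is_redundant(models[i], models[j]):
                    uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(models)):
        groups.setdefault(uf.find(i), []).append(i)
    survivors = []
    for members in groups.values():
        best = min(
            members,
            key=lambda i: (-refs[i].source_priority, models[i].transcript_id),
        )
        survivors.append(best)
    survivors.sort()
    return [models[i] for i in survivors]


class ReferenceIndex:
    """Per-chromosome interval index over transcript locus spans."""

    def __init__(self, reference: Iterable[TranscriptModel]):
        self._by_chrom: dict[str, list[tuple[int, int, TranscriptModel]]] = {}
        for t in reference:
            self._by_chrom.setdefault(t.chrom, []).append((t.start, t.end, t))
        self._starts: dict[str, list[int]] = {}
        for chrom, rows in self._by_chrom.items():
            rows.sort(key=lambda r: (r[0], r[1]))
            self._starts[chrom] = [r[0] for r in rows]

    def overlapping(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        """Reference transcripts whose locus span intersects [start, end]."""
        rows = self._by_chrom.get(chrom, [])
        # spans can nest, so scan from the beginning up to the last start <= end
        hi = bisect.bisect_right(self._starts.get(chrom, []), end)
        return [t for (s, e, t) in rows[:hi] if e >= start]

    def __iter__(self):
        for rows in self._by_chrom.values():
            for _, _, t in rows:
                yield t


def _exonic_overlap_length(a: TranscriptModel, b: TranscriptModel) -> int:
    return sum(ea.overlap_length(eb) for ea in a.exons for eb in b.exons)


def _is_exact_match(query: TranscriptModel, ref: TranscriptModel) -> bool:
    if query.strand != ref.strand or query.chrom != ref.chrom:
        return False
    q_multi = len(query.exons) > 1
    r_multi = len(ref.exons) > 1
    if q_multi != r_multi:
        return False
    if q_multi:
        return _chain_key(query) == _chain_key(ref)
    ov = query.exons[0].overlap_length(ref.exons[0])
    return (
        ov > SINGLE_EXON_OVERLAP_FRACTION * transcript_length(query)
        and ov > SINGLE_EXON_OVERLAP_FRACTION * transcript_length(ref)
    )


def _is_contained(query: TranscriptModel, ref: TranscriptModel) -> bool:
    """Query's intron chain is a contiguous sub-chain of ref and query lies
    within ref's exonic intervals (cuffcompare-style 'c')."""
    if query.strand != ref.strand or query.chrom != ref.chrom:
        return False
    q_introns = tuple((i.start, i.end) for i in intron_chain(query))
    r_introns = tuple((i.start, i.end) for i in intron_chain(ref))
    if q_introns:
        n, m = len(q_introns), len(r_introns)
        if not any(r_introns[i : i + n] == q_introns for i in range(m - n + 1)):
            return False
    # every query exonic base must fall in some ref exon
    for qe in query.exons:
        covered = sum(qe.overlap_length(re_) for re_ in ref.exons)
        if covered < len(qe):
            return False
    return True


def _fully_intronic(query: TranscriptModel, ref: TranscriptModel) -> bool:
    span = locus_span(query)
    return any(i.contains(span) for i in intron_chain(ref))


def assign_class_code(query: TranscriptModel, reference: ReferenceIndex) -> ClassCode:
    """Relate a query transcript to a reference set with a one-character code.

    '=' exact intron-chain match (single-exon: >80% reciprocal overlap);
    'c' contained sub-chain; 'u' no locus overlap at all; 'x' exonic overlap
    on the opposite strand only; 'o' same-strand exonic overlap otherwise;
    'i' fully inside a same-strand reference intron; 'other' otherwise.
    """
    hits = reference.overlapping(query.chrom, query.start, query.end)
    if not hits:
        return ClassCode("u")
    if any(_is_exact_match(query, r) for r in hits):
        return ClassCode("=")
    if any(query.transcript_id != r.transcript_id and _is_contained(query, r) for r in hits):
        return ClassCode("c")
    same_exonic = any(
        r.strand == query.strand and _exonic_overlap_length(query, r) > 0 for r in hits
    )
    opp_exonic = any(
        r.strand != query.strand and _exonic_overlap_length(query, r) > 0 for r in hits
    )
    if same_exonic:
        return ClassCode("o")
    if opp_exonic:
        return ClassCode("x")
    if any(r.strand == query.strand and _fully_intronic(query, r) for r in hits):
        return ClassCode("i")
    return ClassCode("other")


def flag_novel(query: TranscriptModel, reference: ReferenceIndex) -> bool:
    """Novel iff the class code is neither '=' nor 'c'."""
    return assign_class_code(query, reference).code not in ("=", "c")
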