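"""Transcript confidence scoring, shuffled decoys and ROC-based filtering.

The confidence score combines junction-read support in the maximally
expressed sample (J), the 95th-percentile expression (E) and sample
recurrence at FPKM > 0.1 (R), each normalized by its maximum over a stated
scoring universe and scaled so the score lives in [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genome_model_io import GenomicInterval, TranscriptModel, transcript_length

__all__ = [
    "TranscriptEvidence",
    "ScoreContext",
    "RocPoint",
    "CoverageTrack",
    "tcs_components",
    "score_context",
    "transcript_confidence_score",
    "score_transcripts",
    "shuffle_decoys",
    "roc_and_auc",
    "optimal_cutoff",
    "filter_by_tcs",
    "verify_by_coverage",
]

EXPRESSED_FPKM = 0.1


@dataclass
class TranscriptEvidence:
    """Per-sample junction-read counts and FPKM for one transcript."""

    transcript_id: str
    junction_reads_per_sample: dict[str, int]
    fpkm_per_sample: dict[str, float]

    def __post_init__(self) -> None:
        if not self.fpkm_per_sample:
            raise ValueError(f"transcript {self.transcript_id!r}: no samples in evidence")
        if set(self.junction_reads_per_sample) != set(self.fpkm_per_sample):
            raise ValueError(
                f"transcript {self.transcript_id!r}: junction and FPKM samples differ"
            )
        for s, j in self.junction_reads_per_sample.items():
            if j < 0 or int(j) != j:
                raise ValueError(f"junction count must be a non-negative integer, got {j}")
        for s, f in self.fpkm_per_sample.items():
            if f < 0:
                raise ValueError(f"FPKM must be non-negative, got {f}")


@dataclass(frozen=True)
class ScoreContext:
    """Normalizers maxJ/maxE/maxR computed over one scoring universe."""

    max_j: float
    max_e: float
    max_r: float

    def __post_init__(self) -> None:
        if not (self.max_j > 0 and self.max_e > 0 and self.max_r > 0):
            raise ValueError("all score normalizers must be > 0")


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError("sensitivity/specificity must lie in [0, 1]")

    @property
    def distance_to_corner(self) -> float:
        return float(np.hypot(1.0 - self.sensitivity, 1.0 - self.specificity))


@dataclass
class CoverageTrack:
    """Per-base read depth over a transcript's exonic bases."""

    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.size == 0:
            raise ValueError("coverage track is empty")
        if (self.depths < 0).any():
            raise ValueError("coverage depths must be non-negative")


def tcs_components(ev: TranscriptEvidence) -> tuple[float, float, int]:
    """(J, E, R): junction reads in the maximal-FPKM sample, 95th-percentile
    FPKM (linear interpolation), and the number of samples with FPKM > 0.1.

    FPKM ties for the maximal sample resolve toward the larger junction count.
    """
    samples = sorted(ev.fpkm_per_sample)
    fpkm = np.array([ev.fpkm_per_sample[s] for s in samples])
    junc = np.array([ev.junction_reads_per_sample[s] for s in samples])
    max_fpkm = fpkm.max()
    j = float(junc[fpkm == max_fpkm].max())
    e = float(np.percentile(fpkm, 95, method="linear"))
    r = int((fpkm > EXPRESSED_FPKM).sum())
    return j, e, r


def score_context(evidence: Iterable[TranscriptEvidence]) -> ScoreContext:
    """Build normalizers from the full set of transcripts scored in one run."""
    comps = [tcs_components(ev) for ev in evidence]
    if not comps:
        raise ValueError("cannot build a score context from empty evidence")
    js, es, rs = zip(*comps)
    return ScoreContext(max(js), max(es), max(rs))


def transcript_confidence_score(
    components: tuple[float, float, float], ctx: ScoreContext
) -> float:
    """100/3 * (J/maxJ + E/maxE + R/maxR); bounded in [0, 100]."""
    j, e, r = components
    if j > ctx.max_j or e > ctx.max_e or r > ctx.max_r:
        raise ValueError(
            f"components {components} exceed context normalizers "
            f"({ctx.max_j}, {ctx.max_e}, {ctx.max_r}); wrong scoring universe"
        )
    if min(j, e, r) < 0:
        raise ValueError("components must be non-negative")
    return 100.0 / 3.0 * (j / ctx.max_j + e / ctx.max_e + r / ctx.max_r)


def score_transcripts(
    evidence: Sequence[TranscriptEvidence], ctx: ScoreContext | None = None
) -> dict[str, float]:
    """Score every transcript against one shared context (built here if absent)."""
    if ctx is None:
        ctx = score_context(evidence)
    return {
        ev.transcript_id: transcript_confidence_score(tcs_components(ev), ctx)
        for ev in evidence
    }


# --------------------------------------------------------------------------
# Decoy generation
# --------------------------------------------------------------------------


def _exon_offsets(t: TranscriptModel) -> list[tuple[int, int]]:
    """Exon (offset-from-span-start, length) pairs preserving intron structure."""
    origin = t.start
    return [(e.start - origin, len(e)) for e in t.exons]


def shuffle_decoys(
    templates: Sequence[TranscriptModel],
    chrom_sizes: Mapping[str, int],
    exclusion: Sequence[GenomicInterval] = (),
    seed: int = 0,
    max_attempts: int = 1000,
) -> list[TranscriptModel]:
    """Place one decoy per template uniformly at random on the toy genome.

    Each decoy keeps its template's exon/intron length structure and strand;
    the full decoy span must avoid every exclusion interval. Chromosomes are
    drawn weighted by length; placement uses seeded rejection sampling and
    fails loudly (naming the template) after ``max_attempts`` rejections.
    """
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    excl_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in exclusion:
        excl_by_chrom.setdefault(iv.chrom, []).append(iv)

    decoys = []
    for k, t in enumerate(templates):
        span = t.end - t.start + 1
        placed = None
        for _ in range(max_attempts):
            ci = rng.choice(len(chroms), p=weights)
            chrom = chroms[ci]
            limit = chrom_sizes[chrom] - span + 1
            if limit < 1:
                continue
            start = int(rng.integers(1, limit + 1))
            end = start + span - 1
            probe = GenomicInterval(chrom, start, end)
            if any(probe.overlap_length(iv) > 0 for iv in excl_by_chrom.get(chrom, [])):
                continue
            placed = (chrom, start)
            break
        if placed is None:
            raise RuntimeError(
                f"could not place decoy for template {t.transcript_id!r} "
                f"after {max_attempts} attempts"
            )
        chrom, start = placed
        exons = [
            GenomicInterval(chrom, start + off, start + off + length - 1, t.strand)
            for off, length in _exon_offsets(t)
        ]
        decoys.append(
            TranscriptModel(
                transcript_id=f"decoy_{k}_{t.transcript_id}",
                gene_id=f"decoy_gene_{k}",
                exons=exons,
                source="decoy",
                biotype="other",
            )
        )
    return decoys


# --------------------------------------------------------------------------
# ROC / cutoff
# --------------------------------------------------------------------------


def roc_and_auc(
    positive_scores: Sequence[float], negative_scores: Sequence[float]
) -> tuple[list[RocPoint], float]:
    """ROC points at every distinct observed score (predict positive iff
    score >= threshold) plus the AUC as the Mann-Whitney pair statistic
    (ties counted 1/2)."""
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    points = [
        RocPoint(
            threshold=float(thr),
            sensitivity=float((pos >= thr).mean()),
            specificity=float((neg < thr).mean()),
        )
        for thr in thresholds
    ]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = float(u) / (pos.size * neg.size)
    return points, auc


def optimal_cutoff(roc: Sequence[RocPoint]) -> float:
    """Threshold minimizing distance to the (sens=1, spec=1) corner.

    Ties break toward the larger threshold (the stricter filter).
    """
    if not roc:
        raise ValueError("ROC curve is empty")
    best = min(roc, key=lambda p: (p.distance_to_corner, -p.threshold))
    return best.threshold


def filter_by_tcs(scores: Mapping[str, float], cutoff: float) -> set[str]:
    """Transcript ids with score >= cutoff (scores strictly below are excluded)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return {tid for tid, s in scores.items() if s >= cutoff}


def verify_by_coverage(track: CoverageTrack) -> bool:
    """True iff mean per-base depth over exonic bases is strictly > 2."""
    return float(track.depths.mean()) > 2.0
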