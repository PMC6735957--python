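"""Per-transcript expression metrics: quantile normalization, tissue
specificity, splicing efficiency, conservation, variability and filters."""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model_io import ExpressionMatrix, SampleTable, TranscriptModel, transcript_length

__all__ = [
    "ExpressionPattern",
    "IsoformAbundanceSet",
    "quantile_normalize",
    "tissue_specificity_score",
    "splicing_efficiency",
    "conservation_score",
    "interindividual_variability",
    "moderate_expression_filter",
    "recurrence_summary",
    "catalog_percentages",
    "EXPRESSED_FPKM",
]

EXPRESSED_FPKM = 0.1
SPECIFICITY_THRESHOLD = 0.6  # "tissue-specific" when the JS score exceeds this


@dataclass
class ExpressionPattern:
    """A transcript's per-tissue FPKM vector with its probability normalization.

    p_i = log2(e_i + 1) / sum_j log2(e_j + 1).
    """

    tissues: list[str]
    fpkm: np.ndarray

    def __post_init__(self) -> None:
        self.fpkm = np.asarray(self.fpkm, dtype=float)
        if len(self.tissues) != self.fpkm.size:
            raise ValueError("tissue labels and expression vector differ in length")
        if self.fpkm.size < 2:
            raise ValueError("need expression across at least 2 tissues")
        if (self.fpkm < 0).any():
            raise ValueError("FPKM must be non-negative")

    def probabilities(self) -> np.ndarray:
        logged = np.log2(self.fpkm + 1.0)
        total = logged.sum()
        if total <= 0:
            raise ValueError("all-zero expression pattern has no probability vector")
        return logged / total


@dataclass
class IsoformAbundanceSet:
    """A gene's annotated-isoform abundances plus the locus-spanning one."""

    annotated: np.ndarray
    spanning: float

    def __post_init__(self) -> None:
        self.annotated = np.asarray(self.annotated, dtype=float)
        if self.annotated.size == 0:
            raise ValueError("need at least one annotated isoform")
        if (self.annotated < 0).any() or self.spanning < 0:
            raise ValueError("abundances must be non-negative")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the mean distribution of order statistics.

    Ties within a column receive the mean of the target values they span.
    Row and column label order is preserved.
    """
    df = m.values
    arr = df.to_numpy(dtype=float)
    if arr.shape[1] == 0 or arr.shape[0] == 0:
        return ExpressionMatrix(df.copy())
    target = np.mean(np.sort(arr, axis=0), axis=1)  # mean of k-th order statistics
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(col.size)
        assigned = target[ranks]
        # average target values over tied groups
        sorted_col = col[order]
        i = 0
        while i < col.size:
            k = i
            while k + 1 < col.size and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                assigned[order[i : k + 1]] = target[i : k + 1].mean()
            i = k + 1
        out[:, j] = assigned
    return ExpressionMatrix(pd.DataFrame(out, index=df.index, columns=df.columns))


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    m = (p + q) / 2.0
    return _entropy_bits(m) - (_entropy_bits(p) + _entropy_bits(q)) / 2.0


def tissue_specificity_score(e: ExpressionPattern) -> float:
    """Jensen-Shannon tissue-specificity score in [0, 1].

    score = max_t [1 - sqrt(JS(p, e^t))] with e^t the unit vector at tissue t
    and entropy in bits, so a transcript confined to one tissue scores 1.
    """
    p = e.probabilities()
    n = p.size
    best = -math.inf
    for t in range(n):
        unit = np.zeros(n)
        unit[t] = 1.0
        js = max(_js_divergence(p, unit), 0.0)  # clamp tiny negative round-off
        best = max(best, 1.0 - math.sqrt(js))
    return float(min(max(best, 0.0), 1.0))


def splicing_efficiency(a: IsoformAbundanceSet) -> float | None:
    """Annotated abundance share: sum(annotated) / (sum(annotated) + spanning).

    Returns None when the gene has no abundance at all.
    """
    annotated = float(a.annotated.sum())
    total = annotated + a.spanning
    if total == 0:
        return None
    return annotated / total


def conservation_score(t: TranscriptModel, track: pd.DataFrame) -> float:
    """Mean per-base conservation over exonic bases; uncovered bases count 0.

    ``track`` is a tidy frame with columns chrom, start, end (1-based
    inclusive) and value, as produced by ``read_bedgraph``.
    """
    total = 0.0
    rows = track[track["chrom"] == t.chrom]
    for e in t.exons:
        sel = rows[(rows["end"] >= e.start) & (rows["start"] <= e.end)]
        for _, r in sel.iterrows():
            ov = min(e.end, r["end"]) - max(e.start, r["start"]) + 1
            total += ov * float(r["value"])
    return total / transcript_length(t)


def interindividual_variability(per_donor: Sequence[float]) -> float | None:
    """Coefficient of variation across donors (sample sd / mean).

    Returns None when the mean is 0. Chromosome X/Y exclusion and the
    expressed-in-at-least-one-donor gate are applied by the caller.
    """
    x = np.asarray(per_donor, dtype=float)
    if x.size < 2:
        raise ValueError("need expression from at least 2 donors")
    mean = x.mean()
    if mean == 0:
        return None
    return float(x.std(ddof=1) / mean)


def moderate_expression_filter(fpkm: Sequence[float], threshold: float = EXPRESSED_FPKM) -> bool:
    """Q3 + 1.5*IQR > threshold for the per-sample FPKM of one tissue.

    Quartiles use linear interpolation; a single sample degenerates to
    Q1 = Q3 = value.
    """
    x = np.asarray(fpkm, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one sample")
    q1, q3 = np.percentile(x, [25, 75], method="linear")
    return bool(q3 + 1.5 * (q3 - q1) > threshold)


def recurrence_summary(
    m: ExpressionMatrix, samples: SampleTable
) -> pd.DataFrame:
    """Per-transcript counts of tissues and samples with FPKM > 0.1 (strict)."""
    meta = samples.table.set_index("sample_id")
    missing = [s for s in m.sample_ids if s not in meta.index]
    if missing:
        raise KeyError(f"samples absent from metadata: {missing}")
    tissue_of = meta.loc[m.sample_ids, "tissue"]
    if tissue_of.isna().any():
        bad = list(tissue_of[tissue_of.isna()].index)
        raise ValueError(f"samples missing tissue annotation: {bad}")
    expressed = m.values > EXPRESSED_FPKM
    n_samples = expressed.sum(axis=1)
    n_tissues = expressed.T.groupby(tissue_of.values).any().sum(axis=0)
    return pd.DataFrame(
        {"n_tissues_expressed": n_tissues, "n_samples_expressed": n_samples},
        index=m.values.index,
    )


def catalog_percentages(
    counts: Mapping[str, tuple[int, int]], ndigits: int = 1
) -> dict[str, float]:
    """100 * numerator / denominator with half-up rounding.

    ``counts`` maps a label to (numerator, denominator); a zero denominator
    is an error.
    """
    out = {}
    quantum = Decimal(1).scaleb(-ndigits)
    for label, (num, den) in counts.items():
        if den == 0:
            raise ZeroDivisionError(f"{label}: zero denominator")
        pct = Decimal(100) * Decimal(num) / Decimal(den)
        out[label] = float(pct.quantize(quantum, rounding=ROUND_HALF_UP))
    return out
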