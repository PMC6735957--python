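"""Seeded generators for every input the pipeline consumes, with ground truth.

All generators are deterministic under a fixed seed; every generated entity
carries a truth record so analysis modules can be closed-loop tested against
the injected signal. FPKM values follow a log-scale linear model (additive
covariate effects, individual random intercept) exponentiated to abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model_io import (
    ExpressionMatrix,
    GenomicInterval,
    SampleTable,
    TranscriptModel,
)
from .confidence_filter import TranscriptEvidence

__all__ = [
    "FixtureTruth",
    "generate_annotation",
    "generate_expression_cohort",
    "generate_evidence",
    "generate_survival",
    "DEFAULT_CHROM_SIZES",
]

DEFAULT_CHROM_SIZES: Mapping[str, int] = {"chrT1": 1_000_000, "chrT2": 800_000}

SEXES = ("female", "male")
RACES = ("groupA", "groupB", "groupC")


@dataclass
class FixtureTruth:
    """Ground-truth labels for one generated fixture set."""

    records: pd.DataFrame  # one row per transcript
    seed: int
    params: dict = field(default_factory=dict)

    def label(self, transcript_id: str, column: str):
        row = self.records.loc[self.records["transcript_id"] == transcript_id]
        if len(row) != 1:
            raise KeyError(f"no unique truth record for {transcript_id!r}")
        return row.iloc[0][column]


# --------------------------------------------------------------------------
# Annotation
# --------------------------------------------------------------------------

_SLOT = 14_000  # coding gene slot length
_GAP = 10_000  # intergenic gap between slots


def _make_coding_gene(
    rng: np.random.Generator, chrom: str, slot_start: int, idx: int,
    exon_count_range: tuple[int, int],
) -> TranscriptModel:
    n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    pos = slot_start
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(150, 401))
        exons.append(GenomicInterval(chrom, pos, pos + length - 1, strand))
        pos += length + int(rng.integers(500, 1501))  # intron
    return TranscriptModel(
        transcript_id=f"CODING.{idx}.1",
        gene_id=f"CODING.{idx}",
        exons=exons,
        source="GENCODE",
        biotype="protein_coding",
    )


def generate_annotation(
    n_coding_genes: int,
    class_counts: Mapping[str, int] | None = None,
    chrom_sizes: Mapping[str, int] = DEFAULT_CHROM_SIZES,
    exon_count_range: tuple[int, int] = (2, 4),
    seed: int = 0,
) -> tuple[list[TranscriptModel], FixtureTruth]:
    """Place non-overlapping coding genes plus lncRNAs realizing each
    genomic-context class label in known counts.

    Returns the transcript models (coding first, then lncRNAs) and the truth
    table with the planted class label per lncRNA.
    """
    class_counts = dict(class_counts or {})
    unknown = set(class_counts) - {"intergenic", "sense", "antisense", "others"}
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    # sequential slot layout: [gene slot][gap][gene slot][gap]...
    slots: list[tuple[str, int]] = []
    for chrom, size in chrom_sizes.items():
        pos = 1 + _GAP // 2
        while pos + _SLOT + _GAP < size:
            slots.append((chrom, pos))
            pos += _SLOT + _GAP
    if n_coding_genes > len(slots):
        raise ValueError(
            f"toy genome admits only {len(slots)} gene slots, requested {n_coding_genes}"
        )
    n_lnc_dependent = sum(
        class_counts.get(k, 0) for k in ("sense", "antisense", "others")
    )
    if n_lnc_dependent > 0 and n_coding_genes == 0:
        raise ValueError("sense/antisense/others lncRNAs need coding genes to anchor to")

    coding = [
        _make_coding_gene(rng, chrom, start, i, exon_count_range)
        for i, (chrom, start) in enumerate(slots[:n_coding_genes])
    ]

    models: list[TranscriptModel] = list(coding)
    truth_rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "kind": "coding",
            "class_label": None,
            "chrom": t.chrom,
            "n_exons": len(t.exons),
        }
        for t in coding
    ]

    lnc_idx = 0

    def _add_lnc(exons: list[GenomicInterval], label: str) -> None:
        nonlocal lnc_idx
        t = TranscriptModel(
            transcript_id=f"LNC.{lnc_idx}.1",
            gene_id=f"LNC.{lnc_idx}",
            exons=exons,
            source="assembled",
            biotype="lncRNA",
        )
        models.append(t)
        truth_rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "kind": "lncRNA",
                "class_label": label,
                "chrom": t.chrom,
                "n_exons": len(t.exons),
            }
        )
        lnc_idx += 1

    # intergenic: in the middle of gaps after the used slots, or unused slots
    free_slots = slots[n_coding_genes:]
    for i in range(class_counts.get("intergenic", 0)):
        if not free_slots:
            raise ValueError("no intergenic space left for requested lncRNAs")
        chrom, start = free_slots[i % len(free_slots)]
        offset = (i // len(free_slots)) * 1200
        if offset + 1100 > _SLOT:
            raise ValueError("intergenic zone exhausted")
        strand = "+" if rng.random() < 0.5 else "-"
        s = start + offset
        exons = [
            GenomicInterval(chrom, s, s + 299, strand),
            GenomicInterval(chrom, s + 600, s + 899, strand),
        ]
        _add_lnc(exons, "intergenic")

    for i in range(class_counts.get("sense", 0)):
        host = coding[i % len(coding)]
        anchor = host.exons[0]
        # single exon straddling the host's first exon, same strand
        s = max(1, anchor.start - 100)
        exons = [GenomicInterval(host.chrom, s, anchor.start + 150, host.strand)]
        _add_lnc(exons, "sense")

    for i in range(class_counts.get("antisense", 0)):
        host = coding[i % len(coding)]
        opposite = "-" if host.strand == "+" else "+"
        anchor = host.exons[0]
        s = max(1, anchor.start - 150)
        exons = [GenomicInterval(host.chrom, s, anchor.start + 100, opposite)]
        _add_lnc(exons, "antisense")

    others_hosts = [t for t in coding if len(t.exons) >= 2]
    for i in range(class_counts.get("others", 0)):
        if not others_hosts:
            raise ValueError("'others' lncRNAs need a multi-exon coding host")
        host = others_hosts[i % len(others_hosts)]
        a, b = host.exons[0], host.exons[1]
        intron_start, intron_end = a.end + 1, b.start - 1
        s = intron_start + 50
        e = min(intron_end - 50, s + 300)
        exons = [GenomicInterval(host.chrom, s, e, host.strand)]
        _add_lnc(exons, "others")

    truth = FixtureTruth(
        records=pd.DataFrame(truth_rows),
        seed=seed,
        params={
            "n_coding_genes": n_coding_genes,
            "class_counts": class_counts,
            "chrom_sizes": dict(chrom_sizes),
        },
    )
    return models, truth


# --------------------------------------------------------------------------
# Expression cohort
# --------------------------------------------------------------------------


def generate_expression_cohort(
    transcript_ids: Sequence[str],
    n_individuals: int,
    tissues: Sequence[str] = ("tissueA", "tissueB"),
    sex_effects: Mapping[str, float] | None = None,
    age_effects: Mapping[str, float] | None = None,
    race_effects: Mapping[str, Mapping[str, float]] | None = None,
    condition_effects: Mapping[str, float] | None = None,
    tissue_effects: Mapping[str, float] | None = None,
    baseline_log: float = 1.0,
    individual_sd: float = 0.3,
    residual_sd: float = 0.5,
    conditions: Sequence[str] = ("normal",),
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleTable, FixtureTruth]:
    """Simulate an FPKM matrix with metadata under a log-scale linear model.

    log FPKM = baseline + tissue effect + sex effect (males) + age effect *
    age + race effect + condition effect (tumor) + individual intercept +
    residual noise. Effect maps are keyed by transcript id; absent keys mean
    zero effect.
    """
    sex_effects = dict(sex_effects or {})
    age_effects = dict(age_effects or {})
    race_effects = {k: dict(v) for k, v in (race_effects or {}).items()}
    condition_effects = dict(condition_effects or {})
    tissue_effects = dict(tissue_effects or {})
    rng = np.random.default_rng(seed)

    individuals = [f"I{i:04d}" for i in range(n_individuals)]
    sex = rng.choice(SEXES, size=n_individuals)
    age = rng.integers(25, 76, size=n_individuals)
    race = rng.choice(RACES, size=n_individuals)
    intercept = rng.normal(0.0, individual_sd, size=n_individuals)

    rows = []
    for i, ind in enumerate(individuals):
        for tissue in tissues:
            for cond in conditions:
                rows.append(
                    {
                        "sample_id": f"S{len(rows):05d}",
                        "individual_id": ind,
                        "tissue": tissue,
                        "sex": sex[i],
                        "age": int(age[i]),
                        "race": race[i],
                        "condition": cond,
                    }
                )
    meta = pd.DataFrame(rows)
    samples = SampleTable(meta)

    is_male = (meta["sex"] == "male").to_numpy(dtype=float)
    age_v = meta["age"].to_numpy(dtype=float)
    is_tumor = (meta["condition"] == "tumor").to_numpy(dtype=float)
    ind_index = meta["individual_id"].map({ind: i for i, ind in enumerate(individuals)})
    ind_intercept = intercept[ind_index.to_numpy()]
    tissue_term = meta["tissue"].map(lambda t: tissue_effects.get(t, 0.0)).to_numpy()

    values = np.empty((len(transcript_ids), len(meta)))
    for k, tid in enumerate(transcript_ids):
        eta = (
            baseline_log
            + tissue_term
            + sex_effects.get(tid, 0.0) * is_male
            + age_effects.get(tid, 0.0) * age_v
            + condition_effects.get(tid, 0.0) * is_tumor
            + ind_intercept
            + rng.normal(0.0, residual_sd, size=len(meta))
        )
        for race_level, eff in race_effects.get(tid, {}).items():
            eta = eta + eff * (meta["race"] == race_level).to_numpy(dtype=float)
        values[k] = np.exp(eta)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=list(transcript_ids), columns=meta["sample_id"])
    )
    truth = FixtureTruth(
        records=pd.DataFrame(
            {
                "transcript_id": list(transcript_ids),
                "sex_effect": [sex_effects.get(t, 0.0) for t in transcript_ids],
                "age_effect": [age_effects.get(t, 0.0) for t in transcript_ids],
                "condition_effect": [condition_effects.get(t, 0.0) for t in transcript_ids],
            }
        ),
        seed=seed,
        params={
            "n_individuals": n_individuals,
            "tissues": list(tissues),
            "individual_sd": individual_sd,
            "residual_sd": residual_sd,
        },
    )
    return matrix, samples, truth


# --------------------------------------------------------------------------
# TCS evidence
# --------------------------------------------------------------------------


def generate_evidence(
    real_ids: Sequence[str],
    decoy_ids: Sequence[str],
    n_samples: int = 20,
    real_junction_lam: float = 20.0,
    decoy_junction_lam: float = 1.0,
    real_log_fpkm_mean: float = 1.0,
    decoy_log_fpkm_mean: float = -3.5,
    log_fpkm_sd: float = 0.6,
    seed: int = 0,
) -> tuple[list[TranscriptEvidence], FixtureTruth]:
    """Evidence rows separating real transcripts from decoys.

    Real transcripts get Poisson junction counts with a high rate and
    log-normal FPKM around ~e; decoys get sparse junctions and FPKM mostly
    below the 0.1 expression threshold.
    """
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    evidence = []
    labels = []
    for tid, is_real in [(t, True) for t in real_ids] + [(t, False) for t in decoy_ids]:
        lam = real_junction_lam if is_real else decoy_junction_lam
        mu = real_log_fpkm_mean if is_real else decoy_log_fpkm_mean
        junc = rng.poisson(lam, size=n_samples)
        fpkm = np.exp(rng.normal(mu, log_fpkm_sd, size=n_samples))
        if not is_real:
            # decoys are absent from most samples
            silent = rng.random(n_samples) < 0.7
            fpkm[silent] = 0.0
            junc[silent] = 0
        evidence.append(
            TranscriptEvidence(
                transcript_id=tid,
                junction_reads_per_sample=dict(zip(sample_ids, (int(j) for j in junc))),
                fpkm_per_sample=dict(zip(sample_ids, (float(f) for f in fpkm))),
            )
        )
        labels.append(is_real)
    truth = FixtureTruth(
        records=pd.DataFrame(
            {"transcript_id": [e.transcript_id for e in evidence], "is_real": labels}
        ),
        seed=seed,
        params={
            "n_samples": n_samples,
            "real_junction_lam": real_junction_lam,
            "decoy_junction_lam": decoy_junction_lam,
        },
    )
    return evidence, truth


# --------------------------------------------------------------------------
# Survival
# --------------------------------------------------------------------------


def generate_survival(
    expression: pd.Series,
    log_hr: float,
    baseline_hazard: float = 0.05,
    censoring_rate: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times with hazard scaled by exp(log_hr * expression).

    ``expression`` is indexed by sample_id (one per patient). Censoring times
    are independent exponentials; censoring_rate 0 means every event is
    observed. Returns a frame with sample_id, survival_time, event.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be > 0")
    if censoring_rate < 0:
        raise ValueError("censoring rate must be >= 0")
    rng = np.random.default_rng(seed)
    x = expression.to_numpy(dtype=float)
    hazard = baseline_hazard * np.exp(log_hr * x)
    event_time = rng.exponential(1.0 / hazard)
    if censoring_rate > 0:
        censor_time = rng.exponential(1.0 / censoring_rate, size=x.size)
    else:
        censor_time = np.full(x.size, np.inf)
    observed = event_time <= censor_time
    return pd.DataFrame(
        {
            "sample_id": expression.index,
            "survival_time": np.minimum(event_time, censor_time),
            "event": observed.astype(int),
        }
    )
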