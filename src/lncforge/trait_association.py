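"""Association layer: mixed-model trait effects, tumor/normal differential
expression, clinical-outcome association, Cox survival, Kaplan-Meier split,
Fisher tissue enrichment, GWAS SNP overlap and BH-FDR.

Expression responses are modelled on the natural-log scale (FPKM +
pseudocount) with a per-individual random intercept; fold changes are ratios
of group means on the raw FPKM scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, proportional_hazard_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_model_io import ExpressionMatrix, SampleTable, TranscriptModel, locus_span
from .expression_metrics import moderate_expression_filter

__all__ = [
    "AssociationResult",
    "SurvivalResult",
    "EnrichmentResult",
    "GwasSnp",
    "LOG_PSEUDOCOUNT",
    "fit_trait_lmm",
    "trait_association_scan",
    "differential_expression",
    "clinical_outcome_association",
    "cox_survival",
    "km_median_split",
    "tissue_enrichment_or",
    "gwas_overlap_count",
    "bh_fdr",
]

LOG_PSEUDOCOUNT = 1e-6
FDR_THRESHOLD = 0.05
FC_THRESHOLD = 1.5


@dataclass
class AssociationResult:
    transcript_id: str
    covariate: str
    estimate: float
    fold_change: float | None
    p_value: float
    fdr: float | None = None
    flag: str | None = None


@dataclass
class SurvivalResult:
    transcript_id: str
    hazard_ratio: float
    p_value: float
    fdr: float | None = None
    flag: str | None = None

    @property
    def direction(self) -> str:
        if not np.isfinite(self.hazard_ratio):
            return "undetermined"
        return "protective" if self.hazard_ratio < 1 else "risky"


@dataclass(frozen=True)
class EnrichmentResult:
    tissue: str
    odds_ratio: float
    p_value: float


@dataclass(frozen=True)
class GwasSnp:
    id: str
    chrom: str
    position: int
    trait: str = ""
    p_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("SNP position must be >= 1 (1-based)")


# --------------------------------------------------------------------------
# Design-matrix construction
# --------------------------------------------------------------------------

NUMERIC_COVARIATES = ("age", "stage")


def _build_design(
    meta: pd.DataFrame, covariates: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, list[str]], list[str]]:
    """Dummy-code factors (most frequent level as reference); numeric passed
    through. Single-level covariates are dropped with a warning.

    Returns (exog with intercept, covariate -> design column names, dropped).
    """
    cols: dict[str, np.ndarray] = {}
    term_map: dict[str, list[str]] = {}
    dropped: list[str] = []
    for cov in covariates:
        if cov in NUMERIC_COVARIATES:
            vals = pd.to_numeric(meta[cov], errors="raise").to_numpy(dtype=float)
            if np.all(vals == vals[0]):
                dropped.append(cov)
                warnings.warn(f"covariate {cov!r} is constant; dropped from model")
                continue
            cols[cov] = vals
            term_map[cov] = [cov]
        else:
            series = meta[cov].astype(str)
            levels = series.value_counts()
            if len(levels) < 2:
                dropped.append(cov)
                warnings.warn(f"covariate {cov!r} has a single level; dropped from model")
                continue
            reference = levels.index[0]  # most frequent level
            names = []
            for level in sorted(l for l in levels.index if l != reference):
                name = f"{cov}[{level}]"
                cols[name] = (series == level).to_numpy(dtype=float)
                names.append(name)
            term_map[cov] = names
    exog = pd.DataFrame(cols, index=meta.index)
    exog.insert(0, "Intercept", 1.0)
    return exog, term_map, dropped


def _fit_mixed(
    response: np.ndarray, exog: pd.DataFrame, groups: np.ndarray
):
    """Fit a random-intercept LMM, returning (result, flag)."""
    model = sm.MixedLM(response, exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True)
        except Exception:
            return None, "fit_failed"
    if not res.converged:
        return res, "not_converged"
    if np.any(~np.isfinite(res.bse.iloc[: exog.shape[1]])):
        return res, "singular"
    return res, None


@dataclass
class TraitModelSpec:
    """One transcript's response with the covariates and grouping to model."""

    transcript_id: str
    response: pd.Series  # indexed by sample_id
    samples: SampleTable
    covariates: tuple[str, ...] = ("tissue", "sex", "race", "age")
    fpkm: pd.Series | None = None  # raw scale, for fold changes


def fit_trait_lmm(spec: TraitModelSpec) -> list[AssociationResult]:
    """Random-intercept LMM of expression on the requested covariates.

    One result per factor level / numeric covariate (Wald p-values);
    single-level covariates are dropped with a warning. A singular or failed
    fit returns flagged results so callers can exclude them from FDR.
    """
    meta = spec.samples.table.set_index("sample_id").loc[spec.response.index]
    n_individuals = meta["individual_id"].nunique()
    if n_individuals < 2:
        raise ValueError("need samples from at least 2 individuals")
    exog, term_map, _dropped = _build_design(meta, spec.covariates)
    y = spec.response.to_numpy(dtype=float)
    constant_response = bool(np.var(y) == 0)
    if constant_response:
        res, flag = None, None
    else:
        res, flag = _fit_mixed(y, exog, meta["individual_id"].to_numpy())
    results = []
    for cov, names in term_map.items():
        for name in names:
            if constant_response:
                est, p = 0.0, 1.0
            elif res is None:
                est, p = float("nan"), float("nan")
            else:
                est = float(res.params[name])
                p = float(res.pvalues[name])
            fc = None
            if spec.fpkm is not None and "[" in name:
                covariate, level = name.split("[")
                level = level.rstrip("]")
                grp = meta[covariate].astype(str) == level
                m1 = float(spec.fpkm[grp.to_numpy()].mean())
                m0 = float(spec.fpkm[~grp.to_numpy()].mean())
                fc = m1 / m0 if m0 > 0 else float("inf")
            results.append(
                AssociationResult(
                    transcript_id=spec.transcript_id,
                    covariate=name,
                    estimate=est,
                    fold_change=fc,
                    p_value=p,
                    flag=flag,
                )
            )
    return results


def trait_association_scan(
    m: ExpressionMatrix,
    samples: SampleTable,
    covariates: tuple[str, ...] = ("tissue", "sex", "race", "age"),
    test_covariate: str = "sex",
    pseudocount: float = LOG_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Fit the trait LMM per transcript; BH-FDR over the tested covariate."""
    rows = []
    for tid in m.transcript_ids:
        fpkm = m.row(tid)
        spec = TraitModelSpec(
            transcript_id=tid,
            response=np.log(fpkm + pseudocount),
            samples=samples,
            covariates=covariates,
            fpkm=fpkm,
        )
        for r in fit_trait_lmm(spec):
            if r.covariate.split("[")[0] == test_covariate:
                rows.append(r)
    return _collect_with_fdr(rows)


def _collect_with_fdr(results: Sequence[AssociationResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in results],
            "covariate": [r.covariate for r in results],
            "estimate": [r.estimate for r in results],
            "fold_change": [r.fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "flag": [r.flag for r in results],
        }
    )
    df["fdr"] = np.nan
    ok = df["flag"].isna() & df["p_value"].notna()
    if ok.any():
        df.loc[ok, "fdr"] = bh_fdr(df.loc[ok, "p_value"].to_numpy())
    return df


def differential_expression(
    m: ExpressionMatrix,
    samples: SampleTable,
    tissue: str,
    fdr_threshold: float = FDR_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
    pseudocount: float = LOG_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Tumor/normal differential expression within one tissue.

    Per transcript: random-intercept LMM of log expression on condition +
    sex/race/age; a transcript is called DE when FDR < threshold and
    max(FC, 1/FC) > 1.5 with FC the tumor/normal ratio of mean FPKM.
    """
    sub = samples.table[samples.table["tissue"] == tissue]
    conditions = set(sub["condition"])
    if conditions != {"normal", "tumor"}:
        raise ValueError(
            f"tissue {tissue!r} needs both tumor and normal samples, has {sorted(conditions)}"
        )
    sub_samples = SampleTable(sub.reset_index(drop=True))
    sample_ids = [s for s in m.sample_ids if s in set(sub["sample_id"])]
    rows = []
    for tid in m.transcript_ids:
        fpkm = m.row(tid)[sample_ids]
        spec = TraitModelSpec(
            transcript_id=tid,
            response=np.log(fpkm + pseudocount),
            samples=sub_samples,
            covariates=("condition", "sex", "race", "age"),
            fpkm=fpkm,
        )
        for r in fit_trait_lmm(spec):
            if r.covariate.startswith("condition["):
                rows.append(r)
    df = _collect_with_fdr(rows)
    is_tumor = sub.set_index("sample_id").loc[sample_ids, "condition"] == "tumor"
    fcs = []
    for tid in df["transcript_id"]:
        fpkm = m.row(tid)[sample_ids]
        mt, mn = fpkm[is_tumor.to_numpy()].mean(), fpkm[~is_tumor.to_numpy()].mean()
        fcs.append(mt / mn if mn > 0 else float("inf"))
    df["fold_change"] = fcs
    sym_fc = np.maximum(df["fold_change"], 1.0 / df["fold_change"])
    df["de_call"] = (df["fdr"] < fdr_threshold) & (sym_fc > fc_threshold)
    df["direction"] = np.where(df["fold_change"] > 1, "up", "down")
    return df


def clinical_outcome_association(
    m: ExpressionMatrix,
    samples: SampleTable,
    outcome: str,
    tissue: str | None = None,
    fdr_threshold: float = FDR_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
    pseudocount: float = LOG_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Associate expression with metastasis/recurrence/stage in tumor samples.

    Metastasis and recurrence additionally require fold change > 1.5; stage
    is modelled as ordered numeric and gated on FDR plus the moderate
    expression filter only.
    """
    if outcome not in ("metastasis", "recurrence", "stage"):
        raise ValueError(f"unknown outcome {outcome!r}")
    tab = samples.table
    if outcome not in tab.columns:
        raise KeyError(f"sample table has no {outcome!r} column")
    sub = tab[(tab["condition"] == "tumor") & tab[outcome].notna()]
    if tissue is not None:
        sub = sub[sub["tissue"] == tissue]
    if outcome != "stage" and sub[outcome].nunique() < 2:
        raise ValueError(f"outcome {outcome!r} has fewer than 2 groups")
    sub_samples = SampleTable(sub.reset_index(drop=True))
    sample_ids = [s for s in m.sample_ids if s in set(sub["sample_id"])]
    rows = []
    for tid in m.transcript_ids:
        fpkm = m.row(tid)[sample_ids]
        spec = TraitModelSpec(
            transcript_id=tid,
            response=np.log(fpkm + pseudocount),
            samples=sub_samples,
            covariates=(outcome, "sex", "race", "age"),
            fpkm=fpkm,
        )
        for r in fit_trait_lmm(spec):
            if r.covariate.split("[")[0] == outcome:
                rows.append(r)
    df = _collect_with_fdr(rows)
    expressed = {
        tid: moderate_expression_filter(m.row(tid)[sample_ids].to_numpy())
        for tid in m.transcript_ids
    }
    df["expressed"] = df["transcript_id"].map(expressed)
    if outcome == "stage":
        df["retained"] = (df["fdr"] < fdr_threshold) & df["expressed"]
    else:
        fc = df["fold_change"].astype(float)
        sym_fc = np.maximum(fc, 1.0 / fc)
        df["retained"] = (df["fdr"] < fdr_threshold) & (sym_fc > fc_threshold) & df["expressed"]
    return df


# --------------------------------------------------------------------------
# Survival
# --------------------------------------------------------------------------


def _survival_frame(expression: pd.Series, samples: SampleTable) -> pd.DataFrame:
    tab = samples.table
    if "survival_time" not in tab.columns or "event" not in tab.columns:
        raise KeyError("sample table lacks survival_time/event columns")
    sub = tab[tab["survival_time"].notna() & tab["event"].notna()].copy()
    sub = sub[sub["sample_id"].isin(expression.index)]
    # one sample per individual: keep the lexicographically first sample_id
    sub = sub.sort_values("sample_id").drop_duplicates("individual_id", keep="first")
    df = pd.DataFrame(
        {
            "time": pd.to_numeric(sub["survival_time"]).to_numpy(),
            "event": sub["event"].astype(int).to_numpy(),
            "expression": expression[sub["sample_id"]].to_numpy(dtype=float),
            "age": pd.to_numeric(sub["age"]).to_numpy(),
            "sex": sub["sex"].astype(str).to_numpy(),
            "race": sub["race"].astype(str).to_numpy(),
        }
    )
    return df


def cox_survival(
    expression: pd.Series,
    samples: SampleTable,
    transcript_id: str = "",
    min_events: int = 10,
) -> SurvivalResult:
    """Multivariate Cox model of survival on expression + sex/age/race.

    One sample per individual (first sample_id kept). The proportional-
    hazards assumption is checked per covariate on scaled Schoenfeld
    residuals; if age violates it (p < 0.05) the model is refit with age
    stratified into quartiles.
    """
    df = _survival_frame(expression, samples)
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValueError("no observed events; Cox model undefined")
    if n_events < min_events:
        raise ValueError(f"need >= {min_events} events, got {n_events}")
    model_df = pd.get_dummies(df, columns=["sex", "race"], drop_first=True, dtype=float)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(model_df, duration_col="time", event_col="event")
            ph = proportional_hazard_test(cph, model_df, time_transform="rank")
            ph_p = ph.summary["p"]
            age_violates = "age" in ph_p.index and float(ph_p.loc["age"].min()) < 0.05
            if age_violates:
                strat_df = model_df.copy()
                strat_df["age_stratum"] = pd.qcut(
                    strat_df["age"], 4, labels=False, duplicates="drop"
                )
                strat_df = strat_df.drop(columns=["age"])
                cph = CoxPHFitter()
                cph.fit(
                    strat_df,
                    duration_col="time",
                    event_col="event",
                    strata=["age_stratum"],
                )
    except Exception:
        return SurvivalResult(
            transcript_id=transcript_id,
            hazard_ratio=float("nan"),
            p_value=float("nan"),
            flag="fit_failed",
        )
    hr = float(np.exp(cph.params_["expression"]))
    p = float(cph.summary.loc["expression", "p"])
    return SurvivalResult(transcript_id=transcript_id, hazard_ratio=hr, p_value=p)


def km_median_split(expression: pd.Series, samples: SampleTable) -> dict:
    """Kaplan-Meier curves and log-rank p for a median expression split.

    The median is computed only over patients with survival information;
    groups are {expression > median} vs {expression <= median}.
    """
    df = _survival_frame(expression, samples)
    median = float(np.median(df["expression"]))
    high = df["expression"] > median
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("median split leaves a group with < 2 patients")
    km_high, km_low = KaplanMeierFitter(), KaplanMeierFitter()
    km_high.fit(df.loc[high, "time"], df.loc[high, "event"], label="high")
    km_low.fit(df.loc[~high, "time"], df.loc[~high, "event"], label="low")
    lr = logrank_test(
        df.loc[high, "time"],
        df.loc[~high, "time"],
        event_observed_A=df.loc[high, "event"],
        event_observed_B=df.loc[~high, "event"],
    )
    return {
        "median": median,
        "km_high": km_high,
        "km_low": km_low,
        "p_value": float(lr.p_value),
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
    }


# --------------------------------------------------------------------------
# Enrichment / overlap / FDR
# --------------------------------------------------------------------------


def tissue_enrichment_or(
    biased_specific_t: int,
    biased_other: int,
    nonbiased_specific_t: int,
    nonbiased_other: int,
    tissue: str = "",
) -> EnrichmentResult:
    """Odds ratio (a/b)/(c/d) with a one-tailed (enrichment) Fisher p-value.

    When a ratio denominator is zero the odds ratio is NaN but the Fisher
    p-value is still computed from the 2x2 table.
    """
    a, b, c, d = (
        biased_specific_t,
        biased_other,
        nonbiased_specific_t,
        nonbiased_other,
    )
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if b > 0 and d > 0:
        odds = (a / b) / (c / d) if c > 0 else (0.0 if a == 0 else float("inf"))
    else:
        odds = float("nan")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentResult(tissue=tissue, odds_ratio=odds, p_value=float(p))


def gwas_overlap_count(
    t: TranscriptModel, snps: Sequence[GwasSnp]
) -> tuple[int, list[GwasSnp]]:
    """SNPs whose position falls in the transcript's locus span (introns
    included, bounds inclusive, strand ignored)."""
    span = locus_span(t)
    hits = [
        s
        for s in snps
        if s.chrom == span.chrom and span.start <= s.position <= span.end
    ]
    return len(hits), hits


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
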