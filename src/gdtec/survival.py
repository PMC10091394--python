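"""Survival analysis on GDTEC or expression-derived features.

Kaplan-Meier estimation and log-rank tests across patient groups, Cox
proportional-hazards fits (univariate per feature or multivariate) with
hazard ratios, Wald confidence intervals and per-sample risk scores,
median-split risk stratification, and the two-gene event-count grouping
(0/1/2 genes GDTEC-expressing or abnormally expressed).

Estimation is delegated to lifelines (Efron tie handling for Cox); this
module owns the feature construction and grouping rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .omics_io import ClinicalTable, GdtecError, GeneSampleMatrix
from .preprocess import DiscretizationScheme, LFCMatrix, discretize_lfc

__all__ = [
    "CoxFit",
    "km_logrank",
    "cox_fit",
    "risk_stratify",
    "count_group",
    "abnormal_flags",
]


@dataclass
class CoxFit:
    """Cox proportional-hazards fit: coefficients, HRs, CIs, risk scores."""

    summary: pd.DataFrame  # per covariate: coef, hr, hr_lower, hr_upper, z, p
    risk_scores: pd.Series  # per sample: linear predictor
    mode: str
    n: int
    n_events: int
    ties: str = "efron"
    flags: dict = field(default_factory=dict)


def _survival_frame(clinical: ClinicalTable) -> pd.DataFrame:
    df = clinical.records[["os_time", "os_event"]].astype(float)
    return df


def km_logrank(clinical: ClinicalTable, groups: pd.Series | dict) -> dict:
    """Kaplan-Meier curves per group and the log-rank test across groups.

    Returns ``{"curves": {label: survival DataFrame}, "statistic", "pvalue",
    "df", "flags"}``.  All-censored data leaves the statistic undefined and
    sets a flag instead of raising.
    """
    df = _survival_frame(clinical)
    labels = pd.Series(groups).reindex(df.index)
    if labels.isna().any():
        raise GdtecError("group labels missing for some samples")
    if labels.nunique() < 2:
        raise GdtecError("log-rank needs at least two non-empty groups")
    curves = {}
    for g, sub in df.groupby(labels):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_time"], sub["os_event"], label=str(g))
        curves[g] = kmf.survival_function_
    flags = {}
    if df["os_event"].sum() == 0:
        flags["all_censored"] = True
        return {"curves": curves, "statistic": np.nan, "pvalue": np.nan, "flags": flags}
    # identical groups: observed == expected exactly, avoid numerical fuzz
    by_group = [sub.reset_index(drop=True) for _, sub in df.groupby(labels)]
    if len(by_group) == 2 and by_group[0].shape == by_group[1].shape:
        a = by_group[0].sort_values(["os_time", "os_event"]).to_numpy()
        b = by_group[1].sort_values(["os_time", "os_event"]).to_numpy()
        if np.array_equal(a, b):
            return {"curves": curves, "statistic": 0.0, "pvalue": 1.0, "flags": flags}
    res = multivariate_logrank_test(df["os_time"], labels, df["os_event"])
    return {
        "curves": curves,
        "statistic": float(res.test_statistic),
        "pvalue": float(res.p_value),
        "flags": flags,
    }


def cox_fit(
    clinical: ClinicalTable,
    features: pd.DataFrame,
    mode: str = "multivariate",
    alpha: float = 0.05,
) -> CoxFit:
    """Fit Cox proportional-hazards models on the given feature columns.

    ``multivariate`` fits all columns jointly; ``univariate-per-feature``
    fits each column separately and stacks the per-feature summaries (risk
    scores then come from the joint refit on all features and are reported
    for stratification convenience only in multivariate mode).  Ties are
    handled by Efron's method (lifelines default).  Non-convergence or
    separation is flagged, not raised.
    """
    if mode not in ("multivariate", "univariate-per-feature"):
        raise ValueError(f"unknown mode {mode!r}")
    df = _survival_frame(clinical)
    feats = features.reindex(df.index)
    if feats.isna().any().any():
        raise GdtecError("features missing for some clinical samples")
    for col in feats.columns:
        if feats[col].nunique() < 2:
            raise GdtecError(f"feature {col!r} is constant")
    n_events = int(df["os_event"].sum())
    if n_events < (len(feats.columns) if mode == "multivariate" else 1):
        raise GdtecError("fewer events than fitted covariates")
    flags: dict = {}

    def _fit(cols: list[str]) -> pd.DataFrame | None:
        data = pd.concat([df, feats[cols]], axis=1)
        cph = CoxPHFitter(alpha=alpha)
        try:
            cph.fit(data, duration_col="os_time", event_col="os_event")
        except Exception as exc:  # convergence / separation problems
            flags[f"fit_failed:{','.join(cols)}"] = str(exc)
            return None
        s = cph.summary
        out = pd.DataFrame(
            {
                "coef": s["coef"],
                "hr": s["exp(coef)"],
                "hr_lower": np.exp(s["coef lower 95%"]),
                "hr_upper": np.exp(s["coef upper 95%"]),
                "z": s["z"],
                "pvalue": s["p"],
            }
        )
        out.attrs["model"] = cph
        return out

    if mode == "multivariate":
        summary = _fit(list(feats.columns))
        if summary is None:
            return CoxFit(pd.DataFrame(), pd.Series(dtype=float), mode, len(df), n_events, flags=flags)
        coefs = summary["coef"]
        risk = pd.Series(feats[coefs.index].to_numpy() @ coefs.to_numpy(), index=feats.index)
    else:
        parts = []
        for col in feats.columns:
            part = _fit([col])
            if part is not None:
                parts.append(part)
        summary = pd.concat(parts) if parts else pd.DataFrame()
        risk = pd.Series(np.zeros(len(feats)), index=feats.index)
        if not summary.empty:
            coefs = summary["coef"]
            risk = pd.Series(
                feats[coefs.index].to_numpy() @ coefs.to_numpy(), index=feats.index
            )
    return CoxFit(
        summary=summary,
        risk_scores=risk,
        mode=mode,
        n=len(df),
        n_events=n_events,
        flags=flags,
    )


def risk_stratify(fit: CoxFit, split: str = "median") -> pd.Series:
    """Median split of risk scores: > median is high risk, <= median low risk."""
    if split != "median":
        raise ValueError(f"unknown split {split!r}")
    scores = fit.risk_scores
    if scores.empty:
        raise GdtecError("fit has no risk scores")
    if scores.nunique() == 1:
        raise GdtecError("risk scores are constant; cannot stratify")
    med = scores.median()
    return pd.Series(
        np.where(scores > med, "high", "low"), index=scores.index, name="risk_group"
    )


def count_group(feature_matrix: GeneSampleMatrix, genes: list[str]) -> pd.Series:
    """Per-sample count (0/1/2) of the two given genes that are flagged (=1)."""
    if len(genes) != 2:
        raise ValueError("count_group expects exactly two genes")
    for g in genes:
        if g not in feature_matrix.values.index:
            raise KeyError(f"gene {g!r} not in matrix")
    counts = feature_matrix.values.loc[genes].sum(axis=0).astype(int)
    counts.name = "event_count"
    return counts


def abnormal_flags(
    lfc: LFCMatrix, scheme: DiscretizationScheme | None = None
) -> GeneSampleMatrix:
    """1 iff the discretized LFC is nonzero (abnormal expression, either sign)."""
    tern = discretize_lfc(lfc, scheme or DiscretizationScheme())
    flags = np.abs(tern.to_numpy())
    return GeneSampleMatrix(
        pd.DataFrame(flags, index=tern.values.index, columns=tern.values.columns),
        "binary",
    )
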