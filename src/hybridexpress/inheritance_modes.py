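"""Inheritance-mode classification of F1 transcript accumulation.

Midparent additivity model (OLS with single-pass Cook's D pruning and
99% prediction bands), significance-based transgressive calls, the F1
coefficient-of-variation screen, and a correlation-based sample-outlier
advisory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountMatrix, SampleSheet, ValidationError
from .diff_accumulation import PairwiseTestResult, SizeFactors, normalized_counts

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Midparent model
# ---------------------------------------------------------------------------


def midparent_means(
    counts: CountMatrix, sf: SizeFactors, sheet: SampleSheet
) -> pd.DataFrame:
    """Per-contig (mean_parent, mean_F1) on normalized counts.

    mean_parent is the average of the two parental group means (midparent
    value); mean_F1 averages over F1 samples.
    """
    z = normalized_counts(counts, sf)
    col = {s: j for j, s in enumerate(counts.sample_ids)}

    def group_mean(group: str) -> np.ndarray:
        idx = [col[s] for s in sheet.samples_in(group)]
        return z[:, idx].mean(axis=1)

    mean_parent = (group_mean("A") + group_mean("P")) / 2.0
    return pd.DataFrame(
        {
            "contig_id": counts.contig_ids,
            "mean_A": group_mean("A"),
            "mean_P": group_mean("P"),
            "mean_parent": mean_parent,
            "mean_F1": group_mean("F1"),
        }
    )


@dataclass
class AdditivityFit:
    slope: float
    intercept: float
    residual_sd: float
    r_squared: float
    removed_contigs: list[str]
    ci_level: float
    n_used: int
    x_mean: float  # of the refit predictor, for prediction intervals
    sxx: float
    initial_slope: float = np.nan
    initial_intercept: float = np.nan
    slope_se: float = np.nan
    intercept_se: float = np.nan


def _ols(x: np.ndarray, y: np.ndarray):
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx == 0:
        raise ValidationError("zero variance in predictor; cannot fit midparent model")
    slope = ((x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sse = (resid**2).sum()
    s2 = sse / (n - 2)
    sst = ((y - ym) ** 2).sum()
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return slope, intercept, np.sqrt(s2), r2, resid, xm, sxx


def cooks_distance(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cook's D for simple linear regression, from the closed form
    D_i = e_i^2 h_i / (p s^2 (1-h_i)^2) with p = 2."""
    n = len(x)
    slope, intercept, s, _, resid, xm, sxx = _ols(x, y)
    h = 1.0 / n + (x - xm) ** 2 / sxx
    s2 = s**2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = resid**2 * h / (2.0 * s2 * (1.0 - h) ** 2)
    return d


def fit_midparent_model(pairs: pd.DataFrame, ci_level: float = 0.99) -> AdditivityFit:
    """OLS of mean_F1 on mean_parent (raw normalized-count scale) with
    single-pass removal of contigs whose Cook's D exceeds 1, then one refit."""
    if len(pairs) < 10:
        raise ValidationError("need >=10 contigs to fit the midparent model")
    x = pairs["mean_parent"].to_numpy(dtype=float)
    y = pairs["mean_F1"].to_numpy(dtype=float)
    slope0, intercept0, *_ = _ols(x, y)
    d = cooks_distance(x, y)
    drop = d > 1.0
    removed = list(pairs.loc[drop, "contig_id"])
    if drop.any():
        log.info("midparent model: removing %d contigs with Cook's D > 1", drop.sum())
    keep = ~drop
    xk, yk = x[keep], y[keep]
    slope, intercept, s, r2, _, xm, sxx = _ols(xk, yk)
    n = len(xk)
    se_slope = s / np.sqrt(sxx)
    se_intercept = s * np.sqrt(1.0 / n + xm**2 / sxx)
    return AdditivityFit(
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=float(s),
        r_squared=float(r2),
        removed_contigs=removed,
        ci_level=ci_level,
        n_used=n,
        x_mean=float(xm),
        sxx=float(sxx),
        initial_slope=float(slope0),
        initial_intercept=float(intercept0),
        slope_se=float(se_slope),
        intercept_se=float(se_intercept),
    )


def classify_nonadditive(
    fit: AdditivityFit, pairs: pd.DataFrame, level: float | None = None
) -> pd.DataFrame:
    """Label contigs whose mean_F1 falls outside the new-observation
    prediction interval at mean_parent; adds percent_of_predicted."""
    level = fit.ci_level if level is None else level
    x = pairs["mean_parent"].to_numpy(dtype=float)
    y = pairs["mean_F1"].to_numpy(dtype=float)
    pred = fit.intercept + fit.slope * x
    tcrit = stats.t.ppf(0.5 + level / 2.0, fit.n_used - 2)
    se_pred = fit.residual_sd * np.sqrt(1.0 + 1.0 / fit.n_used + (x - fit.x_mean) ** 2 / fit.sxx)
    lo = pred - tcrit * se_pred
    hi = pred + tcrit * se_pred
    call = np.where(y > hi, "above", np.where(y < lo, "below", "intermediate"))
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(pred != 0, 100.0 * y / pred, np.nan)
    return pd.DataFrame(
        {
            "contig_id": pairs["contig_id"].to_numpy(),
            "mean_parent": x,
            "mean_F1": y,
            "predicted": pred,
            "pi_low": lo,
            "pi_high": hi,
            "non_additive": call,
            "percent_of_predicted": pct,
        }
    )


# ---------------------------------------------------------------------------
# Transgressive calls
# ---------------------------------------------------------------------------


def transgressive_direction(
    mean_A: float, mean_F1: float, mean_P: float
) -> str:
    """Direction rule alone: HIGH/LOW iff the F1 mean falls outside the range
    spanned by the two parental means, else none."""
    if mean_F1 > max(mean_A, mean_P):
        return "HIGH"
    if mean_F1 < min(mean_A, mean_P):
        return "LOW"
    return "none"


def classify_transgressive(
    results_A_vs_F1: list[PairwiseTestResult],
    results_P_vs_F1: list[PairwiseTestResult],
    group_means: pd.DataFrame,
) -> pd.DataFrame:
    """HIGH/LOW iff significant against BOTH parents and the F1 mean lies
    outside the parental range (direction consistent)."""
    sig_a = {r.contig_id: r.significant for r in results_A_vs_F1}
    sig_p = {r.contig_id: r.significant for r in results_P_vs_F1}
    calls = []
    for row in group_means.itertuples(index=False):
        direction = transgressive_direction(row.mean_A, row.mean_F1, row.mean_P)
        if direction != "none" and sig_a.get(row.contig_id) and sig_p.get(row.contig_id):
            calls.append(direction)
        else:
            calls.append("none")
    return pd.DataFrame(
        {"contig_id": group_means["contig_id"].to_numpy(), "transgressive": calls}
    )


# ---------------------------------------------------------------------------
# Coefficient of variation across F1 plants
# ---------------------------------------------------------------------------


@dataclass
class CvResult:
    contig_id: str
    sigma_ln: float
    cv: float
    high_cv: bool


def cv_f1(
    counts: CountMatrix,
    sf: SizeFactors,
    f1_samples: list[str],
    threshold: float = 2.0,
    formula: str = "lognormal_standard",
) -> list[CvResult]:
    """Coefficient of variation of F1 counts via the SD of ln(norm count + 1).

    lognormal_standard: cv = sqrt(exp(sigma^2) - 1) (lognormal identity);
    literal: cv = sqrt(exp(2*sigma) - 1).
    """
    if len(f1_samples) < 2:
        raise ValidationError("need >=2 F1 samples for a CV")
    if formula not in ("lognormal_standard", "literal"):
        raise ValidationError(f"unknown CV formula {formula!r}")
    z = normalized_counts(counts, sf)
    idx = counts.sample_index(f1_samples)
    logz = np.log(z[:, idx] + 1.0)
    sigma = logz.std(axis=1, ddof=1)
    if formula == "lognormal_standard":
        cv = np.sqrt(np.expm1(sigma**2))
    else:
        cv = np.sqrt(np.expm1(2.0 * sigma))
    return [
        CvResult(cid, float(s), float(c), bool(c > threshold))
        for cid, s, c in zip(counts.contig_ids, sigma, cv)
    ]


# ---------------------------------------------------------------------------
# Sample-outlier advisory
# ---------------------------------------------------------------------------


def sample_outlier_screen(
    counts: CountMatrix,
    sheet: SampleSheet,
    min_within_group_rho: float = 0.95,
) -> pd.DataFrame:
    """Spearman correlations over all contigs; advisory-flag samples whose
    mean correlation with their own group falls below the threshold.

    Advisory only: reduced-set membership stays a sample-sheet decision.
    """
    if len(counts.sample_ids) < 3:
        raise ValidationError("need >=3 samples for the outlier screen")
    rho, _ = stats.spearmanr(counts.counts, axis=0)
    rho = np.atleast_2d(rho)
    col = {s: j for j, s in enumerate(counts.sample_ids)}
    rows = []
    for s in counts.sample_ids:
        group = sheet.group_of(s)
        mates = [m for m in sheet.samples_in(group) if m != s and m in col]
        if not mates:
            rows.append((s, group, np.nan, False))
            continue
        mean_rho = float(np.mean([rho[col[s], col[m]] for m in mates]))
        rows.append((s, group, mean_rho, mean_rho < min_within_group_rho))
    out = pd.DataFrame(rows, columns=["sample_id", "group", "mean_within_group_rho", "flagged"])
    for r in out.itertuples(index=False):
        if r.flagged:
            log.warning(
                "sample %s: mean within-group Spearman %.3f below %.3f",
                r.sample_id, r.mean_within_group_rho, min_within_group_rho,
            )
    return out
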