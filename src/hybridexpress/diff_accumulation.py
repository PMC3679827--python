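"""Negative-binomial pairwise differential accumulation.

Median-of-ratios normalization, method-of-moments dispersion estimation with a
1/m + const trend (conservative elementwise-max sharing), a conditional NB
exact test on group count sums, and Benjamini-Hochberg adjustment per
comparison family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CountMatrix, SampleSheet, ValidationError

log = logging.getLogger(__name__)

ALPHA_FLOOR = 1e-8
#: full enumeration bound for the exact test; larger K uses central truncation
EXACT_ENUM_MAX = 10_000
#: per-marginal tail mass dropped when truncating (two marginals, two tails)
_TRUNC_TAIL = 1e-13
#: relative slack when comparing joint probabilities to the observed one
_TIE_REL = 1e-8


class EstimationError(ValueError):
    """Raised when normalization or dispersion estimation is impossible."""


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SizeFactors:
    sample_ids: tuple[str, ...]
    factors: np.ndarray  # positive floats, one per sample

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.factors):
            raise ValidationError("size factor / sample count mismatch")
        if np.any(np.asarray(self.factors) <= 0):
            raise ValidationError("size factors must be positive")

    def for_samples(self, sample_ids) -> np.ndarray:
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        return np.array([self.factors[pos[s]] for s in sample_ids])


def estimate_size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors over contigs positive in every sample.

    s_j = median_i counts_ij / geomean_i, restricted to contigs i with all
    counts positive.
    """
    k = counts.counts.astype(float)
    positive = np.all(k > 0, axis=1)
    if not positive.any():
        raise EstimationError("no contig has positive counts in every sample")
    logk = np.log(k[positive])
    log_geomean = logk.mean(axis=1)
    # median taken on the ratio scale (not log): with an even number of
    # contigs the two definitions differ by the mean of the middle pair
    factors = np.median(np.exp(logk - log_geomean[:, None]), axis=0)
    return SizeFactors(sample_ids=tuple(counts.sample_ids), factors=factors)


def normalized_counts(counts: CountMatrix, sf: SizeFactors) -> np.ndarray:
    return counts.counts / sf.for_samples(counts.sample_ids)[None, :]


# ---------------------------------------------------------------------------
# Dispersions
# ---------------------------------------------------------------------------


@dataclass
class DispersionFit:
    alpha_hat: np.ndarray  # raw per-contig MoM estimates (>= 0, NaN if no info)
    alpha_trend: np.ndarray  # trend value a1/m + a0 evaluated per contig
    alpha: np.ndarray  # final max(hat, trend, floor)
    trend_coef: tuple[float, float]  # (a0, a1)


def estimate_dispersions(
    counts: CountMatrix,
    sf: SizeFactors,
    groups: dict[str, list[str]],
    alpha_floor: float = ALPHA_FLOOR,
) -> DispersionFit:
    """Per-contig NB dispersion (variance = m + alpha*m^2) on normalized counts.

    The raw estimate pools within-group squared deviations across all groups
    with >=2 replicates; the trend alpha_fit(m) = a1/m + a0 is an unweighted
    least-squares fit over informative contigs; the final value is the
    elementwise max of raw, trend and floor (conservative sharing).
    """
    replicated = {g: s for g, s in groups.items() if len(s) >= 2}
    if not replicated:
        raise EstimationError("no group has >=2 samples; cannot estimate dispersion")
    z = normalized_counts(counts, sf)
    cols = {s: j for j, s in enumerate(counts.sample_ids)}

    n_total = sum(len(s) for s in replicated.values())
    n_groups = len(replicated)
    sse = np.zeros(z.shape[0])
    total = np.zeros(z.shape[0])
    for samples in replicated.values():
        idx = [cols[s] for s in samples]
        sub = z[:, idx]
        sse += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        total += sub.sum(axis=1)
    m = total / n_total
    v = sse / (n_total - n_groups)  # pooled within-group variance
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.where(m > 0, np.maximum(0.0, (v - m) / m**2), np.nan)

    usable = np.isfinite(alpha_hat) & (m > 0)
    if usable.sum() >= 2 and np.ptp(m[usable]) > 0:
        # least squares on alpha_hat vs 1/m, with MAD trimming so that the
        # trend is not dragged up by genuinely high-dispersion contigs (those
        # keep their own gene-wise estimate through the max sharing below)
        mu = m[usable]
        ah = alpha_hat[usable]
        keep = np.ones(len(ah), dtype=bool)
        a0 = a1 = 0.0
        for _ in range(3):
            X = np.column_stack([np.ones(keep.sum()), 1.0 / mu[keep]])
            coef, *_ = np.linalg.lstsq(X, ah[keep], rcond=None)
            a0, a1 = float(coef[0]), float(coef[1])
            resid = ah - (a0 + a1 / mu)
            mad = np.median(np.abs(resid[keep] - np.median(resid[keep])))
            if mad == 0:
                break
            new_keep = resid <= 3.0 * 1.4826 * mad
            if new_keep.sum() < 10 or np.array_equal(new_keep, keep):
                break
            keep = new_keep
    else:  # degenerate: flat trend at the mean estimate
        a0, a1 = float(np.nanmean(alpha_hat)) if usable.any() else 0.0, 0.0
    with np.errstate(divide="ignore"):
        alpha_trend = np.where(m > 0, a1 / np.where(m > 0, m, 1.0) + a0, 0.0)
    alpha_trend = np.maximum(alpha_trend, 0.0)

    alpha = np.maximum.reduce(
        [np.where(np.isfinite(alpha_hat), alpha_hat, 0.0), alpha_trend]
    )
    alpha = np.maximum(alpha, alpha_floor)
    return DispersionFit(
        alpha_hat=alpha_hat, alpha_trend=alpha_trend, alpha=alpha, trend_coef=(a0, a1)
    )


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------


def _nb_logpmf(x: np.ndarray, mean: float, alpha: float) -> np.ndarray:
    """log pmf of NB with given mean and variance mean + alpha*mean^2."""
    if mean <= 0:
        out = np.full(np.shape(x), -np.inf)
        out[np.asarray(x) == 0] = 0.0
        return out
    if alpha <= 1e-12:  # Poisson limit
        return stats.poisson.logpmf(x, mean)
    size = 1.0 / alpha
    return stats.nbinom.logpmf(x, size, size / (size + mean))


def _enum_range(
    K: int, sA: float, sB: float, qhat: float, kA: int, alpha: float
) -> np.ndarray:
    """Values of a (count in group A) to enumerate for a given total K.

    For K above EXACT_ENUM_MAX the range is a central window wide enough to
    hold all but < 1e-12 of the conditional mass (the unconditional NB
    marginal sd upper-bounds the conditional sd), always extended to cover
    the observed split.
    """
    if K <= EXACT_ENUM_MAX:
        return np.arange(K + 1)
    mA = sA * qhat
    center = sA / (sA + sB) * K
    sd = np.sqrt(mA + alpha * mA**2)
    z = stats.norm.isf(_TRUNC_TAIL)
    lo = int(np.floor(center - (z + 2) * sd - 10))
    hi = int(np.ceil(center + (z + 2) * sd + 10))
    lo = max(0, min(lo, kA - 5))
    hi = min(K, max(hi, kA + 5))
    return np.arange(lo, hi + 1)


def sum_dispersion(alpha: float, factors: np.ndarray) -> float:
    """Dispersion of a sum of independent NB libraries with common per-unit
    mean q and per-sample dispersion alpha: the sum has mean q*sum(s) and
    variance q*sum(s) + alpha*q^2*sum(s^2), i.e. dispersion
    alpha * sum(s^2) / sum(s)^2."""
    s = np.asarray(factors, dtype=float)
    return float(alpha * (s**2).sum() / s.sum() ** 2)


def nb_exact_test(
    k_A: int,
    k_B: int,
    sA: float,
    sB: float,
    alpha: float,
    alpha_B: float | None = None,
) -> float:
    """Two-sided conditional NB exact test on group count sums.

    Conditions on K = k_A + k_B; under the null both groups share per-unit
    mean q = K/(sA+sB). p is the total probability of splits (a, K-a) whose
    joint probability does not exceed the observed one (small relative slack
    for ties), normalized by the total over all splits. K = 0 gives p = 1.

    `alpha` (and `alpha_B`, defaulting to `alpha`) are the dispersions of the
    group-sum distributions; when the groups pool several libraries, scale
    the per-sample dispersion with sum_dispersion() first.
    """
    if k_A < 0 or k_B < 0 or sA <= 0 or sB <= 0:
        raise ValueError("counts must be >=0 and summed size factors positive")
    aA = float(alpha)
    aB = aA if alpha_B is None else float(alpha_B)
    K = int(k_A) + int(k_B)
    if K == 0:
        return 1.0
    qhat = K / (sA + sB)
    a = _enum_range(K, sA, sB, qhat, int(k_A), max(aA, aB))
    logp = _nb_logpmf(a, sA * qhat, aA) + _nb_logpmf(K - a, sB * qhat, aB)
    joint = np.exp(logp)
    obs = np.exp(
        _nb_logpmf(np.array([k_A]), sA * qhat, aA)[0]
        + _nb_logpmf(np.array([k_B]), sB * qhat, aB)[0]
    )
    denom = joint.sum()
    if denom <= 0:
        return 1.0
    num = joint[joint <= obs * (1.0 + _TIE_REL)].sum()
    return float(min(1.0, num / denom))


# ---------------------------------------------------------------------------
# Pairwise differential accumulation
# ---------------------------------------------------------------------------


@dataclass
class PairwiseTestResult:
    contig_id: str
    mean_norm_A: float
    mean_norm_B: float
    log2fc: float  # B over A; +-inf sentinel when one mean is zero
    log2fc_infinite: bool
    pvalue: float  # NaN if untested
    qvalue: float
    significant: bool


def _log2fc(mean_a: float, mean_b: float) -> tuple[float, bool]:
    if mean_a == 0 and mean_b == 0:
        return 0.0, False
    if mean_a == 0:
        return np.inf, True
    if mean_b == 0:
        return -np.inf, True
    return float(np.log2(mean_b / mean_a)), False


def pairwise_da(
    counts: CountMatrix,
    sf: SizeFactors,
    dispersions: np.ndarray,
    samples_X: list[str],
    samples_Y: list[str],
    q_threshold: float = 0.01,
) -> list[PairwiseTestResult]:
    """NB exact test per contig on group X vs group Y sums, BH-adjusted.

    Contigs with zero counts across both groups are reported untested
    (p = q = NaN) and excluded from the BH denominator.
    """
    if not samples_X or not samples_Y:
        raise ValidationError("both comparison groups must be non-empty")
    ix = counts.sample_index(samples_X)
    iy = counts.sample_index(samples_Y)
    fx = sf.for_samples(samples_X)
    fy = sf.for_samples(samples_Y)
    kx = counts.counts[:, ix].sum(axis=1)
    ky = counts.counts[:, iy].sum(axis=1)
    mean_x = (counts.counts[:, ix] / fx[None, :]).mean(axis=1)
    mean_y = (counts.counts[:, iy] / fy[None, :]).mean(axis=1)
    sx, sy = float(fx.sum()), float(fy.sum())

    # per-sample dispersion -> dispersion of each group's library sum
    scale_x = float((fx**2).sum() / fx.sum() ** 2)
    scale_y = float((fy**2).sum() / fy.sum() ** 2)

    tested = (kx + ky) > 0
    pvals = np.full(len(counts.contig_ids), np.nan)
    for i in np.nonzero(tested)[0]:
        pvals[i] = nb_exact_test(
            int(kx[i]), int(ky[i]), sx, sy,
            float(dispersions[i]) * scale_x,
            float(dispersions[i]) * scale_y,
        )

    qvals = np.full_like(pvals, np.nan)
    if tested.any():
        _, q, _, _ = multipletests(pvals[tested], method="fdr_bh")
        qvals[tested] = q

    results = []
    for i, cid in enumerate(counts.contig_ids):
        fc, inf = _log2fc(mean_x[i], mean_y[i])
        q_i = float(qvals[i]) if tested[i] else np.nan
        results.append(
            PairwiseTestResult(
                contig_id=cid,
                mean_norm_A=float(mean_x[i]),
                mean_norm_B=float(mean_y[i]),
                log2fc=fc,
                log2fc_infinite=inf,
                pvalue=float(pvals[i]) if tested[i] else np.nan,
                qvalue=q_i,
                significant=bool(tested[i] and q_i < q_threshold),
            )
        )
    n_sig = sum(r.significant for r in results)
    log.info(
        "pairwise test: %d contigs tested, %d significant at q<%g",
        int(tested.sum()), n_sig, q_threshold,
    )
    return results


def results_frame(results: list[PairwiseTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig_id": [r.contig_id for r in results],
            "meanA": [r.mean_norm_A for r in results],
            "meanB": [r.mean_norm_B for r in results],
            "log2fc": [r.log2fc for r in results],
            "pval": [r.pvalue for r in results],
            "qval": [r.qvalue for r in results],
            "significant": [r.significant for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Full/reduced intersection
# ---------------------------------------------------------------------------


def _direction(r: PairwiseTestResult) -> int:
    if r.mean_norm_B > r.mean_norm_A:
        return 1
    if r.mean_norm_B < r.mean_norm_A:
        return -1
    return 0


def intersect_full_reduced(
    results_full: list[PairwiseTestResult],
    results_reduced: list[PairwiseTestResult],
) -> dict[str, str]:
    """Per-contig provenance of significance: both / full_only / reduced_only / neither.

    A contig significant in both but with opposite direction of change is
    demoted to neither (and logged).
    """
    full = {r.contig_id: r for r in results_full}
    red = {r.contig_id: r for r in results_reduced}
    if set(full) != set(red):
        raise ValidationError("full and reduced analyses cover different contigs")
    out: dict[str, str] = {}
    for cid, rf in full.items():
        rr = red[cid]
        if rf.significant and rr.significant:
            if _direction(rf) == _direction(rr):
                out[cid] = "both"
            else:
                log.warning("contig %s: direction disagrees between analyses", cid)
                out[cid] = "neither"
        elif rf.significant:
            out[cid] = "full_only"
        elif rr.significant:
            out[cid] = "reduced_only"
        else:
            out[cid] = "neither"
    return out


def groups_from_sheet(sheet: SampleSheet) -> dict[str, list[str]]:
    return {g: sheet.samples_in(g) for g in ("A", "P", "F1")}
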