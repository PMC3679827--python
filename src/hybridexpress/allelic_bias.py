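"""Allele-specific expression in F1 hybrids from fixed inter-parental SNPs.

Fixed-SNP discovery from parental pileup records, per-allele counting in F1
samples with a one-strand artifact filter, SNP-level NB exact testing with
shared per-sample size factors, contig-level aggregation with inconsistency
flagging, and cis/trans overlap summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_io import PileupSite, SampleSheet, ValidationError
from .diff_accumulation import (
    CountMatrix,
    PairwiseTestResult,
    SizeFactors,
    estimate_dispersions,
    nb_exact_test,
)
from .inheritance_modes import _ols

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fixed-SNP discovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedSnp:
    contig_id: str
    pos: int
    allele_A: str  # base carried uniformly by every parent-A sample
    allele_P: str
    site_quality: float

    def __post_init__(self) -> None:
        if self.allele_A == self.allele_P:
            raise ValidationError(
                f"{self.contig_id}:{self.pos}: parental alleles identical"
            )


def _uniform_allele(
    site: PileupSite, samples: list[str], minor_tolerance: int
) -> str | None:
    """The single base carried by all `samples` at this site, or None.

    A sample carrying more than `minor_tolerance` reads of a second base, or
    samples disagreeing with each other, disqualify the site.
    """
    allele: str | None = None
    for s in samples:
        ref_d = site.allele_depth(s, site.ref_base)
        alt_d = site.allele_depth(s, site.alt_base)
        if ref_d > minor_tolerance and alt_d > minor_tolerance:
            return None  # within-sample polymorphism
        base = site.ref_base if ref_d >= alt_d else site.alt_base
        if allele is None:
            allele = base
        elif allele != base:
            return None  # within-accession polymorphism
    return allele


def call_fixed_snps(
    pileups: list[PileupSite],
    sheet: SampleSheet,
    min_qual: float = 80.0,
    min_depth: int = 5,
    minor_allele_tolerance: int = 0,
) -> list[FixedSnp]:
    """Sites where the two parental accessions are uniform for different alleles.

    Retained iff: every parental sample has total depth >= min_depth; site
    quality >= min_qual; within each accession exactly one allele is seen
    (up to minor_allele_tolerance reads of a second base); and the accessions'
    alleles differ (which also discards sites where all parents are uniformly
    non-reference).
    """
    a_samples = sheet.samples_in("A")
    p_samples = sheet.samples_in("P")
    if len(a_samples) < 2 or len(p_samples) < 2:
        raise ValidationError("need >=2 samples per parental accession")
    out: list[FixedSnp] = []
    for site in pileups:
        if site.site_quality < min_qual:
            continue
        if any(site.total_depth(s) < min_depth for s in a_samples + p_samples):
            continue
        allele_a = _uniform_allele(site, a_samples, minor_allele_tolerance)
        allele_p = _uniform_allele(site, p_samples, minor_allele_tolerance)
        if allele_a is None or allele_p is None:
            continue
        if allele_a == allele_p:
            # covers both all-reference sites and sites where every parent is
            # uniformly the alternate base (different from reference but not
            # between accessions)
            continue
        out.append(
            FixedSnp(
                contig_id=site.contig_id,
                pos=site.pos,
                allele_A=allele_a,
                allele_P=allele_p,
                site_quality=site.site_quality,
            )
        )
    log.info("fixed SNPs: %d of %d sites retained", len(out), len(pileups))
    return out


# ---------------------------------------------------------------------------
# Per-allele counting in F1 samples
# ---------------------------------------------------------------------------


@dataclass
class AlleleCounts:
    snp: FixedSnp
    count_A: dict[str, int]  # F1 sample -> strand-summed depth of allele_A
    count_P: dict[str, int]
    strand_ok: bool


def extract_allele_counts(
    snps: list[FixedSnp],
    pileups: list[PileupSite],
    f1_samples: list[str],
) -> list[AlleleCounts]:
    """Strand-summed per-allele F1 depths for each fixed SNP.

    strand_ok is False when either allele's F1-pooled reads are nonzero on
    exactly one strand (likely sequencing artifact); such records are kept but
    must be excluded from testing.
    """
    by_key = {(p.contig_id, p.pos): p for p in pileups}
    out: list[AlleleCounts] = []
    for snp in snps:
        site = by_key.get((snp.contig_id, snp.pos))
        if site is None:
            log.warning("SNP %s:%d absent from F1 pileup; skipped", snp.contig_id, snp.pos)
            continue
        count_a = {s: site.allele_depth(s, snp.allele_A) for s in f1_samples}
        count_p = {s: site.allele_depth(s, snp.allele_P) for s in f1_samples}
        strand_ok = True
        for base in (snp.allele_A, snp.allele_P):
            fwd, rev = site.allele_strand_depths(f1_samples, base)
            if (fwd + rev) > 0 and (fwd == 0 or rev == 0):
                strand_ok = False
        out.append(AlleleCounts(snp=snp, count_A=count_a, count_P=count_p, strand_ok=strand_ok))
    return out


# ---------------------------------------------------------------------------
# SNP-level bias test
# ---------------------------------------------------------------------------


def allele_count_matrix(
    allele_counts: list[AlleleCounts], f1_samples: list[str]
) -> CountMatrix:
    """SNP x (allele-by-sample) matrix used for dispersion estimation: the two
    alleles are the comparison groups, each observed in every F1 library."""
    rows = []
    ids = []
    for i, ac in enumerate(allele_counts):
        ids.append(f"{ac.snp.contig_id}:{ac.snp.pos}")
        rows.append(
            [ac.count_A[s] for s in f1_samples] + [ac.count_P[s] for s in f1_samples]
        )
    cols = [f"{s}__A" for s in f1_samples] + [f"{s}__P" for s in f1_samples]
    return CountMatrix(contig_ids=ids, sample_ids=cols, counts=np.array(rows, dtype=np.int64))


def test_allelic_bias(
    allele_counts: list[AlleleCounts],
    sf: SizeFactors,
    f1_samples: list[str],
    q_threshold: float = 0.01,
    dispersions: float | None = None,
) -> pd.DataFrame:
    """NB exact test of allele-A vs allele-P pooled F1 counts per SNP.

    Both alleles come from the same libraries, so the same per-sample size
    factors apply to both groups. Records with strand_ok=False or zero total
    depth are reported untested (NaN p). BH is one family across all SNPs.
    """
    usable = [ac for ac in allele_counts if ac.strand_ok]
    f1_sf = sf.for_samples(f1_samples)
    s_total = float(f1_sf.sum())
    # per-sample dispersion -> dispersion of the pooled 8-library allele sum
    sum_scale = float((f1_sf**2).sum() / f1_sf.sum() ** 2)

    if dispersions is None and usable:
        acm = allele_count_matrix(usable, f1_samples)
        dup_sf = SizeFactors(
            sample_ids=tuple(acm.sample_ids),
            factors=np.concatenate([f1_sf, f1_sf]),
        )
        groups = {
            "allele_A": [f"{s}__A" for s in f1_samples],
            "allele_P": [f"{s}__P" for s in f1_samples],
        }
        disp = estimate_dispersions(acm, dup_sf, groups).alpha
        disp_by_key = {acm.contig_ids[i]: disp[i] for i in range(len(disp))}
    else:
        disp_by_key = None

    rows = []
    for ac in allele_counts:
        key = f"{ac.snp.contig_id}:{ac.snp.pos}"
        k_a = sum(ac.count_A.values())
        k_p = sum(ac.count_P.values())
        tested = ac.strand_ok and (k_a + k_p) > 0
        if tested:
            alpha = float(dispersions) if dispersions is not None else float(disp_by_key[key])
            p = nb_exact_test(k_a, k_p, s_total, s_total, alpha * sum_scale)
        else:
            p = np.nan
        if k_a > 0 and k_p > 0:
            log2_bias = float(np.log2(k_a / k_p))
        elif k_a == 0 and k_p == 0:
            log2_bias = np.nan
        else:
            log2_bias = np.inf if k_p == 0 else -np.inf
        rows.append(
            {
                "contig_id": ac.snp.contig_id,
                "pos": ac.snp.pos,
                "count_A": k_a,
                "count_P": k_p,
                "strand_ok": ac.strand_ok,
                "log2_bias": log2_bias,
                "pval": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["contig_id", "pos", "count_A", "count_P", "strand_ok", "log2_bias", "pval"],
    )
    df["qval"] = np.nan
    tested_mask = df["pval"].notna()
    if tested_mask.any():
        _, q, _, _ = multipletests(df.loc[tested_mask, "pval"], method="fdr_bh")
        df.loc[tested_mask, "qval"] = q
    df["significant"] = tested_mask & (df["qval"] < q_threshold)
    log.info(
        "allelic bias: %d SNPs tested, %d significant at q<%g",
        int(tested_mask.sum()), int(df["significant"].sum()), q_threshold,
    )
    return df


# ---------------------------------------------------------------------------
# Contig-level aggregation
# ---------------------------------------------------------------------------


@dataclass
class AlleleBiasResult:
    contig_id: str
    n_snps_tested: int
    n_snps_significant: int
    mean_log2_bias: float  # over significant SNPs; NaN when none
    direction: str  # A_allele | P_allele | inconsistent | none
    inconsistent_flag: bool
    mean_log2_bias_tested: float = np.nan  # over all tested SNPs (finite only)


def aggregate_to_contig(per_snp: pd.DataFrame) -> list[AlleleBiasResult]:
    """One record per contig: flagged when >=1 SNP significant; significant
    SNPs disagreeing in sign mark the contig inconsistent."""
    out = []
    for cid, grp in per_snp.groupby("contig_id", sort=True):
        tested = grp["pval"].notna()
        sig = grp["significant"].astype(bool)
        n_sig = int(sig.sum())
        b_tested = grp.loc[tested, "log2_bias"].to_numpy(dtype=float)
        b_tested = b_tested[np.isfinite(b_tested)]
        mean_tested = float(np.mean(b_tested)) if b_tested.size else np.nan
        if n_sig == 0:
            out.append(AlleleBiasResult(cid, int(tested.sum()), 0, np.nan, "none",
                                        False, mean_tested))
            continue
        biases = grp.loc[sig, "log2_bias"].to_numpy(dtype=float)
        finite = biases[np.isfinite(biases)]
        signs = set(np.sign(biases[~np.isnan(biases)]).astype(int)) - {0}
        if len(signs) > 1:
            direction, inconsistent = "inconsistent", True
        else:
            direction = "A_allele" if signs == {1} else "P_allele"
            inconsistent = False
        mean_bias = float(np.mean(biases)) if np.isfinite(biases).all() else (
            float(np.mean(finite)) if finite.size else (np.inf if signs == {1} else -np.inf)
        )
        out.append(
            AlleleBiasResult(cid, int(tested.sum()), n_sig, mean_bias, direction,
                             inconsistent, mean_tested)
        )
    return out


def bias_results_frame(results: list[AlleleBiasResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig_id": [r.contig_id for r in results],
            "n_snps_tested": [r.n_snps_tested for r in results],
            "n_snps_significant": [r.n_snps_significant for r in results],
            "mean_log2_bias": [r.mean_log2_bias for r in results],
            "mean_log2_bias_tested": [r.mean_log2_bias_tested for r in results],
            "direction": [r.direction for r in results],
            "inconsistent": [r.inconsistent_flag for r in results],
        }
    )


# ---------------------------------------------------------------------------
# cis/trans overlap analyses
# ---------------------------------------------------------------------------


def overlap_with_parental(
    bias_results: list[AlleleBiasResult],
    parental_results: list[PairwiseTestResult],
) -> dict:
    """Overlap of allele-bias contigs with parental-difference contigs, plus
    the direction-agreement fraction inside the overlap.

    parental_results is the A vs P comparison (log2fc is P over A), so a
    positive parental log2fc (P higher) agrees with a P_allele bias direction.
    """
    parental = {r.contig_id: r for r in parental_results}
    tested = [r for r in bias_results if r.n_snps_tested > 0 and r.contig_id in parental]
    bias_sig = {r.contig_id: r for r in tested if r.n_snps_significant > 0}
    parent_sig = {c for c in parental if parental[c].significant}
    both = [bias_sig[c] for c in bias_sig if c in parent_sig]
    agree = 0
    comparable = 0
    for r in both:
        pr = parental[r.contig_id]
        if r.direction in ("A_allele", "P_allele") and pr.mean_norm_A != pr.mean_norm_B:
            comparable += 1
            parent_dir = "P_higher" if pr.mean_norm_B > pr.mean_norm_A else "A_higher"
            if (parent_dir == "A_higher") == (r.direction == "A_allele"):
                agree += 1
    return {
        "n_contigs_tested": len(tested),
        "n_bias_significant": len(bias_sig),
        "n_parent_significant": int(sum(1 for r in tested if r.contig_id in parent_sig)),
        "n_both": len(both),
        "direction_agreement": (agree / comparable) if comparable else np.nan,
    }


def fit_bias_vs_parental(
    bias_results: list[AlleleBiasResult],
    parental_results: list[PairwiseTestResult],
    min_rows: int = 10,
) -> dict:
    """OLS of mean allelic log2 bias (A over P) on the parental log2 difference
    (A over P) across contigs tested in both analyses; infinities dropped.

    Uses the mean bias over all tested SNPs (not just significant ones) so
    that a no-bias contig contributes its near-zero estimate: under pure cis
    regulation the slope is 1; under pure trans it is 0.
    """
    parental = {r.contig_id: r for r in parental_results}
    xs, ys = [], []
    for r in bias_results:
        pr = parental.get(r.contig_id)
        if pr is None or r.n_snps_tested == 0:
            continue
        if pr.log2fc_infinite or not np.isfinite(r.mean_log2_bias_tested):
            continue
        # convert parental log2fc (P over A) to A-over-P to match bias sign
        xs.append(-pr.log2fc)
        ys.append(r.mean_log2_bias_tested)
    if len(xs) < min_rows:
        raise ValidationError(
            f"only {len(xs)} usable contigs (<{min_rows}) for bias-vs-parental fit"
        )
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept, s, r2, _, xm, sxx = _ols(x, y)
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r_squared": float(r2),
        "slope_se": float(s / np.sqrt(sxx)),
        "n": len(x),
    }
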