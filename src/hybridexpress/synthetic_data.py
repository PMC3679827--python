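"""Synthetic count matrices and pileup tables with known ground truth.

Emulates the study design (2 parent-A + 2 parent-P + 8 F1 libraries over a
contig reference) with planted parental differences, cis (allelic-bias)
effects, trans effects, transgressive and high-variance contigs, fixed SNPs,
filter-violating decoy sites and one-strand artifacts. Everything is
deterministic given the seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import BASES, CountMatrix, PileupSite, SampleSheet

MODES = (
    "null",
    "trans_diff",
    "cis_diff",
    "transgressive_high",
    "transgressive_low",
    "high_variance",
)

#: site-level violation labels; "none" sites must pass every fixed-SNP filter
VIOLATIONS = ("none", "low_qual", "low_depth", "parent_poly", "both_alt", "strand_artifact")


class ConfigError(ValueError):
    pass


def default_sample_sheet() -> SampleSheet:
    """The study layout: 2 A + 2 P + 8 F1, one sample per parent group and one
    F1 marked for exclusion in the reduced analysis."""
    ids = ["A.1", "A.2", "P.1", "P.2"] + [f"F1.{i}" for i in range(1, 9)]
    groups = ["A", "A", "P", "P"] + ["F1"] * 8
    excluded = [False, True, False, False] + [False] * 7 + [True]
    return SampleSheet(tuple(ids), tuple(groups), tuple(excluded))


@dataclass(frozen=True)
class SimConfig:
    n_contigs: int = 2000
    samples: SampleSheet = field(default_factory=default_sample_sheet)
    base_mean_log10_range: tuple[float, float] = (0.5, 3.5)
    dispersion: float = 0.05
    fraction_parent_diff: float = 0.08  # trans-only parental differences
    fraction_cis: float = 0.05
    fraction_trans: float = 0.0  # extra trans fraction (merged with parent_diff)
    fraction_transgressive: float = 0.01
    fraction_high_variance: float = 0.01
    parent_log2fc_magnitude: float = 2.0
    transgressive_multiplier: float = 5.0
    high_variance_sigma: float = 1.5
    snps_per_contig_mean: float = 1.0
    mean_allele_depth: float = 30.0
    strand_artifact_rate: float = 0.0
    filter_violation_fraction: float = 0.0  # of planted sites, split over 4 kinds
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_parent_diff,
            self.fraction_cis,
            self.fraction_trans,
            self.fraction_transgressive,
            self.fraction_high_variance,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigError("effect fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-12:
            raise ConfigError("effect-class fractions sum to more than 1")
        if self.n_contigs <= 0:
            raise ConfigError("n_contigs must be positive")
        if self.dispersion < 0 or self.high_variance_sigma < 0:
            raise ConfigError("dispersion and high_variance_sigma must be >=0")
        if self.transgressive_multiplier <= 1:
            raise ConfigError("transgressive_multiplier must exceed 1")
        for r in (
            self.strand_artifact_rate,
            self.filter_violation_fraction,
        ):
            if r < 0 or r > 1:
                raise ConfigError("rates must lie in [0, 1]")
        if self.mean_allele_depth <= 0 or self.snps_per_contig_mean < 0:
            raise ConfigError("depths must be positive, snps_per_contig_mean >=0")


@dataclass
class TruthTable:
    """Planted ground truth: one row per contig, optionally one per SNP site."""

    contigs: pd.DataFrame  # contig_id, mode, mu_A, mu_P, mu_F1, allele_ratio, n_snps
    sites: pd.DataFrame | None = None  # filled by simulate_pileups

    def contigs_with_mode(self, mode: str) -> list[str]:
        return list(self.contigs.loc[self.contigs["mode"] == mode, "contig_id"])


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    # crc32, not hash(): the latter is salted per process and would break
    # cross-run determinism
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(stream.encode())])
    )


def generate_truth(config: SimConfig) -> TruthTable:
    """Draw per-contig modes and expected group means.

    trans_diff (and the extra fraction_trans) plant mu_A != mu_P with F1 at the
    midparent and allele ratio 1; cis_diff plants the same parental split but
    with allele_ratio = mu_A/mu_P; transgressive modes push mu_F1 outside the
    parental range; high_variance keeps means equal and adds per-plant noise at
    count-simulation time.
    """
    rng = _rng(config, "truth")
    n = config.n_contigs
    probs = [
        config.fraction_parent_diff + config.fraction_trans,
        config.fraction_cis,
        config.fraction_transgressive / 2,
        config.fraction_transgressive / 2,
        config.fraction_high_variance,
    ]
    p_null = 1.0 - sum(probs)
    modes = rng.choice(
        ["trans_diff", "cis_diff", "transgressive_high", "transgressive_low",
         "high_variance", "null"],
        size=n,
        p=probs + [p_null],
    )
    lo, hi = config.base_mean_log10_range
    base = 10 ** rng.uniform(lo, hi, size=n)
    fc = 2.0**config.parent_log2fc_magnitude
    up_in_A = rng.random(n) < 0.5  # direction of parental difference

    mu_A = base.copy()
    mu_P = base.copy()
    mu_F1 = base.copy()
    ratio = np.ones(n)
    diff = (modes == "trans_diff") | (modes == "cis_diff")
    # split the planted fold change symmetrically around the base mean
    mu_A[diff & up_in_A] *= np.sqrt(fc)
    mu_P[diff & up_in_A] /= np.sqrt(fc)
    mu_A[diff & ~up_in_A] /= np.sqrt(fc)
    mu_P[diff & ~up_in_A] *= np.sqrt(fc)
    mu_F1[diff] = (mu_A[diff] + mu_P[diff]) / 2
    cis = modes == "cis_diff"
    ratio[cis] = mu_A[cis] / mu_P[cis]
    mu_F1[modes == "transgressive_high"] *= config.transgressive_multiplier
    mu_F1[modes == "transgressive_low"] /= config.transgressive_multiplier

    if config.snps_per_contig_mean > 0:
        n_snps = rng.poisson(config.snps_per_contig_mean, size=n)
    else:
        n_snps = np.zeros(n, dtype=int)
    # cis effects are only observable through SNPs: guarantee at least one
    n_snps[cis & (n_snps == 0)] = 1

    contigs = pd.DataFrame(
        {
            "contig_id": [f"contig{i:06d}" for i in range(n)],
            "mode": modes,
            "mu_A": mu_A,
            "mu_P": mu_P,
            "mu_F1": mu_F1,
            "allele_ratio": ratio,
            "n_snps": n_snps,
        }
    )
    return TruthTable(contigs=contigs)


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, alpha: float
) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if alpha <= 1e-12:
        return rng.poisson(mean)
    size = 1.0 / alpha
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size, size / (size + mean[pos]))
    return out


def simulate_counts(truth: TruthTable, config: SimConfig) -> CountMatrix:
    """NB counts with per-sample size factors log-uniform in the configured
    range; high-variance contigs get an extra lognormal per-F1 multiplier."""
    rng = _rng(config, "counts")
    sheet = config.samples
    n = len(truth.contigs)
    lo, hi = config.size_factor_range
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(sheet.sample_ids)))

    mu_by_group = {
        "A": truth.contigs["mu_A"].to_numpy(),
        "P": truth.contigs["mu_P"].to_numpy(),
        "F1": truth.contigs["mu_F1"].to_numpy(),
    }
    hv = (truth.contigs["mode"] == "high_variance").to_numpy()
    counts = np.zeros((n, len(sheet.sample_ids)), dtype=np.int64)
    for j, (sample, group) in enumerate(zip(sheet.sample_ids, sheet.groups)):
        mean = s[j] * mu_by_group[group]
        if group == "F1" and hv.any():
            mult = np.ones(n)
            mult[hv] = rng.lognormal(0.0, config.high_variance_sigma, size=hv.sum())
            mean = mean * mult
        counts[:, j] = _nb_draw(rng, mean, config.dispersion)
    return CountMatrix(
        contig_ids=list(truth.contigs["contig_id"]),
        sample_ids=list(sheet.sample_ids),
        counts=counts,
    )


def _pick_bases(rng: np.random.Generator) -> tuple[str, str, str]:
    """(ref, allele_A, allele_P): parents split ref/alt in random orientation."""
    ref, alt = rng.choice(len(BASES), size=2, replace=False)
    ref_b, alt_b = BASES[ref], BASES[alt]
    if rng.random() < 0.5:
        return ref_b, ref_b, alt_b
    return ref_b, alt_b, ref_b


def _split_strands(rng: np.random.Generator, depth: int) -> tuple[int, int]:
    fwd = int(rng.binomial(depth, 0.5)) if depth > 0 else 0
    return fwd, depth - fwd


def simulate_pileups(
    truth: TruthTable, counts: CountMatrix, config: SimConfig
) -> list[PileupSite]:
    """Plant fixed SNP sites consistent with the simulated counts.

    Per-site per-sample depth is a binomial thinning of that sample's contig
    count (capture fraction targeting mean_allele_depth reads of each allele
    in F1s). Parent samples carry their accession allele exclusively; F1 reads
    split between alleles at the truth allele ratio. Strand assignment is
    Bernoulli(0.5). A configurable fraction of sites violates one of the four
    fixed-SNP filters; strand artifacts are extra spurious sites whose alt
    reads sit on a single strand. Site labels land in truth.sites.
    """
    rng = _rng(config, "pileups")
    sheet = config.samples
    col = {s: j for j, s in enumerate(counts.sample_ids)}
    a_samples = sheet.samples_in("A")
    p_samples = sheet.samples_in("P")
    f1_samples = sheet.samples_in("F1")

    sites: list[PileupSite] = []
    site_rows: list[dict] = []
    violation_kinds = ("low_qual", "low_depth", "parent_poly", "both_alt")

    for row in truth.contigs.itertuples(index=False):
        n_snps = int(row.n_snps)
        if n_snps == 0:
            continue
        cid = row.contig_id
        crow = counts.counts[counts.contig_ids.index(cid)]
        mean_count = max(crow.mean(), 1.0)
        # both-allele depth per F1 sample targets 2 * mean_allele_depth reads
        f = min(1.0, 2.0 * config.mean_allele_depth / mean_count)
        positions = rng.choice(np.arange(1, 2001), size=n_snps, replace=False)
        for pos in np.sort(positions):
            violation = "none"
            if config.filter_violation_fraction > 0 and rng.random() < config.filter_violation_fraction:
                violation = violation_kinds[int(rng.integers(len(violation_kinds)))]

            ref_b, allele_a, allele_p = _pick_bases(rng)
            if violation == "both_alt":
                # both accessions uniformly carry the same non-reference base
                alt_b = allele_a if allele_a != ref_b else allele_p
                allele_a = allele_p = alt_b
            else:
                alt_b = allele_a if allele_a != ref_b else allele_p

            qual = float(rng.uniform(80.0, 220.0))
            if violation == "low_qual":
                qual = float(rng.uniform(0.0, 79.0))

            depths: dict[str, tuple[int, int, int, int]] = {}

            def depth_for(sample: str, floor: int = 5) -> int:
                d = int(rng.binomial(int(crow[col[sample]]), f))
                return max(d, floor)  # keep pass-sites above the depth filter

            low_depth_victim = (
                rng.choice(a_samples + p_samples) if violation == "low_depth" else None
            )
            poly_victim = (
                rng.choice(a_samples + p_samples) if violation == "parent_poly" else None
            )
            for s in a_samples + p_samples:
                allele = allele_a if s in a_samples else allele_p
                d = depth_for(s)
                if s == low_depth_victim:
                    d = int(rng.integers(0, 5))
                main, other = d, 0
                if s == poly_victim and d >= 2:
                    other = max(1, int(rng.binomial(d, 0.3)))
                    main = d - other
                main_f, main_r = _split_strands(rng, main)
                other_f, other_r = _split_strands(rng, other)
                other_base = allele_p if allele == allele_a else allele_a
                rf = rr = af = ar = 0
                if allele == ref_b:
                    rf, rr = main_f, main_r
                else:
                    af, ar = main_f, main_r
                if other > 0:
                    if other_base == ref_b:
                        rf, rr = rf + other_f, rr + other_r
                    else:
                        af, ar = af + other_f, ar + other_r
                depths[s] = (rf, rr, af, ar)

            p_a = float(row.allele_ratio / (1.0 + row.allele_ratio))
            for s in f1_samples:
                d = int(rng.binomial(int(crow[col[s]]), f))
                d_a = int(rng.binomial(d, p_a)) if d > 0 else 0
                d_p = d - d_a
                a_f, a_r = _split_strands(rng, d_a)
                p_f, p_r = _split_strands(rng, d_p)
                if allele_a == ref_b:
                    depths[s] = (a_f, a_r, p_f, p_r)
                else:
                    depths[s] = (p_f, p_r, a_f, a_r)

            if violation == "both_alt":
                # rebuild as uniform-alt: every parental read is the alt base
                for s in a_samples + p_samples:
                    rf, rr, af, ar = depths[s]
                    depths[s] = (0, 0, rf + af, rr + ar)
                for s in f1_samples:
                    rf, rr, af, ar = depths[s]
                    depths[s] = (0, 0, rf + af, rr + ar)

            sites.append(
                PileupSite(
                    contig_id=cid,
                    pos=int(pos),
                    ref_base=ref_b,
                    alt_base=alt_b if alt_b != ref_b else ("A" if ref_b != "A" else "C"),
                    site_quality=qual,
                    depths=depths,
                )
            )
            site_rows.append(
                {
                    "contig_id": cid,
                    "pos": int(pos),
                    "allele_A": allele_a,
                    "allele_P": allele_p,
                    "violation": violation,
                    "allele_ratio": float(row.allele_ratio),
                }
            )

        if config.strand_artifact_rate > 0 and rng.random() < config.strand_artifact_rate:
            # passes every parental fixed-SNP filter, but one F1 allele's reads
            # sit on a single strand: must be dropped at dp4 extraction
            pos = int(rng.integers(2001, 2500))
            ref_b, alt_b = (BASES[i] for i in rng.choice(len(BASES), 2, replace=False))
            strand_fwd = bool(rng.random() < 0.5)
            depths = {}
            for s in a_samples + p_samples:
                d = max(5, int(rng.binomial(int(crow[col[s]]), f)))
                d_f, d_r = _split_strands(rng, d)
                if s in a_samples:  # accession A carries the reference base
                    depths[s] = (d_f, d_r, 0, 0)
                else:
                    depths[s] = (0, 0, d_f, d_r)
            for s in f1_samples:
                d = int(rng.binomial(int(crow[col[s]]), f))
                d_ref = int(rng.binomial(d, 0.5)) if d > 0 else 0
                d_alt = max(1, d - d_ref)
                rf, rr = _split_strands(rng, d_ref)
                af, ar = (d_alt, 0) if strand_fwd else (0, d_alt)
                depths[s] = (rf, rr, af, ar)
            sites.append(
                PileupSite(
                    contig_id=cid,
                    pos=pos,
                    ref_base=ref_b,
                    alt_base=alt_b,
                    site_quality=float(rng.uniform(80.0, 220.0)),
                    depths=depths,
                )
            )
            site_rows.append(
                {
                    "contig_id": cid,
                    "pos": pos,
                    "allele_A": ref_b,
                    "allele_P": alt_b,
                    "violation": "strand_artifact",
                    "allele_ratio": 1.0,
                }
            )

    truth.sites = pd.DataFrame(
        site_rows,
        columns=["contig_id", "pos", "allele_A", "allele_P", "violation", "allele_ratio"],
    )
    return sites


def simulate_all(config: SimConfig) -> tuple[TruthTable, CountMatrix, list[PileupSite]]:
    truth = generate_truth(config)
    counts = simulate_counts(truth, config)
    pileups = simulate_pileups(truth, counts, config)
    return truth, counts, pileups
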