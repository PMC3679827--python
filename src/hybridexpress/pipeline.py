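"""End-to-end orchestration: full and reduced analyses, flag merging, reports.

Runs the three pairwise comparisons, the midparent/transgressive/CV screens
and the allelic-bias track on both the complete sample set and the reduced
set (outlier samples dropped), then merges per-flag calls with full/reduced
provenance into one classification row per contig.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allelic_bias as ab
from . import diff_accumulation as da
from . import inheritance_modes as im
from .core_io import (
    ContigClassification,
    CountMatrix,
    PileupSite,
    SampleSheet,
    ValidationError,
    read_count_matrix,
    read_pileup_table,
    read_sample_sheet,
    write_classification_table,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    counts_path: str = ""
    samples_path: str = ""
    pileup_path: str | None = None
    out_dir: str = "results"
    q_threshold: float = 0.01
    ci_level: float = 0.99
    cv_threshold: float = 2.0
    cv_formula: str = "lognormal_standard"
    min_qual: float = 80.0
    min_depth: int = 5
    run_reduced: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.q_threshold < 1) or not (0 < self.ci_level < 1):
            raise ValidationError("q_threshold and ci_level must lie in (0, 1)")
        if self.cv_threshold < 0 or self.min_qual < 0 or self.min_depth < 0:
            raise ValidationError("thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class AnalysisResult:
    """One sample set's complete outputs."""

    label: str  # "full" or "reduced"
    sheet: SampleSheet
    size_factors: da.SizeFactors
    da_results: dict[str, list[da.PairwiseTestResult]]  # "A_vs_P", "A_vs_F1", "P_vs_F1"
    group_means: pd.DataFrame
    fit: im.AdditivityFit
    nonadditive: pd.DataFrame
    transgressive: pd.DataFrame
    cv: list[im.CvResult]
    bias_by_snp: pd.DataFrame | None
    bias_by_contig: list[ab.AlleleBiasResult] | None
    fixed_snps: list[ab.FixedSnp] | None


@dataclass
class AnalysisBundle:
    config: RunConfig
    full: AnalysisResult
    reduced: AnalysisResult | None
    outlier_screen: pd.DataFrame


COMPARISONS = (("A_vs_P", "A", "P"), ("A_vs_F1", "A", "F1"), ("P_vs_F1", "P", "F1"))


def _analyze(
    label: str,
    counts: CountMatrix,
    sheet: SampleSheet,
    pileups: list[PileupSite] | None,
    cfg: RunConfig,
    fixed: list[ab.FixedSnp] | None = None,
) -> AnalysisResult:
    log.info("[%s] analysis over samples: %s", label, ", ".join(sheet.sample_ids))
    sub = counts.subset_samples(list(sheet.sample_ids))
    sf = da.estimate_size_factors(sub)
    groups = da.groups_from_sheet(sheet)
    disp = da.estimate_dispersions(sub, sf, groups).alpha

    results = {}
    for name, gx, gy in COMPARISONS:
        results[name] = da.pairwise_da(
            sub, sf, disp, groups[gx], groups[gy], q_threshold=cfg.q_threshold
        )

    means = im.midparent_means(sub, sf, sheet)
    fit = im.fit_midparent_model(means, ci_level=cfg.ci_level)
    nonadd = im.classify_nonadditive(fit, means)
    transgressive = im.classify_transgressive(
        results["A_vs_F1"], results["P_vs_F1"], means
    )
    cv = im.cv_f1(
        sub, sf, groups["F1"], threshold=cfg.cv_threshold, formula=cfg.cv_formula
    )

    bias_by_snp = bias_by_contig = None
    if pileups is not None:
        if fixed is None:
            fixed = ab.call_fixed_snps(
                pileups, sheet, min_qual=cfg.min_qual, min_depth=cfg.min_depth
            )
        allele_counts = ab.extract_allele_counts(fixed, pileups, groups["F1"])
        bias_by_snp = ab.test_allelic_bias(
            allele_counts, sf, groups["F1"], q_threshold=cfg.q_threshold
        )
        bias_by_contig = ab.aggregate_to_contig(bias_by_snp)

    return AnalysisResult(
        label=label,
        sheet=sheet,
        size_factors=sf,
        da_results=results,
        group_means=means,
        fit=fit,
        nonadditive=nonadd,
        transgressive=transgressive,
        cv=cv,
        bias_by_snp=bias_by_snp,
        bias_by_contig=bias_by_contig,
        fixed_snps=fixed,
    )


def run_full_and_reduced(
    counts: CountMatrix,
    sheet: SampleSheet,
    pileups: list[PileupSite] | None,
    cfg: RunConfig,
) -> AnalysisBundle:
    screen = im.sample_outlier_screen(counts.subset_samples(list(sheet.sample_ids)), sheet)
    full = _analyze("full", counts, sheet, pileups, cfg)
    reduced = None
    if cfg.run_reduced:
        red_sheet = sheet.reduced()
        if red_sheet is sheet:
            log.info("no samples excluded; reduced analysis duplicates the full one")
        # fixed SNPs are discovered once, from the complete parental panel
        reduced = _analyze("reduced", counts, red_sheet, pileups, cfg, fixed=full.fixed_snps)
    return AnalysisBundle(config=cfg, full=full, reduced=reduced, outlier_screen=screen)


# ---------------------------------------------------------------------------
# Flag merging
# ---------------------------------------------------------------------------


def _merge_flag(val_full, val_reduced, inactive) -> tuple[object, str | None]:
    """Combine one flag across analyses -> (merged value, provenance or None).

    Active in both with equal value -> both; active in one -> that analysis;
    active in both but different -> keep the full call, provenance full_only.
    """
    act_f = val_full != inactive
    act_r = val_reduced != inactive
    if act_f and act_r:
        if val_full == val_reduced:
            return val_full, "both"
        return val_full, "full_only"
    if act_f:
        return val_full, "full_only"
    if act_r:
        return val_reduced, "reduced_only"
    return inactive, None


def _species_direction(r: da.PairwiseTestResult) -> str:
    if not r.significant:
        return "none"
    # A vs P comparison: mean_norm_B is the P group
    return "P_higher" if r.mean_norm_B > r.mean_norm_A else "A_higher"


def _flag_maps(res: AnalysisResult) -> dict[str, dict[str, object]]:
    species = {r.contig_id: _species_direction(r) for r in res.da_results["A_vs_P"]}
    nonadd = dict(zip(res.nonadditive["contig_id"], res.nonadditive["non_additive"]))
    trans = dict(zip(res.transgressive["contig_id"], res.transgressive["transgressive"]))
    cv = {r.contig_id: r.high_cv for r in res.cv}
    bias: dict[str, object] = {}
    if res.bias_by_contig is not None:
        bias = {
            r.contig_id: (r.direction if r.n_snps_significant > 0 else "none")
            for r in res.bias_by_contig
        }
    return {
        "species_difference": species,
        "non_additive": nonadd,
        "transgressive": trans,
        "high_cv": cv,
        "allelic_bias": bias,
    }


_INACTIVE = {
    "species_difference": "none",
    "non_additive": "intermediate",
    "transgressive": "none",
    "high_cv": False,
    "allelic_bias": "none",
}


def classify_all(bundle: AnalysisBundle) -> list[ContigClassification]:
    """Merge per-analysis flags into one classification row per contig."""
    maps_full = _flag_maps(bundle.full)
    maps_red = _flag_maps(bundle.reduced) if bundle.reduced is not None else None
    contigs = [r.contig_id for r in bundle.full.da_results["A_vs_P"]]
    rows = []
    for cid in contigs:
        values: dict[str, object] = {}
        provenance: dict[str, str] = {}
        for flag, inactive in _INACTIVE.items():
            vf = maps_full[flag].get(cid, inactive)
            if maps_red is None:
                values[flag] = vf
                if vf != inactive:
                    provenance[flag] = "full_only"
                continue
            vr = maps_red[flag].get(cid, inactive)
            merged, prov = _merge_flag(vf, vr, inactive)
            values[flag] = merged
            if prov is not None:
                provenance[flag] = prov
        rows.append(
            ContigClassification(
                contig_id=cid,
                species_difference=values["species_difference"],
                non_additive=values["non_additive"],
                transgressive=values["transgressive"],
                high_cv=bool(values["high_cv"]),
                allelic_bias=values["allelic_bias"],
                provenance=provenance,
            )
        )
    return rows


def summary_counts(rows: list[ContigClassification]) -> dict[str, int]:
    return {
        "n_contigs": len(rows),
        "species_difference": sum(r.species_difference != "none" for r in rows),
        "species_A_higher": sum(r.species_difference == "A_higher" for r in rows),
        "species_P_higher": sum(r.species_difference == "P_higher" for r in rows),
        "non_additive": sum(r.non_additive != "intermediate" for r in rows),
        "non_additive_above": sum(r.non_additive == "above" for r in rows),
        "non_additive_below": sum(r.non_additive == "below" for r in rows),
        "transgressive": sum(r.transgressive != "none" for r in rows),
        "transgressive_high": sum(r.transgressive == "HIGH" for r in rows),
        "transgressive_low": sum(r.transgressive == "LOW" for r in rows),
        "high_cv": sum(r.high_cv for r in rows),
        "allelic_bias": sum(r.allelic_bias != "none" for r in rows),
        "allelic_bias_A": sum(r.allelic_bias == "A_allele" for r in rows),
        "allelic_bias_P": sum(r.allelic_bias == "P_allele" for r in rows),
        "allelic_bias_inconsistent": sum(r.allelic_bias == "inconsistent" for r in rows),
    }


# ---------------------------------------------------------------------------
# File-level entry point
# ---------------------------------------------------------------------------


def run_from_files(cfg: RunConfig) -> tuple[AnalysisBundle, list[ContigClassification]]:
    counts = read_count_matrix(cfg.counts_path)
    sheet = read_sample_sheet(cfg.samples_path)
    pileups = None
    if cfg.pileup_path:
        pileups = read_pileup_table(cfg.pileup_path, sheet)
    bundle = run_full_and_reduced(counts, sheet, pileups, cfg)
    rows = classify_all(bundle)
    write_outputs(bundle, rows, Path(cfg.out_dir))
    return bundle, rows


def write_outputs(
    bundle: AnalysisBundle, rows: list[ContigClassification], out_dir: Path
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    analyses = [bundle.full] + ([bundle.reduced] if bundle.reduced else [])
    for res in analyses:
        for name, results in res.da_results.items():
            da.results_frame(results).to_csv(
                out_dir / f"da_{name}_{res.label}.tsv", sep="\t", index=False
            )
        res.nonadditive.to_csv(
            out_dir / f"nonadditive_{res.label}.tsv", sep="\t", index=False
        )
        if res.bias_by_snp is not None:
            res.bias_by_snp.to_csv(
                out_dir / f"bias_by_snp_{res.label}.tsv", sep="\t", index=False
            )
            ab.bias_results_frame(res.bias_by_contig).to_csv(
                out_dir / f"bias_by_contig_{res.label}.tsv", sep="\t", index=False
            )
    bundle.outlier_screen.to_csv(out_dir / "outlier_screen.tsv", sep="\t", index=False)
    write_classification_table(rows, out_dir / "classification.tsv")
    with open(out_dir / "summary.txt", "w") as fh:
        fh.write(render_summary(bundle, rows))
    log.info("outputs written to %s", out_dir)


def render_summary(bundle: AnalysisBundle, rows: list[ContigClassification]) -> str:
    lines = ["hybridexpress run summary", "=" * 26, ""]
    cfg = bundle.config
    lines.append(
        f"thresholds: q<{cfg.q_threshold}, prediction level {cfg.ci_level}, "
        f"CV>{cfg.cv_threshold} ({cfg.cv_formula}), SNP qual>={cfg.min_qual}, "
        f"depth>={cfg.min_depth}"
    )
    analyses = [bundle.full] + ([bundle.reduced] if bundle.reduced else [])
    for res in analyses:
        lines.append("")
        lines.append(f"[{res.label}] samples: {', '.join(res.sheet.sample_ids)}")
        f = res.fit
        lines.append(
            f"[{res.label}] midparent model: slope {f.slope:.4f} (+-{f.slope_se:.4f}), "
            f"intercept {f.intercept:.3f} (+-{f.intercept_se:.3f}), "
            f"R^2 {f.r_squared:.4f}, removed {len(f.removed_contigs)} contigs"
        )
        for name, results in res.da_results.items():
            n_sig = sum(r.significant for r in results)
            n_tested = sum(not np.isnan(r.pvalue) for r in results)
            lines.append(f"[{res.label}] {name}: {n_sig} significant of {n_tested} tested")
        if res.bias_by_snp is not None:
            n_snp_sig = int(res.bias_by_snp["significant"].sum())
            n_contig_sig = sum(r.n_snps_significant > 0 for r in res.bias_by_contig)
            lines.append(
                f"[{res.label}] allelic bias: {len(res.fixed_snps)} fixed SNPs, "
                f"{n_snp_sig} significant sites in {n_contig_sig} contigs"
            )
    lines.append("")
    lines.append("merged classification counts:")
    for k, v in summary_counts(rows).items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    return "\n".join(lines)
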