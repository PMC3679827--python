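"""Domain types and TSV readers/writers.

All tabular artifacts are plain TSV with a header row. Pileup positions are
1-based. Count matrices are keyed by contig id; row order is preserved on
round-trip but carries no meaning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GROUPS = ("A", "P", "F1")

#: ASCII tokens used in the classification table (glyph-free encoding).
SPECIES_CODES = {"A_higher": "A", "P_higher": "P", "none": "NONE"}
NONADD_CODES = {"above": "UP", "below": "DOWN", "intermediate": "MID"}
TRANSGRESSIVE_CODES = {"HIGH": "UP", "LOW": "DOWN", "none": "NONE"}
BIAS_CODES = {
    "A_allele": "A",
    "P_allele": "P",
    "inconsistent": "INCONSISTENT",
    "none": "NONE",
}
PROVENANCE_CODES = {
    "both": "BOTH",
    "full_only": "FULL",
    "reduced_only": "REDUCED",
    "neither": "NONE",
}


class FormatError(ValueError):
    """Malformed cell or row in an input file."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSheet:
    """Assignment of samples to groups (parent A, parent P, F1 hybrids).

    ``excluded_in_reduced`` marks samples dropped from the reduced analysis;
    each group must stay non-empty after dropping them.
    """

    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]
    excluded_in_reduced: tuple[bool, ...]
    #: reduced-analysis sheets may keep a single sample per parental group
    is_reduced: bool = False

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_id in sample sheet")
        if len(self.groups) != len(self.sample_ids) or len(
            self.excluded_in_reduced
        ) != len(self.sample_ids):
            raise ValidationError("sample sheet field lengths differ")
        for g in self.groups:
            if g not in GROUPS:
                raise ValidationError(f"unknown group {g!r}; expected one of {GROUPS}")
        min_parent = 1 if self.is_reduced else 2
        for g in ("A", "P"):
            if len(self.samples_in(g)) < min_parent:
                raise ValidationError(
                    f"need >={min_parent} samples in parental group {g}"
                )
        if len(self.samples_in("F1")) < 2:
            raise ValidationError("need >=2 F1 samples")
        for g in GROUPS:
            survivors = [
                s for s, grp, ex in zip(self.sample_ids, self.groups, self.excluded_in_reduced)
                if grp == g and not ex
            ]
            if not survivors:
                raise ValidationError(
                    f"group {g} would be empty after reduced-set exclusions"
                )

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.groups) if g == group]

    def group_of(self, sample_id: str) -> str:
        return self.groups[self.sample_ids.index(sample_id)]

    def reduced(self) -> "SampleSheet":
        """Sample sheet restricted to samples kept in the reduced analysis."""
        keep = [not x for x in self.excluded_in_reduced]
        if all(keep):
            return self
        return SampleSheet(
            sample_ids=tuple(s for s, k in zip(self.sample_ids, keep) if k),
            groups=tuple(g for g, k in zip(self.groups, keep) if k),
            excluded_in_reduced=tuple(False for k in keep if k),
            is_reduced=True,
        )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "group", "excluded_in_reduced"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"sample sheet missing column {col!r}")
    excl = []
    for i, raw in enumerate(df["excluded_in_reduced"]):
        token = str(raw).strip().lower()
        if token in ("true", "1", "yes"):
            excl.append(True)
        elif token in ("false", "0", "no"):
            excl.append(False)
        else:
            raise FormatError(
                f"sample sheet row {i + 1}: bad excluded_in_reduced value {raw!r}"
            )
    return SampleSheet(
        sample_ids=tuple(df["sample_id"]),
        groups=tuple(df["group"]),
        excluded_in_reduced=tuple(excl),
    )


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": sheet.sample_ids,
            "group": sheet.groups,
            "excluded_in_reduced": [str(x).lower() for x in sheet.excluded_in_reduced],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Contig x sample matrix of non-negative integer read counts."""

    contig_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_contigs, n_samples), integer dtype
    contig_lengths: np.ndarray | None = None  # bases; optional

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.contig_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.contig_ids)} contigs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at contig {self.contig_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if len(set(self.contig_ids)) != len(self.contig_ids):
            seen: set[str] = set()
            dup = next(c for c in self.contig_ids if c in seen or seen.add(c))
            raise ValidationError(f"duplicate contig_id {dup!r}")
        if self.contig_lengths is not None:
            self.contig_lengths = np.asarray(self.contig_lengths)
            if len(self.contig_lengths) != len(self.contig_ids) or np.any(
                self.contig_lengths <= 0
            ):
                raise ValidationError("contig_lengths must be positive, one per contig")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"samples absent from count matrix: {missing}")
        return np.array([pos[s] for s in sample_ids], dtype=int)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = self.sample_index(sample_ids)
        return CountMatrix(
            contig_ids=list(self.contig_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx].copy(),
            contig_lengths=None
            if self.contig_lengths is None
            else self.contig_lengths.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.contig_ids, columns=self.sample_ids)


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix (first column contig_id, then one column per sample)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("count matrix needs a contig_id column and >=1 sample column")
    contig_col = df.columns[0]
    length_cols = [c for c in df.columns[1:] if c == "length"]
    sample_cols = [c for c in df.columns[1:] if c != "length"]
    counts = np.empty((len(df), len(sample_cols)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        for i, raw in enumerate(df[col]):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer count {raw!r} at row {df[contig_col][i]!r}, "
                    f"column {col!r}"
                ) from None
            if v < 0:
                raise FormatError(
                    f"negative count {raw!r} at row {df[contig_col][i]!r}, "
                    f"column {col!r}"
                )
            counts[i, j] = v
    lengths = None
    if length_cols:
        lengths = df["length"].astype(np.int64).to_numpy()
    cm = CountMatrix(
        contig_ids=list(df[contig_col]),
        sample_ids=sample_cols,
        counts=counts,
        contig_lengths=lengths,
    )
    log.info("read count matrix: %d contigs x %d samples", *cm.shape)
    return cm


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    df = cm.to_frame()
    df.index.name = "contig_id"
    if cm.contig_lengths is not None:
        df.insert(0, "length", cm.contig_lengths)
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Pileup table
# ---------------------------------------------------------------------------

BASES = ("A", "C", "G", "T")


@dataclass
class PileupSite:
    """One variant site: strand-resolved ref/alt depths per sample (dp4)."""

    contig_id: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    site_quality: float
    depths: dict[str, tuple[int, int, int, int]]  # sample -> (rf, rr, af, ar)

    def __post_init__(self) -> None:
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise ValidationError(
                f"{self.contig_id}:{self.pos}: bases must be in {BASES}"
            )
        if self.ref_base == self.alt_base:
            raise ValidationError(
                f"{self.contig_id}:{self.pos}: ref_base equals alt_base "
                f"({self.ref_base!r})"
            )
        if self.pos < 1:
            raise ValidationError(f"{self.contig_id}:{self.pos}: pos must be >=1")
        if self.site_quality < 0:
            raise ValidationError(f"{self.contig_id}:{self.pos}: negative quality")
        for sample, dp4 in self.depths.items():
            if len(dp4) != 4 or any(int(d) != d or d < 0 for d in dp4):
                raise ValidationError(
                    f"{self.contig_id}:{self.pos}: bad dp4 for sample {sample!r}"
                )

    def total_depth(self, sample: str) -> int:
        return sum(self.depths[sample])

    def allele_depth(self, sample: str, base: str) -> int:
        """Strand-summed depth of `base` (must be ref or alt) in one sample."""
        rf, rr, af, ar = self.depths[sample]
        if base == self.ref_base:
            return rf + rr
        if base == self.alt_base:
            return af + ar
        return 0

    def allele_strand_depths(self, samples: Iterable[str], base: str) -> tuple[int, int]:
        """(forward, reverse) depth of `base` pooled over `samples`."""
        fwd = rev = 0
        for s in samples:
            rf, rr, af, ar = self.depths[s]
            if base == self.ref_base:
                fwd, rev = fwd + rf, rev + rr
            elif base == self.alt_base:
                fwd, rev = fwd + af, rev + ar
        return fwd, rev


def _pileup_columns(sample_ids: Sequence[str]) -> list[str]:
    cols = ["contig", "pos", "ref", "alt", "qual"]
    for s in sample_ids:
        cols += [f"{s}_rf", f"{s}_rr", f"{s}_af", f"{s}_ar"]
    return cols


def read_pileup_table(path: str | Path, sheet: SampleSheet) -> list[PileupSite]:
    """Read a pileup TSV; per-sample dp4 column blocks follow sample-sheet order."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = _pileup_columns(sheet.sample_ids)
    if list(df.columns) != expected:
        raise FormatError(
            f"pileup columns {list(df.columns)} do not match sample sheet "
            f"(expected {expected})"
        )
    sites: list[PileupSite] = []
    for i, row in enumerate(df.itertuples(index=False)):
        depths = {}
        for k, s in enumerate(sheet.sample_ids):
            # positional indexing: itertuples mangles underscore column names
            dp4 = tuple(int(row[5 + 4 * k + m]) for m in range(4))
            if any(d < 0 for d in dp4):
                raise FormatError(f"pileup row {i + 1}: negative depth for {s}")
            depths[s] = dp4
        try:
            sites.append(
                PileupSite(
                    contig_id=str(row[0]),
                    pos=int(row[1]),
                    ref_base=str(row[2]),
                    alt_base=str(row[3]),
                    site_quality=float(row[4]),
                    depths=depths,
                )
            )
        except ValidationError as e:
            raise ValidationError(f"pileup row {i + 1}: {e}") from None
    log.info("read pileup table: %d sites, %d samples", len(sites), len(sheet.sample_ids))
    return sites


def write_pileup_table(
    sites: Sequence[PileupSite], sheet: SampleSheet, path: str | Path
) -> None:
    cols = _pileup_columns(sheet.sample_ids)
    rows = []
    for site in sites:
        row = [site.contig_id, site.pos, site.ref_base, site.alt_base, site.site_quality]
        for s in sheet.sample_ids:
            row.extend(site.depths[s])
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Classification table
# ---------------------------------------------------------------------------


@dataclass
class ContigClassification:
    """Merged per-contig flags with full/reduced provenance per flag."""

    contig_id: str
    species_difference: str = "none"  # A_higher | P_higher | none
    non_additive: str = "intermediate"  # above | below | intermediate
    transgressive: str = "none"  # HIGH | LOW | none
    high_cv: bool = False
    allelic_bias: str = "none"  # A_allele | P_allele | inconsistent | none
    provenance: dict[str, str] = field(default_factory=dict)  # flag -> both/full_only/..

    _FLAGS = ("species_difference", "non_additive", "transgressive", "high_cv", "allelic_bias")

    def __post_init__(self) -> None:
        checks = {
            "species_difference": SPECIES_CODES,
            "non_additive": NONADD_CODES,
            "transgressive": TRANSGRESSIVE_CODES,
            "allelic_bias": BIAS_CODES,
        }
        for fld, codes in checks.items():
            if getattr(self, fld) not in codes:
                raise ValidationError(
                    f"{self.contig_id}: bad {fld} value {getattr(self, fld)!r}"
                )
        for fld, prov in self.provenance.items():
            if fld not in self._FLAGS or prov not in PROVENANCE_CODES:
                raise ValidationError(
                    f"{self.contig_id}: bad provenance entry {fld!r}={prov!r}"
                )
        # every non-none flag must carry provenance
        active = {
            "species_difference": self.species_difference != "none",
            "non_additive": self.non_additive != "intermediate",
            "transgressive": self.transgressive != "none",
            "high_cv": self.high_cv,
            "allelic_bias": self.allelic_bias != "none",
        }
        for fld, on in active.items():
            if on and fld not in self.provenance:
                raise ValidationError(
                    f"{self.contig_id}: flag {fld} set but no provenance recorded"
                )


CLASSIFICATION_COLUMNS = [
    "contig_id",
    "SPECIES_DIFFERENCE",
    "SPECIES_DIFFERENCE_PROV",
    "NON_ADDITIVE",
    "NON_ADDITIVE_PROV",
    "TRANSGRESSIVE",
    "TRANSGRESSIVE_PROV",
    "HIGH_CV",
    "HIGH_CV_PROV",
    "ALLELIC_BIAS",
    "ALLELIC_BIAS_PROV",
]

_HEADER_COMMENT = (
    "# Per-contig classification. Flag codes: SPECIES_DIFFERENCE/ALLELIC_BIAS in "
    "{A,P,INCONSISTENT,NONE}; NON_ADDITIVE in {UP,DOWN,MID}; TRANSGRESSIVE in "
    "{UP,DOWN,NONE}; HIGH_CV in {YES,NO}. *_PROV columns give full/reduced "
    "provenance in {BOTH,FULL,REDUCED,NONE}.\n"
)


def write_classification_table(
    rows: Sequence[ContigClassification], path: str | Path
) -> None:
    def prov(r: ContigClassification, fld: str) -> str:
        return PROVENANCE_CODES[r.provenance.get(fld, "neither")]

    records = [
        {
            "contig_id": r.contig_id,
            "SPECIES_DIFFERENCE": SPECIES_CODES[r.species_difference],
            "SPECIES_DIFFERENCE_PROV": prov(r, "species_difference"),
            "NON_ADDITIVE": NONADD_CODES[r.non_additive],
            "NON_ADDITIVE_PROV": prov(r, "non_additive"),
            "TRANSGRESSIVE": TRANSGRESSIVE_CODES[r.transgressive],
            "TRANSGRESSIVE_PROV": prov(r, "transgressive"),
            "HIGH_CV": "YES" if r.high_cv else "NO",
            "HIGH_CV_PROV": prov(r, "high_cv"),
            "ALLELIC_BIAS": BIAS_CODES[r.allelic_bias],
            "ALLELIC_BIAS_PROV": prov(r, "allelic_bias"),
        }
        for r in rows
    ]
    df = pd.DataFrame(records, columns=CLASSIFICATION_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_HEADER_COMMENT)
        df.to_csv(fh, sep="\t", index=False)


def read_classification_table(path: str | Path) -> list[ContigClassification]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    inv_species = {v: k for k, v in SPECIES_CODES.items()}
    inv_nonadd = {v: k for k, v in NONADD_CODES.items()}
    inv_trans = {v: k for k, v in TRANSGRESSIVE_CODES.items()}
    inv_bias = {v: k for k, v in BIAS_CODES.items()}
    inv_prov = {v: k for k, v in PROVENANCE_CODES.items()}
    rows = []
    for rec in df.to_dict("records"):
        provenance = {}
        for fld, col in [
            ("species_difference", "SPECIES_DIFFERENCE_PROV"),
            ("non_additive", "NON_ADDITIVE_PROV"),
            ("transgressive", "TRANSGRESSIVE_PROV"),
            ("high_cv", "HIGH_CV_PROV"),
            ("allelic_bias", "ALLELIC_BIAS_PROV"),
        ]:
            p = inv_prov[rec[col]]
            if p != "neither":
                provenance[fld] = p
        rows.append(
            ContigClassification(
                contig_id=rec["contig_id"],
                species_difference=inv_species[rec["SPECIES_DIFFERENCE"]],
                non_additive=inv_nonadd[rec["NON_ADDITIVE"]],
                transgressive=inv_trans[rec["TRANSGRESSIVE"]],
                high_cv=rec["HIGH_CV"] == "YES",
                allelic_bias=inv_bias[rec["ALLELIC_BIAS"]],
                provenance=provenance,
            )
        )
    return rows
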