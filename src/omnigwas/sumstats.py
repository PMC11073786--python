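"""Read, harmonize and quality-filter per-sex GWAS summary-statistic tables.

The expected inputs are two TSV (optionally gzipped) files of per-variant
summary statistics, one per sex, in the style of the Neale lab UK Biobank
sex-stratified exports: variant id, chromosome, position, alleles,
imputation INFO score, per-sex sample size, minor-allele frequency, effect
estimate (beta, per copy of the minor allele) and its standard error and/or
p-value.  Column names are mapped explicitly through ``column_map``; a
default matching Neale-style exports is shipped — there is no auto-detection.

Harmonization pairs the two files per variant, re-orients the male record
when its major/minor coding is swapped relative to the female file
(flipping the beta and z signs), and drops variants present in only one
file.  Quality control keeps variants with per-sex MAF above ``maf_min``
in *both* sexes and INFO above ``info_min``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "VariantKey",
    "GroupAssoc",
    "PairedRecord",
    "QCReport",
    "DEFAULT_COLUMN_MAP",
    "read_sumstats",
    "as_records",
    "harmonize_groups",
    "apply_variant_qc",
    "write_results",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Logical name -> column name in a Neale-style sex-stratified export.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant": "variant",
    "chr": "chr",
    "pos": "pos",
    "major": "major_allele",
    "minor": "minor_allele",
    "info": "info",
    "n": "n_complete_samples",
    "maf": "minor_AF",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
}

_REQUIRED = ("variant", "chr", "pos", "major", "minor", "info", "n", "maf", "beta")
_NUMERIC = ("pos", "info", "n", "maf", "beta", "se", "pval")

#: Fixed column order of result tables written by :func:`write_results`.
RESULT_COLUMNS = [
    "variant", "chr", "pos", "major", "minor", "info",
    "maf_F", "maf_M", "beta_F", "se_F", "p_F", "beta_M", "se_M", "p_M",
    "z_diff", "p_diff", "z_metaL", "p_metaL",
    "chi2_metaQ", "p_metaQ", "neglog10_p_metaQ", "n_F", "n_M",
]


@dataclass(frozen=True)
class VariantKey:
    """Identity, location, allele coding and imputation quality of a variant.

    Chromosomes are integers 1-23 with X coded as 23 and treated exactly
    like an autosome throughout. Positions are 1-based; the genome build is
    carried as metadata only (``build``, hg19 in the shipped fixtures).
    INDEL alleles are multi-character strings.
    """

    id: str
    chromosome: int
    position: int
    major_allele: str
    minor_allele: str
    info: float
    build: str = "hg19"

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1 ({self.id})")
        if not self.major_allele or not self.minor_allele:
            raise ValueError(f"alleles must be non-empty ({self.id})")
        if self.major_allele == self.minor_allele:
            raise ValueError(f"alleles must be distinct ({self.id})")
        if not 0.0 <= self.info <= 1.0:
            raise ValueError(f"INFO must be in [0,1] ({self.id})")


@dataclass(frozen=True)
class GroupAssoc:
    """One sex group's association summary for one variant."""

    group: str
    n: int
    maf: float
    beta: float
    se: float
    z: float
    p: float
    neglog10p: float

    def __post_init__(self):
        if self.group not in ("female", "male"):
            raise ValueError("group must be 'female' or 'male'")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if not self.se > 0:
            raise ValueError("se must be > 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        # p may underflow to exactly 0 for extreme z; neglog10p then carries
        # the magnitude and must stay finite.
        if self.p == 0.0 and not np.isfinite(self.neglog10p):
            raise ValueError("underflowed p requires a finite neglog10p")


@dataclass(frozen=True)
class PairedRecord:
    """Per-variant join of the female and male stratified summaries."""

    key: VariantKey
    female: GroupAssoc
    male: GroupAssoc
    maf_all: float | None = None


@dataclass
class QCReport:
    """Per-stage bookkeeping of variant counts; drops sum to the input."""

    n_input: int = 0
    n_kept: int = 0
    n_dropped_maf: int = 0
    n_dropped_info: int = 0
    n_dropped_unmatched: int = 0
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self):
        total = (self.n_kept + self.n_dropped_maf + self.n_dropped_info
                 + self.n_dropped_unmatched)
        if self.n_input != total:
            raise ValueError("QCReport counts do not add up")


def _parse_chrom(values: pd.Series) -> pd.Series:
    """Parse chromosome labels; X (or 'chrX') becomes 23."""
    s = values.astype(str).str.strip().str.replace("^chr", "", regex=True)
    s = s.str.upper().replace({"X": "23"})
    return pd.to_numeric(s, errors="coerce")


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    group: str = "female",
    strict: bool = True,
) -> pd.DataFrame:
    """Read one per-sex summary-statistic TSV into a harmonizable frame.

    Fills ``z`` and ``p`` from whichever of (beta, se) or (beta, pval) is
    present; when both se and pval are present and disagree by more than 1%
    on the z scale, se wins and a warning is logged (printed p columns are
    often rounded).

    Parameters
    ----------
    path : str or Path
        TSV or TSV.GZ file; lines starting with ``#`` are ignored.
    column_map : mapping, optional
        Logical name -> file column name; defaults to
        :data:`DEFAULT_COLUMN_MAP`. At least one of ``se``/``pval`` must be
        mapped alongside ``beta``.
    group : {'female', 'male'}
        Label attached to the returned records.
    strict : bool
        If True (default) an unparseable numeric cell raises with its line
        number; if False the offending row is skipped with a warning.

    Returns
    -------
    pandas.DataFrame with columns
        ``variant, chr, pos, major, minor, info, n, maf, beta, se, z, p,
        neglog10p`` (one row per input data row).
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    if "se" not in cmap and "pval" not in cmap:
        raise ValueError("column_map must map at least one of 'se', 'pval'")

    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for logical in _REQUIRED:
        col = cmap.get(logical)
        if col is None or col not in raw.columns:
            raise ValueError(
                f"mapped column for '{logical}' ({col!r}) not found in {path}"
            )
    # se/pval are alternatives: only columns present in the file are used,
    # but explicitly remapped names must exist.
    if column_map is not None:
        for logical in ("se", "pval"):
            col = cmap.get(logical)
            if col is not None and col not in raw.columns:
                raise ValueError(
                    f"mapped column for '{logical}' ({col!r}) not found in {path}"
                )
    has_se = cmap.get("se") in raw.columns
    has_p = cmap.get("pval") in raw.columns
    if not (has_se or has_p):
        raise ValueError(f"neither se nor pval column found in {path}")

    df = pd.DataFrame({k: raw[v] for k, v in cmap.items() if v in raw.columns})
    df["chr"] = _parse_chrom(df["chr"])
    numeric_cols = [c for c in _NUMERIC if c in df.columns and c != "chr"]
    for c in numeric_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")

    bad = df[["chr"] + [c for c in ("pos", "n", "maf", "beta") if c in df]].isna().any(axis=1)
    if has_se:
        bad |= df["se"].isna()
    elif has_p:
        bad |= df["pval"].isna()
    if bad.any():
        lineno = int(df.index[bad][0]) + 2  # header + 1-based
        if strict:
            raise ValueError(f"unparseable numeric cell in {path} at line {lineno}")
        logger.warning("skipping %d unparseable rows in %s (first at line %d)",
                       int(bad.sum()), path, lineno)
        df = df[~bad].reset_index(drop=True)

    df["chr"] = df["chr"].astype(int)
    df["pos"] = df["pos"].astype(int)
    df["n"] = df["n"].astype(int)
    # MAF is stored folded to (0, 0.5] relative to the stated minor allele.
    df["maf"] = np.minimum(df["maf"], 1.0 - df["maf"])

    if has_se:
        z = stats.z_from_beta_se(df["beta"].to_numpy(), df["se"].to_numpy())
        if has_p and df["pval"].notna().any():
            z_from_p = stats.z_from_p_sign(
                df["pval"].to_numpy(), np.sign(df["beta"].to_numpy())
            )
            with np.errstate(invalid="ignore"):
                rel = np.abs(np.abs(z) - np.abs(z_from_p)) / np.maximum(1.0, np.abs(z))
            n_disagree = int(np.sum(rel > 0.01))
            if n_disagree:
                logger.warning(
                    "%d variants: se- and p-derived z disagree by >1%%; using se",
                    n_disagree,
                )
        df["z"] = z
        df["p"], df["neglog10p"] = stats.p_from_z(z)
    else:
        z = stats.z_from_p_sign(df["pval"].to_numpy(), np.sign(df["beta"].to_numpy()))
        df["z"] = z
        df["p"], df["neglog10p"] = stats.p_from_z(z)
        with np.errstate(divide="ignore"):
            df["se"] = np.where(df["beta"] != 0, np.abs(df["beta"]) / np.abs(z), np.nan)

    df["group"] = group
    cols = ["variant", "chr", "pos", "major", "minor", "info", "n",
            "maf", "beta", "se", "z", "p", "neglog10p", "group"]
    return df[cols]


def as_records(df: pd.DataFrame) -> Iterator[tuple[VariantKey, GroupAssoc]]:
    """Yield ``(VariantKey, GroupAssoc)`` dataclass pairs from a read frame."""
    group = {"female": "female", "male": "male"}[str(df["group"].iloc[0])]
    for row in df.itertuples(index=False):
        key = VariantKey(
            id=row.variant, chromosome=int(row.chr), position=int(row.pos),
            major_allele=row.major, minor_allele=row.minor, info=float(row.info),
        )
        assoc = GroupAssoc(
            group=group, n=int(row.n), maf=float(row.maf), beta=float(row.beta),
            se=float(row.se), z=float(row.z), p=float(row.p),
            neglog10p=float(row.neglog10p),
        )
        yield key, assoc


def harmonize_groups(
    female: pd.DataFrame, male: pd.DataFrame
) -> tuple[pd.DataFrame, QCReport]:
    """Pair female and male records per variant on a shared allele coding.

    Variants are matched on (variant id, position). When the male file's
    major/minor orientation is swapped relative to the female file, the male
    beta and z signs are flipped before pairing (the stored MAF is already
    folded to the minor allele, so it is unchanged).  Variants present in
    only one file, or with conflicting positions or incompatible allele
    sets, are dropped and counted as unmatched.

    Returns the paired frame (suffix ``_F``/``_M`` on per-sex columns,
    female allele orientation) and a :class:`QCReport` over the union of
    input variants.
    """
    fem = female.set_index("variant", drop=False)
    mal = male.set_index("variant", drop=False)
    shared = fem.index.intersection(mal.index)
    n_union = len(fem.index.union(mal.index))

    f = fem.loc[shared]
    m = mal.loc[shared]
    same_pos = (f["pos"].to_numpy() == m["pos"].to_numpy()) & (
        f["chr"].to_numpy() == m["chr"].to_numpy()
    )
    same_orient = (f["major"].to_numpy() == m["major"].to_numpy()) & (
        f["minor"].to_numpy() == m["minor"].to_numpy()
    )
    swapped = (f["major"].to_numpy() == m["minor"].to_numpy()) & (
        f["minor"].to_numpy() == m["major"].to_numpy()
    )
    ok = same_pos & (same_orient | swapped)
    n_conflict = int(np.sum(~ok))
    if n_conflict:
        logger.warning("dropping %d variants with conflicting position or alleles",
                       n_conflict)
    f, m, swapped = f[ok], m[ok], swapped[ok]

    flip = np.where(swapped, -1.0, 1.0)
    paired = pd.DataFrame({
        "variant": f["variant"].to_numpy(),
        "chr": f["chr"].to_numpy(),
        "pos": f["pos"].to_numpy(),
        "major": f["major"].to_numpy(),
        "minor": f["minor"].to_numpy(),
        "info": np.minimum(f["info"].to_numpy(), m["info"].to_numpy()),
        "n_F": f["n"].to_numpy(), "n_M": m["n"].to_numpy(),
        "maf_F": f["maf"].to_numpy(), "maf_M": m["maf"].to_numpy(),
        "beta_F": f["beta"].to_numpy(), "se_F": f["se"].to_numpy(),
        "z_F": f["z"].to_numpy(), "p_F": f["p"].to_numpy(),
        "neglog10_p_F": f["neglog10p"].to_numpy(),
        "beta_M": m["beta"].to_numpy() * flip, "se_M": m["se"].to_numpy(),
        "z_M": m["z"].to_numpy() * flip, "p_M": m["p"].to_numpy(),
        "neglog10_p_M": m["neglog10p"].to_numpy(),
    }).reset_index(drop=True)

    report = QCReport(
        n_input=n_union,
        n_kept=len(paired),
        n_dropped_unmatched=n_union - len(paired),
    )
    return paired, report


def apply_variant_qc(
    pairs: pd.DataFrame, maf_min: float = 0.01, info_min: float = 0.8
) -> tuple[pd.DataFrame, QCReport]:
    """Keep variants with per-sex MAF > ``maf_min`` in both sexes and
    INFO > ``info_min``.  MAF is checked first when counting drop reasons.
    Idempotent; an empty result is allowed."""
    maf_ok = (pairs["maf_F"] > maf_min) & (pairs["maf_M"] > maf_min)
    info_ok = pairs["info"] > info_min
    kept = pairs[maf_ok & info_ok].reset_index(drop=True)
    report = QCReport(
        n_input=len(pairs),
        n_kept=len(kept),
        n_dropped_maf=int((~maf_ok).sum()),
        n_dropped_info=int((maf_ok & ~info_ok).sum()),
    )
    return kept, report


def write_results(results: pd.DataFrame, path, header_comments=()) -> None:
    """Write a result table as TSV in the fixed column order.

    P-value columns are serialized in scientific notation with 6
    significant digits; a ``neglog10_p_metaQ`` column preserves omnibus
    significance beyond double underflow. Optional ``header_comments`` are
    written as leading ``#`` lines (skipped on re-read).
    """
    df = results.copy()
    cols = [c for c in RESULT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols and c.startswith("neglog10")]
    df = df[cols]
    formatters = {}
    for c in cols:
        if c.startswith("p_"):
            formatters[c] = lambda v: f"{v:.5E}"
        elif df[c].dtype.kind == "f":
            formatters[c] = lambda v: f"{v:.10g}"
    for c, fmt in formatters.items():
        df[c] = df[c].map(fmt)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
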