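"""Worked-example tables of published sex-stratified UK Biobank GWAS results.

Two small lead-SNP tables derived from the public Neale-lab round-2
(imputed-v3) sex-stratified UK Biobank GWAS are shipped as plain TSV:

* ``testosterone_loci`` — 12 bi-allelic lead SNPs for serum testosterone,
  each genome-wide significant by the omnibus 2-df meta-analysis but by no
  other method (one lies on the X chromosome, coded 23);
* ``urate_opposite_snps`` — 19 bi-allelic SNPs near *SLC2A9* with
  genome-wide significant effects on serum urate in *both* sexes but in
  opposite directions, all in strong mutual LD (r^2 ~ 1).

The tables carry the published per-sex betas (per copy of the minor
allele, hg19 positions) and p-values; standard errors are reconstructed
from (beta, p) by :func:`paired_from_published` so the full test battery
can be recomputed from the printed numbers alone.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "load_testosterone_loci",
    "load_urate_opposite_snps",
    "paired_from_published",
    "TESTOSTERONE_N",
    "URATE_N",
]

#: Per-sex sample sizes of the source GWAS (females, males).
TESTOSTERONE_N = (154364, 157738)
URATE_N = (184755, 159081)


def _load(name: str, n_fm: tuple[int, int]) -> pd.DataFrame:
    with resources.files("omnigwas.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["n_F"], df["n_M"] = n_fm
    return df


def load_testosterone_loci() -> pd.DataFrame:
    """The 12-SNP testosterone lead-variant table (published columns)."""
    return _load("testosterone_loci.tsv", TESTOSTERONE_N)


def load_urate_opposite_snps() -> pd.DataFrame:
    """The 19-SNP urate opposite-direction table (published columns)."""
    return _load("urate_opposite_snps.tsv", URATE_N)


def paired_from_published(published: pd.DataFrame) -> pd.DataFrame:
    """Build a harmonized paired frame from a published lead-SNP table.

    Per sex, the signed z-score is inverted from the printed two-sided
    p-value with the sign of the printed beta, and the standard error is
    back-derived as ``|beta| / |z|``.  The published sex-combined p-value
    columns are kept under ``*_published`` names so recomputed statistics
    can be compared against them.
    """
    df = published.copy()
    for sex in ("F", "M"):
        z = stats.z_from_p_sign(df[f"p_{sex}"], np.sign(df[f"beta_{sex}"]))
        df[f"z_{sex}"] = z
        df[f"se_{sex}"] = np.abs(df[f"beta_{sex}"]) / np.abs(z)
        df[f"neglog10_p_{sex}"] = stats.neglog10p_from_z(z)
    for col in ("p_diff", "p_metaL", "p_metaQ"):
        if col in df.columns:
            df = df.rename(columns={col: f"{col}_published"})
    return df
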