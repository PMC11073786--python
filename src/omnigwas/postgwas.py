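"""Post-GWAS stage: significance filtering, LD clumping, locus merging,
opposite-direction flagging and per-method hit comparison.

Linkage disequilibrium is consumed through an abstract provider exposing
``r2(id_a, id_b)`` so the stage can run against a dense matrix fixture, a
long-format TSV, or a synthetic block-diagonal generator — reference-panel
LD computation itself is out of scope.  Clumping follows the usual
clump-index convention: repeatedly take the remaining variant with the
smallest p-value as an index SNP and absorb every remaining variant on the
same chromosome within ``window_bp`` whose r-squared with the index exceeds
``r2_min`` (defaults 10 Mb and 0.01).  Independent SNPs within ``merge_bp``
(default 250 kb, single linkage) are then merged into risk loci, each led
by its minimum-p member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LDProvider",
    "MatrixLDProvider",
    "ConstantLDProvider",
    "BlockLDProvider",
    "Locus",
    "filter_genome_wide",
    "clump",
    "merge_loci",
    "loci_to_frame",
    "flag_opposite_direction",
    "method_unique_hits",
    "GENOME_WIDE_ALPHA",
]

GENOME_WIDE_ALPHA = 5e-8


class LDProvider:
    """Contract: ``r2(a, b)`` returns squared genotype correlation in [0,1];
    symmetric, with ``r2(v, v) == 1``."""

    def r2(self, id_a: str, id_b: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError


class MatrixLDProvider(LDProvider):
    """LD from an explicit pairwise table; missing pairs raise."""

    def __init__(self, pairs: dict[tuple[str, str], float]):
        self._pairs = {}
        for (a, b), v in pairs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"r2 out of [0,1] for ({a},{b})")
            self._pairs[(a, b)] = v
            self._pairs[(b, a)] = v

    @classmethod
    def from_long_tsv(cls, path):
        """Read a (id_a, id_b, r2) TSV."""
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls({(r.id_a, r.id_b): float(r.r2) for r in df.itertuples()})

    @classmethod
    def from_square_tsv(cls, path):
        """Read a square matrix TSV with variant ids as header and index."""
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        pairs = {}
        for a in df.index:
            for b in df.columns:
                pairs[(str(a), str(b))] = float(df.loc[a, b])
        return cls(pairs)

    def r2(self, id_a, id_b):
        if id_a == id_b:
            return 1.0
        try:
            return self._pairs[(id_a, id_b)]
        except KeyError:
            raise KeyError(f"no LD entry for pair ({id_a}, {id_b})") from None


class ConstantLDProvider(LDProvider):
    """Every distinct pair shares one r-squared value (e.g. ~1 for a tight
    haplotype, 0 for independence)."""

    def __init__(self, value: float):
        if not 0.0 <= value <= 1.0:
            raise ValueError("r2 must be in [0,1]")
        self.value = float(value)

    def r2(self, id_a, id_b):
        return 1.0 if id_a == id_b else self.value


class BlockLDProvider(LDProvider):
    """Block-diagonal synthetic LD: variants in the same block share
    ``within_r2``; cross-block pairs share ``between_r2``."""

    def __init__(self, blocks: dict[str, int], within_r2: float = 0.95,
                 between_r2: float = 0.0):
        self.blocks = dict(blocks)
        self.within_r2 = float(within_r2)
        self.between_r2 = float(between_r2)

    def r2(self, id_a, id_b):
        if id_a == id_b:
            return 1.0
        try:
            ba, bb = self.blocks[id_a], self.blocks[id_b]
        except KeyError as err:
            raise KeyError(f"no LD block for pair ({id_a}, {id_b})") from err
        return self.within_r2 if ba == bb else self.between_r2


@dataclass
class Locus:
    """A risk locus: an independent lead variant (minimum p) plus the
    member variants merged into its span."""

    lead: str
    lead_p: float
    lead_neglog10p: float
    chromosome: int
    span_start: int
    span_end: int
    members: list[str]

    def __post_init__(self):
        if self.lead not in self.members:
            raise ValueError("lead must be one of the members")
        if self.span_start > self.span_end:
            raise ValueError("span_start must be <= span_end")


def _neglog_col(df: pd.DataFrame, p_col: str) -> pd.Series:
    nl = f"neglog10_{p_col}"
    if nl in df.columns:
        return df[nl]
    with np.errstate(divide="ignore"):
        return -np.log10(df[p_col])


def filter_genome_wide(
    results: pd.DataFrame, alpha: float = GENOME_WIDE_ALPHA, p_col: str = "p_metaQ"
) -> pd.DataFrame:
    """Keep records with ``p < alpha`` (strict).

    The comparison runs on the -log10 scale (using a ``neglog10_<p_col>``
    column when present) so that p-values below double underflow are still
    retained.
    """
    if results.empty:
        return results.copy()
    nl = _neglog_col(results, p_col)
    return results[nl > -np.log10(alpha)].reset_index(drop=True)


def _canonical_order(df: pd.DataFrame, p_col: str) -> pd.DataFrame:
    key = pd.DataFrame({
        "nl": -_neglog_col(df, p_col),  # ascending p = descending evidence
        "chr": df["chr"], "pos": df["pos"], "id": df["variant"],
    }, index=df.index)
    order = key.sort_values(["nl", "chr", "pos", "id"], kind="mergesort").index
    return df.loc[order]


def clump(
    significant: pd.DataFrame,
    ld: LDProvider,
    window_bp: int = 10_000_000,
    r2_min: float = 0.01,
    p_col: str = "p_metaQ",
) -> pd.DataFrame:
    """Greedy LD clumping to independent index SNPs.

    Repeatedly selects the remaining variant with the smallest p-value as
    an index and absorbs all remaining variants on the same chromosome
    within ``window_bp`` of it with ``r2 > r2_min``.  Ties in p are broken
    by (chromosome, position, id), making the output invariant to input
    order.  Returns the index-variant rows in selection order.
    """
    if significant.empty:
        return significant.copy()
    df = _canonical_order(significant, p_col).reset_index(drop=True)
    alive = np.ones(len(df), dtype=bool)
    chrom = df["chr"].to_numpy()
    pos = df["pos"].to_numpy()
    ids = df["variant"].to_numpy()
    keep = []
    for i in range(len(df)):
        if not alive[i]:
            continue
        keep.append(i)
        candidates = np.flatnonzero(
            alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        )
        for j in candidates:
            if j == i:
                continue
            if ld.r2(ids[i], ids[j]) > r2_min:
                alive[j] = False
        alive[i] = False
    return df.iloc[keep].reset_index(drop=True)


def merge_loci(
    independent: pd.DataFrame,
    merge_bp: int = 250_000,
    p_col: str = "p_metaQ",
) -> list[Locus]:
    """Single-linkage merge of independent SNPs within ``merge_bp`` into
    risk loci; each locus is led by its minimum-p member.  A chain A-B-C
    with consecutive gaps within ``merge_bp`` forms one locus even when the
    ends are further apart."""
    loci: list[Locus] = []
    if independent.empty:
        return loci
    df = independent.copy()
    df["_nl"] = _neglog_col(df, p_col)
    for chrom, sub in df.groupby("chr", sort=True):
        sub = sub.sort_values(["pos", "variant"], kind="mergesort")
        pos = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > merge_bp) + 1
        for chunk in np.split(np.arange(len(sub)), breaks):
            members = sub.iloc[chunk]
            lead = members.loc[members["_nl"].idxmax()]
            loci.append(Locus(
                lead=str(lead["variant"]),
                lead_p=float(lead[p_col]),
                lead_neglog10p=float(lead["_nl"]),
                chromosome=int(chrom),
                span_start=int(members["pos"].min()),
                span_end=int(members["pos"].max()),
                members=list(members["variant"]),
            ))
    return loci


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    """Tabular locus report (one row per locus)."""
    return pd.DataFrame([
        dict(locus_id=i + 1, chr=l.chromosome, start=l.span_start,
             end=l.span_end, lead=l.lead, lead_p=l.lead_p,
             lead_neglog10p=l.lead_neglog10p, n_members=len(l.members),
             members=",".join(l.members))
        for i, l in enumerate(loci)
    ])


def flag_opposite_direction(
    results: pd.DataFrame, alpha: float = GENOME_WIDE_ALPHA
) -> pd.DataFrame:
    """Variants significant in *both* sexes with opposite effect directions.

    Keeps rows with ``p_F < alpha``, ``p_M < alpha`` and
    ``sign(beta_F) != sign(beta_M)`` with both betas nonzero.
    """
    if results.empty:
        return results.copy()
    nl_alpha = -np.log10(alpha)
    sig = (_neglog_col(results, "p_F") > nl_alpha) & (
        _neglog_col(results, "p_M") > nl_alpha
    )
    opposite = (
        (results["beta_F"] != 0)
        & (results["beta_M"] != 0)
        & (np.sign(results["beta_F"]) != np.sign(results["beta_M"]))
    )
    return results[sig & opposite].reset_index(drop=True)


_METHOD_PCOLS = {
    "T_Female": "p_F",
    "T_Male": "p_M",
    "T_Diff": "p_diff",
    "T_1_metaL": "p_metaL",
    "T_2_metaQ": "p_metaQ",
}


def method_unique_hits(
    results: pd.DataFrame, alpha: float = GENOME_WIDE_ALPHA
) -> dict:
    """Per-method significant, unique and pairwise identified/missed sets.

    ``unique[m]`` holds variants significant by method ``m`` and by no
    other method; ``pairwise[(a, b)]`` holds variants identified by ``a``
    but missed by ``b``.
    """
    nl_alpha = -np.log10(alpha)
    sig = {
        m: set(results.loc[_neglog_col(results, col) > nl_alpha, "variant"])
        for m, col in _METHOD_PCOLS.items()
        if col in results.columns or f"neglog10_{col}" in results.columns
    }
    methods = list(sig)
    unique = {
        m: sig[m] - set().union(*(sig[o] for o in methods if o != m))
        for m in methods
    }
    pairwise = {
        (a, b): sig[a] - sig[b] for a in methods for b in methods if a != b
    }
    return {"significant": sig, "unique": unique, "pairwise": pairwise}
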