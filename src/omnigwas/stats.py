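"""Sex-combined association tests built from sex-stratified summary statistics.

Three tests combine the female and male Wald statistics (z_F, z_M) for one
variant:

* ``test_diff`` — the interaction-only test of the effect *difference*
  between sexes, ``(beta_F - beta_M) / sqrt(se_F^2 + se_M^2)``, standard
  normal under the null of equal effects.
* ``test_meta_linear`` — the traditional fixed-effect (inverse-variance
  weighted) meta-analysis z statistic, standard normal under the null of no
  association.
* ``test_meta_quadratic`` — the omnibus 2-df test ``z_F^2 + z_M^2``,
  chi-square with 2 df under the null.  It is the summary-statistic
  counterpart of jointly testing a variant's main and SNPxsex interaction
  effects on individual-level data, and is direction-agnostic, so it keeps
  power when effects are present in only one sex or point in opposite
  directions.

All tail probabilities are computed through log-space survival functions so
that p-values far below the smallest positive double (|z| up to ~40 per sex,
chi-square statistics in the hundreds) remain exact on the -log10 scale.
Every function is vectorized over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "MetaResult",
    "z_from_beta_se",
    "p_from_z",
    "neglog10p_from_z",
    "z_from_p_sign",
    "se_from_beta_p",
    "test_diff",
    "test_meta_linear",
    "test_meta_quadratic",
    "neglog10p_from_chi2_2df",
    "run_all_tests",
]

_LN10 = np.log(10.0)
_LN2 = np.log(2.0)


@dataclass(frozen=True)
class MetaResult:
    """The three sex-combined statistics and p-values for one variant."""

    z_diff: float
    p_diff: float
    neglog10_p_diff: float
    z_metaL: float
    p_metaL: float
    neglog10_p_metaL: float
    chi2_metaQ: float
    p_metaQ: float
    neglog10_p_metaQ: float


def _check_positive(se, name: str) -> np.ndarray:
    se = np.asarray(se, dtype=float)
    if np.any(~(se > 0)):
        raise ValueError(f"{name} must be > 0 (got {se[~(se > 0)][:5]!r})")
    return se


def z_from_beta_se(beta, se):
    """Wald statistic ``beta / se``; ``se`` must be strictly positive."""
    beta = np.asarray(beta, dtype=float)
    se = _check_positive(se, "se")
    return beta / se


def log_p_from_z(z):
    """Natural log of the two-sided normal p-value, exact for large |z|."""
    z = np.asarray(z, dtype=float)
    return _LN2 + special.log_ndtr(-np.abs(z))


def p_from_z(z):
    """Two-sided normal p-value ``2*Phi(-|z|)`` and its -log10.

    Returns ``(p, neglog10p)``.  For |z| large enough that p underflows,
    ``p`` is 0.0 but ``neglog10p`` stays finite and accurate.
    """
    logp = log_p_from_z(z)
    return np.exp(logp), -logp / _LN10


def neglog10p_from_z(z):
    """-log10 of the two-sided normal p-value, finite for any finite z."""
    return -log_p_from_z(z) / _LN10


def z_from_p_sign(p, sign):
    """Signed z-score with two-sided p-value ``p``.

    ``|z| = Phi^-1(1 - p/2)`` computed via :func:`scipy.special.ndtri_exp`
    on log(p/2), which is exact down to p ~ 1e-300 and beyond.
    """
    p = np.asarray(p, dtype=float)
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p must lie in (0, 1]")
    absz = -special.ndtri_exp(np.log(p) - _LN2)
    absz = np.where(p == 1.0, 0.0, absz)
    return np.asarray(sign, dtype=float) * absz


def se_from_beta_p(beta, p):
    """Back-derive the standard error from an effect estimate and its p-value.

    ``se = |beta| / |z(p)|`` — used to reconstruct per-sex sampling variances
    from published tables that print beta and p but not se.
    """
    beta = np.asarray(beta, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(beta == 0):
        raise ValueError("se is undefined for beta = 0")
    if np.any(~((p > 0) & (p < 1))):
        raise ValueError("p must lie in (0, 1) to back-derive se")
    return np.abs(beta) / np.abs(z_from_p_sign(p, 1.0))


def test_diff(beta_f, se_f, beta_m, se_m):
    """Interaction-only test of the female-male effect difference.

    ``z = (beta_F - beta_M) / sqrt(se_F^2 + se_M^2)``; returns ``(z, p)``
    with p two-sided normal.
    """
    beta_f = np.asarray(beta_f, dtype=float)
    beta_m = np.asarray(beta_m, dtype=float)
    se_f = _check_positive(se_f, "se_f")
    se_m = _check_positive(se_m, "se_m")
    z = (beta_f - beta_m) / np.hypot(se_f, se_m)
    return z, p_from_z(z)[0]


def test_meta_linear(z_f, se_f, z_m, se_m):
    """Fixed-effect inverse-variance weighted meta-analysis z statistic.

    ``z = (z_F/v_F + z_M/v_M) / sqrt(1/v_F^2 + 1/v_M^2)`` where v are the
    per-sex standard errors; equivalently the IVW-combined effect divided by
    its standard error.  Returns ``(z, p)``; scale-invariant in (v_F, v_M).
    """
    z_f = np.asarray(z_f, dtype=float)
    z_m = np.asarray(z_m, dtype=float)
    se_f = _check_positive(se_f, "se_f")
    se_m = _check_positive(se_m, "se_m")
    wf, wm = 1.0 / se_f, 1.0 / se_m
    z = (wf * z_f + wm * z_m) / np.sqrt(wf**2 + wm**2)
    return z, p_from_z(z)[0]


def test_meta_quadratic(z_f, z_m):
    """Omnibus 2-df test: ``chi2 = z_F^2 + z_M^2``.

    Returns ``(chi2, p)`` with p the chi-square df=2 upper tail, which has
    the closed form ``exp(-chi2/2)``; computed in log space.  Invariant to
    the signs of both inputs.
    """
    z_f = np.asarray(z_f, dtype=float)
    z_m = np.asarray(z_m, dtype=float)
    if np.any(~np.isfinite(z_f)) or np.any(~np.isfinite(z_m)):
        raise ValueError("z statistics must be finite")
    chi2 = z_f**2 + z_m**2
    return chi2, np.exp(-chi2 / 2.0)


def neglog10p_from_chi2_2df(chi2):
    """-log10 of the chi-square df=2 upper tail: ``chi2 / (2 ln 10)``."""
    return np.asarray(chi2, dtype=float) / (2.0 * _LN10)


def run_all_tests(pairs):
    """Apply the three sex-combined tests to paired per-sex statistics.

    Parameters
    ----------
    pairs
        Either a :class:`pandas.DataFrame` with columns ``beta_F, se_F,
        z_F, beta_M, se_M, z_M`` (``z_*`` filled from beta/se if absent), or
        a single :class:`omnigwas.sumstats.PairedRecord`.

    Returns
    -------
    For a DataFrame input: a copy with columns ``z_diff, p_diff, z_metaL,
    p_metaL, chi2_metaQ, p_metaQ`` and their ``neglog10_*`` companions.
    For a single record: a :class:`MetaResult`.
    """
    import pandas as pd

    from .sumstats import PairedRecord

    if isinstance(pairs, PairedRecord):
        return _run_single(pairs)
    if not isinstance(pairs, pd.DataFrame):
        raise TypeError("pairs must be a DataFrame or a PairedRecord")

    df = pairs.copy()
    for sex in ("F", "M"):
        if f"z_{sex}" not in df.columns:
            df[f"z_{sex}"] = z_from_beta_se(df[f"beta_{sex}"], df[f"se_{sex}"])
    try:
        z_diff, p_diff = test_diff(
            df["beta_F"], df["se_F"], df["beta_M"], df["se_M"]
        )
        z_metal, p_metal = test_meta_linear(
            df["z_F"], df["se_F"], df["z_M"], df["se_M"]
        )
        chi2, p_metaq = test_meta_quadratic(df["z_F"], df["z_M"])
    except ValueError as err:
        bad = _offending_variants(df)
        raise ValueError(f"invalid per-sex statistics for variant(s) {bad}: {err}") from err
    df["z_diff"] = z_diff
    df["p_diff"] = p_diff
    df["neglog10_p_diff"] = neglog10p_from_z(z_diff)
    df["z_metaL"] = z_metal
    df["p_metaL"] = p_metal
    df["neglog10_p_metaL"] = neglog10p_from_z(z_metal)
    df["chi2_metaQ"] = chi2
    df["p_metaQ"] = p_metaq
    df["neglog10_p_metaQ"] = neglog10p_from_chi2_2df(chi2)
    return df


def _offending_variants(df):
    bad = (~(df["se_F"] > 0)) | (~(df["se_M"] > 0))
    if "variant" in df.columns:
        return list(df.loc[bad, "variant"].head(5))
    return list(df.index[bad][:5])


def _run_single(pair) -> MetaResult:
    f, m = pair.female, pair.male
    z_diff, p_diff = test_diff(f.beta, f.se, m.beta, m.se)
    z_metal, p_metal = test_meta_linear(f.z, f.se, m.z, m.se)
    chi2, p_metaq = test_meta_quadratic(f.z, m.z)
    return MetaResult(
        z_diff=float(z_diff),
        p_diff=float(p_diff),
        neglog10_p_diff=float(neglog10p_from_z(z_diff)),
        z_metaL=float(z_metal),
        p_metaL=float(p_metal),
        neglog10_p_metaL=float(neglog10p_from_z(z_metal)),
        chi2_metaQ=float(chi2),
        p_metaQ=float(p_metaq),
        neglog10_p_metaQ=float(neglog10p_from_chi2_2df(chi2)),
    )
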