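"""Monte-Carlo and analytic type-I error / power for the five tests.

For each scenario the five association tests are evaluated on simulated
per-sex summary statistics and their rejection proportions at level
``alpha`` recorded.  A closed-form oracle (:func:`analytic_power`) computes
the exact asymptotic power from the per-sex noncentralities
``lambda_s = beta_s^2 * 2*maf*(1-maf) * n_s / sigma_s^2``: the four 1-df
tests are shifted standard normals, and the omnibus 2-df test is a
noncentral chi-square with noncentrality ``lambda_F + lambda_M``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats
from .simulate import Scenario, simulate_cohort, simulate_sumstats_batch

__all__ = [
    "METHODS",
    "estimate_rejection_rates",
    "analytic_power",
    "compare_methods",
    "plot_rejection_rates",
]

METHODS = ("T_Female", "T_Male", "T_Diff", "T_1_metaL", "T_2_metaQ")


def _pvalues_from_sumstats(beta_f, se_f, beta_m, se_m):
    z_f = beta_f / se_f
    z_m = beta_m / se_m
    p_f, _ = stats.p_from_z(z_f)
    p_m, _ = stats.p_from_z(z_m)
    _, p_diff = stats.test_diff(beta_f, se_f, beta_m, se_m)
    _, p_metal = stats.test_meta_linear(z_f, se_f, z_m, se_m)
    _, p_metaq = stats.test_meta_quadratic(z_f, z_m)
    return dict(T_Female=p_f, T_Male=p_m, T_Diff=p_diff,
                T_1_metaL=p_metal, T_2_metaQ=p_metaq)


def estimate_rejection_rates(
    scenarios: dict[str, Scenario] | list[Scenario],
    n_reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    engine: str = "summary",
) -> pd.DataFrame:
    """Monte-Carlo rejection proportions for every (scenario, method) pair.

    ``engine='summary'`` (default) draws per-sex effect estimates from
    their asymptotic sampling distribution, vectorized over replicates;
    ``engine='cohort'`` simulates full individual-level cohorts and runs
    the stratified GWAS per replicate (slow; for end-to-end validation at
    reduced replicate counts).

    Returns a tidy frame with columns ``scenario, method, rejection,
    n_reps, alpha, mc_se`` where ``mc_se = sqrt(p*(1-p)/n_reps)``.
    Deterministic given ``seed`` (one spawned substream per scenario).
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if isinstance(scenarios, dict):
        items = list(scenarios.items())
    else:
        items = [(sc.name or f"scenario{i}", sc) for i, sc in enumerate(scenarios)]

    streams = np.random.SeedSequence(seed).spawn(len(items))
    rows = []
    for (name, sc), ss in zip(items, streams):
        if engine == "summary":
            bf, vf, bm, vm = simulate_sumstats_batch(sc, n_reps, np.random.default_rng(ss))
        elif engine == "cohort":
            rep_streams = ss.spawn(n_reps)
            bf = np.empty(n_reps); vf = np.empty(n_reps)
            bm = np.empty(n_reps); vm = np.empty(n_reps)
            for r, rs in enumerate(rep_streams):
                cohort = simulate_cohort(sc, seed=rs)
                from .mega import stratified_gwas
                fem, mal = stratified_gwas(cohort)
                bf[r], vf[r] = fem.beta, fem.se
                bm[r], vm[r] = mal.beta, mal.se
        else:
            raise ValueError("engine must be 'summary' or 'cohort'")
        pvals = _pvalues_from_sumstats(bf, vf, bm, vm)
        for method in METHODS:
            phat = float(np.mean(pvals[method] < alpha))
            rows.append(dict(
                scenario=name, method=method, rejection=phat,
                n_reps=n_reps, alpha=alpha,
                mc_se=float(np.sqrt(phat * (1 - phat) / n_reps)),
            ))
    return pd.DataFrame(rows)


def analytic_power(scenario: Scenario, alpha: float = 0.05) -> dict[str, float]:
    """Exact asymptotic power of each test under a scenario.

    The per-sex z statistics are normal with means ``sqrt(lambda_s)`` (sign
    of beta); each 1-df test's power is a two-sided normal tail around its
    shifted mean, and the omnibus test is the upper tail of a noncentral
    chi-square (2 df, noncentrality ``lambda_F + lambda_M``) beyond the
    central chi-square critical value.
    """
    v_f = scenario.sampling_sd("female")
    v_m = scenario.sampling_sd("male")
    za = sps.norm.isf(alpha / 2.0)

    def two_sided(mean):
        return float(sps.norm.sf(za - mean) + sps.norm.cdf(-za - mean))

    mean_f = scenario.beta_f / v_f
    mean_m = scenario.beta_m / v_m
    mean_diff = (scenario.beta_f - scenario.beta_m) / np.hypot(v_f, v_m)
    mean_metal = (scenario.beta_f / v_f**2 + scenario.beta_m / v_m**2) / np.sqrt(
        1.0 / v_f**2 + 1.0 / v_m**2
    )
    lam = mean_f**2 + mean_m**2
    crit = sps.chi2.isf(alpha, df=2)
    power_q = float(sps.ncx2.sf(crit, df=2, nc=lam)) if lam > 0 else float(alpha)
    return {
        "T_Female": two_sided(mean_f),
        "T_Male": two_sided(mean_m),
        "T_Diff": two_sided(mean_diff),
        "T_1_metaL": two_sided(mean_metal),
        "T_2_metaQ": power_q,
    }


@dataclass
class MethodComparison:
    """Per-scenario power ranking and the omnibus test's deficit."""

    table: pd.DataFrame  # scenario, method, rejection, rank, best_method, deficit_metaQ

    def deficit(self, scenario: str) -> float:
        sub = self.table[self.table["scenario"] == scenario]
        return float(sub["deficit_metaQ"].iloc[0])


def compare_methods(table: pd.DataFrame) -> MethodComparison:
    """Rank methods by power within each scenario.

    Adds per-row power rank (1 = most powerful), the best method and the
    omnibus test's absolute power deficit from it.
    """
    if table["method"].nunique() < 2:
        out = table.copy()
        out["rank"] = 1
        out["best_method"] = out["method"]
        out["deficit_metaQ"] = np.nan
        return MethodComparison(out)
    parts = []
    for name, sub in table.groupby("scenario", sort=False):
        sub = sub.copy()
        sub["rank"] = sub["rejection"].rank(ascending=False, method="min").astype(int)
        best = sub.loc[sub["rejection"].idxmax()]
        sub["best_method"] = best["method"]
        metaq = sub.loc[sub["method"] == "T_2_metaQ", "rejection"]
        sub["deficit_metaQ"] = (
            float(best["rejection"]) - float(metaq.iloc[0]) if len(metaq) else np.nan
        )
        parts.append(sub)
    return MethodComparison(pd.concat(parts, ignore_index=True))


def plot_rejection_rates(table: pd.DataFrame, path=None):
    """Grouped bar chart of rejection proportions per scenario and method."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scen = list(dict.fromkeys(table["scenario"]))
    x = np.arange(len(scen))
    width = 0.8 / len(METHODS)
    fig, ax = plt.subplots(figsize=(1.8 * len(scen) + 2, 4))
    for i, method in enumerate(METHODS):
        vals = [
            float(table[(table["scenario"] == s) & (table["method"] == method)]
                  ["rejection"].iloc[0])
            for s in scen
        ]
        ax.bar(x + (i - 2) * width, vals, width, label=method)
    ax.set_xticks(x, scen, rotation=20)
    ax.set_ylabel("rejection proportion")
    ax.axhline(float(table["alpha"].iloc[0]), ls="--", c="gray", lw=0.8)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
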