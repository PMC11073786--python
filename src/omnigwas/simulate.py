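"""Synthetic cohorts and summary statistics with sex-specific genetic effects.

The generator emulates the structure the analysis assumes: Hardy-Weinberg
genotypes at a given minor-allele frequency, sex-specific phenotype means
and residual variances, and sex-specific additive effects covering the
canonical heterogeneity configurations (no effect, equal effects, an effect
in one sex only, opposite directions, different magnitudes).  Two engines
are provided:

* :func:`simulate_cohort` draws individual-level data
  ``y = mu_s + beta_s*g + X b_X + N(0, sigma_s^2)`` per sex, for the mega
  models;
* :func:`simulate_sumstats` draws per-sex effect estimates directly from
  their asymptotic sampling distribution
  ``beta_hat_s ~ N(beta_s, sigma_s^2 / (2*maf*(1-maf)*n_s))``, which is
  orders of magnitude faster and matches the cohort engine's (z_F, z_M)
  distribution asymptotically — the workhorse of the power study.

All randomness flows from explicit seeds via :class:`numpy.random.Generator`;
replicate streams are spawned with :class:`numpy.random.SeedSequence` so
every (scenario, replicate) pair has an independent documented substream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special, stats as sps

from .mega import Cohort
from .sumstats import GroupAssoc, PairedRecord, VariantKey

__all__ = [
    "Scenario",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_sumstats",
    "simulate_sumstats_batch",
    "scenario_grid",
    "apply_irnt",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Scenario:
    """Generative parameters for one simulated variant and cohort.

    ``beta_f``/``beta_m`` are additive effects per copy of the minor allele
    in phenotype units; ``mu`` and ``sigma`` are sex-specific phenotype
    means and residual SDs.  ``covariate_effects`` lists shared effects of
    standard-normal nuisance covariates.
    """

    n_f: int = 2000
    n_m: int = 2000
    maf: float = 0.3
    beta_f: float = 0.0
    beta_m: float = 0.0
    mu_f: float = 0.0
    mu_m: float = 0.0
    sigma_f: float = 1.0
    sigma_m: float = 1.0
    covariate_effects: tuple[float, ...] = ()
    name: str = ""

    def __post_init__(self):
        if self.n_f < 0 or self.n_m < 0:
            raise ValueError("sample sizes must be >= 0")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if self.sigma_f <= 0 or self.sigma_m <= 0:
            raise ValueError("residual SDs must be > 0")

    def sampling_sd(self, sex: str) -> float:
        """Asymptotic SE of the per-allele effect estimate in one sex."""
        n = self.n_f if sex == "female" else self.n_m
        sigma = self.sigma_f if sex == "female" else self.sigma_m
        return float(sigma / np.sqrt(2.0 * self.maf * (1.0 - self.maf) * n))


def simulate_genotypes(n: int, maf: float, seed=None) -> np.ndarray:
    """Minor-allele counts under Hardy-Weinberg equilibrium.

    I.i.d. Binomial(2, maf) draws: P(0)=(1-maf)^2, P(1)=2*maf*(1-maf),
    P(2)=maf^2.  Deterministic given the seed.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    return _rng(seed).binomial(2, maf, size=n)


def simulate_cohort(scenario: Scenario, seed=None) -> Cohort:
    """Draw one individual-level cohort; rows are shuffled.

    Phenotype: ``y = mu_s + beta_s * g + X b_X + N(0, sigma_s^2)`` with the
    mean, effect and residual SD of the individual's sex.
    """
    rng = _rng(seed)
    sc = scenario
    n = sc.n_f + sc.n_m
    s = np.concatenate([np.zeros(sc.n_f, dtype=int), np.ones(sc.n_m, dtype=int)])
    g = simulate_genotypes(n, sc.maf, rng).astype(float)
    beta = np.where(s == 0, sc.beta_f, sc.beta_m)
    mu = np.where(s == 0, sc.mu_f, sc.mu_m)
    sigma = np.where(s == 0, sc.sigma_f, sc.sigma_m)
    y = mu + beta * g + rng.normal(0.0, sigma)
    X = None
    if sc.covariate_effects:
        X = rng.standard_normal((n, len(sc.covariate_effects)))
        y = y + X @ np.asarray(sc.covariate_effects)
    order = rng.permutation(n)
    return Cohort(
        y=y[order], g=g[order], s=s[order],
        X=X[order] if X is not None else None,
        ids=np.array([f"id{i}" for i in order]),
    )


def _draw_sumstats(scenario: Scenario, n_reps: int, rng: np.random.Generator):
    v_f = scenario.sampling_sd("female")
    v_m = scenario.sampling_sd("male")
    beta_f = rng.normal(scenario.beta_f, v_f, size=n_reps)
    beta_m = rng.normal(scenario.beta_m, v_m, size=n_reps)
    return beta_f, np.full(n_reps, v_f), beta_m, np.full(n_reps, v_m)


def simulate_sumstats(scenario: Scenario, seed=None) -> PairedRecord:
    """Draw one paired summary-statistic record from the asymptotic
    sampling distribution (summary-level shortcut).

    Requires at least 30 individuals per sex for the normal approximation.
    """
    if scenario.n_f < 30 or scenario.n_m < 30:
        raise ValueError("summary-level simulation requires n >= 30 per sex")
    from . import stats

    rng = _rng(seed)
    bf, vf, bm, vm = _draw_sumstats(scenario, 1, rng)
    key = VariantKey(id="sim", chromosome=1, position=1, major_allele="A",
                     minor_allele="G", info=1.0)
    groups = {}
    for label, b, v, n in (("female", bf[0], vf[0], scenario.n_f),
                           ("male", bm[0], vm[0], scenario.n_m)):
        z = b / v
        p, nlp = stats.p_from_z(z)
        groups[label] = GroupAssoc(group=label, n=n, maf=scenario.maf,
                                   beta=float(b), se=float(v), z=float(z),
                                   p=float(p), neglog10p=float(nlp))
    return PairedRecord(key=key, female=groups["female"], male=groups["male"],
                        maf_all=scenario.maf)


def simulate_sumstats_batch(scenario: Scenario, n_reps: int, seed=None):
    """Vectorized summary-level replicates.

    Returns arrays ``(beta_f, se_f, beta_m, se_m)`` of length ``n_reps``.
    """
    if scenario.n_f < 30 or scenario.n_m < 30:
        raise ValueError("summary-level simulation requires n >= 30 per sex")
    return _draw_sumstats(scenario, n_reps, _rng(seed))


#: Default per-allele effect for the preset grid: per-sex power ~0.83 at
#: alpha=0.05 with n=2000/2000, maf=0.3, sigma=1 (mid-range, so the power
#: comparison between methods stays discriminative at desk scale).
_GRID_BETA = 0.1


def scenario_grid() -> dict[str, Scenario]:
    """The preset heterogeneity configurations used by the power study.

    All presets share n=2000 per sex, maf=0.3, equal residual SDs of 1 (so
    power differences reflect the tests, not the error model) and a sex
    difference in phenotype mean.
    """
    base = dict(n_f=2000, n_m=2000, maf=0.3, mu_f=0.0, mu_m=0.5,
                sigma_f=1.0, sigma_m=1.0)
    b = _GRID_BETA
    return {
        "null": Scenario(beta_f=0.0, beta_m=0.0, name="null", **base),
        "homogeneous": Scenario(beta_f=b, beta_m=b, name="homogeneous", **base),
        "female_only": Scenario(beta_f=b, beta_m=0.0, name="female_only", **base),
        "male_only": Scenario(beta_f=0.0, beta_m=b, name="male_only", **base),
        "opposite_equal": Scenario(beta_f=-b, beta_m=b, name="opposite_equal", **base),
        "magnitude_diff": Scenario(beta_f=b / 2, beta_m=1.2 * b,
                                   name="magnitude_diff", **base),
    }


def apply_irnt(y, groups=None, mode: str = "pooled", offset: float = 0.5):
    """Rank-based inverse normal transformation of a phenotype.

    ``Phi^-1((r - offset) / (n - 2*offset + 1))`` with average ranks for
    ties; the default offset 0.5 gives ``(r - 0.5)/n``.  ``mode='pooled'``
    ranks the whole vector; ``mode='per_group'`` transforms within each
    group of ``groups`` separately (note: per-group transforms place each
    group on its own quantile scale, which breaks comparability of the
    response between stratified and pooled analyses when the groups differ
    in mean or variance).
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("y must be non-empty")
    if mode == "pooled":
        return _irnt_vector(y, offset)
    if mode != "per_group":
        raise ValueError("mode must be 'pooled' or 'per_group'")
    if groups is None:
        raise ValueError("per_group mode requires a groups vector")
    groups = np.asarray(groups)
    out = np.empty_like(y)
    for gval in np.unique(groups):
        m = groups == gval
        out[m] = _irnt_vector(y[m], offset)
    return out


def _irnt_vector(y, offset):
    if np.ptp(y) == 0:
        raise ValueError("all phenotype values equal; ranks are degenerate")
    r = sps.rankdata(y, method="average")
    q = (r - offset) / (len(y) - 2.0 * offset + 1.0)
    return special.ndtri(q)
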