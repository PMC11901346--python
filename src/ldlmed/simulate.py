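"""Synthetic cohort generator: lipid phenotypes and NB read counts.

Emulates a whole-blood mRNA-seq study of LDL cholesterol in an adult cohort:
per-sample LDL-C and sdLDL (small dense LDL) concentrations with a configurable
positive correlation, demographic covariates (age, sex, education, lipid
medication), and a gene x sample matrix of negative-binomial read counts whose
log-mean depends on LDL-C both directly and through sdLDL.  Ground truth
(per-gene effect class, coefficients, dispersion, true proportion mediated) is
returned alongside the counts so that the downstream differential-expression
and mediation stages can be validated by recovery simulations.

The phenotype model is a linear Gaussian structure truncated at zero: sdLDL is
linear in standardized LDL-C plus independent Gaussian noise, drawn from the
conditional normal truncated to (0, inf).  Because truncation distorts both the
marginal moments and the correlation, the latent location, scale and slope are
*calibrated* (Gauss-Hermite quadrature + root finding) so that the observed,
truncated variables match the configured mean, SD and Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, stats

__all__ = [
    "SimulationConfig",
    "EDUCATION_LEVELS",
    "simulate_phenotypes",
    "simulate_counts",
    "simulate_cohort",
    "true_proportion_mediated",
]

#: Ordered education levels; "not_available" is kept as its own category so a
#: large missingness fraction does not shrink the cohort.
EDUCATION_LEVELS = (
    "<=high_school",
    "some_college",
    "college_grad",
    ">graduate",
    "not_available",
)

_DEFAULT_EDU_PROBS = (0.06, 0.15, 0.17, 0.20, 0.42)

GENE_CLASSES = ("null", "direct_only", "mediated", "mixed")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Phenotype defaults are calibrated to the cohort margins the pipeline is
    designed for: LDL-C mean 105 / SD 33 mg/dL; sdLDL mean 477 / SD 333 assay
    units, Pearson correlation 0.4 with LDL-C; age mean 48 / SD 12; 69%
    female; education including a 42% "not_available" level.

    ``mediator_slope`` is the slope of standardized sdLDL on standardized
    LDL-C, which for this model equals the target Pearson correlation.

    Planted per-gene effects are per-SD-of-phenotype natural-log fold changes,
    drawn as ``sign * (effect_min + |N(0, effect_sd)|)`` so that non-null genes
    carry effects bounded away from zero (a deliberately strong-signal regime,
    chosen so recovery simulations measure the screen rather than raw power).
    """

    n_samples: int = 400
    n_genes: int = 2000
    seed: int = 0

    # phenotype margins
    ldl_mean: float = 105.0
    ldl_sd: float = 33.0
    sdldl_mean: float = 477.0
    sdldl_sd: float = 333.0
    mediator_slope: float = 0.4
    age_mean: float = 48.0
    age_sd: float = 12.0
    female_frac: float = 0.69
    education_probs: tuple = _DEFAULT_EDU_PROBS
    lipid_med_frac: float = 0.10

    # gene-class mixture; the remainder (if any) is the "mixed" class with
    # both a direct and a mediator coefficient of the same sign
    frac_null: float = 0.90
    frac_direct_only: float = 0.05
    frac_mediated: float = 0.05

    # planted effect magnitudes (natural log per SD of phenotype)
    direct_effect_sd: float = 0.4
    mediated_effect_sd: float = 0.4
    direct_effect_min: float = 0.2
    mediated_effect_min: float = 0.2

    # nuisance covariate effects on expression (natural log)
    age_effect_sd: float = 0.02
    sex_effect_sd: float = 0.05

    # fraction of non-null genes whose lipid effects act in females only,
    # for exercising the sex-stratified screen (0 = sex-homogeneous effects)
    frac_effects_female_only: float = 0.0

    # NB dispersion ~ Gamma(shape, scale); mean = shape * scale
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.05

    # log-normal library sizes and per-gene relative abundances
    lib_size_log_mean: float = math.log(2.0e6)
    lib_size_log_sd: float = 0.3
    abundance_log_sd: float = 1.5

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("ldl_sd", "sdldl_sd", "age_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1.0 < self.mediator_slope < 1.0:
            raise ValueError("mediator_slope (target correlation) must lie in (-1, 1)")
        fracs = (self.frac_null, self.frac_direct_only, self.frac_mediated)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("class fractions must lie in [0, 1]")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValueError("frac_null + frac_direct_only + frac_mediated must be <= 1")
        if len(self.education_probs) != len(EDUCATION_LEVELS):
            raise ValueError("education_probs must have one entry per education level")
        if abs(sum(self.education_probs) - 1.0) > 1e-9:
            raise ValueError("education_probs must sum to 1")
        if not 0.0 <= self.female_frac <= 1.0:
            raise ValueError("female_frac must lie in [0, 1]")
        if not 0.0 <= self.frac_effects_female_only <= 1.0:
            raise ValueError("frac_effects_female_only must lie in [0, 1]")


def _rng(seed: int, stream: int) -> np.random.Generator:
    # fan a single user seed out into independent per-stage streams
    return np.random.default_rng([np.uint32(stream), np.uint32(seed)])


# ---------------------------------------------------------------------------
# latent calibration for the truncated sdLDL model
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = hermegauss(101)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()  # probabilist's weights -> N(0,1)


def _truncated_observables(mu: float, sigma: float, rho: float):
    """Observed (mean, sd, corr) of y | z ~ TN_(0,inf)(mu + sigma*rho*z,
    sigma*sqrt(1-rho^2)) integrated over z ~ N(0, 1)."""
    scale = sigma * math.sqrt(max(1.0 - rho * rho, 1e-12))
    loc = mu + sigma * rho * _GH_NODES
    a = (0.0 - loc) / scale
    m1, v = stats.truncnorm.stats(a, np.inf, loc=loc, scale=scale, moments="mv")
    mean = float(np.dot(_GH_WEIGHTS, m1))
    second = float(np.dot(_GH_WEIGHTS, v + m1 ** 2))
    var = max(second - mean ** 2, 1e-12)
    cov = float(np.dot(_GH_WEIGHTS, _GH_NODES * m1))
    return mean, math.sqrt(var), cov / math.sqrt(var)


def _calibrate_sdldl(mean: float, sd: float, corr: float):
    """Solve for latent (mu, sigma, rho) so the truncated model reproduces the
    requested observed mean, SD, and correlation with standardized LDL-C."""

    def equations(theta):
        mu, log_sigma, atanh_rho = theta
        m, s, r = _truncated_observables(mu, math.exp(log_sigma), math.tanh(atanh_rho))
        return [m - mean, s - sd, r - corr]

    x0 = np.array([mean, math.log(sd), math.atanh(np.clip(corr, -0.99, 0.99))])
    sol = optimize.root(equations, x0, method="hybr", tol=1e-12)
    mu, log_sigma, atanh_rho = sol.x
    resid = np.max(np.abs(equations(sol.x)))
    if not sol.success or resid > max(1e-6, 1e-6 * abs(mean)):
        raise RuntimeError(
            "could not calibrate the truncated sdLDL model to "
            f"mean={mean}, sd={sd}, corr={corr} (residual {resid:.3g}); "
            "the requested moments may be infeasible under truncation at zero"
        )
    return float(mu), float(math.exp(log_sigma)), float(math.tanh(atanh_rho))


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(config: SimulationConfig | None = None, **overrides) -> pd.DataFrame:
    """Draw a per-sample phenotype table.

    Returns a DataFrame indexed by ``sample_id`` with columns ``ldl_c``,
    ``sdldl``, ``age``, ``sex``, ``education``, ``on_lipid_med``.  LDL-C is a
    zero-truncated normal; sdLDL is drawn from the calibrated truncated linear
    model so its marginal moments and its Pearson correlation with LDL-C match
    the configured targets; identical seeds give identical tables.
    """
    if config is None:
        config = SimulationConfig()
    if overrides:
        config = replace(config, **overrides)
    config.validate()
    rng = _rng(config.seed, stream=1)
    n = config.n_samples

    a_ldl = (0.0 - config.ldl_mean) / config.ldl_sd
    ldl = stats.truncnorm.ppf(
        rng.uniform(size=n), a_ldl, np.inf, loc=config.ldl_mean, scale=config.ldl_sd
    )
    z_ldl = (ldl - config.ldl_mean) / config.ldl_sd

    mu_y, sigma_y, rho = _calibrate_sdldl(
        config.sdldl_mean, config.sdldl_sd, config.mediator_slope
    )
    cond_scale = sigma_y * math.sqrt(max(1.0 - rho * rho, 1e-12))
    cond_loc = mu_y + sigma_y * rho * z_ldl
    sdldl = stats.truncnorm.ppf(
        rng.uniform(size=n), (0.0 - cond_loc) / cond_scale, np.inf,
        loc=cond_loc, scale=cond_scale,
    )

    a_age = (0.0 - config.age_mean) / config.age_sd
    age = stats.truncnorm.ppf(
        rng.uniform(size=n), a_age, np.inf, loc=config.age_mean, scale=config.age_sd
    )
    sex = np.where(rng.uniform(size=n) < config.female_frac, "female", "male")
    education = rng.choice(EDUCATION_LEVELS, size=n, p=np.asarray(config.education_probs))
    on_med = rng.uniform(size=n) < config.lipid_med_frac

    width = max(4, len(str(n)))
    table = pd.DataFrame(
        {
            "ldl_c": ldl,
            "sdldl": sdldl,
            "age": age,
            "sex": pd.Categorical(sex, categories=["female", "male"]),
            "education": pd.Categorical(education, categories=list(EDUCATION_LEVELS), ordered=True),
            "on_lipid_med": on_med,
        },
        index=pd.Index([f"S{i + 1:0{width}d}" for i in range(n)], name="sample_id"),
    )
    return table


# ---------------------------------------------------------------------------
# counts + ground truth
# ---------------------------------------------------------------------------

def _planted_effects(rng, n, sd, floor):
    sign = np.where(rng.uniform(size=n) < 0.5, -1.0, 1.0)
    return sign * (floor + np.abs(rng.normal(0.0, sd, size=n)))


def true_proportion_mediated(beta_direct, beta_mediator, mediator_slope):
    """Ground-truth percent of the total LDL-C effect carried by the mediator.

    On standardized phenotypes the total per-SD effect of LDL-C on log
    expression decomposes into a direct path ``beta_direct`` and an indirect
    path ``beta_mediator * a`` where ``a`` is the standardized slope of sdLDL
    on LDL-C.  Returns ``100 * beta_mediator*a / (beta_direct + beta_mediator*a)``
    clamped to [0, 100]; NaN (undefined) where the total effect is zero.
    """
    bd = np.asarray(beta_direct, dtype=float)
    bm = np.asarray(beta_mediator, dtype=float)
    indirect = bm * mediator_slope
    total = bd + indirect
    with np.errstate(divide="ignore", invalid="ignore"):
        pm = 100.0 * indirect / total
    pm = np.where(np.abs(total) < 1e-12, np.nan, pm)
    pm = np.clip(pm, 0.0, 100.0)
    if np.ndim(beta_direct) == 0 and np.ndim(beta_mediator) == 0:
        return float(pm)
    return pm


def simulate_counts(
    phenotypes: pd.DataFrame, config: SimulationConfig | None = None, **overrides
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a gene x sample NB count matrix plus the ground-truth table.

    For gene g and sample i the count is NB with mean
    ``L_i * w_g * exp(bd_g z(ldl_i) + bm_g z(sdldl_i) + c_age,g z(age_i)
    + c_sex,g male_i)`` and gene dispersion ``phi_g`` (variance
    ``mu + phi mu^2``), where ``L_i`` is a log-normal library-size scale and
    ``w_g`` a relative abundance summing to one over genes.  Gene classes are
    assigned in fixed blocks (null, direct_only, mediated, mixed) by the
    configured fractions.
    """
    if config is None:
        config = SimulationConfig()
    if overrides:
        config = replace(config, **overrides)
    config.validate()
    if len(phenotypes) == 0:
        raise ValueError("phenotype table is empty")
    rng = _rng(config.seed, stream=2)
    n, g = len(phenotypes), config.n_genes

    z_ldl = _standardize(phenotypes["ldl_c"].to_numpy(float))
    z_sdldl = _standardize(phenotypes["sdldl"].to_numpy(float))
    z_age = _standardize(phenotypes["age"].to_numpy(float))
    male = (phenotypes["sex"].astype(str) == "male").to_numpy(float)

    n_null = int(round(config.frac_null * g))
    n_direct = int(round(config.frac_direct_only * g))
    n_mediated = int(round(config.frac_mediated * g))
    n_mixed = g - n_null - n_direct - n_mediated
    if n_mixed < 0:
        raise ValueError("class fractions round to more genes than n_genes")
    classes = np.repeat(
        np.array(GENE_CLASSES, dtype=object), [n_null, n_direct, n_mediated, n_mixed]
    )

    beta_direct = np.zeros(g)
    beta_mediator = np.zeros(g)
    direct_mask = classes == "direct_only"
    mediated_mask = classes == "mediated"
    mixed_mask = classes == "mixed"
    beta_direct[direct_mask] = _planted_effects(
        rng, direct_mask.sum(), config.direct_effect_sd, config.direct_effect_min
    )
    beta_mediator[mediated_mask] = _planted_effects(
        rng, mediated_mask.sum(), config.mediated_effect_sd, config.mediated_effect_min
    )
    if mixed_mask.any():
        # shared sign so the direct and indirect paths reinforce each other
        sign = np.where(rng.uniform(size=mixed_mask.sum()) < 0.5, -1.0, 1.0)
        beta_direct[mixed_mask] = sign * (
            config.direct_effect_min + np.abs(rng.normal(0, config.direct_effect_sd, mixed_mask.sum()))
        )
        beta_mediator[mixed_mask] = sign * (
            config.mediated_effect_min + np.abs(rng.normal(0, config.mediated_effect_sd, mixed_mask.sum()))
        )

    c_age = rng.normal(0.0, config.age_effect_sd, size=g)
    c_sex = rng.normal(0.0, config.sex_effect_sd, size=g)
    dispersion = rng.gamma(config.dispersion_shape, config.dispersion_scale, size=g)

    abundance = np.exp(rng.normal(0.0, config.abundance_log_sd, size=g))
    abundance /= abundance.sum()
    lib_sizes = np.exp(rng.normal(config.lib_size_log_mean, config.lib_size_log_sd, size=n))

    nonnull = classes != "null"
    female_only = np.zeros(g, dtype=bool)
    if config.frac_effects_female_only > 0 and nonnull.any():
        female_only[nonnull] = rng.uniform(size=nonnull.sum()) < config.frac_effects_female_only
    # lipid effects of female-only genes are switched off in male samples
    effect_scale = np.where(female_only[:, None] & (male[None, :] > 0), 0.0, 1.0)

    log_mu = (
        np.log(lib_sizes)[None, :]
        + np.log(abundance)[:, None]
        + effect_scale * (
            beta_direct[:, None] * z_ldl[None, :]
            + beta_mediator[:, None] * z_sdldl[None, :]
        )
        + c_age[:, None] * z_age[None, :]
        + c_sex[:, None] * male[None, :]
    )
    mu = np.exp(log_mu)
    size = 1.0 / dispersion[:, None]
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)

    gene_width = max(5, len(str(g)))
    gene_ids = pd.Index([f"G{i + 1:0{gene_width}d}" for i in range(g)], name="gene_id")
    count_df = pd.DataFrame(counts, index=gene_ids, columns=phenotypes.index)

    truth = pd.DataFrame(
        {
            "gene_class": classes,
            "beta_direct": beta_direct,
            "beta_mediator": beta_mediator,
            "dispersion": dispersion,
            "female_only_effect": female_only,
            "true_proportion_mediated": true_proportion_mediated(
                beta_direct, beta_mediator, config.mediator_slope
            ),
        },
        index=gene_ids,
    )
    return count_df, truth


def simulate_cohort(config: SimulationConfig | None = None, **overrides):
    """Convenience wrapper: (phenotypes, counts, truth) for one config."""
    if config is None:
        config = SimulationConfig()
    if overrides:
        config = replace(config, **overrides)
    phenotypes = simulate_phenotypes(config)
    counts, truth = simulate_counts(phenotypes, config)
    return phenotypes, counts, truth


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant phenotype")
    return (x - x.mean()) / sd
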