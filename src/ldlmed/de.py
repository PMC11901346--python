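"""Tertile-extremes negative-binomial differential expression.

The contrast is the upper versus lower tertile of a continuous phenotype
(LDL-C or sdLDL), with the middle tertile excluded.  Each gene's counts are
modeled with a negative-binomial GLM (log link, log effective-library-size
offset); the group coefficient is tested with a likelihood-ratio test against
a chi-square with one degree of freedom, and p-values are Benjamini-Hochberg
adjusted across genes.

Per-gene NB dispersions are estimated by maximizing the Cox-Reid adjusted
profile likelihood over a bounded log10-dispersion grid and then shrunk toward
a running-median mean-dispersion trend with a fixed prior weight (10 prior
degrees of freedom).  All GLM fits share one design matrix, so the IRLS
iterations are vectorized across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .normalize import NormalizationResult, compute_tmm_factors

__all__ = [
    "TertileDesign",
    "assign_tertiles",
    "build_design_matrix",
    "fit_nb_glm",
    "estimate_dispersion",
    "lrt_de",
    "bh_adjust",
    "TertileDE",
]

LOG10_DISP_LO, LOG10_DISP_HI = -6.0, 1.0


# ---------------------------------------------------------------------------
# tertile design
# ---------------------------------------------------------------------------

@dataclass
class TertileDesign:
    """Low/high/excluded assignment from the empirical tertiles of a phenotype."""

    phenotype_name: str
    group: pd.Series  # values in {"low", "high", "excluded"}
    cutpoints: tuple[float, float]

    @property
    def included(self) -> pd.Index:
        return self.group.index[self.group != "excluded"]


def assign_tertiles(values: pd.Series, phenotype_name: str = "") -> TertileDesign:
    """Split samples at the empirical 1/3 and 2/3 quantiles.

    Quantiles use the linear-interpolation definition; samples at or below the
    lower cutpoint go to "low", strictly above the upper cutpoint to "high",
    the rest are excluded.  Ties at a cutpoint therefore fall into the lower
    bin, which keeps the assignment deterministic on granular data.
    """
    vals = pd.Series(values).astype(float)
    finite = vals[np.isfinite(vals)]
    if len(finite) < 3:
        raise ValueError("need at least 3 finite values to form tertiles")
    if finite.nunique() < 2:
        raise ValueError(f"phenotype {phenotype_name!r} is degenerate (fewer than 2 distinct values)")
    lower, upper = np.quantile(finite.to_numpy(), [1.0 / 3.0, 2.0 / 3.0])
    group = pd.Series("excluded", index=vals.index, dtype=object)
    group[vals <= lower] = "low"
    group[vals > upper] = "high"
    return TertileDesign(phenotype_name=phenotype_name, group=group, cutpoints=(float(lower), float(upper)))


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

EDUCATION_REFERENCE = "<=high_school"


def build_design_matrix(
    phenotypes: pd.DataFrame,
    design: TertileDesign,
    covariates: tuple[str, ...] = ("age", "sex", "education"),
    extra_continuous: tuple[str, ...] = (),
    extra_tertile: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Model matrix for the tertile contrast on the included samples.

    Columns: intercept; ``group_high`` (1 = upper tertile); standardized age;
    male indicator; education dummies against the ``<=high_school`` reference
    (with "not_available" kept as its own level); one standardized column per
    extra continuous covariate (the default coding when adjusting for the
    mediator); and, for each ``extra_tertile`` covariate, two dummies for its
    middle and upper tertile computed on the included samples (the
    alternative tertile coding of the mediator).  Constant columns are
    dropped with a warning; a rank-deficient matrix raises with the offending
    columns named.
    """
    missing = [
        c
        for c in list(covariates) + list(extra_continuous) + list(extra_tertile)
        if c not in phenotypes.columns
    ]
    if missing:
        raise ValueError(f"covariates not in phenotype table: {missing}")
    idx = design.included
    sub = phenotypes.loc[idx]
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(idx))}
    cols["group_high"] = (design.group.loc[idx] == "high").to_numpy(float)

    for cov in covariates:
        if cov == "sex":
            cols["sex_male"] = (sub["sex"].astype(str) == "male").to_numpy(float)
        elif cov == "education":
            edu = sub["education"].astype(str)
            for level in pd.unique(edu):
                if level == EDUCATION_REFERENCE:
                    continue
                cols[f"education_{level}"] = (edu == level).to_numpy(float)
        else:
            cols[cov] = _zscore(sub[cov].to_numpy(float), cov)
    for cov in extra_continuous:
        cols[f"{cov}_z"] = _zscore(sub[cov].to_numpy(float), cov)
    for cov in extra_tertile:
        tert = assign_tertiles(sub[cov], cov).group
        cols[f"{cov}_tmid"] = (tert == "excluded").to_numpy(float)
        cols[f"{cov}_thigh"] = (tert == "high").to_numpy(float)

    X = pd.DataFrame(cols, index=idx)
    constant = [c for c in X.columns if c != "intercept" and X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant design columns: {constant}", stacklevel=2)
        X = X.drop(columns=constant)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = _collinear_columns(X)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")
    return X


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"covariate {name!r} is constant on the included samples")
    return (x - x.mean()) / sd


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    _, r = np.linalg.qr(X.to_numpy())
    small = np.abs(np.diag(r)) < 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    return [str(c) for c, s in zip(X.columns, small) if s]


# ---------------------------------------------------------------------------
# batched NB GLM via IRLS
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood (Poisson when the row's dispersion is ~0)."""
    phi = np.asarray(phi, dtype=float)[:, None]
    mu = np.maximum(mu, 1e-300)
    poisson = y * np.log(mu) - mu - gammaln(y + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        size = 1.0 / np.maximum(phi, 1e-300)
        nb = (
            gammaln(y + size)
            - gammaln(size)
            - gammaln(y + 1.0)
            + y * np.log(phi * mu / (1.0 + phi * mu))
            - size * np.log1p(phi * mu)
        )
    ll = np.where(phi > 1e-10, nb, poisson)
    return ll.sum(axis=1)


def _irls(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
):
    """Fit NB GLMs with a shared design across genes.

    Y: (G, n) counts; X: (n, p); offset: (n,); phi: (G,) dispersions.
    Returns (beta (G, p), loglik (G,), mu (G, n), converged (G,), xtwx (G, p, p)).
    """
    Y = np.asarray(Y, dtype=float)
    G, n = Y.shape
    p = X.shape[1]
    phi_col = np.asarray(phi, dtype=float)[:, None]
    mu = np.maximum(Y, 0.5)
    eta = np.log(mu)
    dev_old = np.full(G, np.inf)
    converged = np.zeros(G, dtype=bool)
    beta = np.zeros((G, p))
    xtwx = np.empty((G, p, p))
    for _ in range(max_iter):
        w = mu / (1.0 + phi_col * mu)  # IRLS working weights for log link
        z = (eta - offset[None, :]) + (Y - mu) / mu
        xtwx = np.einsum("ip,gi,iq->gpq", X, w, X, optimize=True)
        xtwz = np.einsum("ip,gi,gi->gp", X, w, z, optimize=True)
        try:
            beta_new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            xtwx_r = xtwx + 1e-8 * np.eye(p)[None, :, :]
            beta_new = np.linalg.solve(xtwx_r, xtwz[..., None])[..., 0]
        beta = np.where(converged[:, None], beta, beta_new)
        eta = np.clip(beta @ X.T + offset[None, :], -50.0, 50.0)
        mu = np.maximum(np.exp(eta), 1e-10)
        dev = _nb_deviance(Y, mu, phi_col)
        delta = np.abs(dev - dev_old) / (np.abs(dev) + 0.1)
        converged = converged | (delta < tol)
        dev_old = dev
        if converged.all():
            break
    ll = _nb_loglik(Y, mu, phi)
    # final-weight information matrix (needed for the Cox-Reid adjustment)
    w = mu / (1.0 + phi_col * mu)
    xtwx = np.einsum("ip,gi,iq->gpq", X, w, X, optimize=True)
    return beta, ll, mu, converged, xtwx


def _nb_deviance(Y, mu, phi_col):
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(Y > 0, Y * (np.log(np.maximum(Y, 1e-300)) - np.log(mu)), 0.0)
        phi_safe = np.maximum(phi_col, 1e-300)
        nb_term = (Y + 1.0 / phi_safe) * (np.log1p(phi_col * mu) - np.log1p(phi_col * Y))
        pois_term = mu - Y
        term2 = np.where(phi_col > 1e-10, nb_term, -pois_term)
    return 2.0 * (term1 - term2).sum(axis=1)


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    offset: np.ndarray | None = None,
    dispersion: float = 0.0,
):
    """Fit one gene's NB GLM; returns (coefficients, log-likelihood, fitted means, converged).

    Coefficients are on the natural-log scale.  ``dispersion=0`` degrades to a
    Poisson fit.  Convergence is a relative deviance change below 1e-8 within
    100 iterations.
    """
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if offset is None:
        offset = np.zeros(len(y))
    if Xa.shape[0] != len(y) or len(offset) != len(y):
        raise ValueError("rows of X, y, and offsets must match")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if np.all(y == 0):
        raise ValueError("all-zero counts: coefficients are undefined")
    beta, ll, mu, conv, _ = _irls(y[None, :], Xa, np.asarray(offset, float), np.array([dispersion]))
    return beta[0], float(ll[0]), mu[0], bool(conv[0])


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersion(
    counts: pd.DataFrame,
    X: pd.DataFrame,
    offset: np.ndarray,
    prior_df: float = 10.0,
    grid_size: int = 29,
) -> pd.Series:
    """Per-gene NB dispersions: Cox-Reid APL maximized on a log10 grid, then
    shrunk toward a running-median mean-dispersion trend.

    The Cox-Reid adjusted profile likelihood is ``ll(beta_hat; phi) - 0.5
    log det(X'WX)``, evaluated on ``grid_size`` points of log10 dispersion in
    [-6, 1] with a quadratic refinement around the grid maximum.  The trend is
    a running median of the per-gene maximizers ordered by average log2 CPM;
    shrinkage weights the gene estimate by its residual degrees of freedom
    against ``prior_df`` prior degrees of freedom (on the log scale).  Genes
    with fewer positive counts than design columns take the trend directly.
    """
    Y = counts.to_numpy(dtype=float)
    Xa = X.to_numpy(dtype=float)
    G, n = Y.shape
    p = Xa.shape[1]
    if n <= p:
        raise ValueError("need more samples than design columns to estimate dispersion")

    grid = np.linspace(LOG10_DISP_LO, LOG10_DISP_HI, grid_size)
    apl = np.empty((G, grid_size))
    for j, ld in enumerate(grid):
        phi = np.full(G, 10.0 ** ld)
        _, ll, _, _, xtwx = _irls(Y, Xa, offset, phi)
        sign, logdet = np.linalg.slogdet(xtwx)
        apl[:, j] = ll - 0.5 * logdet

    best = np.argmax(apl, axis=1)
    log10_hat = grid[best].astype(float)
    # quadratic refinement where the maximum is interior
    interior = (best > 0) & (best < grid_size - 1)
    if interior.any():
        i = best[interior]
        y0 = apl[interior, i - 1]
        y1 = apl[interior, i]
        y2 = apl[interior, i + 1]
        denom = y0 - 2.0 * y1 + y2
        step = grid[1] - grid[0]
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        log10_hat[interior] = grid[i] + np.clip(shift, -1.0, 1.0) * step

    # mean-dispersion trend: running median over genes ordered by abundance
    cpm = Y * 1.0e6 / np.exp(offset)[None, :]
    ave_log_cpm = np.log2(cpm.mean(axis=1) + 0.5)
    order = np.argsort(ave_log_cpm, kind="stable")
    window = max(11, (G // 10) | 1)
    trend_sorted = (
        pd.Series(log10_hat[order]).rolling(window, center=True, min_periods=1).median().to_numpy()
    )
    log10_trend = np.empty(G)
    log10_trend[order] = trend_sorted

    resid_df = n - p
    log10_shrunk = (resid_df * log10_hat + prior_df * log10_trend) / (resid_df + prior_df)

    few_positive = (Y > 0).sum(axis=1) < p
    log10_shrunk[few_positive] = log10_trend[few_positive]
    return pd.Series(10.0 ** log10_shrunk, index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# BH adjustment and the LRT driver
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def lrt_de(
    counts: pd.DataFrame,
    phenotypes: pd.DataFrame,
    target: str,
    covariates: tuple[str, ...] = ("age", "sex", "education"),
    extra_continuous: tuple[str, ...] = (),
    extra_tertile: tuple[str, ...] = (),
    normalization: NormalizationResult | None = None,
    dispersion: pd.Series | None = None,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Differential expression between the extreme tertiles of ``target``.

    Fits, per gene, a full NB GLM (group + covariates) and a reduced model
    without the group column at the gene's shrunken dispersion; the LRT
    statistic is referred to chi-square(1).  Returns a DataFrame indexed by
    gene id, sorted by p-value, with columns ``logFC`` (log2, high vs low),
    ``dispersion``, ``lrt_stat``, ``p_value``, ``fdr_adjusted_p``,
    ``direction`` and ``converged``.  Non-converged genes keep their row but
    carry NaN p-values and are excluded from the BH adjustment.
    """
    if target not in phenotypes.columns:
        raise ValueError(f"target phenotype {target!r} not in the phenotype table")
    if not counts.columns.equals(phenotypes.index):
        phenotypes = phenotypes.loc[counts.columns]

    design = assign_tertiles(phenotypes[target], target)
    X = build_design_matrix(phenotypes, design, covariates, extra_continuous, extra_tertile)
    idx = X.index
    Y = counts.loc[:, idx]

    if normalization is None:
        normalization = compute_tmm_factors(counts)
    offset = np.log(normalization.effective_library_size.loc[idx].to_numpy(float))

    if dispersion is None:
        dispersion = estimate_dispersion(Y, X, offset, prior_df=prior_df)
    else:
        dispersion = dispersion.loc[Y.index]

    Xa = X.to_numpy(float)
    group_col = X.columns.get_loc("group_high")
    X_red = np.delete(Xa, group_col, axis=1)
    phi = dispersion.to_numpy(float)
    Ym = Y.to_numpy(float)

    beta_f, ll_f, _, conv_f, _ = _irls(Ym, Xa, offset, phi)
    _, ll_r, _, conv_r, _ = _irls(Ym, X_red, offset, phi)
    converged = conv_f & conv_r
    all_zero = (Ym == 0).all(axis=1)
    converged &= ~all_zero

    lrt = np.maximum(2.0 * (ll_f - ll_r), 0.0)
    logfc = beta_f[:, group_col] / np.log(2.0)
    p = chi2.sf(lrt, df=1)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    result = pd.DataFrame(
        {
            "logFC": logfc,
            "dispersion": phi,
            "lrt_stat": lrt,
            "p_value": np.where(converged, p, np.nan),
            "fdr_adjusted_p": np.nan,
            "direction": np.where(logfc > 0, "up", "down"),
            "converged": converged,
        },
        index=Y.index,
    )
    ok = result["converged"].to_numpy()
    if ok.any():
        result.loc[ok, "fdr_adjusted_p"] = bh_adjust(result.loc[ok, "p_value"].to_numpy())
    n_flagged = int((~ok).sum())
    if n_flagged:
        warnings.warn(f"{n_flagged} gene(s) flagged (non-converged or all-zero) and excluded from FDR", stacklevel=2)
    return result.sort_values("p_value", kind="stable")


class TertileDE(BaseEstimator):
    """Estimator wrapper for the tertile-extremes NB differential expression.

    ``fit(counts, phenotypes)`` populates ``results_`` (the per-gene table),
    ``design_``, ``normalization_`` and ``dispersions_``.
    """

    def __init__(
        self,
        target: str = "ldl_c",
        covariates: tuple[str, ...] = ("age", "sex", "education"),
        extra_continuous: tuple[str, ...] = (),
        alpha: float = 0.05,
        prior_df: float = 10.0,
    ):
        self.target = target
        self.covariates = covariates
        self.extra_continuous = extra_continuous
        self.alpha = alpha
        self.prior_df = prior_df

    def fit(self, X: pd.DataFrame, y: pd.DataFrame = None, normalization=None):
        counts, phenotypes = X, y
        if phenotypes is None:
            raise ValueError("fit requires the phenotype table as y")
        self.design_ = assign_tertiles(phenotypes.loc[counts.columns, self.target], self.target)
        self.normalization_ = normalization or compute_tmm_factors(counts)
        self.results_ = lrt_de(
            counts,
            phenotypes,
            self.target,
            tuple(self.covariates),
            tuple(self.extra_continuous),
            normalization=self.normalization_,
            prior_df=self.prior_df,
        )
        self.dispersions_ = self.results_["dispersion"]
        self.significant_genes_ = self.results_.index[
            self.results_["fdr_adjusted_p"] <= self.alpha
        ]
        return self
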