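"""Between-sample normalization for read-count matrices.

Implements trimmed-mean-of-M-values (TMM) scaling factors, counts-per-million,
and the low-expression filter (CPM >= 1 in at least three samples) that
standard bulk RNA-seq workflows apply before model fitting.

Count matrices are pandas DataFrames with genes as rows (index = gene ids) and
samples as columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "NormalizationResult",
    "compute_tmm_factors",
    "compute_cpm",
    "filter_low_expression",
    "TMMNormalizer",
    "LowExpressionFilter",
]


@dataclass
class NormalizationResult:
    """TMM factors and the effective library sizes they imply."""

    tmm_factor: pd.Series
    library_size: pd.Series
    reference_sample: str

    @property
    def effective_library_size(self) -> pd.Series:
        return self.library_size * self.tmm_factor


def _validate_counts(counts: pd.DataFrame) -> np.ndarray:
    mat = counts.to_numpy()
    if mat.size == 0:
        raise ValueError("count matrix is empty")
    if np.any(mat < 0):
        raise ValueError("count matrix contains negative entries")
    return np.asarray(mat, dtype=float)


def _pair_factor(y_s, y_r, n_s, n_r, trim_m, trim_a, weighted):
    """TMM factor of one sample against the reference on their shared genes."""
    shared = (y_s > 0) & (y_r > 0)
    ys, yr = y_s[shared], y_r[shared]
    if ys.size == 0:
        return 1.0, 0
    with np.errstate(divide="ignore"):
        m = np.log2((ys / n_s) / (yr / n_r))
        a = 0.5 * np.log2((ys / n_s) * (yr / n_r))
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    n_kept = int(keep.sum())
    if n_kept == 0:
        return 1.0, 0
    if weighted:
        # inverse asymptotic (delta-method binomial) variance of M
        w = (n_s - ys[keep]) / (n_s * ys[keep]) + (n_r - yr[keep]) / (n_r * yr[keep])
        w = 1.0 / w
        mean_m = np.sum(w * m[keep]) / np.sum(w)
    else:
        mean_m = float(np.mean(m[keep]))
    return float(2.0 ** mean_m), n_kept


def compute_tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    weighted: bool = True,
) -> NormalizationResult:
    """Compute TMM scaling factors for every sample of a count matrix.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean of those fractions (ties broken by column order).  For
    each sample, per-gene log2 ratios against the reference (M) and average
    log2 abundances (A) are computed over genes expressed in both samples, the
    extreme ``trim_m`` / ``trim_a`` tails of each are discarded, and the factor
    is 2 to the precision-weighted mean of the remaining M values.  Factors are
    rescaled to geometric mean one.
    """
    mat = _validate_counts(counts)
    if mat.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = mat.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(
            f"sample {counts.columns[zero[0]]!r} has all-zero counts; "
            "remove it before normalization"
        )
    uq = np.array([np.quantile(mat[:, j], 0.75) for j in range(mat.shape[1])]) / lib
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        f, n_kept = _pair_factor(
            mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a, weighted
        )
        if j != ref_idx and n_kept < 10:
            warnings.warn(
                f"fewer than 10 genes survived TMM trimming for sample "
                f"{counts.columns[j]!r}; its factor is set to 1",
                stacklevel=2,
            )
            f = 1.0
        factors[j] = f
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationResult(
        tmm_factor=pd.Series(factors, index=counts.columns, name="tmm_factor"),
        library_size=pd.Series(lib, index=counts.columns, name="library_size"),
        reference_sample=str(counts.columns[ref_idx]),
    )


def compute_cpm(
    counts: pd.DataFrame, norm: NormalizationResult | None = None
) -> pd.DataFrame:
    """Counts per million over (effective) library sizes.

    With ``norm=None`` the raw column sums are used (factors of one), which is
    what the pre-normalization expression filter expects.
    """
    mat = _validate_counts(counts)
    if norm is None:
        eff = mat.sum(axis=0)
    else:
        if not norm.tmm_factor.index.equals(counts.columns):
            raise ValueError("normalization result does not match the count matrix samples")
        eff = norm.effective_library_size.to_numpy()
    if np.any(eff <= 0):
        raise ValueError("library sizes must be positive")
    return pd.DataFrame(
        mat * 1.0e6 / eff, index=counts.index, columns=counts.columns
    )


def filter_low_expression(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 3
) -> pd.DataFrame:
    """Drop genes not reaching ``min_cpm`` in at least ``min_samples`` samples.

    CPM is computed with unit factors (raw library sizes): the filter runs
    before TMM in the standard workflow.  The boundary is inclusive, so a gene
    at exactly ``min_cpm`` in exactly ``min_samples`` samples is retained.
    """
    if min_samples > counts.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    cpm = compute_cpm(counts)
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            "no genes pass the expression filter; review min_cpm/min_samples"
        )
    return counts.loc[keep]


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """Transformer wrapper around TMM: fit learns per-sample scaling factors,
    transform returns the CPM matrix under the effective library sizes.

    Parameters
    ----------
    trim_m, trim_a : float
        Two-sided trim fractions for the log-ratio (M) and abundance (A)
        arrays; defaults are the canonical 0.30 / 0.05.
    weighted : bool
        Precision-weight the trimmed mean (default) or use a plain mean.
    """

    def __init__(self, trim_m: float = 0.30, trim_a: float = 0.05, weighted: bool = True):
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.weighted = weighted

    def fit(self, X: pd.DataFrame, y=None):
        result = compute_tmm_factors(X, self.trim_m, self.trim_a, self.weighted)
        self.normalization_ = result
        self.tmm_factors_ = result.tmm_factor
        self.effective_library_sizes_ = result.effective_library_size
        self.reference_sample_ = result.reference_sample
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return compute_cpm(X, self.normalization_)


class LowExpressionFilter(BaseEstimator, TransformerMixin):
    """Transformer wrapper around the CPM expression filter."""

    def __init__(self, min_cpm: float = 1.0, min_samples: int = 3):
        self.min_cpm = min_cpm
        self.min_samples = min_samples

    def fit(self, X: pd.DataFrame, y=None):
        kept = filter_low_expression(X, self.min_cpm, self.min_samples)
        self.retained_genes_ = kept.index
        self.n_genes_in_ = X.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[self.retained_genes_.intersection(X.index)]
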