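"""Sex-stratified mediation over a pre-identified gene set.

The three-condition screen is re-run independently within the female and the
male stratum: tertile cutpoints and TMM factors are recomputed on the stratum
(a stratum is treated as a fresh cohort), sex is removed from the covariates,
and the BH adjustment runs within the supplied gene subset per stratum.  Each
gene is then classified as mediated in both sexes, females only, males only,
or neither.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .de import lrt_de
from .mediation import screen_mediation
from .normalize import compute_tmm_factors

__all__ = ["stratified_mediation", "classify_overlap", "SexStratifiedMediation"]


def _stratum_screen(counts, phenotypes, gene_subset, covariates, alpha, target, mediator):
    norm = compute_tmm_factors(counts)
    sub = counts.loc[gene_subset]
    de_ldl = lrt_de(sub, phenotypes, target, covariates, normalization=norm).loc[sub.index]
    de_med = lrt_de(sub, phenotypes, mediator, covariates, normalization=norm).loc[sub.index]
    sig = (de_ldl["fdr_adjusted_p"] <= alpha) & (de_med["fdr_adjusted_p"] <= alpha)
    concordant = sig & (np.sign(de_ldl["logFC"]) == np.sign(de_med["logFC"]))
    candidates = sub.index[concordant.to_numpy()]
    if len(candidates):
        de_adj = lrt_de(
            sub.loc[candidates], phenotypes, target, covariates,
            extra_continuous=(mediator,), normalization=norm,
        )
    else:
        de_adj = de_ldl.iloc[0:0]
    return screen_mediation(de_ldl, de_med, de_adj, alpha=alpha)


def stratified_mediation(
    counts: pd.DataFrame,
    phenotypes: pd.DataFrame,
    gene_subset,
    covariates: tuple[str, ...] = ("age", "education"),
    alpha: float = 0.05,
    target: str = "ldl_c",
    mediator: str = "sdldl",
) -> tuple[pd.DataFrame, dict]:
    """Run the mediation screen within each sex and classify the overlap.

    ``counts`` should be the full (filtered) matrix so that TMM factors rest
    on all genes; the screen itself, including the per-stratum BH adjustment,
    is restricted to ``gene_subset``.  ``covariates`` must not contain "sex".
    Returns the per-gene table (per-stratum logFC, mediated flags, proportion
    mediated, classification) and the summary counts per class.
    """
    gene_subset = pd.Index(gene_subset)
    if "sex" in covariates:
        raise ValueError("sex must be removed from the covariates in a sex-stratified run")
    if len(gene_subset) == 0:
        empty = pd.DataFrame(
            columns=[
                "logfc_ldl_female", "logfc_ldl_male", "mediated_female", "mediated_male",
                "pm_female", "pm_male", "classification",
            ]
        )
        return empty, {"both": 0, "female_only": 0, "male_only": 0, "neither": 0}
    missing = gene_subset.difference(counts.index)
    if len(missing):
        raise ValueError(f"gene subset contains {len(missing)} gene(s) absent from the count matrix")

    records = {}
    # a crude lower bound on the design: intercept + group + covariate columns
    min_cols = 2 + len(covariates) + 3 * ("education" in covariates)
    for stratum in ("female", "male"):
        mask = phenotypes["sex"].astype(str) == stratum
        n_str = int(mask.sum())
        if n_str < 3 * min_cols:
            raise ValueError(
                f"stratum {stratum!r} has only {n_str} samples; "
                f"need at least {3 * min_cols} for the stratified screen"
            )
        ph = phenotypes.loc[mask]
        records[stratum] = _stratum_screen(
            counts.loc[:, ph.index], ph, gene_subset, covariates, alpha, target, mediator
        )

    f, m = records["female"], records["male"]
    classification, summary = classify_overlap(f["mediated"], m["mediated"])
    table = pd.DataFrame(
        {
            "logfc_ldl_female": f["logfc_ldl"],
            "logfc_ldl_male": m["logfc_ldl"],
            "mediated_female": f["mediated"],
            "mediated_male": m["mediated"],
            "pm_female": f["proportion_mediated"],
            "pm_male": m["proportion_mediated"],
            "classification": classification,
        },
        index=gene_subset,
    )
    return table, summary


def classify_overlap(mediated_female: pd.Series, mediated_male: pd.Series):
    """Four-way classification of two mediated-flag vectors.

    Returns (per-gene classification Series, counts dict); the counts always
    partition the gene set.
    """
    if not mediated_female.index.equals(mediated_male.index):
        if set(mediated_female.index) != set(mediated_male.index):
            raise ValueError("female and male records cover different gene sets")
        mediated_male = mediated_male.loc[mediated_female.index]
    f = mediated_female.astype(bool)
    m = mediated_male.astype(bool)
    classification = pd.Series(
        np.select(
            [f & m, f & ~m, ~f & m],
            ["both", "female_only", "male_only"],
            default="neither",
        ),
        index=f.index,
        name="classification",
    )
    summary = {
        "both": int((f & m).sum()),
        "female_only": int((f & ~m).sum()),
        "male_only": int((~f & m).sum()),
        "neither": int((~f & ~m).sum()),
    }
    return classification, summary


class SexStratifiedMediation(BaseEstimator):
    """Estimator wrapper for the sex-stratified screen.

    ``fit(counts, phenotypes, gene_subset=...)`` populates ``results_`` and
    ``summary_`` (the both / female_only / male_only / neither counts).
    """

    def __init__(
        self,
        covariates: tuple[str, ...] = ("age", "education"),
        alpha: float = 0.05,
        target: str = "ldl_c",
        mediator: str = "sdldl",
    ):
        self.covariates = covariates
        self.alpha = alpha
        self.target = target
        self.mediator = mediator

    def fit(self, X: pd.DataFrame, y: pd.DataFrame = None, gene_subset=None):
        if y is None or gene_subset is None:
            raise ValueError("fit requires the phenotype table as y and a gene_subset")
        self.results_, self.summary_ = stratified_mediation(
            X, y, gene_subset, covariates=tuple(self.covariates),
            alpha=self.alpha, target=self.target, mediator=self.mediator,
        )
        return self
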