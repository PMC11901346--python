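"""Readers and writers for the pipeline's interchange formats.

Counts travel as gene x sample TSV (gene id in the first column) or as
MatrixMarket MTX triplets with ``.genes.txt`` / ``.samples.txt`` sidecars;
phenotypes as CSV; per-gene result tables as TSV with "NA" for missing
values; run configuration as YAML.  The packaged reference table of 33
mediated mRNAs (differential-expression effect sizes and p-values for both
lipid contrasts) is checksum-pinned.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_phenotypes",
    "write_phenotypes",
    "read_result_table",
    "write_result_table",
    "load_table2_fixture",
    "PipelineConfig",
    "run_full_pipeline",
]

_FIXTURE_NAME = "mediated_mrnas_de.tsv"
_FIXTURE_SHA256 = "86b9214c50bac930b79e5e82a254d664d024987353f07a867a12874eae14eea0"


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample integer count matrix from TSV or MTX."""
    path = Path(path)
    if path.suffix == ".mtx":
        genes = _read_lines(path.with_suffix(".genes.txt"))
        samples = _read_lines(path.with_suffix(".samples.txt"))
        m = mmread(path)
        mat = m.toarray() if hasattr(m, "toarray") else np.asarray(m)
        df = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=samples)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = "gene_id"
    if df.empty:
        raise ValueError(f"{path}: empty count matrix")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicate gene ids, e.g. {dupes}")
    arr = df.to_numpy()
    bad = np.argwhere(~np.isfinite(arr.astype(float)) | (arr.astype(float) % 1 != 0))
    if bad.size:
        g, s = bad[0]
        raise ValueError(f"{path}: non-integer entry at gene {df.index[g]!r}, sample {df.columns[s]!r}")
    neg = np.argwhere(arr.astype(float) < 0)
    if neg.size:
        g, s = neg[0]
        raise ValueError(f"{path}: negative entry at gene {df.index[g]!r}, sample {df.columns[s]!r}")
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    """Write counts as TSV (default) or MTX + sidecar id files by extension."""
    path = Path(path)
    if path.suffix == ".mtx":
        mmwrite(path, coo_matrix(counts.to_numpy()), field="integer")
        _write_lines(path.with_suffix(".genes.txt"), counts.index)
        _write_lines(path.with_suffix(".samples.txt"), counts.columns)
    else:
        counts.to_csv(path, sep="\t", index_label="gene_id")


def _read_lines(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _write_lines(path, items) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for item in items:
            fh.write(f"{item}\n")


# ---------------------------------------------------------------------------
# phenotypes and result tables
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    """Read the per-sample phenotype CSV written by :func:`write_phenotypes`."""
    df = pd.read_csv(path, index_col="sample_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    for col in ("ldl_c", "sdldl"):
        if col in df.columns and (df[col] <= 0).any():
            raise ValueError(f"{path}: column {col!r} must be positive")
    if "sex" in df.columns:
        df["sex"] = pd.Categorical(df["sex"], categories=["female", "male"])
    if "education" in df.columns:
        from .simulate import EDUCATION_LEVELS

        df["education"] = pd.Categorical(df["education"], categories=list(EDUCATION_LEVELS), ordered=True)
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index_label="sample_id")


def write_result_table(table: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    table.to_csv(path, sep="\t", index_label=index_label, na_rep="NA")


def read_result_table(path, index_col: str = "gene_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])


# ---------------------------------------------------------------------------
# packaged fixture
# ---------------------------------------------------------------------------

def load_table2_fixture() -> pd.DataFrame:
    """The packaged table of 33 mediated mRNAs with per-contrast DE results.

    Columns: ``logfc_ldl``, ``p_ldl``, ``fdr_ldl`` and the sdLDL
    counterparts, indexed by gene symbol.  The file is checksum-pinned; a
    mismatch means the packaged data were altered.
    """
    ref = resources.files("ldlmed").joinpath("data").joinpath(_FIXTURE_NAME)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise RuntimeError(
            f"packaged fixture {_FIXTURE_NAME} is corrupted (sha256 {digest})"
        )
    from io import BytesIO

    table = pd.read_csv(BytesIO(raw), sep="\t", index_col="gene")
    if len(table) != 33 or table.index.duplicated().any():
        raise RuntimeError("packaged fixture failed its shape invariants")
    return table


# ---------------------------------------------------------------------------
# pipeline configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration; round-trips losslessly through YAML."""

    counts: str | None = None
    phenotypes: str | None = None
    gmt: str | None = None
    outdir: str = "ldlmed_run"
    alpha: float = 0.05
    min_cpm: float = 1.0
    min_samples: int = 3
    enrichment_p: float = 0.05
    min_overlap: int = 2
    covariates: tuple = ("age", "sex", "education")
    seed: int = 0
    simulate: bool = False
    n_samples: int = 400
    n_genes: int = 2000
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 < self.alpha <= 1 or not 0 < self.enrichment_p <= 1:
            raise ValueError("significance thresholds must lie in (0, 1]")
        if self.min_cpm < 0 or self.min_samples < 1:
            raise ValueError("invalid expression-filter thresholds")
        self.covariates = tuple(self.covariates)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["covariates"] = list(data["covariates"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_full_pipeline(config: PipelineConfig) -> Path:
    """Execute simulate (optional) -> filter -> TMM -> DE x2 -> mediation ->
    sex stratification -> enrichment (optional), writing every stage table,
    the stage-count summary, and the effective configuration to ``outdir``.
    """
    import logging

    from .enrichment import hypergeometric_enrichment, read_gmt
    from .mediation import run_mediation_pipeline
    from .normalize import compute_tmm_factors, filter_low_expression
    from .simulate import SimulationConfig, simulate_cohort
    from .stratified import stratified_mediation

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("ldlmed")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    gene_sets = None
    if config.gmt is not None:
        gene_sets = read_gmt(config.gmt)  # fail before any compute if unreadable

    if config.simulate:
        sim = SimulationConfig(n_samples=config.n_samples, n_genes=config.n_genes, seed=config.seed)
        phenotypes, counts, truth = simulate_cohort(sim)
        write_phenotypes(phenotypes, outdir / "phenotypes.csv")
        write_counts(counts, outdir / "counts.tsv")
        write_result_table(truth, outdir / "simulation_truth.tsv")
    else:
        if config.counts is None or config.phenotypes is None:
            raise ValueError("either set simulate=true or provide counts and phenotypes paths")
        counts = read_counts(config.counts)
        phenotypes = read_phenotypes(config.phenotypes)

    log.info("pipeline: seed=%s alpha=%s covariates=%s", config.seed, config.alpha, config.covariates)

    filtered = filter_low_expression(counts, config.min_cpm, config.min_samples)
    norm = compute_tmm_factors(filtered)
    norm.tmm_factor.to_frame().assign(library_size=norm.library_size).to_csv(
        outdir / "tmm_factors.tsv", sep="\t", index_label="sample_id"
    )

    records, summary = run_mediation_pipeline(
        filtered, phenotypes, covariates=config.covariates, alpha=config.alpha, apply_filter=False
    )
    write_result_table(records, outdir / "mediation.tsv")

    mediated = records.index[records["mediated"]]
    strat_covariates = tuple(c for c in config.covariates if c != "sex")
    strat_summary = {}
    if len(mediated):
        strat, strat_summary = stratified_mediation(
            filtered, phenotypes, mediated, covariates=strat_covariates, alpha=config.alpha
        )
        write_result_table(strat, outdir / "sex_stratified.tsv")

    if gene_sets is not None and len(mediated):
        enriched = hypergeometric_enrichment(
            mediated, filtered.index, gene_sets, config.enrichment_p, config.min_overlap
        )
        enriched.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    summary_all = {"stages": summary, "sex_classification": strat_summary, "seed": config.seed}
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary_all, fh, indent=2)
    config.to_yaml(outdir / "config.yaml")
    return outdir
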