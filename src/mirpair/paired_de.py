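"""Per-gene paired differential expression.

Each gene's counts are modelled with a negative-binomial mixed model: a
tumor-status fixed effect, a random intercept per subject (the paired
tumor/normal samples share a baseline), and the log total protein-coding
expression of the sample as offset.  The tumor coefficient is the log fold
change; genes are classified up-regulated at fold change >= 1.50 and
down-regulated at <= 0.67, with Benjamini-Hochberg control of the false
discovery rate across the genes tested in a run.  Runs can be restricted to
the MSI or MSS stratum (complete pairs only).

Two fold changes are reported per gene: the model-based estimate
``exp(beta_tumor)`` (used for classification) and the plain ratio of
per-group mean RPMPCG values, which is what printed summary tables show.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohort import PairedCohort, check_paired, stratum_subjects
from .nbmm import NegativeBinomialMixedModel
from .normalization import rpmpcg

__all__ = ["DEFit", "DEResult", "fit_nb_mixed", "run_de", "classify_direction", "bh_fdr"]

logger = logging.getLogger(__name__)

FC_UP = 1.50
FC_DOWN = 0.67


@dataclass
class DEFit:
    """A single-gene negative-binomial mixed-model fit."""

    gene: str
    beta_tumor: float
    fold_change: float
    dispersion: float
    subject_sd: float
    raw_p: float
    converged: bool
    n_pairs: int
    estimable: bool = True  # False for degenerate (e.g. all-zero) genes


@dataclass
class DEResult:
    """Reportable per-gene differential-expression record."""

    gene: str
    tumor_mean: float
    normal_mean: float
    fold_change: float
    raw_p: float
    fdr_p: float
    direction: str
    stratum: str = "overall"
    ratio_of_means: float = np.nan
    beta_tumor: float = np.nan
    subject_sd: float = np.nan
    dispersion: float = np.nan
    converged: bool = True
    n_pairs: int = 0


def classify_direction(fold_change: float, fc_up: float = FC_UP,
                       fc_down: float = FC_DOWN) -> str:
    """``up`` iff FC >= 1.50, ``down`` iff FC <= 0.67, else ``neither``."""
    if not np.isfinite(fold_change) or fold_change <= 0:
        raise ValueError(f"fold change must be a positive real, got {fold_change}")
    if fold_change >= fc_up:
        return "up"
    if fold_change <= fc_down:
        return "down"
    return "neither"


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_nb_mixed(gene_counts, offsets, tissue_status, subject_ids,
                 gene: str = "", n_quad: int = 9, use_lrt: bool = False,
                 **fit_kws) -> DEFit:
    """Fit the paired NB mixed model for one gene.

    Parameters
    ----------
    gene_counts : array-like of nonnegative int, per sample
    offsets : array-like
        Per-sample log total protein-coding expression.
    tissue_status : array-like of {"tumor", "normal"} or {1, 0}
    subject_ids : array-like
        Pairing labels; each subject must contribute one tumor and one
        normal sample.
    use_lrt : bool
        Report a likelihood-ratio p-value for the tumor effect instead of
        the default Wald test.
    """
    y = np.asarray(gene_counts, dtype=float)
    status = np.asarray(tissue_status)
    if status.dtype.kind in "UO":
        tumor = (status == "tumor").astype(float)
    else:
        tumor = status.astype(float)
    subj = np.asarray(subject_ids)
    meta = pd.DataFrame({"sample_id": np.arange(y.size), "subject_id": subj,
                         "tissue_status": np.where(tumor == 1, "tumor", "normal")})
    check_paired(meta)
    n_pairs = np.unique(subj).size

    if not np.any(y > 0):
        return DEFit(gene=gene, beta_tumor=np.nan, fold_change=np.nan,
                     dispersion=np.nan, subject_sd=np.nan, raw_p=np.nan,
                     converged=False, n_pairs=n_pairs, estimable=False)

    X = np.column_stack([np.ones_like(y), tumor])
    model = NegativeBinomialMixedModel(y, X, subj, offset=np.asarray(offsets, float),
                                       exog_names=["intercept", "tumor"])
    res = model.fit(n_quad=n_quad, **fit_kws)
    if use_lrt:
        _, raw_p = res.lr_test(drop=1)
    else:
        raw_p = float(res.pvalues[1])
    beta = float(res.params[1])
    return DEFit(gene=gene, beta_tumor=beta, fold_change=float(np.exp(beta)),
                 dispersion=res.dispersion, subject_sd=res.sigma,
                 raw_p=raw_p, converged=res.converged, n_pairs=n_pairs)


def run_de(cohort: PairedCohort, gene_set, stratum: str = "overall",
           protein_coding_ids=None, pseudocount: float = 0.0,
           fc_up: float = FC_UP, fc_down: float = FC_DOWN,
           n_quad: int = 9, use_lrt: bool = False) -> list[DEResult]:
    """Paired differential expression for a gene set, one stratum at a time.

    Offsets are the log protein-coding totals; reported means are arithmetic
    means of RPMPCG values per tissue group.  BH adjustment runs across the
    genes tested here (non-converged fits are excluded from it and logged).

    Raises
    ------
    ValueError
        If ``gene_set`` contains unknown genes or the stratum has < 3
        complete pairs.
    """
    genes = list(gene_set)
    unknown = [g for g in genes if g not in cohort.gene_counts.index]
    if unknown:
        raise ValueError(f"genes absent from count matrix: {unknown[:5]}")
    if protein_coding_ids is None:
        protein_coding_ids = cohort.gene_counts.index
    subjects = set(stratum_subjects(cohort.metadata, stratum))
    if len(subjects) < 3:
        raise ValueError(f"stratum {stratum!r} has {len(subjects)} pairs; need >= 3")
    meta = cohort.metadata[cohort.metadata["subject_id"].isin(subjects)]
    samples = meta["sample_id"].tolist()
    counts = cohort.gene_counts[samples]

    norm = rpmpcg(counts, protein_coding_ids)
    offsets = np.log(norm.scale_factors.to_numpy())
    tumor_samples = meta.loc[meta["tissue_status"] == "tumor", "sample_id"]
    normal_samples = meta.loc[meta["tissue_status"] == "normal", "sample_id"]
    status = meta.set_index("sample_id").loc[samples, "tissue_status"].to_numpy()
    subj = meta.set_index("sample_id").loc[samples, "subject_id"].to_numpy()

    results: list[DEResult] = []
    for gene in genes:
        fit = fit_nb_mixed(counts.loc[gene].to_numpy(), offsets, status, subj,
                           gene=gene, n_quad=n_quad, use_lrt=use_lrt)
        tmean = float(norm.values.loc[gene, tumor_samples].mean())
        nmean = float(norm.values.loc[gene, normal_samples].mean())
        denom = nmean + pseudocount
        ratio = (tmean + pseudocount) / denom if denom > 0 else np.nan
        direction = ("neither" if not np.isfinite(fit.fold_change)
                     else classify_direction(fit.fold_change, fc_up, fc_down))
        results.append(DEResult(
            gene=gene, tumor_mean=tmean, normal_mean=nmean,
            fold_change=fit.fold_change, raw_p=fit.raw_p, fdr_p=np.nan,
            direction=direction, stratum=stratum, ratio_of_means=ratio,
            beta_tumor=fit.beta_tumor, subject_sd=fit.subject_sd,
            dispersion=fit.dispersion, converged=fit.converged,
            n_pairs=fit.n_pairs))

    ok = [r for r in results if r.converged and np.isfinite(r.raw_p)]
    excluded = len(results) - len(ok)
    if excluded:
        logger.warning("run_de(%s): %d gene fit(s) non-converged/degenerate, excluded from FDR",
                       stratum, excluded)
    if ok:
        adj = bh_fdr([r.raw_p for r in ok])
        for r, q in zip(ok, adj):
            r.fdr_p = float(q)
    return results


def de_table(results: list[DEResult]) -> pd.DataFrame:
    """Tabulate DE results, one row per gene."""
    return pd.DataFrame([{
        "gene": r.gene, "stratum": r.stratum, "tumor_mean": r.tumor_mean,
        "normal_mean": r.normal_mean, "fold_change": r.fold_change,
        "ratio_of_means": r.ratio_of_means, "raw_p": r.raw_p, "fdr_p": r.fdr_p,
        "direction": r.direction, "converged": r.converged,
        "n_pairs": r.n_pairs} for r in results])
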