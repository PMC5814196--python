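"""Subject-level miRNA::mRNA differential-profile association.

For each subject the *differential profile* is the tumor-minus-normal
expression difference (RPMPCG scale for genes, normalized array intensity
for miRNAs).  A gene's differential profile is regressed on a miRNA's
differential profile by ordinary least squares, adjusted for age and sex:

    gene_diff_s = b0 + b1 * mirna_diff_s + b2 * age_s + b3 * sex_s + e_s

The test statistic is the partial F for dropping the miRNA term.  Its null
distribution is built by residual-resampling bootstrap: residuals of the
covariates-only null model are resampled with replacement, added back to the
null fitted values, and the partial F recomputed; with B resamples the
p-value is (1 + #{F* >= F_obs}) / (B + 1), never exactly zero.

Multiplicity is controlled at the gene level: Benjamini-Hochberg across the
miRNAs tested for each gene (a global-BH option exists).  The significant
set additionally requires both fold changes to pass the 1.50 / 0.67
cutpoints, mirroring the exclusion of associations whose miRNA barely moves.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import pair_table
from .paired_de import FC_DOWN, FC_UP, bh_fdr

__all__ = [
    "DifferentialProfile",
    "AssociationResult",
    "differential_profile",
    "fit_association",
    "bootstrap_null_pvalue",
    "run_associations",
    "mirna_group_stats",
]

logger = logging.getLogger(__name__)


@dataclass
class DifferentialProfile:
    """Per-subject tumor-minus-normal expression, features x subjects."""

    values: pd.DataFrame
    scale: str = ""


@dataclass
class AssociationResult:
    """One gene::miRNA differential-profile regression record."""

    gene: str
    mirna: str
    beta: float
    f_stat: float
    raw_p: float
    fdr_p: float
    gene_fc: float
    mirna_fc: float
    mirna_tumor_mean: float = np.nan
    mirna_tumor_sd: float = np.nan
    mirna_normal_mean: float = np.nan
    mirna_normal_sd: float = np.nan
    significant: bool = False


def differential_profile(expr, metadata: pd.DataFrame, scale: str = "") -> DifferentialProfile:
    """Tumor-minus-normal difference per subject for every feature.

    ``expr`` may be a features x samples DataFrame or a ``NormalizedMatrix``.
    Raises a structural error naming the subject if a mate sample is missing.
    """
    values = expr.values if hasattr(expr, "method") else expr
    if not isinstance(values, pd.DataFrame):
        raise TypeError("expr must be a DataFrame or NormalizedMatrix")
    pairs = pair_table(metadata)
    for col in ("tumor_sample", "normal_sample"):
        missing = pairs.index[pairs[col].isna()].tolist()
        if missing:
            raise ValueError(f"subject(s) missing a {col}: {missing}")
    diff = (values[pairs["tumor_sample"]].to_numpy()
            - values[pairs["normal_sample"]].to_numpy())
    return DifferentialProfile(
        values=pd.DataFrame(diff, index=values.index, columns=pairs.index),
        scale=scale)


# ----------------------------------------------------------------------
def _design(mirna_diff, age, sex):
    n = len(age)
    X_full = np.column_stack([np.ones(n), np.asarray(mirna_diff, float),
                              np.asarray(age, float), np.asarray(sex, float)])
    X_null = X_full[:, [0, 2, 3]]
    return X_full, X_null


def _rss(Q: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares given an orthonormal basis Q of the design."""
    total = np.sum(y * y, axis=0)
    proj = Q.T @ y
    return total - np.sum(proj * proj, axis=0)


def _partial_f(y, Q_full, Q_null, df_resid):
    rss1 = _rss(Q_full, y)
    rss0 = _rss(Q_null, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (rss0 - rss1) / (rss1 / df_resid)
    # an essentially-zero residual (perfect fit up to roundoff) is infinite F
    return np.where(rss1 <= 1e-12 * np.maximum(rss0, np.finfo(float).tiny),
                    np.inf, f)


def fit_association(gene_diff, mirna_diff, age, sex) -> tuple[float, float]:
    """OLS of a gene differential on a miRNA differential with age/sex.

    Returns ``(beta, f_stat)`` where ``beta`` is the miRNA slope and
    ``f_stat`` the partial F (1 numerator df) for dropping the miRNA term.
    A perfect linear fit yields an infinite F.

    Raises
    ------
    ValueError
        With fewer than 5 subjects or a rank-deficient design (e.g. a
        constant miRNA differential).
    """
    y = np.asarray(gene_diff, dtype=float)
    if y.size < 5:
        raise ValueError(f"need at least 5 subjects, got {y.size}")
    X_full, X_null = _design(mirna_diff, age, sex)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design (constant miRNA differential or collinear covariates)")
    beta = np.linalg.lstsq(X_full, y, rcond=None)[0][1]
    Q_full = np.linalg.qr(X_full)[0]
    Q_null = np.linalg.qr(X_null)[0]
    df_resid = y.size - X_full.shape[1]
    f = float(_partial_f(y[:, None], Q_full, Q_null, df_resid)[0])
    return float(beta), f


def bootstrap_null_pvalue(gene_diff, mirna_diff, age, sex, B: int = 10000,
                          seed=None, rng: np.random.Generator | None = None) -> float:
    """Residual-resampling bootstrap p-value for the partial F statistic.

    Fits the covariates-only null model, draws B bootstrap responses by
    resampling its residuals with replacement onto its fitted values, and
    recomputes the partial F each time.  ``p = (1 + #{F* >= F_obs})/(B + 1)``.
    Deterministic for a given ``seed`` (or supplied generator).
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    y = np.asarray(gene_diff, dtype=float)
    _, f_obs = fit_association(y, mirna_diff, age, sex)
    X_full, X_null = _design(mirna_diff, age, sex)
    Q_full = np.linalg.qr(X_full)[0]
    Q_null = np.linalg.qr(X_null)[0]
    n = y.size
    df_resid = n - X_full.shape[1]
    fitted0 = Q_null @ (Q_null.T @ y)
    resid0 = y - fitted0
    if rng is None:
        rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(B, 4_000_000 // max(n, 1)))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, n, size=(n, b))
        ystar = fitted0[:, None] + resid0[idx]
        fstar = _partial_f(ystar, Q_full, Q_null, df_resid)
        exceed += int(np.sum(fstar >= f_obs))
        done += b
    return (1 + exceed) / (B + 1)


def mirna_group_stats(intensity: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Tumor/normal mean, SD and fold change per miRNA (normalized scale)."""
    pairs = pair_table(metadata)
    tum = intensity[pairs["tumor_sample"]]
    nor = intensity[pairs["normal_sample"]]
    out = pd.DataFrame({
        "tumor_mean": tum.mean(axis=1),
        "tumor_sd": tum.std(axis=1, ddof=1),
        "normal_mean": nor.mean(axis=1),
        "normal_sd": nor.std(axis=1, ddof=1),
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fold_change"] = out["tumor_mean"] / out["normal_mean"]
    return out


def run_associations(
    gene_diffs: DifferentialProfile,
    mirna_diffs: DifferentialProfile,
    candidate_genes: Sequence[str],
    candidate_mirnas: Sequence[str],
    metadata: pd.DataFrame,
    gene_fc: Mapping[str, float],
    mirna_intensity: pd.DataFrame,
    B: int = 10000,
    seed: int = 0,
    fdr_scope: str = "per_gene",
    fdr_alpha: float = 0.05,
    fc_up: float = FC_UP,
    fc_down: float = FC_DOWN,
) -> list[AssociationResult]:
    """Bootstrap-F association tests for every candidate gene x miRNA pair.

    Parameters
    ----------
    gene_fc : mapping
        Gene fold changes from the differential-expression stage (used for
        the significant-set cutpoint rule and reporting).
    mirna_intensity : DataFrame
        Normalized miRNA matrix (for group means/SDs/fold changes).
    fdr_scope : {"per_gene", "global"}
        BH within each gene across its miRNAs (default) or over all pairs.

    The ``significant`` flag requires ``fdr_p <= fdr_alpha`` *and* both fold
    changes outside the (fc_down, fc_up) band.
    """
    if fdr_scope not in ("per_gene", "global"):
        raise ValueError(f"unknown fdr_scope: {fdr_scope!r}")
    genes = [g for g in candidate_genes]
    mirnas = [m for m in candidate_mirnas]
    if not genes or not mirnas:
        logger.info("run_associations: empty candidate set; nothing to test")
        return []
    pairs = pair_table(metadata)
    subjects = gene_diffs.values.columns
    age = pairs.loc[subjects, "age"].to_numpy(float)
    sex = (pairs.loc[subjects, "sex"] == "M").to_numpy(float)
    stats = mirna_group_stats(mirna_intensity, metadata)

    results: list[AssociationResult] = []
    for gene in genes:
        y = gene_diffs.values.loc[gene].to_numpy(float)
        for mirna in mirnas:
            x = mirna_diffs.values.loc[mirna, subjects].to_numpy(float)
            beta, f = fit_association(y, x, age, sex)
            # per-pair generator keyed by the ids: each pair's p-value is
            # reproducible regardless of candidate ordering
            rng = np.random.default_rng(
                [seed, zlib.crc32(gene.encode()), zlib.crc32(mirna.encode())])
            p = bootstrap_null_pvalue(y, x, age, sex, B=B, rng=rng)
            st = stats.loc[mirna]
            results.append(AssociationResult(
                gene=gene, mirna=mirna, beta=beta, f_stat=f, raw_p=p,
                fdr_p=np.nan, gene_fc=float(gene_fc[gene]),
                mirna_fc=float(st["fold_change"]),
                mirna_tumor_mean=float(st["tumor_mean"]),
                mirna_tumor_sd=float(st["tumor_sd"]),
                mirna_normal_mean=float(st["normal_mean"]),
                mirna_normal_sd=float(st["normal_sd"])))

    if fdr_scope == "global":
        adj = bh_fdr([r.raw_p for r in results])
        for r, q in zip(results, adj):
            r.fdr_p = float(q)
    else:
        for gene in genes:
            rows = [r for r in results if r.gene == gene]
            adj = bh_fdr([r.raw_p for r in rows])
            for r, q in zip(rows, adj):
                r.fdr_p = float(q)

    def passes_fc(fc):
        return np.isfinite(fc) and (fc >= fc_up or fc <= fc_down)

    for r in results:
        r.significant = bool(r.fdr_p <= fdr_alpha and passes_fc(r.gene_fc)
                             and passes_fc(r.mirna_fc))
    return results


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabulate association records, one row per gene::miRNA pair."""
    return pd.DataFrame([{
        "gene": r.gene, "mirna": r.mirna,
        "mirna_tumor_mean": r.mirna_tumor_mean, "mirna_tumor_sd": r.mirna_tumor_sd,
        "mirna_normal_mean": r.mirna_normal_mean, "mirna_normal_sd": r.mirna_normal_sd,
        "gene_fc": r.gene_fc, "mirna_fc": r.mirna_fc, "beta": r.beta,
        "f_stat": r.f_stat, "raw_p": r.raw_p, "fdr_p": r.fdr_p,
        "significant": r.significant} for r in results])
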