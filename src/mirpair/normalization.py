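"""Expression normalization for the paired tumor/normal pipeline.

Two schemes are provided:

* **RPMPCG** (reads per million protein-coding genes) for RNA-Seq counts:
  every gene's count in a sample is divided by that sample's total count
  over the protein-coding gene set and multiplied by one million.  The
  protein-coding total is also the exposure used as the log-offset in the
  negative-binomial model, so the two stages share one denominator.

* **75th-percentile scaling** for miRNA array intensities: each sample is
  multiplied by (median of all samples' 75th percentiles) / (its own 75th
  percentile), equalizing the upper-quartile signal across arrays.

Percentiles use linear interpolation between order statistics (numpy's
default, the "type 7" convention); the convention is exposed as an argument
because array vendors differ on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["NormalizedMatrix", "rpmpcg", "q75_scale", "expression_filter"]


@dataclass
class NormalizedMatrix:
    """A features x samples matrix after normalization.

    Attributes
    ----------
    values : pandas.DataFrame
        Normalized expression, rows = features, columns = samples.
    method : str
        ``"rpmpcg"`` or ``"q75"``.
    scale_factors : pandas.Series
        Per-sample multipliers (``q75``) or the per-sample protein-coding
        totals used as denominators (``rpmpcg``).
    """

    values: pd.DataFrame
    method: str
    scale_factors: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def rpmpcg(counts: pd.DataFrame, protein_coding_ids: Iterable[str]) -> NormalizedMatrix:
    """Normalize a count matrix to reads per million protein-coding genes.

    ``value(g, s) = count(g, s) / sum_{g' in protein-coding} count(g', s) * 1e6``.

    Rows outside the protein-coding set are scaled by the same per-sample
    denominator, so the column sum over the protein-coding set is exactly
    one million.

    Parameters
    ----------
    counts : pandas.DataFrame
        Nonnegative counts, rows = genes, columns = samples.
    protein_coding_ids : iterable of str
        Gene ids defining the denominator; must be a subset of the rows.

    Raises
    ------
    ValueError
        If a protein-coding id is absent from the matrix, a count is
        negative, or a sample has zero protein-coding total (the offending
        sample is named).
    """
    pc = list(dict.fromkeys(protein_coding_ids))
    missing = [g for g in pc if g not in counts.index]
    if missing:
        raise ValueError(f"protein-coding ids absent from count matrix: {missing[:5]}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts are not allowed")
    totals = counts.loc[pc].sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"zero protein-coding total in sample(s): {zero}")
    values = counts.div(totals, axis=1) * 1e6
    return NormalizedMatrix(values=values, method="rpmpcg", scale_factors=totals.astype(float))


def q75_scale(intensity: pd.DataFrame, interpolation: str = "linear") -> NormalizedMatrix:
    """Scale each sample so its 75th percentile matches the cohort median P75.

    ``scale_factor(s) = median_over_samples(P75) / P75(s)`` and every value
    in column *s* is multiplied by it.  Applying the operation twice is the
    same as applying it once (all post-scaling P75s are equal).

    Raises
    ------
    ValueError
        If any sample's 75th percentile is not strictly positive.
    """
    if intensity.shape[0] == 0:
        return NormalizedMatrix(values=intensity.copy(), method="q75",
                                scale_factors=pd.Series(1.0, index=intensity.columns))
    p75 = pd.Series(
        np.percentile(intensity.to_numpy(float), 75, axis=0, method=interpolation),
        index=intensity.columns,
    )
    bad = p75.index[p75 <= 0].tolist()
    if bad:
        raise ValueError(f"nonpositive 75th percentile in sample(s): {bad}")
    factors = p75.median() / p75
    return NormalizedMatrix(values=intensity.mul(factors, axis=1), method="q75",
                            scale_factors=factors)


def expression_filter(
    normal_intensity: pd.DataFrame,
    min_frac_expressed: float = 0.20,
    detect_threshold: float = 0.0,
) -> list[str]:
    """Retain miRNAs detected in more than ``min_frac_expressed`` of normal samples.

    A miRNA is kept iff the fraction of normal-mucosa samples with intensity
    strictly above ``detect_threshold`` strictly exceeds ``min_frac_expressed``
    ("expressed in greater than 20%" is a strict inequality).  An empty
    matrix yields an empty list.
    """
    if not 0 <= min_frac_expressed <= 1:
        raise ValueError("min_frac_expressed must lie in [0, 1]")
    if normal_intensity.shape[1] == 0:
        return []
    frac = (normal_intensity > detect_threshold).mean(axis=1)
    return frac.index[frac > min_frac_expressed].tolist()
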