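"""Report rendering: cohort summary and association tables.

Printed tables round half-away-from-zero at render time only; all upstream
computation keeps full precision.  Fold-change cells in the association
table are the 2-decimal ratio of the printed tumor and normal means, so a
reader can reproduce every cell from its row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .cohort import check_paired

__all__ = ["round_half_away", "percentage", "fold_change_cell",
           "CohortSummary", "summarize_cohort", "report_association_table"]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """A count as a percentage of a total, rounded for display (e.g. 77.9)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_away(100.0 * count / total, ndigits)


def fold_change_cell(tumor_mean: float, normal_mean: float, ndigits: int = 2) -> float:
    """The fold-change cell implied by two printed group means."""
    if normal_mean <= 0:
        raise ValueError("normal mean must be positive")
    return round_half_away(tumor_mean / normal_mean, ndigits)


@dataclass
class CohortSummary:
    """Study-population description: counts, percentages and age."""

    n_subjects: int
    categories: dict = field(default_factory=dict)  # column -> {level: (n, pct)}
    age_mean: float = float("nan")
    age_sd: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for col, levels in self.categories.items():
            for level, (n, pct) in levels.items():
                rows.append({"variable": col, "level": level, "n": n, "percent": pct})
        rows.append({"variable": "age", "level": "mean (sd)",
                     "n": self.age_mean, "percent": self.age_sd})
        return pd.DataFrame(rows)


def summarize_cohort(metadata: pd.DataFrame) -> CohortSummary:
    """Per-category subject counts and percentages (1 decimal) plus age.

    Summarizes every categorical subject-level column present among
    ``site``, ``sex`` and ``msi_status``; percentages within a category sum
    to 100 up to rounding.
    """
    check_paired(metadata)
    subjects = metadata.drop_duplicates("subject_id")
    n = len(subjects)
    categories = {}
    for col in ("site", "sex", "msi_status"):
        if col not in subjects.columns:
            continue
        counts = subjects[col].value_counts()
        categories[col] = {level: (int(c), percentage(int(c), n))
                           for level, c in counts.items()}
    return CohortSummary(
        n_subjects=n,
        categories=categories,
        age_mean=round_half_away(float(subjects["age"].mean()), 1),
        age_sd=round_half_away(float(subjects["age"].std(ddof=1)), 1),
    )


def report_association_table(de_results, assoc_results, seed_records) -> pd.DataFrame:
    """Render the significant gene::miRNA associations as a printable table.

    One row per significant association, grouped by gene, with the gene's
    group means and 2-decimal fold change, the miRNA's means/SDs/FC, the
    regression slope, raw and FDR p-values, and a seed-match flag (the
    printed table's bold).  Raises if an association references a gene
    absent from the differential-expression results.
    """
    de_by_gene = {r.gene: r for r in de_results}
    significant = [a for a in assoc_results if a.significant]
    orphans = sorted({a.gene for a in significant} - set(de_by_gene))
    if orphans:
        raise ValueError(f"associations reference gene(s) missing from DE results: {orphans}")
    seed_pairs = {(s.gene, s.mirna) for s in seed_records}
    rows = []
    for a in sorted(significant, key=lambda a: (a.gene, a.mirna)):
        de = de_by_gene[a.gene]
        rows.append({
            "gene": a.gene,
            "gene_tumor_mean": round_half_away(de.tumor_mean, 2),
            "gene_normal_mean": round_half_away(de.normal_mean, 2),
            "gene_fc": fold_change_cell(de.tumor_mean, de.normal_mean),
            "mirna": a.mirna,
            "mirna_tumor_mean": round_half_away(a.mirna_tumor_mean, 2),
            "mirna_tumor_sd": round_half_away(a.mirna_tumor_sd, 2),
            "mirna_normal_mean": round_half_away(a.mirna_normal_mean, 2),
            "mirna_normal_sd": round_half_away(a.mirna_normal_sd, 2),
            "mirna_fc": fold_change_cell(a.mirna_tumor_mean, a.mirna_normal_mean),
            "beta": round_half_away(a.beta, 2),
            "raw_p": a.raw_p,
            "fdr_p": round_half_away(a.fdr_p, 4),
            "seed_match": (a.gene, a.mirna) in seed_pairs,
        })
    return pd.DataFrame(rows)
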