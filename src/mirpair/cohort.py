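"""The paired tumor/normal cohort container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["PairedCohort", "check_paired", "pair_table", "stratum_subjects"]

METADATA_COLUMNS = ["sample_id", "subject_id", "tissue_status", "age", "sex", "msi_status"]


@dataclass
class PairedCohort:
    """Expression matrices plus per-sample metadata for a paired design.

    Attributes
    ----------
    gene_counts : pandas.DataFrame
        Raw RNA-Seq counts, genes x samples (nonnegative integers).
    mirna_intensity : pandas.DataFrame
        miRNA array intensities, miRNAs x samples (nonnegative reals).
    metadata : pandas.DataFrame
        One row per sample with columns ``sample_id, subject_id,
        tissue_status (tumor|normal), age, sex (M|F), msi_status (MSI|MSS)``.
        Every subject contributes exactly one tumor and one normal sample,
        and age/sex/msi_status agree within a subject.
    mirna_sequences : dict
        miRNA id -> mature sequence, RNA alphabet, 5'->3'.
    utr_sequences : dict
        gene id -> 3'UTR sequence, DNA alphabet, 5'->3'.
    """

    gene_counts: pd.DataFrame
    mirna_intensity: pd.DataFrame
    metadata: pd.DataFrame
    mirna_sequences: dict = field(default_factory=dict)
    utr_sequences: dict = field(default_factory=dict)

    def validate(self) -> "PairedCohort":
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        check_paired(self.metadata)
        invariant = self.metadata.groupby("subject_id")[["age", "sex", "msi_status"]].nunique()
        bad = invariant.index[(invariant > 1).any(axis=1)].tolist()
        if bad:
            raise ValueError(f"tissue-invariant metadata differs within subject(s): {bad}")
        return self


def check_paired(metadata: pd.DataFrame) -> None:
    """Raise unless every subject has exactly one tumor and one normal sample."""
    counts = (metadata.groupby("subject_id")["tissue_status"]
              .value_counts().unstack(fill_value=0))
    for status in ("tumor", "normal"):
        if status not in counts.columns:
            counts[status] = 0
    bad = counts.index[(counts["tumor"] != 1) | (counts["normal"] != 1)].tolist()
    if bad:
        raise ValueError(f"subject(s) without exactly one tumor and one normal sample: {bad}")


def pair_table(metadata: pd.DataFrame) -> pd.DataFrame:
    """One row per subject with its tumor/normal sample ids and covariates."""
    check_paired(metadata)
    wide = metadata.pivot(index="subject_id", columns="tissue_status", values="sample_id")
    covs = metadata.drop_duplicates("subject_id").set_index("subject_id")[
        ["age", "sex", "msi_status"]]
    out = wide.join(covs).rename(columns={"tumor": "tumor_sample", "normal": "normal_sample"})
    return out.sort_index()


def stratum_subjects(metadata: pd.DataFrame, stratum: str) -> list:
    """Subjects belonging to a stratum (``overall``, ``MSI`` or ``MSS``)."""
    if stratum not in ("overall", "MSI", "MSS"):
        raise ValueError(f"unknown stratum: {stratum!r}")
    pairs = pair_table(metadata)
    if stratum == "overall":
        return pairs.index.tolist()
    return pairs.index[pairs["msi_status"] == stratum].tolist()
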