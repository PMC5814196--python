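"""Readers and writers for the pipeline's plain-text formats.

Matrices are TSV with a header row of sample ids and feature ids in the
first column; metadata is a TSV with one row per sample; sequences are
FASTA (miRNAs in RNA alphabet, 3'UTRs in DNA); gene lists are one id per
line.  All readers validate enough to fail loudly on malformed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .cohort import METADATA_COLUMNS, PairedCohort

__all__ = ["read_matrix", "read_fasta", "read_metadata", "read_gene_list",
           "read_cohort", "PipelineConfig"]


def read_matrix(path) -> pd.DataFrame:
    """Read a features x samples TSV matrix.

    Rejects duplicate feature ids, ragged rows and non-numeric cells with
    an error naming the offending line.  A header-only file yields a valid
    empty matrix.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        ncol = len(header.split("\t"))
        ids = []
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\r\n").split("\t")
            if len(parts) != ncol:
                raise ValueError(f"{path}:{lineno}: expected {ncol} columns, found {len(parts)}")
            ids.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate feature id(s): {dupes[:5]}")
    columns = header.split("\t")[1:]
    df = pd.DataFrame(rows, index=pd.Index(ids, name="feature_id"), columns=columns)
    return df


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into id -> uppercase sequence (id = first header token)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for {rec.id!r}")
        out[rec.id] = seq
    return out


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    return meta


def read_gene_list(path) -> list[str]:
    """One id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    dupes = pd.Index(out)[pd.Index(out).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate id(s): {dupes[:5]}")
    return out


def read_cohort(counts_path, intensity_path, metadata_path,
                mirna_fasta=None, utr_fasta=None) -> PairedCohort:
    """Assemble a validated PairedCohort from its on-disk parts."""
    return PairedCohort(
        gene_counts=read_matrix(counts_path),
        mirna_intensity=read_matrix(intensity_path),
        metadata=read_metadata(metadata_path),
        mirna_sequences=read_fasta(mirna_fasta) if mirna_fasta else {},
        utr_sequences=read_fasta(utr_fasta) if utr_fasta else {},
    ).validate()


@dataclass
class PipelineConfig:
    """Declarative configuration of a full pipeline run.

    The analysis thresholds default to the study's: fold-change cutpoints
    1.50 / 0.67, FDR 0.05, miRNA expressed in > 20% of normal samples,
    10,000 bootstrap resamples.
    """

    counts: str = ""
    intensities: str = ""
    metadata: str = ""
    pathway_genes: str = ""
    protein_coding: str = ""  # empty -> all genes protein-coding
    mirna_fasta: str = ""
    utr_fasta: str = ""
    outdir: str = "results"
    fc_up: float = 1.50
    fc_down: float = 0.67
    fdr_alpha: float = 0.05
    mirna_expr_frac: float = 0.20
    detect_threshold: float = 0.0
    bootstrap_B: int = 10000
    seed: int = 0
    strata: list = dc_field(default_factory=lambda: ["overall"])
    simulate: dict | None = None  # SimConfig overrides; triggers generation

    def validate(self) -> "PipelineConfig":
        if not (0 < self.fc_down < 1 < self.fc_up):
            raise ValueError("need 0 < fc_down < 1 < fc_up")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        bad = [s for s in self.strata if s not in ("overall", "MSI", "MSS")]
        if bad:
            raise ValueError(f"unknown strata: {bad}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config field(s): {sorted(unknown)}")
        return cls(**data).validate()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
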