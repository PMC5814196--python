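"""Synthetic paired tumor/normal cohort generator.

Generates RNA-Seq-like gene counts, array-like miRNA intensities, sample
metadata and sequences with the statistical structure the pipeline assumes,
together with the planted ground truth needed for recovery testing:

* counts: NB2 with mean ``L_s * u_subj * m_g * FC_g^tumor`` — per-sample
  library size ``L_s``, a log-normal subject intercept ``u_subj`` shared by
  a subject's two samples, baseline relative abundance ``m_g`` and a planted
  tumor fold change for a random subset of genes;
* miRNA intensities: log-normal around a per-miRNA baseline with planted
  tumor fold changes and multiplicative noise;
* couplings: for chosen (gene, miRNA) pairs, the subject's tumor-minus-
  normal mRNA differential (RPMPCG scale) is shifted by ``b`` times that
  subject's miRNA intensity differential, implemented by adding the
  corresponding counts to the tumor sample — exactly the scale and slope
  the association stage regresses;
* sequences: i.i.d. uniform random 3'UTRs (DNA) and mature miRNAs (RNA);
  for a fraction of couplings a seed-site reverse complement is written
  into the gene's UTR at a recorded offset.

All randomness flows through one ``numpy`` generator seeded by
``SimConfig.seed``; the draw order is fixed, so outputs are byte-identical
across runs with the same config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cohort import PairedCohort
from .seed_match import SEED_START, reverse_complement_dna

__all__ = ["SimConfig", "SimTruth", "PairedCohort", "default_config",
           "generate_cohort", "write_cohort", "write_truth", "read_truth"]


class ConfigurationError(ValueError):
    """A SimConfig field violates its constraints."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    The defaults emulate the study design scale — 217 tumor/normal pairs,
    13.4% MSI, age 64.8 (SD 10.1) years — with gene and miRNA panel sizes
    reduced to desk scale.  ``nb_dispersion`` is the NB2 size ``k``
    (variance ``mu + mu^2/k``); ``subject_effect_sd`` is the SD of the
    log-scale subject intercept.
    """

    n_subjects: int = 217
    n_genes: int = 600
    n_pathway_genes: int = 40
    n_mirnas: int = 80
    frac_genes_dysregulated: float = 0.3
    fc_up_range: tuple[float, float] = (1.5, 4.0)
    fc_down_range: tuple[float, float] = (0.25, 0.67)
    nb_dispersion: float = 5.0
    subject_effect_sd: float = 0.4
    library_size_range: tuple[float, float] = (2e6, 6e6)
    mirna_noise_sd: float = 0.4
    n_couplings: int = 10
    coupling_effect_range: tuple[float, float] = (0.2, 0.4)
    frac_seed_planted: float = 0.5
    msi_fraction: float = 0.134
    age_mean_sd: tuple[float, float] = (64.8, 10.1)
    seed: int = 0
    utr_length: int = 1000
    mirna_length: int = 22

    def validate(self) -> "SimConfig":
        for name in ("n_subjects", "n_genes", "n_pathway_genes", "n_mirnas",
                     "utr_length", "mirna_length"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_couplings < 0:
            raise ConfigurationError("n_couplings must be >= 0")
        for name in ("frac_genes_dysregulated", "frac_seed_planted", "msi_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("nb_dispersion", "subject_effect_sd", "mirna_noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        lo, hi = self.fc_up_range
        if not (1 < lo <= hi):
            raise ConfigurationError("fc_up_range must be an interval of fold changes > 1")
        lo, hi = self.fc_down_range
        if not (0 < lo <= hi < 1):
            raise ConfigurationError("fc_down_range must be an interval within (0, 1)")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("library_size_range must be positive")
        if self.n_pathway_genes > self.n_genes:
            raise ConfigurationError("n_pathway_genes must be <= n_genes")
        if self.n_couplings > self.n_pathway_genes * self.n_mirnas:
            raise ConfigurationError("n_couplings must be <= n_pathway_genes * n_mirnas")
        if self.mirna_length < SEED_START + 8:
            raise ConfigurationError(f"mirna_length must be >= {SEED_START + 8} for seed extraction")
        return self


@dataclass
class SimTruth:
    """Planted parameters: what a perfect analysis should recover."""

    true_fc_by_gene: dict = field(default_factory=dict)
    true_fc_by_mirna: dict = field(default_factory=dict)
    # (gene, mirna, standardized effect, raw RPMPCG-per-intensity slope)
    couplings: list = field(default_factory=list)
    planted_sites: list = field(default_factory=list)  # (mirna, gene, seed_length, utr_position)
    pathway_genes: list = field(default_factory=list)


def default_config(**overrides) -> SimConfig:
    """The study-scale default configuration (overridable field by field)."""
    return SimConfig(**overrides).validate()


def _random_seq(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), size=length)])


def generate_cohort(config: SimConfig) -> tuple[PairedCohort, SimTruth]:
    """Draw a paired cohort and its ground truth from the generative model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g, m = config.n_subjects, config.n_genes, config.n_mirnas
    subjects = [f"subj{i:04d}" for i in range(n)]
    genes = [f"gene{i:05d}" for i in range(g)]
    mirnas = [f"mir{i:04d}" for i in range(m)]
    pathway_genes = genes[:config.n_pathway_genes]

    # 1. metadata ------------------------------------------------------
    age = np.round(rng.normal(*config.age_mean_sd, size=n), 1)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    msi = np.where(rng.random(n) < config.msi_fraction, "MSI", "MSS")
    rows = []
    tumor_ids, normal_ids = [], []
    for i, s in enumerate(subjects):
        for status in ("tumor", "normal"):
            sid = f"{s}_{'T' if status == 'tumor' else 'N'}"
            (tumor_ids if status == "tumor" else normal_ids).append(sid)
            rows.append({"sample_id": sid, "subject_id": s, "tissue_status": status,
                         "age": age[i], "sex": sex[i], "msi_status": msi[i]})
    metadata = pd.DataFrame(rows)
    samples = metadata["sample_id"].tolist()
    is_tumor = (metadata["tissue_status"] == "tumor").to_numpy()
    subj_idx = np.repeat(np.arange(n), 2)

    # 2-5. library sizes, subject intercepts, baselines, fold changes --
    lib = rng.uniform(*config.library_size_range, size=2 * n)
    u = np.exp(rng.normal(0.0, config.subject_effect_sd, size=n))[subj_idx]
    base = rng.lognormal(mean=0.0, sigma=1.2, size=g)
    base /= base.sum()
    dys = rng.random(g) < config.frac_genes_dysregulated
    up = rng.random(g) < 0.5
    fc = np.ones(g)
    fc[dys & up] = rng.uniform(*config.fc_up_range, size=int((dys & up).sum()))
    fc[dys & ~up] = rng.uniform(*config.fc_down_range, size=int((dys & ~up).sum()))

    # 6. counts --------------------------------------------------------
    mu = (base[:, None] * np.where(is_tumor, fc[:, None], 1.0)
          * (lib * u)[None, :])
    k = config.nb_dispersion
    counts = rng.negative_binomial(k, k / (k + mu)).astype(np.int64)

    # 7. miRNA intensities --------------------------------------------
    mbase = rng.lognormal(mean=2.0, sigma=1.5, size=m)
    mdys = rng.random(m) < config.frac_genes_dysregulated
    mup = rng.random(m) < 0.5
    mfc = np.ones(m)
    mfc[mdys & mup] = rng.uniform(*config.fc_up_range, size=int((mdys & mup).sum()))
    mfc[mdys & ~mup] = rng.uniform(*config.fc_down_range, size=int((mdys & ~mup).sum()))
    noise = np.exp(rng.normal(0.0, config.mirna_noise_sd, size=(m, 2 * n)))
    intensity = mbase[:, None] * np.where(is_tumor, mfc[:, None], 1.0) * noise

    # 8. couplings -----------------------------------------------------
    # preferentially couple dysregulated pathway genes with dysregulated
    # miRNAs so planted pairs can pass the downstream fold-change cutpoints
    path_dys = [i for i, gn in enumerate(genes[:config.n_pathway_genes]) if dys[i]]
    gene_pool = path_dys if len(path_dys) >= 1 else list(range(config.n_pathway_genes))
    mir_pool = [j for j in range(m) if mdys[j]] or list(range(m))
    all_pairs = [(gi, mj) for gi in gene_pool for mj in mir_pool]
    if config.n_couplings > len(all_pairs):
        all_pairs = [(gi, mj) for gi in range(config.n_pathway_genes) for mj in range(m)]
    chosen = rng.choice(len(all_pairs), size=config.n_couplings, replace=False)
    couplings = []
    tumor_cols = np.flatnonzero(is_tumor)
    normal_cols = np.flatnonzero(~is_tumor)
    pc_tot = counts.sum(axis=0).astype(float)
    # a coupling's strength is a *standardized* effect b: the raw RPMPCG-
    # per-intensity slope is b * s_gene / s_mirna, where s_gene is the
    # generative NB noise SD of the gene's RPMPCG differential and s_mirna
    # the SD of the miRNA's intensity differential — so power depends on b
    # and the pair count, not on the features' arbitrary abundance scales
    lbar = float(np.mean(config.library_size_range))
    sig2 = config.mirna_noise_sd ** 2
    for c in chosen:
        gi, mj = all_pairs[int(c)]
        b = float(rng.uniform(*config.coupling_effect_range))
        rpm_t, rpm_n = base[gi] * fc[gi] * 1e6, base[gi] * 1e6
        s_gene = np.sqrt((rpm_t + rpm_n) * 1e6 / lbar
                         + (rpm_t ** 2 + rpm_n ** 2) / k)
        s_mir = mbase[mj] * np.sqrt((mfc[mj] ** 2 + 1)
                                    * np.exp(sig2) * (np.exp(sig2) - 1))
        slope = b * s_gene / s_mir
        d = intensity[mj, tumor_cols] - intensity[mj, normal_cols]  # per subject
        # center the miRNA differential before injecting: the regression
        # slope is invariant to centering x, while the gene's mean tumor
        # expression (hence its planted fold change) stays untouched
        delta = np.rint(slope * (d - d.mean()) * pc_tot[tumor_cols] / 1e6).astype(np.int64)
        counts[gi, tumor_cols] = np.maximum(counts[gi, tumor_cols] + delta, 0)
        couplings.append((genes[gi], mirnas[mj], b, slope))

    # 9. sequences -----------------------------------------------------
    mirna_sequences = {mi: _random_seq(rng, "ACGU", config.mirna_length) for mi in mirnas}
    utr_sequences = {gn: _random_seq(rng, "ACGT", config.utr_length) for gn in genes}

    # 10. planted seed sites ------------------------------------------
    n_plant = int(round(config.frac_seed_planted * len(couplings)))
    planted_sites = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for gene_id, mirna_id, *_ in couplings[:n_plant]:
        length = int(rng.choice([6, 7, 8]))
        seed = mirna_sequences[mirna_id][SEED_START:SEED_START + length]
        site = reverse_complement_dna(seed)
        used = occupied.setdefault(gene_id, [])
        pos = None
        for _ in range(200):
            p = int(rng.integers(0, config.utr_length - length + 1))
            if all(p + length <= a or p >= b for a, b in used):
                pos = p
                break
        if pos is None:
            continue  # UTR too crowded; skip rather than overlap
        s = utr_sequences[gene_id]
        utr_sequences[gene_id] = s[:pos] + site + s[pos + length:]
        used.append((pos, pos + length))
        planted_sites.append((mirna_id, gene_id, length, pos))

    cohort = PairedCohort(
        gene_counts=pd.DataFrame(counts, index=genes, columns=samples),
        mirna_intensity=pd.DataFrame(intensity, index=mirnas, columns=samples),
        metadata=metadata,
        mirna_sequences=mirna_sequences,
        utr_sequences=utr_sequences,
    ).validate()
    truth = SimTruth(
        true_fc_by_gene={gn: float(f) for gn, f in zip(genes, fc)},
        true_fc_by_mirna={mi: float(f) for mi, f in zip(mirnas, mfc)},
        couplings=couplings,
        planted_sites=planted_sites,
        pathway_genes=pathway_genes,
    )
    return cohort, truth


# ----------------------------------------------------------------------
def write_cohort(cohort: PairedCohort, directory) -> dict[str, Path]:
    """Write the cohort as TSV matrices, a metadata TSV and two FASTAs.

    Round-trips losslessly through :func:`mirpair.io.read_matrix`,
    :func:`mirpair.io.read_metadata` and :func:`mirpair.io.read_fasta`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "gene_counts": directory / "gene_counts.tsv",
        "mirna_intensity": directory / "mirna_intensity.tsv",
        "metadata": directory / "metadata.tsv",
        "mirna_fasta": directory / "mirna.fasta",
        "utr_fasta": directory / "utr.fasta",
    }
    cohort.gene_counts.rename_axis("feature_id").to_csv(manifest["gene_counts"], sep="\t")
    cohort.mirna_intensity.rename_axis("feature_id").to_csv(
        manifest["mirna_intensity"], sep="\t", float_format="%.10g")
    cohort.metadata.to_csv(manifest["metadata"], sep="\t", index=False)
    SeqIO.write((SeqRecord(Seq(s), id=i, description="") for i, s in
                 cohort.mirna_sequences.items()), manifest["mirna_fasta"], "fasta")
    SeqIO.write((SeqRecord(Seq(s), id=i, description="") for i, s in
                 cohort.utr_sequences.items()), manifest["utr_fasta"], "fasta")
    return manifest


def write_truth(truth: SimTruth, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(asdict(truth), indent=1, sort_keys=True))
    return path


def read_truth(path) -> SimTruth:
    data = json.loads(Path(path).read_text())
    data["couplings"] = [tuple(c) for c in data["couplings"]]
    data["planted_sites"] = [tuple(s) for s in data["planted_sites"]]
    return SimTruth(**data)
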