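"""End-to-end orchestration: simulate -> normalize -> DE -> associate -> seed-match -> report.

Each stage logs its input/output counts so Results-style sentences (genes
passing cutpoints, miRNAs passing the expression filter, significant
associations, seed matches) can be reconstructed from the log.  The whole
chain is deterministic under the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .association import (association_table, differential_profile,
                          run_associations)
from .cohort import PairedCohort
from .io import PipelineConfig, read_cohort, read_gene_list
from .normalization import expression_filter, q75_scale, rpmpcg
from .paired_de import de_table, run_de
from .report import report_association_table, summarize_cohort
from .seed_match import annotate_associations

logger = logging.getLogger(__name__)

__all__ = ["run_all", "load_or_simulate"]


def load_or_simulate(config: PipelineConfig, outdir: Path) -> tuple[PairedCohort, list[str], list[str]]:
    """Load the configured input files, or generate a synthetic cohort.

    Returns (cohort, pathway_genes, protein_coding_genes).
    """
    if config.simulate is not None:
        sim = synthetic.default_config(**{**config.simulate, "seed": config.seed})
        cohort, truth = synthetic.generate_cohort(sim)
        manifest = synthetic.write_cohort(cohort, outdir / "simulated")
        synthetic.write_truth(truth, outdir / "simulated" / "truth.json")
        logger.info("simulated cohort: %d pairs, %d genes, %d miRNAs",
                    sim.n_subjects, sim.n_genes, sim.n_mirnas)
        pathway = truth.pathway_genes
        protein_coding = list(cohort.gene_counts.index)
        (outdir / "simulated" / "pathway_genes.txt").write_text(
            "\n".join(pathway) + "\n")
        return cohort, pathway, protein_coding
    for fieldname in ("counts", "intensities", "metadata", "pathway_genes"):
        if not getattr(config, fieldname):
            raise ValueError(f"config field {fieldname!r} is required when not simulating")
    cohort = read_cohort(config.counts, config.intensities, config.metadata,
                         config.mirna_fasta or None, config.utr_fasta or None)
    pathway = read_gene_list(config.pathway_genes)
    protein_coding = (read_gene_list(config.protein_coding)
                      if config.protein_coding else list(cohort.gene_counts.index))
    return cohort, pathway, protein_coding


_STAGE_ORDER = ("normalize", "de", "associate", "seedmatch", "report")


def run_all(config: PipelineConfig, until: str = "report") -> dict:
    """Run the chain up to ``until`` (default: everything).

    Returns a manifest of outputs and stage counts.
    """
    if until not in _STAGE_ORDER:
        raise ValueError(f"unknown stage {until!r}")
    stop = _STAGE_ORDER.index(until)
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"config": {k: v for k, v in vars(config).items()},
                      "stages": {}}

    cohort, pathway, protein_coding = load_or_simulate(config, outdir)

    # --- normalization -------------------------------------------------
    norm_genes = rpmpcg(cohort.gene_counts, protein_coding)
    norm_mirna = q75_scale(cohort.mirna_intensity)
    normal_samples = cohort.metadata.loc[
        cohort.metadata["tissue_status"] == "normal", "sample_id"]
    expressed = expression_filter(norm_mirna.values[normal_samples],
                                  config.mirna_expr_frac, config.detect_threshold)
    manifest["stages"]["normalization"] = {
        "n_mirnas_total": int(cohort.mirna_intensity.shape[0]),
        "n_mirnas_expressed": len(expressed)}
    logger.info("expression filter: %d of %d miRNAs retained",
                len(expressed), cohort.mirna_intensity.shape[0])
    norm_genes.values.rename_axis("feature_id").to_csv(
        outdir / "rpmpcg.tsv", sep="\t", float_format="%.10g")
    norm_mirna.values.rename_axis("feature_id").to_csv(
        outdir / "mirna_normalized.tsv", sep="\t", float_format="%.10g")
    if stop < 1:
        return _finish(manifest, config, outdir, t0)

    # --- differential expression --------------------------------------
    de_all = []
    for stratum in config.strata:
        res = run_de(cohort, pathway, stratum=stratum,
                     protein_coding_ids=protein_coding,
                     fc_up=config.fc_up, fc_down=config.fc_down)
        de_all.extend(res)
        n_up = sum(r.direction == "up" and r.fdr_p <= config.fdr_alpha for r in res)
        n_down = sum(r.direction == "down" and r.fdr_p <= config.fdr_alpha for r in res)
        manifest["stages"][f"de_{stratum}"] = {"n_genes": len(res),
                                               "n_up": n_up, "n_down": n_down}
        logger.info("DE %s: %d genes tested, %d up / %d down at FDR %.2f",
                    stratum, len(res), n_up, n_down, config.fdr_alpha)
    de_path = outdir / "differential_expression.tsv"
    de_table(de_all).to_csv(de_path, sep="\t", index=False, float_format="%.6g")

    # candidate genes: dysregulated (direction != neither, FDR pass) in any stratum
    candidates = sorted({r.gene for r in de_all
                         if r.direction != "neither"
                         and np.isfinite(r.fdr_p) and r.fdr_p <= config.fdr_alpha})
    manifest["stages"]["candidates"] = {"n_candidate_genes": len(candidates)}
    logger.info("candidate dysregulated pathway genes (union over strata): %d",
                len(candidates))
    if stop < 2:
        return _finish(manifest, config, outdir, t0)

    # --- association ---------------------------------------------------
    overall_de = [r for r in de_all if r.stratum == "overall"]
    gene_fc = {r.gene: r.fold_change for r in overall_de}
    gene_diffs = differential_profile(norm_genes, cohort.metadata, scale="RPMPCG")
    mirna_diffs = differential_profile(norm_mirna, cohort.metadata,
                                       scale="normalized intensity")
    assoc = run_associations(
        gene_diffs, mirna_diffs, candidates, expressed, cohort.metadata,
        gene_fc=gene_fc, mirna_intensity=norm_mirna.values,
        B=config.bootstrap_B, seed=config.seed, fdr_alpha=config.fdr_alpha,
        fc_up=config.fc_up, fc_down=config.fc_down)
    n_sig = sum(a.significant for a in assoc)
    manifest["stages"]["association"] = {"n_pairs_tested": len(assoc),
                                         "n_significant": n_sig}
    logger.info("associations: %d pairs tested, %d significant", len(assoc), n_sig)
    assoc_path = outdir / "associations.tsv"
    association_table(assoc).to_csv(assoc_path, sep="\t", index=False,
                                    float_format="%.6g")
    if stop < 3:
        return _finish(manifest, config, outdir, t0)

    # --- seed matching -------------------------------------------------
    significant = [a for a in assoc if a.significant]
    seeds = annotate_associations(significant, cohort.mirna_sequences,
                                  cohort.utr_sequences)
    matched_pairs = {(s.gene, s.mirna) for s in seeds}
    n_inverse = len({(s.gene, s.mirna) for s in seeds
                     if s.direction_class == "inverse"})
    manifest["stages"]["seed_match"] = {
        "n_significant_associations": len(significant),
        "n_pairs_with_seed_match": len(matched_pairs),
        "n_inverse_seed_matches": n_inverse}
    logger.info("seed matches: %d of %d significant pairs (%d inverse)",
                len(matched_pairs), len(significant), n_inverse)
    seeds_path = outdir / "seed_matches.tsv"
    pd.DataFrame([{
        "mirna": s.mirna, "gene": s.gene, "seed_length": s.seed_length,
        "seed": s.seed_sequence, "n_sites": len(s.site_positions),
        "positions": ",".join(map(str, s.site_positions)),
        "direction_class": s.direction_class,
        "direct_candidate": s.direct_candidate} for s in seeds]).to_csv(
        seeds_path, sep="\t", index=False)
    if stop < 4:
        return _finish(manifest, config, outdir, t0)

    # --- reports -------------------------------------------------------
    summary = summarize_cohort(cohort.metadata)
    summary_path = outdir / "cohort_summary.tsv"
    summary.to_frame().to_csv(summary_path, sep="\t", index=False)
    table_path = outdir / "association_report.tsv"
    report_association_table(overall_de, assoc, seeds).to_csv(
        table_path, sep="\t", index=False)

    manifest["outputs"] = {
        "differential_expression": str(de_path),
        "associations": str(assoc_path),
        "seed_matches": str(seeds_path),
        "cohort_summary": str(summary_path),
        "association_report": str(table_path)}
    return _finish(manifest, config, outdir, t0)


def _finish(manifest: dict, config: PipelineConfig, outdir: Path, t0: float) -> dict:
    manifest["seed"] = config.seed
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1,
                                                         sort_keys=True))
    return manifest
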