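import numpy as np
import pandas as pd
import pytest

from mirpair.cohort import PairedCohort
from mirpair.io import read_fasta, read_matrix, read_metadata
from mirpair.normalization import rpmpcg
from mirpair.seed_match import match_seed_to_utr, reverse_complement_dna
from mirpair.synthetic import (ConfigurationError, default_config,
                               generate_cohort, read_truth, write_cohort,
                               write_truth)


class TestSimConfig:
    def test_default_emulates_study_design(self):
        cfg = default_config()
        assert cfg.n_subjects == 217
        assert cfg.msi_fraction == pytest.approx(0.134)
        assert cfg.age_mean_sd == pytest.approx((64.8, 10.1))
        cfg.validate()  # self-consistent

    @pytest.mark.parametrize("field, value", [
        ("n_genes", 0), ("frac_genes_dysregulated", 1.5), ("nb_dispersion", -1),
        ("fc_up_range", (0.5, 2.0)), ("fc_down_range", (0.2, 1.2)),
        ("msi_fraction", -0.1), ("subject_effect_sd", 0.0),
    ])
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            default_config(**{field: value})

    def test_too_many_pathway_genes_rejected(self):
        with pytest.raises(ConfigurationError, match="n_pathway_genes"):
            default_config(n_genes=10, n_pathway_genes=11)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        cfg = default_config(n_subjects=10, n_genes=30, n_pathway_genes=5,
                             n_mirnas=8, n_couplings=2, seed=9)
        c1, t1 = generate_cohort(cfg)
        c2, t2 = generate_cohort(cfg)
        assert c1.gene_counts.equals(c2.gene_counts)
        assert c1.mirna_intensity.equals(c2.mirna_intensity)
        assert c1.metadata.equals(c2.metadata)
        assert c1.utr_sequences == c2.utr_sequences
        assert t1.couplings == t2.couplings

    def test_no_dysregulation_means_unit_fold_changes(self):
        cfg = default_config(n_subjects=8, n_genes=20, n_pathway_genes=4,
                             n_mirnas=6, n_couplings=0,
                             frac_genes_dysregulated=0.0, seed=1)
        _, truth = generate_cohort(cfg)
        assert all(fc == 1.0 for fc in truth.true_fc_by_gene.values())

    def test_paired_structure_invariant(self, small_cohort):
        cohort, _ = small_cohort
        counts = (cohort.metadata.groupby("subject_id")["tissue_status"]
                  .value_counts().unstack())
        assert (counts["tumor"] == 1).all() and (counts["normal"] == 1).all()
        assert set(cohort.gene_counts.columns) == set(cohort.metadata.sample_id)

    def test_sequences_use_their_alphabets(self, small_cohort):
        cohort, _ = small_cohort
        assert all(set(s) <= set("ACGU") for s in cohort.mirna_sequences.values())
        assert all(set(s) <= set("ACGT") for s in cohort.utr_sequences.values())

    def test_generative_mean_recovers_planted_fold_change(self):
        # dysregulated genes planted at FC exactly 2 or 0.5; with 200 pairs
        # the tumor/normal mean RPMPCG ratio should sit within 10% of truth
        # for well-expressed genes.  The dysregulated fraction is kept small
        # so the normalization denominator stays comparable between tissues
        # (a large composition shift compresses every measured fold change).
        cfg = default_config(n_subjects=200, n_genes=60, n_pathway_genes=5,
                             n_mirnas=5, n_couplings=0,
                             frac_genes_dysregulated=0.1,
                             fc_up_range=(2.0, 2.0), fc_down_range=(0.5, 0.5),
                             seed=77)
        cohort, truth = generate_cohort(cfg)
        norm = rpmpcg(cohort.gene_counts, cohort.gene_counts.index).values
        meta = cohort.metadata
        tum = meta.loc[meta.tissue_status == "tumor", "sample_id"]
        nor = meta.loc[meta.tissue_status == "normal", "sample_id"]
        ratio = norm[tum].mean(axis=1) / norm[nor].mean(axis=1)
        checked = 0
        for gene, fc in truth.true_fc_by_gene.items():
            if fc != 1.0 and norm.loc[gene, nor].mean() > 100:
                assert ratio[gene] == pytest.approx(fc, rel=0.10)
                checked += 1
        assert checked >= 2

    def test_planted_sites_discoverable_by_matcher(self, small_cohort):
        cohort, truth = small_cohort
        assert truth.planted_sites, "generator should plant seed sites"
        for mirna, gene, length, pos in truth.planted_sites:
            seed = cohort.mirna_sequences[mirna][1:1 + length]
            hits = match_seed_to_utr(seed, cohort.utr_sequences[gene])
            assert pos in hits
            rc = reverse_complement_dna(seed)
            assert cohort.utr_sequences[gene][pos:pos + length] == rc

    def test_coupling_effects_within_configured_range(self, small_cohort):
        _, truth = small_cohort
        cfg = default_config()
        lo, hi = cfg.coupling_effect_range
        for _, _, b, slope in truth.couplings:
            assert lo <= b <= hi
            assert np.sign(slope) == np.sign(b)


class TestWriteCohort:
    def test_round_trip(self, small_cohort, tmp_path):
        cohort, truth = small_cohort
        manifest = write_cohort(cohort, tmp_path)
        counts = read_matrix(manifest["gene_counts"])
        intensity = read_matrix(manifest["mirna_intensity"])
        meta = read_metadata(manifest["metadata"])
        assert np.array_equal(counts.to_numpy(), cohort.gene_counts.to_numpy())
        assert np.allclose(intensity.to_numpy(), cohort.mirna_intensity.to_numpy(),
                           rtol=1e-9)
        assert meta[["sample_id", "subject_id", "tissue_status"]].equals(
            cohort.metadata[["sample_id", "subject_id", "tissue_status"]])
        assert read_fasta(manifest["mirna_fasta"]) == cohort.mirna_sequences
        assert read_fasta(manifest["utr_fasta"]) == cohort.utr_sequences

    def test_truth_round_trip(self, small_cohort, tmp_path):
        _, truth = small_cohort
        path = write_truth(truth, tmp_path / "truth.json")
        back = read_truth(path)
        assert back.true_fc_by_gene == truth.true_fc_by_gene
        assert [tuple(c) for c in back.couplings] == [tuple(c) for c in truth.couplings]
        assert back.planted_sites == truth.planted_sites

    def test_empty_cohort_written_without_crash(self, tmp_path):
        empty = PairedCohort(
            gene_counts=pd.DataFrame(index=pd.Index([], name="feature_id"),
                                     columns=["s1T", "s1N"], dtype=int),
            mirna_intensity=pd.DataFrame(index=pd.Index([], name="feature_id"),
                                         columns=["s1T", "s1N"], dtype=float),
            metadata=pd.DataFrame([
                {"sample_id": "s1T", "subject_id": "s1", "tissue_status": "tumor",
                 "age": 60.0, "sex": "F", "msi_status": "MSS"},
                {"sample_id": "s1N", "subject_id": "s1", "tissue_status": "normal",
                 "age": 60.0, "sex": "F", "msi_status": "MSS"}]))
        manifest = write_cohort(empty, tmp_path)
        counts = read_matrix(manifest["gene_counts"])
        assert counts.shape == (0, 2)
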