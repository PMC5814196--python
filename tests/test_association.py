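import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mirpair.association import (DifferentialProfile, association_table,
                                 bootstrap_null_pvalue, differential_profile,
                                 fit_association, run_associations)


def _covariates(n, rng):
    return rng.uniform(40, 85, n), rng.integers(0, 2, n).astype(float)


class TestDifferentialProfile:
    def test_tumor_equals_normal_gives_zero(self, paired_metadata):
        samples = paired_metadata["sample_id"]
        expr = pd.DataFrame(np.ones((3, len(samples))),
                            index=["f1", "f2", "f3"], columns=samples)
        prof = differential_profile(expr, paired_metadata)
        assert np.allclose(prof.values, 0.0)
        assert list(prof.values.columns) == sorted(paired_metadata.subject_id.unique())

    def test_matches_loop_oracle(self, paired_metadata, rng):
        samples = paired_metadata["sample_id"]
        expr = pd.DataFrame(rng.normal(size=(4, len(samples))),
                            index=[f"f{i}" for i in range(4)], columns=samples)
        prof = differential_profile(expr, paired_metadata)
        for subj in prof.values.columns:
            rows = paired_metadata[paired_metadata.subject_id == subj]
            t = rows.loc[rows.tissue_status == "tumor", "sample_id"].iloc[0]
            n = rows.loc[rows.tissue_status == "normal", "sample_id"].iloc[0]
            assert np.allclose(prof.values[subj], expr[t] - expr[n])

    def test_missing_mate_names_subject(self, paired_metadata):
        broken = paired_metadata.drop(index=1)  # removes subj0's normal
        expr = pd.DataFrame(np.ones((1, len(broken))), index=["f1"],
                            columns=broken.sample_id)
        with pytest.raises(ValueError, match="subj0"):
            differential_profile(expr, broken)


class TestFitAssociation:
    def test_exact_linear_relation(self, rng):
        n = 20
        x = rng.normal(size=n)
        y = 0.3 * x
        age, sex = _covariates(n, rng)
        beta, f = fit_association(y, x, age, sex)
        assert beta == pytest.approx(0.3, abs=1e-10)
        assert np.isinf(f)

    def test_constant_mirna_rejected(self, rng):
        n = 12
        age, sex = _covariates(n, rng)
        with pytest.raises(ValueError, match="rank"):
            fit_association(rng.normal(size=n), np.ones(n), age, sex)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            fit_association(np.ones(4), np.ones(4), np.ones(4), np.ones(4))

    def test_matches_statsmodels_ols(self, rng):
        n = 200
        age, sex = _covariates(n, rng)
        x = rng.normal(size=n)
        y = 0.4 * x + 0.01 * age + 0.3 * sex + rng.normal(size=n)
        beta, f = fit_association(y, x, age, sex)
        X = sm.add_constant(np.column_stack([x, age, sex]))
        ols = sm.OLS(y, X).fit()
        assert beta == pytest.approx(ols.params[1], abs=1e-10)
        assert f == pytest.approx(ols.tvalues[1] ** 2, rel=1e-8)


class TestBootstrap:
    def test_minimum_p_for_perfect_relation(self, rng):
        n = 30
        age, sex = _covariates(n, rng)
        x = rng.normal(size=n)
        y = 0.5 * x
        p = bootstrap_null_pvalue(y, x, age, sex, B=500, seed=1)
        assert p == pytest.approx(1 / 501)

    def test_deterministic_given_seed(self, rng):
        n = 40
        age, sex = _covariates(n, rng)
        x = rng.normal(size=n)
        y = 0.1 * x + rng.normal(size=n)
        p1 = bootstrap_null_pvalue(y, x, age, sex, B=1000, seed=7)
        p2 = bootstrap_null_pvalue(y, x, age, sex, B=1000, seed=7)
        assert p1 == p2

    def test_small_b_rejected(self, rng):
        n = 20
        age, sex = _covariates(n, rng)
        with pytest.raises(ValueError, match="B"):
            bootstrap_null_pvalue(rng.normal(size=n), rng.normal(size=n),
                                  age, sex, B=50)

    def test_close_to_classical_f_on_gaussian_data(self, rng):
        from scipy.stats import f as fdist
        diffs = []
        for _ in range(20):
            n = 60
            age, sex = _covariates(n, rng)
            x = rng.normal(size=n)
            y = 0.25 * x + rng.normal(size=n)
            beta, F = fit_association(y, x, age, sex)
            p_boot = bootstrap_null_pvalue(y, x, age, sex, B=10000, rng=rng)
            diffs.append(abs(p_boot - fdist.sf(F, 1, n - 4)))
        assert np.mean(diffs) < 0.01


def _profiles(rng, n_genes, n_mirnas, n_subjects, couplings, effect):
    subjects = [f"subj{i}" for i in range(n_subjects)]
    mirna_vals = rng.normal(0, 1, size=(n_mirnas, n_subjects))
    gene_vals = rng.normal(0, 1, size=(n_genes, n_subjects))
    for gi, mj in couplings:
        gene_vals[gi] += effect * mirna_vals[mj]
    genes = [f"g{i}" for i in range(n_genes)]
    mirnas = [f"m{j}" for j in range(n_mirnas)]
    gene_diffs = DifferentialProfile(pd.DataFrame(gene_vals, index=genes,
                                                  columns=subjects))
    mirna_diffs = DifferentialProfile(pd.DataFrame(mirna_vals, index=mirnas,
                                                   columns=subjects))
    return genes, mirnas, subjects, gene_diffs, mirna_diffs


def _assoc_metadata(subjects, rng):
    rows = []
    for i, s in enumerate(subjects):
        for status in ("tumor", "normal"):
            rows.append({"sample_id": f"{s}{status[0]}", "subject_id": s,
                         "tissue_status": status,
                         "age": float(40 + (i % 40)),
                         "sex": "M" if i % 2 else "F",
                         "msi_status": "MSS"})
    return pd.DataFrame(rows)


def _intensity_with_fc(mirnas, metadata, rng, fc=2.0):
    samples = metadata["sample_id"]
    normal = rng.uniform(5, 50, size=(len(mirnas), 1))
    cols = {}
    for _, row in metadata.iterrows():
        cols[row.sample_id] = (normal[:, 0] * (fc if row.tissue_status == "tumor"
                                               else 1.0))
    return pd.DataFrame(cols, index=mirnas)[samples]


class TestRunAssociations:
    def test_planted_couplings_recovered(self, rng):
        # power: a standardized slope of 0.3 against unit noise at n=200 has
        # se ~ 1/sqrt(200) = 0.0707; within-gene BH over 20 miRNAs demands
        # p <= 0.05/20, i.e. |t| >= 3.05, so per-pair recovery probability is
        # ~Phi((0.3 - 0.216)/0.0707) ~ 0.88.  Over 25 pair-replicates the
        # binomial 99% lower bound is 18 recoveries.
        couplings = [(0, 1), (1, 5), (2, 9), (3, 13), (4, 17)]
        recovered, false_pos, total_null = 0, 0, 0
        for rep in range(5):
            genes, mirnas, subjects, gd, md = _profiles(
                rng, 5, 20, 200, couplings, effect=0.3)
            meta = _assoc_metadata(subjects, rng)
            res = run_associations(
                gd, md, genes, mirnas, meta,
                gene_fc={g: 2.0 for g in genes},
                mirna_intensity=_intensity_with_fc(mirnas, meta, rng),
                B=1000, seed=rep)
            sig = {(r.gene, r.mirna) for r in res if r.significant}
            planted = {(f"g{gi}", f"m{mj}") for gi, mj in couplings}
            recovered += len(sig & planted)
            false_pos += len(sig - planted)
            total_null += len(res) - len(planted)
        assert recovered >= 18
        assert false_pos / total_null <= 0.05 + 0.03

    def test_null_calibration(self, rng):
        genes, mirnas, subjects, gd, md = _profiles(rng, 3, 30, 100, [], 0.0)
        meta = _assoc_metadata(subjects, rng)
        res = run_associations(gd, md, genes, mirnas, meta,
                               gene_fc={g: 2.0 for g in genes},
                               mirna_intensity=_intensity_with_fc(mirnas, meta, rng),
                               B=400, seed=0)
        frac = np.mean([r.raw_p < 0.05 for r in res])
        assert 0.01 <= frac <= 0.10  # ~0.05 with Monte-Carlo margin

    def test_fc_cutpoint_excludes_weakly_changed_mirna(self, rng):
        # a coupled miRNA whose fold change sits inside (0.67, 1.50) cannot
        # enter the significant set however small its p-value
        genes, mirnas, subjects, gd, md = _profiles(rng, 1, 2, 100,
                                                    [(0, 0), (0, 1)], 0.8)
        meta = _assoc_metadata(subjects, rng)
        intensity = _intensity_with_fc(mirnas, meta, rng, fc=1.2)
        res = run_associations(gd, md, genes, mirnas, meta,
                               gene_fc={"g0": 2.0}, mirna_intensity=intensity,
                               B=400, seed=0)
        assert all(r.raw_p <= 0.05 for r in res)
        assert not any(r.significant for r in res)

    def test_within_gene_fdr_invariant_to_mirna_order(self, rng):
        genes, mirnas, subjects, gd, md = _profiles(rng, 2, 8, 60, [(0, 0)], 0.5)
        meta = _assoc_metadata(subjects, rng)
        intensity = _intensity_with_fc(mirnas, meta, rng)
        kw = dict(metadata=meta, gene_fc={g: 2.0 for g in genes},
                  mirna_intensity=intensity, B=300, seed=5)
        res1 = run_associations(gd, md, genes, mirnas, **kw)
        res2 = run_associations(gd, md, genes, mirnas[::-1], **kw)
        for g in genes:
            q1 = sorted(r.fdr_p for r in res1 if r.gene == g)
            q2 = sorted(r.fdr_p for r in res2 if r.gene == g)
            assert q1 == pytest.approx(q2)

    def test_empty_candidates(self, rng):
        genes, mirnas, subjects, gd, md = _profiles(rng, 1, 1, 10, [], 0.0)
        meta = _assoc_metadata(subjects, rng)
        assert run_associations(gd, md, [], [], meta, gene_fc={},
                                mirna_intensity=md.values, B=200, seed=0) == []

    def test_sign_coherence_on_noiseless_data(self, rng):
        n = 50
        subjects = [f"subj{i}" for i in range(n)]
        x = rng.normal(size=n)
        gd = DifferentialProfile(pd.DataFrame([-0.7 * x, 0.4 * x],
                                              index=["g0", "g1"], columns=subjects))
        md = DifferentialProfile(pd.DataFrame([x], index=["m0"], columns=subjects))
        meta = _assoc_metadata(subjects, rng)
        res = run_associations(gd, md, ["g0", "g1"], ["m0"], meta,
                               gene_fc={"g0": 0.5, "g1": 2.0},
                               mirna_intensity=_intensity_with_fc(["m0"], meta, rng),
                               B=200, seed=0)
        signs = {r.gene: np.sign(r.beta) for r in res}
        assert signs == {"g0": -1.0, "g1": 1.0}
        table = association_table(res)
        assert len(table) == 2
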