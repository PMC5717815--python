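import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import rccsig as r


def make_matrix(values, scale="log2"):
    values = np.asarray(values, dtype=float)
    genes = [f"G{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return r.ExpressionMatrix(genes, samples, values, scale=scale)


class TestLog2:
    def test_hand_values(self):
        m = make_matrix([[0.0, 7.0]], scale="raw")
        out = r.log2_transform(m, pseudocount=1.0)
        np.testing.assert_allclose(out.values, [[0.0, 3.0]])
        assert out.scale == "log2"

    def test_noop_with_warning_on_log2_input(self):
        m = make_matrix([[1.0, 2.0]])
        with pytest.warns(UserWarning, match="no-op"):
            out = r.log2_transform(m)
        np.testing.assert_array_equal(out.values, m.values)

    def test_negative_raw_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            r.log2_transform(make_matrix([[-1.0, 1.0]], scale="raw"))


class TestQuantileNormalize:
    def test_two_sample_hand_example(self):
        m = make_matrix([[1, 4], [2, 5], [3, 6]])
        out = r.quantile_normalize(m)
        np.testing.assert_allclose(out.values,
                                   [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_identical_columns_unchanged(self):
        m = make_matrix([[1, 1], [5, 5], [3, 3]])
        out = r.quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_all_tied_column_stays_tied(self):
        m = make_matrix([[2, 1], [2, 5], [2, 9]])
        out = r.quantile_normalize(m)
        assert len(set(out.values[:, 0])) == 1

    def test_columns_share_identical_distribution(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(50, 6)))
        out = r.quantile_normalize(m)
        ref = np.sort(out.values[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(size=(40, 4)))
        out = r.quantile_normalize(m)
        for j in range(4):
            assert (np.argsort(out.values[:, j], kind="stable")
                    == np.argsort(m.values[:, j], kind="stable")).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            r.quantile_normalize(make_matrix([[1.0], [2.0]]))


class TestZscore:
    def test_hand_example_population_sd(self):
        out = r.zscore_genes(make_matrix([[1, 2, 3]]))
        np.testing.assert_allclose(out.values,
                                   [[-1.224745, 0.0, 1.224745]], atol=1e-6)

    def test_constant_row_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = r.zscore_genes(make_matrix([[5, 5, 5], [1, 2, 3]]))
        np.testing.assert_array_equal(out.values[0], 0.0)

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        out = r.zscore_genes(make_matrix(rng.normal(2, 3, size=(20, 9))))
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=1), 1.0, atol=1e-9)


def two_batch_cohort(seed=0, shift=2.0, n_genes=60, per_batch=12):
    rng = np.random.default_rng(seed)
    Y = rng.normal(7, 1, size=(n_genes, 2 * per_batch))
    Y[:, per_batch:] += shift
    labels = (["ccRCC"] * (per_batch // 2) + ["pRCC"] * (per_batch - per_batch // 2)) * 2
    sids = [f"s{i}" for i in range(2 * per_batch)]
    m = r.ExpressionMatrix([f"G{i}" for i in range(n_genes)], sids, Y)
    ann = r.SampleAnnotation(pd.DataFrame({
        "sample_id": sids, "label": labels,
        "batch": ["b1"] * per_batch + ["b2"] * per_batch, "cohort": "t"}))
    return m, ann


def batch_f_stat(values, batches):
    """Gene-averaged one-way F statistic for the batch factor."""
    from scipy.stats import f_oneway

    groups = [values[:, batches == b] for b in sorted(set(batches))]
    f = f_oneway(*[g.T for g in groups], axis=0).statistic
    return np.nanmean(f)


class TestCombat:
    def test_single_batch_identity(self):
        m, _ = two_batch_cohort(shift=0.0)
        sids = m.sample_ids
        ann = r.SampleAnnotation(pd.DataFrame({
            "sample_id": sids, "label": "", "batch": "b1", "cohort": "t"}))
        out, model = r.combat_adjust(m, ann, covariate=False)
        np.testing.assert_allclose(out.values, m.values, atol=1e-6)
        np.testing.assert_allclose(model.gamma_star, 0.0, atol=1e-9)

    def test_two_batch_constant_shift_removed(self):
        # batch b2 is exactly batch b1 + 2.0 on every gene
        rng = np.random.default_rng(0)
        A = rng.normal(7, 1, size=(60, 12))
        Y = np.hstack([A, A + 2.0])
        sids = [f"s{i}" for i in range(24)]
        m = r.ExpressionMatrix([f"G{i}" for i in range(60)], sids, Y)
        ann = r.SampleAnnotation(pd.DataFrame({
            "sample_id": sids, "label": (["ccRCC"] * 6 + ["pRCC"] * 6) * 2,
            "batch": ["b1"] * 12 + ["b2"] * 12, "cohort": "t"}))
        out, _ = r.combat_adjust(m, ann)
        batches = ann.batches_for(m.sample_ids)
        raw_gap = (m.values[:, batches == "b1"].mean(axis=1)
                   - m.values[:, batches == "b2"].mean(axis=1))
        gap = (out.values[:, batches == "b1"].mean(axis=1)
               - out.values[:, batches == "b2"].mean(axis=1))
        # the systematic offset vanishes on average; per-gene residuals
        # stay at the shrinkage scale, far below the planted 2.0
        assert abs(gap.mean()) < 0.1
        assert np.abs(gap).mean() < 0.5 * np.abs(raw_gap).mean()

    def test_two_batch_noisy_shift_mean_gap_removed(self):
        m, ann = two_batch_cohort(shift=2.0)
        out, _ = r.combat_adjust(m, ann)
        batches = ann.batches_for(m.sample_ids)
        gap = (out.values[:, batches == "b1"].mean(axis=1)
               - out.values[:, batches == "b2"].mean(axis=1))
        assert abs(gap.mean()) < 0.1  # the systematic 2.0 offset is gone

    def test_between_batch_f_statistic_decreases(self):
        m, ann = two_batch_cohort(shift=1.5, seed=3)
        out, _ = r.combat_adjust(m, ann)
        batches = ann.batches_for(m.sample_ids)
        assert batch_f_stat(out.values, batches) < batch_f_stat(m.values, batches)

    def test_class_separation_preserved(self):
        # plant a class effect orthogonal to the batch shift
        m, ann = two_batch_cohort(shift=2.0, seed=4)
        labels = ann.labels_for(m.sample_ids)
        V = m.values.copy()
        V[:10, labels == "ccRCC"] += 2.0
        m = m.copy_with(values=V)
        out, _ = r.combat_adjust(m, ann)
        before = (V[:10, labels == "ccRCC"].mean()
                  - V[:10, labels == "pRCC"].mean())
        after = (out.values[:10, labels == "ccRCC"].mean()
                 - out.values[:10, labels == "pRCC"].mean())
        assert abs(after - before) / before < 0.2

    def test_shrinkage_pulls_extreme_batch_effects_inward(self):
        m, ann = two_batch_cohort(shift=0.5, seed=5)
        V = m.values.copy()
        batches = ann.batches_for(m.sample_ids)
        V[0, batches == "b2"] += 5.0  # one gene with an extreme batch effect
        out, model = r.combat_adjust(m.copy_with(values=V), ann)
        i = model.batches.index("b2")
        assert abs(model.gamma_star[i, 0]) < abs(model.gamma_hat[i, 0])
        # shrunk location lies between the raw estimate and the prior mean
        lo = np.minimum(model.gamma_hat, model.gamma_bar[:, None]) - 1e-9
        hi = np.maximum(model.gamma_hat, model.gamma_bar[:, None]) + 1e-9
        assert ((model.gamma_star >= lo) & (model.gamma_star <= hi)).all()
        assert (model.delta2_star > 0).all()

    def test_permutation_invariance(self):
        m, ann = two_batch_cohort(seed=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n_samples)
        mp = m.copy_with(values=m.values[:, perm],
                         sample_ids=[m.sample_ids[i] for i in perm])
        out, _ = r.combat_adjust(m, ann)
        outp, _ = r.combat_adjust(mp, ann)
        np.testing.assert_allclose(outp.values[:, np.argsort(perm)],
                                   out.values, atol=1e-8)

    def test_singleton_batch_rejected(self):
        m, ann = two_batch_cohort()
        tab = ann.table.copy()
        tab.loc[0, "batch"] = "lonely"
        with pytest.raises(ValueError, match="single sample"):
            r.combat_adjust(m, r.SampleAnnotation(tab))

    def test_missing_batch_label_rejected(self):
        m, ann = two_batch_cohort()
        tab = ann.table.copy()
        tab.loc[0, "batch"] = ""
        with pytest.raises(ValueError, match="missing"):
            r.combat_adjust(m, r.SampleAnnotation(tab))

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_reference_eb_implementation(self, tmp_path):
        """Cross-check against the Bioconductor parametric implementation."""
        m, ann = two_batch_cohort(seed=42, n_genes=30, per_batch=9)
        out, _ = r.combat_adjust(m, ann, covariate=False)
        y_path, b_path, o_path = (tmp_path / n for n in ("Y.txt", "b.txt", "o.txt"))
        np.savetxt(y_path, m.values)
        b_path.write_text("\n".join(ann.batches_for(m.sample_ids)) + "\n")
        script = tmp_path / "combat.R"
        script.write_text(
            'suppressMessages(library(sva))\n'
            f'Y <- as.matrix(read.table("{y_path}"))\n'
            f'batch <- readLines("{b_path}")\n'
            'out <- ComBat(dat=Y, batch=batch, par.prior=TRUE)\n'
            f'write.table(out, "{o_path}", row.names=FALSE, col.names=FALSE)\n')
        proc = subprocess.run(["Rscript", str(script)], capture_output=True)
        if proc.returncode != 0:
            pytest.skip(f"reference implementation unavailable: {proc.stderr[:200]}")
        ref = np.loadtxt(o_path)
        np.testing.assert_allclose(out.values, ref, atol=1e-4)


class TestProjectOntoSignature:
    def make_sig(self, genes):
        return r.GeneSignature([(g, None, None) for g in genes])

    def test_restricts_to_signature_order(self, harmonized_cohort, trained_signature):
        z, _, _ = harmonized_cohort
        out = r.project_onto_signature(z, trained_signature)
        assert out.gene_symbols == trained_signature.unique_genes

    def test_self_mode_rows_standardized(self):
        rng = np.random.default_rng(0)
        m = r.ExpressionMatrix([f"G{i}" for i in range(5)],
                               [f"s{j}" for j in range(20)],
                               rng.normal(5, 2, size=(5, 20)))
        out = r.project_onto_signature(m, self.make_sig([f"G{i}" for i in range(5)]))
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=1), 1, atol=1e-9)

    def test_missing_gene_zero_filled_with_warning(self):
        rng = np.random.default_rng(1)
        m = r.ExpressionMatrix([f"G{i}" for i in range(9)],
                               [f"s{j}" for j in range(10)],
                               rng.normal(size=(9, 10)))
        sig = self.make_sig([f"G{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="G9"):
            out = r.project_onto_signature(m, sig)
        np.testing.assert_array_equal(out.values[9], 0.0)

    def test_too_many_missing_rejected(self):
        rng = np.random.default_rng(2)
        m = r.ExpressionMatrix(["G0", "G1"], ["s0", "s1", "s2"],
                               rng.normal(size=(2, 3)))
        with pytest.raises(ValueError, match="unusable"):
            r.project_onto_signature(m, self.make_sig([f"G{i}" for i in range(4)]))

    def test_reference_mode_uses_training_stats(self):
        m = r.ExpressionMatrix(["G0"], ["s0", "s1"], np.array([[4.0, 6.0]]))
        sig = self.make_sig(["G0"])
        out = r.project_onto_signature(m, sig, reference_stats=([5.0], [2.0]),
                                       mode="reference")
        np.testing.assert_allclose(out.values, [[-0.5, 0.5]])
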