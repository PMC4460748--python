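"""Probe collapse, empirical-Bayes batch correction, IQR filtering."""

import numpy as np
import pandas as pd
import pytest

from biomodules.errors import DataError
from biomodules.expression import (
    ExpressionMatrix,
    collapse_probes,
    correct_batches,
    iqr_filter,
    read_matrix,
    read_sample_sheet,
    write_matrix,
    write_sample_sheet,
)


def matrix_from(values, phenotype=None, batch=None, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(
        values=df,
        phenotype=pd.Series(phenotype, index=samples) if phenotype is not None else None,
        batch=pd.Series(batch, index=samples) if batch is not None else None,
    )


class TestCollapse:
    def test_max_mean_probe_retained(self):
        probes = pd.DataFrame(
            [[1.0, 1.0], [2.0, 2.0]], index=["p1", "p2"], columns=["s1", "s2"]
        )
        out = collapse_probes(probes, {"p1": "G", "p2": "G"})
        assert list(out.index) == ["G"]
        assert (out.loc["G"] == 2.0).all()

    def test_one_probe_per_gene_is_relabeling(self):
        probes = pd.DataFrame(
            np.arange(6.0).reshape(3, 2), index=["p1", "p2", "p3"], columns=["s1", "s2"]
        )
        mapping = {"p1": "GA", "p2": "GB", "p3": "GC"}
        out = collapse_probes(probes, mapping)
        assert sorted(out.index) == ["GA", "GB", "GC"]
        for p, g in mapping.items():
            assert (out.loc[g] == probes.loc[p]).all()

    def test_random_matrix_matches_argmax_oracle(self):
        rng = np.random.default_rng(5)
        probes = pd.DataFrame(
            rng.normal(size=(200, 10)), index=[f"p{i:03d}" for i in range(200)]
        )
        mapping = {f"p{i:03d}": f"G{i % 60:02d}" for i in range(200)}
        out = collapse_probes(probes, mapping)
        means = probes.mean(axis=1)
        for gene in out.index:
            candidates = sorted(p for p, g in mapping.items() if g == gene)
            best = max(candidates, key=lambda p: (means[p], ))  # ties: first lexical wins
            best = sorted([p for p in candidates if means[p] == means[best]])[0]
            assert (out.loc[gene] == probes.loc[best]).all()

    def test_no_mapped_probe_is_error(self):
        probes = pd.DataFrame([[1.0, 2.0]], index=["p1"], columns=["s1", "s2"])
        with pytest.raises(DataError):
            collapse_probes(probes, {"other": "G"})


def _pure_shift_fixture(n_genes=60, n_per_batch=6, shift=3.0):
    """Gene offsets + a shared sample pattern, batch 2 shifted by +3.

    Within each batch every gene sees the same sample pattern, so the batch
    effect is exactly the planted shift and perfect removal is achievable.
    """
    rng = np.random.default_rng(17)
    offsets = rng.normal(8, 1, size=n_genes)
    pattern = rng.normal(0, 1, size=n_per_batch)
    block = offsets[:, None] + pattern[None, :]
    values = np.hstack([block, block + shift])
    batch = ["b1"] * n_per_batch + ["b2"] * n_per_batch
    return matrix_from(values, batch=batch)


class TestBatchCorrection:
    def test_pure_location_shift_removed_exactly(self):
        m = _pure_shift_fixture()
        out = correct_batches(m, protect=False)
        b = m.batch
        mean1 = out.values.loc[:, (b == "b1").to_numpy()].mean(axis=1)
        mean2 = out.values.loc[:, (b == "b2").to_numpy()].mean(axis=1)
        assert np.abs(mean1 - mean2).max() < 1e-6

    def test_single_batch_identity(self):
        m = matrix_from(np.random.default_rng(1).normal(size=(10, 6)), batch=["b"] * 6)
        out = correct_batches(m, protect=False)
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_confounded_design_rejected(self):
        m = matrix_from(
            np.random.default_rng(2).normal(size=(10, 8)),
            phenotype=["case"] * 4 + ["ctrl"] * 4,
            batch=["b1"] * 4 + ["b2"] * 4,
        )
        with pytest.raises(DataError, match="confounded"):
            correct_batches(m, protect=True)

    def test_simulated_shift_and_scale_removed(self):
        from biomodules.synthetic import simulate_expression
        from scipy import stats as sps

        m, _ = simulate_expression(
            n_genes=1000, n_case=14, n_control=14, module_size=10, rng_seed=9,
            batch_design={"n_batches": 2, "shifts": [0.0, 2.0], "scales": [1.0, 1.5]},
        )
        out = correct_batches(m, protect=True)
        b = (m.batch == "batch2").to_numpy()
        Y = out.values.to_numpy()
        g1, g2 = Y[:, ~b], Y[:, b]
        n1, n2 = g1.shape[1], g2.shape[1]
        # per-gene one-way F statistic for a residual batch effect
        gm = Y.mean(axis=1, keepdims=True)
        ssb = n1 * (g1.mean(1) - gm[:, 0]) ** 2 + n2 * (g2.mean(1) - gm[:, 0]) ** 2
        ssw = ((g1 - g1.mean(1, keepdims=True)) ** 2).sum(1) + (
            (g2 - g2.mean(1, keepdims=True)) ** 2
        ).sum(1)
        F = ssb / (ssw / (n1 + n2 - 2))
        crit = sps.f.ppf(0.95, 1, n1 + n2 - 2)
        assert (F < crit).mean() >= 0.95

    def test_protect_preserves_group_effect(self):
        from biomodules.synthetic import simulate_expression

        m, truth = simulate_expression(
            n_genes=800, n_case=20, n_control=20, module_size=60, rho=0.0,
            log2_effect=2.0, rng_seed=13,
            batch_design={"n_batches": 2, "shifts": [0.0, 3.0]},
        )
        out = correct_batches(m, protect=True)
        case = (m.phenotype == "case").to_numpy()
        module = [g for g in truth.module_genes if g != truth.seed_gene]
        eff = (
            out.values.loc[module, case].mean(axis=1)
            - out.values.loc[module, ~case].mean(axis=1)
        )
        assert abs(eff.mean() - 2.0) / 2.0 < 0.1

    def test_balanced_batches_keep_global_gene_means(self):
        m = _pure_shift_fixture()
        out = correct_batches(m, protect=False)
        assert np.allclose(
            out.values.mean(axis=1), m.values.mean(axis=1), atol=1e-8
        )

    def test_matches_frozen_sva_combat_oracle(self):
        """Corner of the corrected matrix vs values computed independently
        with the reference R implementation (sva::ComBat, parametric prior)
        on the identical seeded fixture."""
        from biomodules.synthetic import simulate_expression

        m, _ = simulate_expression(
            n_genes=20, n_case=6, n_control=6, module_size=4, rng_seed=42,
            batch_design={"n_batches": 2, "shifts": [0.0, 1.5], "scales": [1.0, 1.2]},
        )
        out = correct_batches(m, protect=True)
        expected = np.array([
            [8.658006, 8.709239, 9.904110],
            [7.516382, 7.732275, 8.905861],
            [9.178648, 10.328811, 9.720648],
            [9.957732, 9.332079, 9.460176],
        ])
        got = out.values.iloc[:4, :3].to_numpy()
        assert np.allclose(got, expected, atol=1e-4)


class TestIqrFilter:
    def test_keeps_highest_iqr_genes(self):
        rng = np.random.default_rng(3)
        rows = [rng.uniform(-s, s, size=20) for s in (1, 2, 3, 4)]
        m = matrix_from(np.array(rows), genes=["g1", "g2", "g3", "g4"])
        out = iqr_filter(m, keep_fraction=0.5)
        assert sorted(out.values.index) == ["g3", "g4"]

    def test_keep_all_is_identity(self):
        m = matrix_from(np.random.default_rng(4).normal(size=(7, 5)))
        out = iqr_filter(m, keep_fraction=1.0)
        assert out.values.equals(m.values)

    def test_study_scale_count(self):
        rng = np.random.default_rng(6)
        m = matrix_from(rng.normal(size=(8442, 10)))
        out = iqr_filter(m, keep_fraction=0.5)
        assert out.values.shape[0] == 4221

    def test_always_keep_retains_low_iqr_gene(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=(20, 10))
        vals[0] *= 0.01  # nearly flat gene
        m = matrix_from(vals, genes=[f"g{i:02d}" for i in range(20)])
        dropped = iqr_filter(m, 0.5)
        assert "g00" not in dropped.values.index
        kept = iqr_filter(m, 0.5, always_keep={"g00"})
        assert "g00" in kept.values.index
        assert kept.values.shape[0] == 11  # quota plus the protected gene

    def test_invariant_to_joint_affine_rescale(self):
        rng = np.random.default_rng(8)
        m = matrix_from(rng.normal(size=(50, 12)))
        scaled = matrix_from(2.5 * m.values.to_numpy() + 7.0)
        out1 = iqr_filter(m, 0.4)
        out2 = iqr_filter(scaled, 0.4)
        assert list(out1.values.index) == list(out2.values.index)


class TestIO:
    def test_matrix_and_sheet_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        m = matrix_from(
            rng.normal(size=(6, 4)),
            phenotype=["case", "case", "ctrl", "ctrl"],
            batch=["b1", "b2", "b1", "b2"],
        )
        mp = write_matrix(m.values, tmp_path / "m.tsv")
        sp = write_sample_sheet(m.phenotype, m.batch, tmp_path / "s.tsv")
        values = read_matrix(mp)
        pheno, batch = read_sample_sheet(sp)
        assert np.allclose(values.to_numpy(), m.values.to_numpy())
        assert list(pheno) == list(m.phenotype)
        assert list(batch) == list(m.batch)

    def test_duplicate_gene_ids_rejected(self):
        df = pd.DataFrame(np.zeros((2, 2)), index=["g", "g"], columns=["a", "b"])
        with pytest.raises(Exception):
            ExpressionMatrix(values=df)
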