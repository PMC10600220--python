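"""QC filtering, pseudo-bulk DE, and junction classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tetherscope.expression import (
    CountMatrix,
    IsoformModelSet,
    QCThresholds,
    classify_junctions,
    gene_set_expression_summary,
    pseudobulk_lfc,
    qc_filter,
)
from tetherscope.simulate import CountSimSpec, generate_count_matrix, generate_junctions


def brute_force_qc(counts: pd.DataFrame, thr: QCThresholds, mito_prefix="mt-"):
    """Independent row/column scan implementing the QC rules directly."""
    mito_frac = {}
    for cell in counts.columns:
        col = counts[cell]
        total = col.sum()
        mito = col[col.index.str.startswith(mito_prefix)].sum()
        mito_frac[cell] = mito / total if total > 0 else 0.0
    genes = [
        g for g in counts.index
        if (counts.loc[g] > 0).sum() >= thr.min_cells_per_gene
    ]
    sub = counts.loc[genes]
    cells = []
    for cell in counts.columns:
        detected = (sub[cell] > 0).sum()
        if (
            detected >= thr.min_genes_per_cell
            and detected <= thr.max_genes_per_cell
            and mito_frac[cell] <= thr.max_mito_fraction
        ):
            cells.append(cell)
    return len(genes), len(cells)


class TestQCFilter:
    @staticmethod
    def _toy_matrix(seed, n_genes=60, n_cells=30, thr=None):
        """Random matrix whose detected-gene counts straddle the thresholds."""
        rng = np.random.default_rng(seed)
        thr = thr or QCThresholds(min_genes_per_cell=20, max_genes_per_cell=50,
                                  max_mito_fraction=0.18, min_cells_per_gene=3)
        genes = [f"mt-g{i}" for i in range(5)] + [f"g{i}" for i in range(n_genes - 5)]
        counts = np.zeros((n_genes, n_cells), dtype=int)
        for j in range(n_cells):
            n_detected = rng.integers(10, n_genes)
            idx = rng.choice(n_genes, size=n_detected, replace=False)
            counts[idx, j] = rng.integers(1, 50, size=n_detected)
            if rng.uniform() < 0.3:  # push some cells over the mito limit
                counts[:5, j] += rng.integers(50, 200, size=5)
        return CountMatrix(pd.DataFrame(counts, index=genes)), thr

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_scan(self, seed):
        matrix, thr = self._toy_matrix(seed)
        exp_genes, exp_cells = brute_force_qc(matrix.counts, thr)
        if exp_cells == 0:
            with pytest.raises(ValueError, match="survive"):
                qc_filter(matrix, thr)
            return
        filtered, report = qc_filter(matrix, thr)
        assert filtered.counts.shape == (exp_genes, exp_cells)
        assert report["genes_kept"] == exp_genes
        assert report["cells_kept"] == exp_cells

    def test_boundary_cases_retained(self):
        """A cell with exactly min genes and a gene in exactly min cells stay."""
        thr = QCThresholds(min_genes_per_cell=3, max_genes_per_cell=10,
                           max_mito_fraction=0.18, min_cells_per_gene=3)
        counts = pd.DataFrame(
            0,
            index=[f"g{i}" for i in range(6)],
            columns=[f"c{i}" for i in range(4)],
        )
        # every gene detected in exactly 3 cells, every cell detects exactly 3+ genes
        for g in range(6):
            for c in range(3):
                counts.iloc[g, (g + c) % 4] = 5
        detected = (counts > 0).sum()
        assert (detected >= 3).all()
        filtered, _ = qc_filter(CountMatrix(counts), thr)
        assert filtered.counts.shape == counts.shape

    def test_cell_below_gene_floor_removed(self):
        thr = QCThresholds(min_genes_per_cell=3, max_genes_per_cell=100,
                           max_mito_fraction=0.18, min_cells_per_gene=1)
        counts = pd.DataFrame(
            {"good": [1, 2, 3, 4], "bad": [5, 0, 0, 0]},
            index=[f"g{i}" for i in range(4)],
        )
        filtered, report = qc_filter(CountMatrix(counts), thr)
        assert list(filtered.counts.columns) == ["good"]
        assert report["cells_removed_low_genes"] == 1

    def test_mito_fraction_uses_prefilter_totals(self):
        thr = QCThresholds(min_genes_per_cell=1, max_genes_per_cell=100,
                           max_mito_fraction=0.5, min_cells_per_gene=2)
        # the mito gene is detected in only 1 cell so it is removed as a gene,
        # but its counts still push that cell past the mito limit
        counts = pd.DataFrame(
            {"c1": [120, 40, 40], "c2": [0, 50, 50]},
            index=["mt-x", "g1", "g2"],
        )
        filtered, _ = qc_filter(CountMatrix(counts), thr)
        assert list(filtered.counts.columns) == ["c2"]

    def test_idempotent_on_simulated_data(self):
        spec = CountSimSpec(n_genes=400, seed=3)
        matrix, _ = generate_count_matrix(spec)
        thr = QCThresholds(min_genes_per_cell=50, max_genes_per_cell=400,
                           max_mito_fraction=0.18, min_cells_per_gene=3)
        once, _ = qc_filter(matrix, thr)
        twice, report = qc_filter(once, thr)
        assert twice.counts.shape == once.counts.shape
        assert report["cells_removed_total"] == 0


class TestPseudobulkLFC:
    def test_identical_groups_give_zero_lfc(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(50, size=(30, 3))
        counts = pd.DataFrame(
            np.hstack([base, base]),
            index=[f"g{i}" for i in range(30)],
            columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)],
        )
        groups = pd.Series(["case"] * 3 + ["ctrl"] * 3, index=counts.columns)
        de = pseudobulk_lfc(CountMatrix(counts), groups, "case", "ctrl")
        assert np.allclose(de["log2_fc"], 0.0)

    def test_planted_lmna_scale_fold_change_recovered(self):
        spec = CountSimSpec(
            n_genes=2000,
            group_sizes={"control": 5, "case": 5},
            de_genes={"gene00100": 3.40},
            seed=42,
        )
        matrix, _ = generate_count_matrix(spec)
        de = pseudobulk_lfc(matrix, matrix.unit_meta["group"], "case", "control")
        assert de.loc["gene00100", "log2_fc"] == pytest.approx(3.40, abs=0.5)
        assert de.loc["gene00100", "p_adj"] < 0.05

    def test_all_zero_gene_reported_flat(self):
        counts = pd.DataFrame(
            {"a1": [0, 10], "a2": [0, 12], "b1": [0, 9], "b2": [0, 11]},
            index=["dead", "alive"],
        )
        groups = pd.Series(["case", "case", "ctrl", "ctrl"], index=counts.columns)
        de = pseudobulk_lfc(CountMatrix(counts), groups, "case", "ctrl")
        assert de.loc["dead", "log2_fc"] == 0.0
        assert de.loc["dead", "p_value"] == 1.0

    def test_antisymmetric_under_group_swap(self):
        spec = CountSimSpec(n_genes=200, de_genes={"gene00010": 2.0}, seed=9)
        matrix, _ = generate_count_matrix(spec)
        groups = matrix.unit_meta["group"]
        fwd = pseudobulk_lfc(matrix, groups, "case", "control")
        rev = pseudobulk_lfc(matrix, groups, "control", "case")
        np.testing.assert_allclose(fwd["log2_fc"], -rev["log2_fc"], atol=1e-12)

    def test_bh_adjustment_monotone(self):
        spec = CountSimSpec(n_genes=500, seed=2)
        matrix, _ = generate_count_matrix(spec)
        de = pseudobulk_lfc(matrix, matrix.unit_meta["group"], "case", "control")
        assert (de["p_adj"] >= de["p_value"] - 1e-15).all()
        assert (de["p_adj"] <= 1.0).all()
        ranked = de.sort_values("p_value")
        assert ranked["p_adj"].is_monotonic_increasing

    def test_null_false_positive_fraction(self):
        fracs = []
        for seed in range(20):
            spec = CountSimSpec(n_genes=2000, seed=seed)
            matrix, _ = generate_count_matrix(spec)
            de = pseudobulk_lfc(matrix, matrix.unit_meta["group"], "case", "control")
            fracs.append((de["p_adj"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05

    def test_zero_count_group_errors(self):
        counts = pd.DataFrame(
            {"a1": [0, 0], "a2": [0, 0], "b1": [5, 5], "b2": [3, 3]},
            index=["g1", "g2"],
        )
        groups = pd.Series(["case", "case", "ctrl", "ctrl"], index=counts.columns)
        with pytest.raises(ValueError, match="zero total"):
            pseudobulk_lfc(CountMatrix(counts), groups, "case", "ctrl")


class TestClassifyJunctions:
    def test_only_lc_reads_give_alpha_zero(self):
        table = generate_junctions(5000, alpha_la=0.0, seed=1)
        result = classify_junctions(table, IsoformModelSet.packaged_lmna())
        assert result["alpha_la"] == 0.0

    def test_equal_counts_give_half(self):
        models = IsoformModelSet(
            diagnostic={"LA": [("c", 10, 20)], "LC": [("c", 10, 15)]},
        )
        table = pd.DataFrame(
            {"chrom": ["c", "c"], "donor": [10, 10], "acceptor": [20, 15],
             "count": [250, 250]}
        )
        result = classify_junctions(table, models)
        assert result["alpha_la"] == 0.5

    def test_zero_diagnostic_reads_flagged_not_error(self):
        models = IsoformModelSet(
            diagnostic={"LA": [("c", 10, 20)], "LC": [("c", 10, 15)]},
            shared=[("c", 1, 5)],
        )
        table = pd.DataFrame(
            {"chrom": ["c"], "donor": [1], "acceptor": [5], "count": [100]}
        )
        result = classify_junctions(table, models)
        assert result["alpha_la"] is None
        assert result["flag"] == "no diagnostic reads"

    def test_estimate_invariant_to_count_scaling(self):
        table = generate_junctions(10_000, alpha_la=0.7, seed=2)
        models = IsoformModelSet.packaged_lmna()
        a1 = classify_junctions(table, models)["alpha_la"]
        scaled = table.assign(count=table["count"] * 10)
        a2 = classify_junctions(scaled, models)["alpha_la"]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_binomial_ci_covers_planted_alpha(self):
        covered = 0
        for seed in range(100):
            table = generate_junctions(10_000, alpha_la=0.7, seed=seed)
            result = classify_junctions(table, IsoformModelSet.packaged_lmna())
            lo, hi = result["ci_95"]
            covered += lo <= 0.7 <= hi
        assert covered >= 93

    def test_diagnostic_sets_must_be_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            IsoformModelSet(diagnostic={"LA": [("c", 1, 2)], "LC": [("c", 1, 2)]})


class TestJunctionSimulator:
    def test_zero_reads_empty_table(self):
        table = generate_junctions(0, alpha_la=0.5, seed=0)
        assert len(table) == 0

    def test_balanced_alpha_yields_balanced_counts(self):
        table = generate_junctions(100_000, alpha_la=0.5, seed=3,
                                   shared_read_fraction=0.0)
        result = classify_junctions(table, IsoformModelSet.packaged_lmna())
        assert result["alpha_la"] == pytest.approx(0.5, abs=0.02)


class TestGeneSetSummary:
    def test_identical_groups_flat(self):
        rng = np.random.default_rng(8)
        base = rng.poisson(30, size=(20, 4))
        counts = pd.DataFrame(
            np.hstack([base, base]),
            index=[f"g{i}" for i in range(20)],
            columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
        )
        groups = pd.Series(["case"] * 4 + ["ctrl"] * 4, index=counts.columns)
        out = gene_set_expression_summary(
            CountMatrix(counts), [f"g{i}" for i in range(10)], groups, "case", "ctrl"
        )
        assert out["wilcoxon_p"] == pytest.approx(1.0)
        assert out["median_shift_cpm"] == pytest.approx(0.0)

    def test_shifted_set_detected(self):
        spec = CountSimSpec(
            n_genes=300,
            de_genes={f"gene{i:05d}": 2.0 for i in range(10, 30)},
            seed=11,
        )
        matrix, _ = generate_count_matrix(spec)
        out = gene_set_expression_summary(
            matrix, [f"gene{i:05d}" for i in range(10, 30)],
            matrix.unit_meta["group"], "case", "control",
        )
        assert out["wilcoxon_p"] < 0.01
        assert out["median_shift_cpm"] > 0

    def test_disjoint_gene_set_errors(self):
        counts = pd.DataFrame({"a": [1], "b": [2]}, index=["g1"])
        groups = pd.Series(["x", "y"], index=["a", "b"])
        with pytest.raises(ValueError, match="intersect"):
            gene_set_expression_summary(CountMatrix(counts), ["nope"], groups, "x", "y")


class TestCountSimulator:
    def test_dimensions(self):
        spec = CountSimSpec(n_genes=100, group_sizes={"a": 4, "b": 6}, seed=0)
        matrix, truth = generate_count_matrix(spec)
        assert matrix.counts.shape == (100, 10)
        assert len(truth) == 100

    def test_null_truth_all_zero(self):
        spec = CountSimSpec(n_genes=50, seed=1)
        _, truth = generate_count_matrix(spec)
        assert (truth["planted_log2fc"] == 0).all()

    def test_planted_lfc_recovered_from_group_means(self):
        spec = CountSimSpec(
            n_genes=500, group_sizes={"control": 50, "case": 50},
            de_genes={"gene00005": 3.0}, seed=21,
        )
        matrix, _ = generate_count_matrix(spec)
        cpm = matrix.cpm()
        groups = matrix.unit_meta["group"]
        est = np.log2(
            cpm.loc["gene00005", groups[groups == "case"].index].mean()
            / cpm.loc["gene00005", groups[groups == "control"].index].mean()
        )
        assert est == pytest.approx(3.0, abs=0.5)

    def test_mtx_round_trip(self, tmp_path):
        spec = CountSimSpec(n_genes=40, seed=2)
        matrix, _ = generate_count_matrix(spec)
        matrix.to_mtx(tmp_path / "m")
        back = CountMatrix.from_mtx(tmp_path / "m")
        np.testing.assert_array_equal(back.counts.to_numpy(), matrix.counts.to_numpy())


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_junction_simulator_deterministic(seed):
    t1 = generate_junctions(1000, 0.6, seed=seed)
    t2 = generate_junctions(1000, 0.6, seed=seed)
    assert t1.equals(t2)
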