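import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromdyn import single_cell as sc

TRAJECTORY_SEED = 3  # a fixed study realization for trajectory-level checks


class TestQC:
    def test_identical_cells_all_pass(self):
        counts = pd.DataFrame(np.full((20, 5), 3))
        assert sc.qc_cells(counts).all()

    def test_tenfold_library_cell_fails_high_end(self):
        counts = pd.DataFrame(np.full((100, 20), 5.0))
        rng = np.random.default_rng(0)
        counts += rng.uniform(0, 0.5, size=counts.shape)  # break MAD degeneracy
        counts.iloc[0] *= 10
        qc = sc.qc_cells(counts)
        assert not qc.iloc[0]
        assert qc.iloc[1:].all()

    def test_planted_outliers_recovered_exactly(self, single_cells):
        qc = sc.qc_cells(single_cells.counts)
        truth = single_cells.cells["outlier_type"] != "none"
        assert ((~qc) == truth).all()

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            sc.qc_cells(pd.DataFrame(np.ones((5, 5))))


class TestFilterGenes:
    def test_mean_exactly_at_threshold_kept(self):
        counts = pd.DataFrame({"g1": [1] + [0] * 19, "g2": [0] * 20})
        kept = sc.filter_genes(counts, min_mean=0.05)
        assert list(kept) == ["g1"]

    def test_zero_threshold_keeps_everything(self):
        counts = pd.DataFrame({"g1": [0, 0], "g2": [0, 1]})
        assert len(sc.filter_genes(counts, min_mean=0.0)) == 2


class TestNormalize:
    def test_size_factors_center_to_unity(self, single_cells, sc_processed):
        assert sc_processed["size_factor"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_cpm_rows_sum_to_million(self, sc_processed):
        assert np.allclose(sc_processed["cpm"].sum(axis=1), 1e6)


class TestHVG:
    def test_null_selection_stays_below_fdr(self):
        rng = np.random.default_rng(5)
        mu, phi = 5.0, 0.3
        size = 1 / phi
        counts = rng.negative_binomial(size, size / (size + mu), size=(300, 2000))
        cpm = pd.DataFrame(
            counts / counts.sum(1, keepdims=True) * 1e6,
            columns=[f"g{i}" for i in range(2000)],
        )
        hvgs, _ = sc.hvg_select(cpm)
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert len(hvgs) / 2000 <= 0.05 + 2 * se

    def test_single_inflated_gene_selected(self):
        rng = np.random.default_rng(6)
        base = rng.poisson(20.0, size=(300, 500)).astype(float)
        # one gene with strong extra biological spread across cells
        base[:, 0] *= np.exp(rng.normal(0, 1.2, size=300))
        cpm = pd.DataFrame(base, columns=[f"g{i}" for i in range(500)])
        hvgs, table = sc.hvg_select(cpm)
        assert "g0" in hvgs
        assert table.loc["g0", "biological"] > 0

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            sc.hvg_select(pd.DataFrame(np.ones((30, 10))))


class TestCoexpressionScore:
    def test_empty_gene_set_gives_zero_scores(self):
        binary = pd.DataFrame(np.eye(4, dtype=int), columns=list("abcd"))
        z, _ = sc.coexpression_score(binary, [])
        assert (z == 0).all()

    def test_pooled_mean_zero_sd_one(self, sc_processed, single_cells):
        uni = single_cells.universe
        members = [
            g
            for g in uni.index[(uni["regulon"] == 0) & ~uni["is_driver"]]
            if g in sc_processed["binary"].columns
        ]
        z, _ = sc.coexpression_score(sc_processed["binary"], members)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_two_cell_closed_form_population_sd(self):
        binary = pd.DataFrame([[0, 0, 0, 0], [1, 1, 1, 1]], columns=list("abcd"))
        z, _ = sc.coexpression_score(binary, list("abcd"))
        assert np.allclose(z.to_numpy(), [-1.0, 1.0])
        # with two cells at s=(0,4): (s - 2)/2 under population sd
        assert z.iloc[1] == pytest.approx((4 - 2) / 2)

    def test_constant_scores_warn_and_zero(self):
        binary = pd.DataFrame(np.ones((5, 2), dtype=int), columns=["a", "b"])
        with pytest.warns(UserWarning):
            z, _ = sc.coexpression_score(binary, ["a", "b"])
        assert (z == 0).all()

    def test_condition_summary_reports_each_level(self):
        binary = pd.DataFrame(np.eye(6, dtype=int)[:, :3], columns=list("abc"))
        cond = pd.Series(["x", "x", "x", "y", "y", "y"], index=binary.index)
        _, summary = sc.coexpression_score(binary, list("abc"), condition=cond)
        assert set(summary.index) == {"x", "y"}


class TestJSI:
    def test_identical_vectors_give_one(self):
        binary = pd.DataFrame({"a": [1, 0, 1], "b": [1, 0, 1]})
        m = sc.jsi_matrix(binary, ["a", "b"])
        assert m.values.loc["a", "b"] == pytest.approx(1.0)

    def test_disjoint_vectors_give_zero(self):
        binary = pd.DataFrame({"a": [1, 0, 0], "b": [0, 1, 1]})
        m = sc.jsi_matrix(binary, ["a", "b"])
        assert m.values.loc["a", "b"] == pytest.approx(0.0)

    def test_half_overlap_gives_three_quarters(self):
        # overlap 1 of union 2: JD = 0.5, JSI = 1 - 0.25
        binary = pd.DataFrame({"a": [1, 1, 0], "b": [1, 0, 0]})
        m = sc.jsi_matrix(binary, ["a", "b"])
        assert m.values.loc["a", "b"] == pytest.approx(0.75)

    def test_empty_union_flagged_and_zero(self):
        binary = pd.DataFrame({"a": [0, 0], "b": [0, 0]})
        m = sc.jsi_matrix(binary, ["a", "b"])
        assert m.values.loc["a", "b"] == 0.0
        assert ("a", "b") in m.flagged or ("a", "a") in m.flagged

    def test_reference_order_is_pure_permutation(self):
        rng = np.random.default_rng(0)
        binary = pd.DataFrame(
            rng.integers(0, 2, size=(30, 5)), columns=list("abcde")
        )
        ref = sc.jsi_matrix(binary, list("abcde"))
        reordered = sc.jsi_matrix(binary, list("abcde"), reference_order=ref.order)
        assert reordered.values.equals(ref.values)
        other = sc.jsi_matrix(binary, list("abcde"), reference_order=list("edcba"))
        assert other.values.loc["b", "d"] == ref.values.loc["b", "d"]

    def test_matrix_symmetric(self):
        rng = np.random.default_rng(1)
        binary = pd.DataFrame(rng.integers(0, 2, size=(40, 6)),
                              columns=[f"g{i}" for i in range(6)])
        m = sc.jsi_matrix(binary, list(binary.columns)).values
        assert np.allclose(m.to_numpy(), m.to_numpy().T)


class TestMCC:
    def test_identical_vectors_give_one(self):
        binary = pd.DataFrame({"a": [1, 0, 1, 0], "b": [1, 0, 1, 0]})
        m = sc.mcc_matrix(binary, ["a", "b"])
        assert m.values.loc["a", "b"] == pytest.approx(1.0)

    def test_complementary_vectors_give_minus_one(self):
        binary = pd.DataFrame({"a": [1, 0, 1, 0], "b": [0, 1, 0, 1]})
        m = sc.mcc_matrix(binary, ["a", "b"])
        assert m.values.loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_margin_defined_as_zero_and_flagged(self):
        binary = pd.DataFrame({"a": [1, 1, 1], "b": [1, 0, 1]})
        m = sc.mcc_matrix(binary, ["a", "b"])
        assert m.values.loc["a", "b"] == 0.0
        assert any(g == "a" for g, _ in m.flagged)

    def test_equals_pearson_of_binary_vectors(self):
        rng = np.random.default_rng(2)
        binary = pd.DataFrame(rng.integers(0, 2, size=(30, 4)), columns=list("abcd"))
        m = sc.mcc_matrix(binary, list("abcd")).values
        for i in "abcd":
            for j in "abcd":
                r = np.corrcoef(binary[i], binary[j])[0, 1]
                assert m.loc[i, j] == pytest.approx(r, abs=1e-12)


class TestRegulonAUC:
    def _cpm(self, order, n_cells=3):
        # expression descending along `order`
        G = len(order)
        rows = {g: float(G - i) for i, g in enumerate(order)}
        return pd.DataFrame([rows] * n_cells)

    def test_regulon_at_top_gives_auc_one(self):
        genes = [f"g{i}" for i in range(40)]
        cpm = self._cpm(genes)
        res = sc.regulon_auc(cpm, genes[:2], top_fraction=0.05, seed=0)
        assert np.allclose(res["auc"], 1.0)

    def test_regulon_outside_top_fraction_gives_zero(self):
        genes = [f"g{i}" for i in range(40)]
        cpm = self._cpm(genes)
        res = sc.regulon_auc(cpm, genes[-3:], top_fraction=0.05, seed=0)
        assert np.allclose(res["auc"], 0.0)

    def test_matches_exhaustive_rank_walk(self):
        # 20 genes, regulon of 3, top fraction 0.25 -> K = 5
        genes = [f"g{i}" for i in range(20)]
        expr = {g: float(20 - i) for i, g in enumerate(genes)}
        cpm = pd.DataFrame([expr])
        regulon = ["g1", "g3", "g7"]
        res = sc.regulon_auc(cpm, regulon, top_fraction=0.25, seed=0)
        # recovery curve over k=1..5: hits at ranks 2 and 4 -> [0,1,1,2,2]
        curve = [0, 1, 1, 2, 2]
        max_curve = [1, 2, 3, 3, 3]
        assert res["auc"].iloc[0] == pytest.approx(sum(curve) / sum(max_curve))

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        cpm = pd.DataFrame(rng.uniform(0.1, 100, size=(20, 50)),
                           columns=[f"g{i}" for i in range(50)])
        regulon = [f"g{i}" for i in range(0, 50, 7)]
        a = sc.regulon_auc(cpm, regulon, seed=1)["auc"]
        b = sc.regulon_auc(np.log1p(cpm) ** 2, regulon, seed=1)["auc"]
        assert np.allclose(a, b)

    def test_missing_regulon_rejected(self):
        cpm = pd.DataFrame(np.ones((5, 10)), columns=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError):
            sc.regulon_auc(cpm, ["absent"], seed=0)


class TestPseudotime:
    def _study(self):
        from chromdyn.synthetic import SimulationConfig, simulate_single_cells

        cfg = SimulationConfig(seed=TRAJECTORY_SEED)
        sim = simulate_single_cells(cfg)
        qc = sc.qc_cells(sim.counts)
        kept = sc.filter_genes(sim.counts, qc)
        _, cpm = sc.normalize_cells(sim.counts[kept], qc)
        hvgs, _ = sc.hvg_select(cpm)
        cond = sim.cells["condition"].loc[cpm.index]
        return sim, cpm, list(hvgs), cond, kept

    def test_recovers_planted_gradient(self):
        sim, cpm, hvgs, cond, _ = self._study()
        pt = sc.pseudotime_rank(cpm, hvgs, condition=cond)
        rho = stats.spearmanr(pt, sim.cells["t_true"].loc[pt.index]).statistic
        assert rho >= 0.9

    def test_invariant_to_cell_order(self):
        sim, cpm, hvgs, cond, _ = self._study()
        order = ["esc", "d1", "d2"]
        pt = sc.pseudotime_rank(cpm, hvgs, condition=cond, condition_order=order)
        perm = cpm.sample(frac=1.0, random_state=0).index
        pt2 = sc.pseudotime_rank(
            cpm.loc[perm], hvgs, condition=cond.loc[perm], condition_order=order
        )
        assert np.allclose(pt.loc[perm].to_numpy(), pt2.to_numpy(), atol=1e-8)

    def test_later_condition_has_higher_mean_pseudotime(self):
        sim, cpm, hvgs, cond, _ = self._study()
        pt = sc.pseudotime_rank(cpm, hvgs, condition=cond)
        means = pt.groupby(cond).mean()
        assert means["esc"] < means["d1"] < means["d2"]

    def test_degenerate_variance_rejected(self):
        cpm = pd.DataFrame(np.ones((20, 5)), columns=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError):
            sc.pseudotime_rank(cpm, [f"g{i}" for i in range(5)])


class TestRegulonTrajectory:
    def test_driver_strata_separate_planted_program(self):
        from chromdyn.synthetic import SimulationConfig, simulate_single_cells

        cfg = SimulationConfig(seed=TRAJECTORY_SEED)
        sim = simulate_single_cells(cfg)
        qc = sc.qc_cells(sim.counts)
        kept = sc.filter_genes(sim.counts, qc)
        _, cpm = sc.normalize_cells(sim.counts[kept], qc)
        hvgs, _ = sc.hvg_select(cpm)
        cond = sim.cells["condition"].loc[cpm.index]
        pt = sc.pseudotime_rank(cpm, list(hvgs), condition=cond)
        uni = sim.universe
        members = [g for g in uni.index[(uni["regulon"] == 0) & ~uni["is_driver"]]
                   if g in kept]
        driver = uni.index[(uni["regulon"] == 0) & uni["is_driver"]][0]
        binary = (sim.counts.loc[cpm.index, kept] > 0).astype(np.int8)
        traj = sc.regulon_trajectory(binary, members, pt, driver)
        pos = traj[traj["driver_positive"]]
        neg = traj[~traj["driver_positive"]]
        rho_pos = stats.spearmanr(pos["pseudotime"], pos["fraction"]).statistic
        rho_neg = stats.spearmanr(neg["pseudotime"], neg["fraction"]).statistic
        assert rho_pos >= 0.5
        assert abs(rho_neg) < 0.2

    def test_fully_detected_regulon_gives_fraction_one(self):
        binary = pd.DataFrame(np.ones((12, 3), dtype=int), columns=list("abc"))
        pt = pd.Series(np.linspace(0, 1, 12), index=binary.index)
        traj = sc.regulon_trajectory(binary, list("abc"), pt, pd.Series(True, index=binary.index))
        assert (traj["fraction"] == 1.0).all()

    def test_empty_stratum_is_not_an_error(self):
        binary = pd.DataFrame(np.ones((12, 3), dtype=int), columns=list("abc"))
        pt = pd.Series(np.linspace(0, 1, 12), index=binary.index)
        traj = sc.regulon_trajectory(
            binary, list("abc"), pt, pd.Series(False, index=binary.index)
        )
        assert traj[traj["driver_positive"]].empty


class TestPseudobulk:
    def test_counts_sum_per_condition(self):
        counts = pd.DataFrame({"g": [3, 4, 10]}, index=["c1", "c2", "c3"])
        cond = pd.Series(["a", "a", "b"], index=counts.index)
        bulk = sc.pseudobulk(counts, cond)
        assert bulk.counts.loc["g", "a"] == 7
        assert bulk.counts.loc["g", "b"] == 10

    def test_column_sums_conserve_reads(self, single_cells, sc_processed):
        qc = sc_processed["qc"]
        bulk = sc.pseudobulk(single_cells.counts, single_cells.cells["condition"], qc)
        total = single_cells.counts.loc[qc[qc].index].to_numpy().sum()
        assert bulk.counts.to_numpy().sum() == total

    def test_condition_without_cells_rejected(self):
        counts = pd.DataFrame({"g": [3, 4]}, index=["c1", "c2"])
        cond = pd.Series(["a", "a"], index=counts.index)
        qc = pd.Series([True, True], index=counts.index)
        full_cond = pd.Series(["a", "a", "b"], index=["c1", "c2", "c3"])
        with pytest.raises(ValueError):
            sc.pseudobulk(counts, full_cond, qc)
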