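"""Signed network, TOM, module detection, eigengenes, kME and hubs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from embryolnc import coexpr
from embryolnc.simdata import SimConfig, simulate_all


def tom_triple_loop(adj):
    """Independent oracle: literal triple-loop topological overlap."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    n = len(a)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (L + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def expr_frame(X, prefix="g"):
    return pd.DataFrame(X, index=[f"{prefix}{i}" for i in range(len(X))],
                        columns=[f"s{j}" for j in range(X.shape[1])])


class TestStageSpecificGenes:
    def test_identical_distributions_not_flagged(self, sim_bundle):
        truth = sim_bundle["truth"]
        de = coexpr.stage_specific_genes(sim_bundle["matrix"],
                                         sim_bundle["sheet"])
        flagged = set(coexpr.stage_specific_set(de))
        pair_genes = {g for p in truth.planted_pairs
                      for g in (p.gene_a, p.gene_b)}
        flat = [g for g, a in truth.gene_archetype.items()
                if a == "flat" and g not in pair_genes]
        false_pos = sum(g in flagged for g in flat) / len(flat)
        assert false_pos <= 0.05

    def test_planted_specific_genes_flagged(self, sim_bundle):
        truth = sim_bundle["truth"]
        de = coexpr.stage_specific_genes(sim_bundle["matrix"],
                                         sim_bundle["sheet"])
        flagged = set(coexpr.stage_specific_set(de))
        spec = [g for g, a in truth.gene_archetype.items()
                if a.startswith("stage_specific")]
        assert sum(g in flagged for g in spec) / len(spec) >= 0.95

    def test_zero_variance_step_change(self):
        # 10 -> 100 FPKM with no within-stage variance: fold change is
        # log2(101/11) and the gene must be flagged
        sheet = pd.DataFrame({"cell_id": ["a1", "a2", "b1", "b2"],
                              "stage": ["s1", "s1", "s2", "s2"]})
        m = pd.DataFrame({"a1": [10.0], "a2": [10.0],
                          "b1": [100.0], "b2": [100.0]}, index=["g0"])
        de = coexpr.stage_specific_genes(m, sheet)
        row = de.iloc[0]
        assert row.log2_fc == pytest.approx(np.log2(101 / 11))
        assert row.q_value < 0.01 and row.is_stage_specific

    def test_single_cell_stage_skipped(self):
        sheet = pd.DataFrame({"cell_id": ["a1", "b1", "b2"],
                              "stage": ["s1", "s2", "s2"]})
        m = pd.DataFrame({"a1": [1.0], "b1": [5.0], "b2": [6.0]}, index=["g0"])
        de = coexpr.stage_specific_genes(m, sheet)
        assert de.empty


class TestSoftThreshold:
    def test_override_returned_unchanged(self, rng):
        cor = np.corrcoef(rng.normal(size=(10, 20)))
        beta, _ = coexpr.pick_soft_threshold(cor, beta_override=5)
        assert beta == 5.0

    def test_zero_target_gives_smallest_candidate(self, rng):
        cor = np.corrcoef(rng.normal(size=(30, 20)))
        beta, _ = coexpr.pick_soft_threshold(cor, r2_target=0.0)
        assert beta == 1.0

    def test_power_law_degree_sequence_fits_well(self, rng):
        # hub-and-spoke-ish correlation structure gives a heavy-tailed
        # degree distribution whose log-log fit should be strong
        n = 120
        latent = rng.normal(size=(3, 60))
        X = np.vstack([latent[i % 3] * rng.uniform(0.3, 1.0)
                       + rng.normal(scale=rng.uniform(0.2, 3.0), size=60)
                       for i in range(n)])
        beta, fits = coexpr.pick_soft_threshold(np.corrcoef(X), r2_target=0.8)
        assert (fits.r2 <= 1.0).all()
        assert fits.r2.max() >= 0.5


class TestBuildNetwork:
    def test_two_gene_tom_equals_adjacency(self, rng):
        X = rng.normal(size=(2, 10))
        net = coexpr.build_network(expr_frame(X), beta=5)
        a = net.adjacency[0, 1]
        assert net.tom[0, 1] == pytest.approx(a, abs=1e-12)

    def test_perfect_correlation_gives_all_ones(self):
        base = np.arange(10, dtype=float)
        X = np.vstack([base, 2 * base + 1, 0.5 * base])
        net = coexpr.build_network(expr_frame(X), beta=5)
        np.testing.assert_allclose(net.adjacency, 1.0, atol=1e-12)
        np.testing.assert_allclose(net.tom, 1.0, atol=1e-12)

    def test_tom_matches_triple_loop_oracle(self, rng):
        for n in (4, 6, 12, 20):
            X = rng.normal(size=(n, 15))
            net = coexpr.build_network(expr_frame(X), beta=3)
            np.testing.assert_allclose(net.tom, tom_triple_loop(net.adjacency),
                                       atol=1e-12)

    def test_tom_bounds_symmetry_diagonal(self, rng):
        X = rng.normal(size=(15, 12))
        net = coexpr.build_network(expr_frame(X), beta=5)
        assert np.all(net.adjacency >= 0) and np.all(net.adjacency <= 1)
        assert np.all(net.tom >= -1e-12) and np.all(net.tom <= 1 + 1e-12)
        np.testing.assert_allclose(net.tom, net.tom.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(net.tom), 1.0)

    def test_constant_gene_errors_with_name(self):
        X = np.vstack([np.arange(8.0), np.full(8, 3.0), np.arange(8.0) ** 2])
        with pytest.raises(ValueError, match="g1"):
            coexpr.build_network(expr_frame(X), beta=5)


class TestModules:
    def two_block_frame(self, rng, cross_noise=0.0):
        base1, base2 = rng.normal(size=(2, 20))
        rows = [base1 * rng.uniform(0.5, 1.5) for _ in range(35)]
        rows += [base2 * rng.uniform(0.5, 1.5) for _ in range(35)]
        X = np.array(rows)
        if cross_noise:
            X = X + rng.normal(scale=cross_noise, size=X.shape)
        return expr_frame(X)

    def test_two_perfect_blocks_recovered(self, rng):
        expr = self.two_block_frame(rng, cross_noise=0.05)
        net = coexpr.build_network(expr, beta=5)
        mods = coexpr.detect_modules(net, expr, min_module_size=10)
        labels = mods.assignment
        first = set(labels.iloc[:35]) ; second = set(labels.iloc[35:])
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_highly_correlated_modules_merged(self, rng):
        base = rng.normal(size=20)
        rows = [base + rng.normal(scale=0.05, size=20) for _ in range(30)]
        rows += [base + rng.normal(scale=0.05, size=20) for _ in range(30)]
        expr = expr_frame(np.array(rows))
        net = coexpr.build_network(expr, beta=5)
        mods = coexpr.detect_modules(net, expr, min_module_size=10,
                                     merge_cor=0.85)
        assert len(mods.modules) == 1

    def test_merging_terminates_below_cutoff(self, rng):
        expr = self.two_block_frame(rng, cross_noise=0.3)
        net = coexpr.build_network(expr, beta=5)
        mods = coexpr.detect_modules(net, expr, min_module_size=10)
        me = mods.eigengenes.to_numpy().T
        if len(me) > 1:
            C = np.corrcoef(me)
            np.fill_diagonal(C, 0.0)
            assert C.max() <= 0.85 + 1e-9

    def test_planted_modules_recovered_across_seeds(self):
        aris = []
        for seed in range(5):
            cfg = SimConfig(seed=seed)
            ann, truth, matrix, sheet, _ = simulate_all(cfg)
            expr = np.log10(matrix + 1.0)
            de = coexpr.stage_specific_genes(matrix, sheet)
            genes = [g for g in coexpr.stage_specific_set(de)
                     if expr.loc[g].std() > 0]
            sub = expr.loc[genes]
            net = coexpr.build_network(sub, beta=5)
            mods = coexpr.detect_modules(net, sub, min_module_size=30)
            planted = {g: m for m, gs in truth.planted_modules.items()
                       for g in gs}
            pg = [g for g in planted if g in sub.index]
            aris.append(adjusted_rand_score(
                [planted[g] for g in pg],
                [mods.assignment.get(g, "grey") for g in pg]))
        assert min(aris) >= 0.9


class TestTraitsAndHubs:
    @staticmethod
    def modset_from(expr, min_module_size=5):
        net = coexpr.build_network(expr, beta=5)
        return net, coexpr.detect_modules(net, expr,
                                          min_module_size=min_module_size)

    def test_eigengene_unit_variance_and_sign(self, rng):
        base = rng.normal(size=20)
        rows = [base * rng.uniform(0.5, 1.5) + rng.normal(scale=0.1, size=20)
                for _ in range(12)]
        me = coexpr.module_eigengene(expr_frame(np.array(rows)))
        assert me.std() == pytest.approx(1.0)
        cors = [np.corrcoef(r, me)[0, 1] for r in rows]
        assert np.mean(cors) > 0

    def test_module_trait_closed_form(self, rng):
        x = rng.normal(size=6)
        y = 0.6 * x + rng.normal(scale=0.5, size=6)
        r = float(np.corrcoef(x, y)[0, 1])
        from embryolnc.coexpr import _cor_p
        from scipy import stats as st
        t = r * np.sqrt(4 / (1 - r * r))
        assert _cor_p(r, 6) == pytest.approx(2 * st.t.sf(abs(t), df=4))

    def test_eigengene_equal_to_stage_indicator(self, rng):
        sheet = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(12)],
            "stage": ["s1"] * 6 + ["s2"] * 6})
        traits = coexpr.stage_trait_table(sheet, ["s1", "s2"])
        ind = traits["s1"].to_numpy()
        rows = [ind * sc + rng.normal(scale=1e-6, size=12)
                for sc in rng.uniform(0.5, 2.0, size=8)]
        expr = pd.DataFrame(np.array(rows),
                            index=[f"g{i}" for i in range(8)],
                            columns=sheet.cell_id)
        net, mods = self.modset_from(expr)
        mods = coexpr.module_trait(mods, traits)
        assert abs(mods.trait_cor.iloc[0]["s1"]) == pytest.approx(1.0, abs=1e-3)

    def test_kme_of_proportional_gene_is_one(self, rng):
        base = rng.normal(size=15)
        rows = [base * s for s in rng.uniform(0.5, 2.0, size=10)]
        rows.append(-base)  # anti-correlated gene
        expr = expr_frame(np.array(rows))
        net, mods = self.modset_from(expr)
        mods = coexpr.kme_and_hubs(expr, mods, hub_kme=0.9)
        mod = mods.eigengenes.columns[0]
        assert mods.kme.loc["g0", mod] == pytest.approx(1.0, abs=1e-9)
        assert mods.kme.loc["g10", mod] == pytest.approx(-1.0, abs=1e-9)
        assert "g0" in mods.hubs[mod] and "g10" not in mods.hubs[mod]

    def test_kme_matches_direct_correlation(self, rng):
        X = rng.normal(size=(10, 12))
        expr = expr_frame(X)
        net, mods = self.modset_from(expr, min_module_size=3)
        if not len(mods.eigengenes.columns):
            pytest.skip("no module formed on random data")
        mods = coexpr.kme_and_hubs(expr, mods)
        mod = mods.eigengenes.columns[0]
        me = mods.eigengenes[mod].to_numpy()
        for g in expr.index:
            direct = np.corrcoef(expr.loc[g], me)[0, 1]
            assert mods.kme.loc[g, mod] == pytest.approx(direct, abs=1e-10)

    def test_sign_flip_consistency(self, rng):
        base = rng.normal(size=15)
        rows = [base * s + rng.normal(scale=0.05, size=15)
                for s in rng.uniform(0.5, 2.0, size=10)]
        expr = expr_frame(np.array(rows))
        net, mods = self.modset_from(expr)
        mods = coexpr.kme_and_hubs(expr, mods)
        mod = mods.eigengenes.columns[0]
        own = mods.kme.loc[[g for g in expr.index
                            if mods.assignment[g] == mod], mod]
        assert own.mean() > 0


class TestHubEdgesAndInteractions:
    def make_net(self, rng):
        X = rng.normal(size=(6, 10))
        return coexpr.build_network(expr_frame(X), beta=2)

    def test_cutoff_above_all_weights_empty(self, rng):
        net = self.make_net(rng)
        assert coexpr.hub_edges(net, net.genes, weight_cutoff=1.1).empty

    def test_cutoff_zero_gives_complete_graph(self, rng):
        net = self.make_net(rng)
        edges = coexpr.hub_edges(net, net.genes, weight_cutoff=0.0)
        assert len(edges) == 15  # C(6,2)

    def test_three_hubs_at_half(self):
        X = np.vstack([np.arange(10.0), 2 * np.arange(10.0),
                       3 * np.arange(10.0)])
        net = coexpr.build_network(expr_frame(X), beta=5)
        edges = coexpr.hub_edges(net, net.genes, weight_cutoff=0.5)
        assert len(edges) == 3

    @pytest.mark.parametrize("ndg,kept", [(-0.1, True), (-0.05, False),
                                          (-0.5, True), (0.2, False)])
    def test_interaction_cutoff_boundary(self, ndg, kept):
        table = pd.DataFrame({"lnc_id": ["l1"], "gene_id": ["g1"],
                              "ndG": [ndg]})
        out = coexpr.filter_interactions(table)
        assert (len(out) == 1) is kept

    def test_interaction_row_tally(self, rng):
        vals = np.round(rng.uniform(-0.3, 0.1, size=10), 3)
        table = pd.DataFrame({"lnc_id": [f"l{i}" for i in range(10)],
                              "gene_id": [f"g{i}" for i in range(10)],
                              "ndG": vals})
        out = coexpr.filter_interactions(table)
        assert len(out) == int((vals <= -0.1).sum())

    def test_non_numeric_ndg_errors_with_row(self):
        table = pd.DataFrame({"lnc_id": ["l1", "l2"], "gene_id": ["g1", "g2"],
                              "ndG": [-0.2, "oops"]})
        with pytest.raises(ValueError, match="row 1"):
            coexpr.filter_interactions(table)
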