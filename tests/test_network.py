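"""rWGCNA core: correlations, soft power, TOM, tree cutting, consensus."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from coexmod import (PipelineConfig, adjacency, compute_kim, consensus_modules,
                     detect_modules, merge_modules, module_eigengene,
                     pairwise_correlation, pick_soft_power, qc_modules,
                     tom_similarity)
from coexmod.io import ExpressionMatrix
from coexmod.network import _scale_free_r2


def _expr(vals, layer="scaled"):
    n_genes, n_obs = vals.shape
    return ExpressionMatrix(vals, [f"g{i:03d}" for i in range(n_genes)],
                            [f"c{i}" for i in range(n_obs)], layer_tag=layer)


def _random_adjacency(rng, n=15):
    a = rng.uniform(0, 1, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


def tom_bruteforce(adj):
    """O(n^3) reference implementation of the topological overlap matrix."""
    n = adj.shape[0]
    k = adj.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(adj[i, u] * adj[u, j] for u in range(n))
            out[i, j] = (shared + adj[i, j]) / (min(k[i], k[j]) + 1 - adj[i, j])
    return out


class TestPairwiseCorrelation:
    def test_matches_textbook_formula(self, rng):
        X = rng.normal(0, 1, (10, 50))
        corr = pairwise_correlation(_expr(X))
        np.testing.assert_allclose(corr, np.corrcoef(X), atol=1e-12)

    def test_duplicate_and_negated_gene(self, rng):
        X = rng.normal(0, 1, (3, 40))
        X[1] = X[0]
        X[2] = -X[0]
        corr = pairwise_correlation(_expr(X))
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)

    def test_zero_variance_gene_zeroed(self, rng):
        X = rng.normal(0, 1, (4, 40))
        X[2] = 3.14
        corr = pairwise_correlation(_expr(X))
        assert np.all(corr[2] == 0) and np.all(corr[:, 2] == 0)

    def test_spearman_is_rank_pearson(self, rng):
        X = rng.normal(0, 1, (6, 45))
        from scipy.stats import rankdata, spearmanr
        corr = pairwise_correlation(_expr(X), method="spearman")
        expected = spearmanr(X, axis=1).statistic
        np.testing.assert_allclose(corr, expected, atol=1e-12)

    def test_too_few_observations(self, rng):
        with pytest.raises(ValueError, match="30 observations"):
            pairwise_correlation(_expr(rng.normal(0, 1, (5, 20))))


class TestAdjacency:
    def test_arithmetic_cases(self):
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert adjacency(corr, 2, "unsigned")[0, 1] == pytest.approx(0.25)
        neg = np.array([[1.0, -0.5], [-0.5, 1.0]])
        assert adjacency(neg, 2, "signed-hybrid")[0, 1] == 0.0
        assert adjacency(neg, 2, "unsigned")[0, 1] == pytest.approx(0.25)

    def test_elementwise_formula_oracle(self, rng):
        corr = np.clip(rng.uniform(-1, 1, (8, 8)), -1, 1)
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        adj = adjacency(corr, 3, "unsigned")
        expected = np.abs(corr) ** 3
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(adj, expected, atol=1e-14)

    def test_mean_adjacency_nonincreasing_in_power(self, rng):
        corr = np.corrcoef(rng.normal(0, 1, (12, 60)))
        means = [adjacency(corr, b, "unsigned").mean() for b in range(1, 10)]
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_unknown_type(self):
        with pytest.raises(ValueError, match="network_type"):
            adjacency(np.eye(2), 2, "bogus")


class TestSoftPower:
    def test_exact_power_law_scores_one(self):
        # degrees placed at bin centres with counts following an exact power
        # law across bins -> signed fit approaches 1
        edges = np.linspace(10.0, 110.0, 11)
        centres = (edges[:-1] + edges[1:]) / 2
        counts = np.round(1e7 * centres ** -2.0).astype(int)
        k = np.repeat(centres, counts)
        assert _scale_free_r2(k) == pytest.approx(1.0, abs=1e-3)

    def test_target_zero_picks_smallest_power(self, rng):
        corr = np.corrcoef(rng.normal(0, 1, (20, 80)))
        fit = pick_soft_power(corr, powers=range(1, 8), r2_target=-10,
                              network_type="unsigned")
        assert fit.chosen_power == 1

    def test_r2_matches_independent_histogram_regression(self, rng):
        # correlated data via latent factor
        f = rng.normal(0, 1, 100)
        X = np.outer(rng.uniform(0.5, 1.5, 30), f) + rng.normal(0, 1, (30, 100))
        corr = np.corrcoef(X)
        fit = pick_soft_power(corr, powers=[2, 4, 6],
                              network_type="unsigned")
        for beta, got in zip(fit.powers, fit.r_squared):
            k = (np.abs(corr) ** beta).sum(axis=1) - 1.0  # exclude self
            k = k[k > 0]
            edges = np.linspace(k.min(), k.max(), 11)
            which = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
            xs, ys = [], []
            for b in range(10):
                sel = which == b
                if sel.sum():
                    xs.append(np.log10(k[sel].mean()))
                    ys.append(np.log10(sel.mean()))
            slope, icpt = np.polyfit(xs, ys, 1)
            resid = np.array(ys) - (slope * np.array(xs) + icpt)
            r2 = 1 - resid @ resid / ((np.array(ys) - np.mean(ys)) ** 2).sum()
            assert got == pytest.approx(-np.sign(slope) * r2, abs=1e-10)

    def test_mean_connectivity_decreasing(self, rng):
        corr = np.corrcoef(rng.normal(0, 1, (15, 60)))
        fit = pick_soft_power(corr, powers=range(1, 10),
                              network_type="unsigned")
        assert all(a > b for a, b in
                   zip(fit.mean_connectivity, fit.mean_connectivity[1:]))


class TestTom:
    def test_hand_evaluated_triangles(self):
        ones = np.ones((3, 3)) - np.eye(3)
        tom = tom_similarity(ones)
        assert tom[0, 1] == pytest.approx(1.0)  # (1+1)/(2+1-1)
        halves = np.full((3, 3), 0.5) - np.diag([0.5] * 3)
        tom = tom_similarity(halves)
        assert tom[0, 1] == pytest.approx(0.5)  # (0.25+0.5)/(1+1-0.5)

    def test_matches_bruteforce_oracle(self, rng):
        adj = _random_adjacency(rng)
        np.testing.assert_allclose(tom_similarity(adj), tom_bruteforce(adj),
                                   atol=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounds_property(self, seed):
        adj = _random_adjacency(np.random.default_rng(seed), n=10)
        tom = tom_similarity(adj)
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        np.testing.assert_array_equal(np.diag(tom), 1.0)

    def test_invalid_adjacency_rejected(self):
        bad = np.array([[0.0, 1.5], [1.5, 0.0]])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            tom_similarity(bad)


def _block_tom(rng, sizes, within=0.9, noise=0.02):
    n = sum(sizes)
    tom = rng.uniform(0, noise, (n, n))
    tom = (tom + tom.T) / 2
    start = 0
    labels = np.empty(n, dtype=int)
    for b, s in enumerate(sizes):
        tom[start:start + s, start:start + s] = within \
            + rng.uniform(-noise, noise, (s, s))
        labels[start:start + s] = b
        start += s
    tom = np.clip((tom + tom.T) / 2, 0, 1)
    np.fill_diagonal(tom, 1.0)
    return tom, labels


class TestDetectModules:
    def test_two_perfect_blocks(self):
        tom = np.zeros((40, 40))
        tom[:20, :20] = 1.0
        tom[20:, 20:] = 1.0
        genes = [f"g{i:02d}" for i in range(40)]
        mset = detect_modules(tom, genes, min_size=10)
        assert sorted(m.size for m in mset.modules) == [20, 20]
        assert {frozenset(m.genes) for m in mset.modules} == {
            frozenset(genes[:20]), frozenset(genes[20:])}

    def test_min_size_above_total_all_background(self, rng):
        tom, _ = _block_tom(rng, [5, 5])
        mset = detect_modules(tom, [f"g{i}" for i in range(10)], min_size=11)
        assert mset.modules == []
        assert len(mset.background_genes) == 10

    def test_three_planted_modules_recovered_from_simulated_tom(self):
        # TOM produced by the pipeline itself on data with 3 planted modules
        from coexmod import (SimConfig, normalize_log, qc_filter_cells,
                             scale_within_batch, simulate_sc_dataset)
        cfg = SimConfig(seed=1, n_genes=300, n_modules_per_type=3,
                        cells_per_donor=100, phenotype_effect_grid={})
        sc, truth = simulate_sc_dataset(cfg)
        logn = normalize_log(qc_filter_cells(sc, min_genes=50))
        scaled = scale_within_batch(logn, logn.obs_meta["donor"].to_numpy())
        corr = pairwise_correlation(scaled)
        fit = pick_soft_power(corr)
        tom = tom_similarity(adjacency(corr, fit.chosen_power))
        mset = detect_modules(tom, scaled.gene_ids, min_size=10,
                              cell_type="T1")
        lab = truth.gene_labels("T1")
        pred = mset.labels(list(lab.index))
        assert adjusted_rand_score(lab.to_numpy(), pred) >= 0.9


class TestEigengene:
    def test_identical_genes_give_standardized_profile(self, rng):
        profile = rng.normal(0, 2, 50)
        X = np.tile(profile, (4, 1))
        eig = module_eigengene(_expr(X), [f"g{i:03d}" for i in range(4)])
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eig, z, atol=1e-8)
        assert np.corrcoef(eig, profile)[0, 1] == pytest.approx(1.0)

    def test_orientation_deterministic_under_sign_flip(self, rng):
        X = rng.normal(0, 1, (6, 60))
        X[0] += 2 * rng.normal(0, 1, 60)  # dominant direction
        genes = [f"g{i:03d}" for i in range(6)]
        a = module_eigengene(_expr(X), genes)
        b = module_eigengene(_expr(-X), genes)
        # orientation follows mean expression, so flipping data flips both
        np.testing.assert_allclose(a, -b, atol=1e-8)

    def test_matches_power_iteration_oracle(self, rng):
        X = rng.normal(0, 1, (8, 70))
        genes = [f"g{i:03d}" for i in range(8)]
        eig = module_eigengene(_expr(X), genes)
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        C = Z.T @ Z
        v = np.ones(70) / np.sqrt(70)
        for _ in range(3000):
            v = C @ v
            v /= np.linalg.norm(v)
        v = v / v.std()
        sign = np.sign(np.dot(eig, v))
        np.testing.assert_allclose(eig, sign * v, atol=1e-6)

    def test_constant_submatrix_rejected(self):
        X = np.full((3, 40), 2.0)
        with pytest.raises(ValueError, match="constant"):
            module_eigengene(_expr(X), ["g000", "g001", "g002"])


class TestKim:
    def test_two_gene_and_perfect_block(self):
        tom = np.array([[1.0, 0.4], [0.4, 1.0]])
        raw, norm = compute_kim(tom, ["a", "b"], ["a", "b"])
        assert raw == {"a": pytest.approx(0.4), "b": pytest.approx(0.4)}
        s = 6
        block = np.ones((s, s))
        genes = [f"g{i}" for i in range(s)]
        raw, norm = compute_kim(block, genes, genes)
        assert all(v == pytest.approx(s - 1) for v in raw.values())
        assert all(v == pytest.approx(1 / s) for v in norm.values())

    def test_rowsum_oracle(self, rng):
        adj = _random_adjacency(rng, 12)
        tom = tom_similarity(adj)
        genes = [f"g{i}" for i in range(12)]
        members = ["g2", "g5", "g7", "g9"]
        raw, _ = compute_kim(tom, genes, members)
        idx = [2, 5, 7, 9]
        for g, i in zip(members, idx):
            expected = sum(tom[i, j] for j in idx if j != i)
            assert raw[g] == pytest.approx(expected, rel=1e-12)

    def test_singleton_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            compute_kim(np.eye(3), ["a", "b", "c"], ["a"])


def _factor_expr(rng, blocks, n_obs=200, factor_sd=2.0, noise=0.5):
    """Scaled expression with latent-factor blocks; returns expr, labels."""
    rows, labels = [], []
    for b, size in enumerate(blocks):
        f = rng.normal(0, factor_sd, n_obs)
        for _ in range(size):
            rows.append(rng.uniform(0.7, 1.3) * f + rng.normal(0, noise, n_obs))
            labels.append(b)
    X = np.array(rows)
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    return _expr(X), np.array(labels)


class TestMergeAndQc:
    def test_identical_eigengene_modules_merged(self, rng):
        expr, _ = _factor_expr(rng, [12], n_obs=150)
        genes = expr.gene_ids
        adj = adjacency(pairwise_correlation(expr), 2)
        tom = tom_similarity(adj)
        from coexmod.network import GeneModule, ModuleSet
        halves = [genes[:6], genes[6:]]
        mods = []
        for i, gs in enumerate(halves):
            raw, norm = compute_kim(tom, genes, gs)
            mods.append(GeneModule(f"M-X-{i+1}", "X", gs, raw, norm))
        mset = ModuleSet(mods, [], {"_tom": tom, "_tom_genes": genes})
        merged = merge_modules(expr, mset, merge_corr=0.85)
        assert len(merged.modules) == 1
        assert sorted(merged.modules[0].genes) == sorted(genes)

    def test_unreachable_merge_threshold_is_identity(self, rng):
        expr, _ = _factor_expr(rng, [8, 8], n_obs=150)
        genes = expr.gene_ids
        tom = tom_similarity(adjacency(pairwise_correlation(expr), 2))
        from coexmod.network import GeneModule, ModuleSet
        mods = []
        for i, gs in enumerate([genes[:8], genes[8:]]):
            raw, norm = compute_kim(tom, genes, gs)
            mods.append(GeneModule(f"M-X-{i+1}", "X", gs, raw, norm))
        mset = ModuleSet(mods, [], {"_tom": tom, "_tom_genes": genes})
        merged = merge_modules(expr, mset, merge_corr=1.01)
        assert {frozenset(m.genes) for m in merged.modules} == \
            {frozenset(genes[:8]), frozenset(genes[8:])}

    def test_qc_drops_noise_module_keeps_planted(self, rng):
        # one coherent factor module, one pure-noise gene set, 500 obs
        expr, _ = _factor_expr(rng, [10], n_obs=500)
        noise = rng.normal(0, 1, (10, 500))
        noise = (noise - noise.mean(axis=1, keepdims=True)) \
            / noise.std(axis=1, keepdims=True)
        X = np.vstack([expr.dense(), noise])
        full = _expr(X)
        genes = full.gene_ids
        tom = tom_similarity(adjacency(np.corrcoef(X), 2))
        from coexmod.network import GeneModule, ModuleSet
        mods = []
        for i, gs in enumerate([genes[:10], genes[10:]]):
            raw, norm = compute_kim(tom, genes, gs)
            mods.append(GeneModule(f"M-X-{i+1}", "X", gs, raw, norm))
        mset = ModuleSet(mods, [], {})
        kept = qc_modules(full, mset, min_size=5, min_mean_kme=0.3)
        assert len(kept.modules) == 1
        assert sorted(kept.modules[0].genes) == sorted(genes[:10])
        # permissive thresholds keep everything
        kept_all = qc_modules(full, mset, min_size=1, min_mean_kme=-1.0)
        assert len(kept_all.modules) == 2


class TestConsensus:
    def test_degenerate_consensus_equals_single_run(self, rng):
        expr, _ = _factor_expr(rng, [15, 15], n_obs=120)
        cfg = PipelineConfig(b_net=1, resample_frac=1.0, min_module_size=5)
        mset = consensus_modules(expr, cfg, cell_type="X")
        # manual single-run pipeline on the full data with the same power
        corr = pairwise_correlation(expr, cfg.corr_method)
        power = mset.provenance["chosen_power"]
        tom = tom_similarity(adjacency(corr, power, cfg.network_type))
        np.testing.assert_allclose(mset.consensus_tom, tom, atol=1e-12)
        single = detect_modules(tom, expr.gene_ids, cfg.min_module_size,
                                cfg.cut_quantile, "X")
        assert {frozenset(m.genes) for m in single.modules} >= \
            {frozenset(m.genes) for m in mset.modules}

    def test_bitwise_reproducibility(self, rng):
        expr, _ = _factor_expr(rng, [12, 12], n_obs=110)
        cfg = PipelineConfig(b_net=5, min_module_size=5)
        a = consensus_modules(expr, cfg, "X", seed=9)
        b = consensus_modules(expr, cfg, "X", seed=9)
        np.testing.assert_array_equal(a.consensus_tom, b.consensus_tom)
        assert [m.genes for m in a.modules] == [m.genes for m in b.modules]
        assert [m.kim for m in a.modules] == [m.kim for m in b.modules]

    def test_consensus_beats_single_subsample(self, rng):
        # planted recovery from the consensus should match or beat a single
        # 50% subsample in most replicates
        wins = 0
        reps = 10
        for r in range(reps):
            rr = np.random.default_rng(100 + r)
            expr, labels = _factor_expr(rr, [15, 15, 15], n_obs=160,
                                        factor_sd=1.0, noise=1.0)
            cfg = PipelineConfig(b_net=8, min_module_size=5)
            cons = consensus_modules(expr, cfg, "X", seed=r)
            ari_cons = adjusted_rand_score(labels, cons.labels(expr.gene_ids))
            cols = rr.choice(expr.n_obs, expr.n_obs // 2, replace=False)
            sub = _expr(expr.dense()[:, np.sort(cols)])
            corr = pairwise_correlation(sub)
            tom = tom_similarity(adjacency(corr,
                                           cons.provenance["chosen_power"]))
            single = detect_modules(tom, expr.gene_ids, cfg.min_module_size,
                                    cfg.cut_quantile, "X")
            ari_single = adjusted_rand_score(labels,
                                             single.labels(expr.gene_ids))
            wins += ari_cons >= ari_single - 1e-12
        assert wins >= 0.8 * reps

    def test_too_few_observations(self, rng):
        expr, _ = _factor_expr(rng, [10], n_obs=50)
        with pytest.raises(ValueError, match="100 observations"):
            consensus_modules(expr, PipelineConfig(), "X")


def test_module_set_json_roundtrip(tmp_path, rng):
    expr, _ = _factor_expr(rng, [10, 10], n_obs=120)
    cfg = PipelineConfig(b_net=2, min_module_size=5)
    mset = consensus_modules(expr, cfg, "X", seed=1)
    mset.to_json(tmp_path / "m.json")
    from coexmod.network import ModuleSet
    back = ModuleSet.from_json(tmp_path / "m.json")
    assert [m.genes for m in back.modules] == [m.genes for m in mset.modules]
    for a, b in zip(back.modules, mset.modules):
        for g in a.genes:
            assert a.kim_normalized[g] == pytest.approx(b.kim_normalized[g],
                                                        abs=1e-9)
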