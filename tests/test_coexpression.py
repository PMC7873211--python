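"""Co-expression network procedure: bicor, outlier screening, module
detection, eigengenes, iterative merging, kME, and module-trait tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from syndromics.containers import ExpressionMatrix
from syndromics.coexpression import (
    NetworkParams,
    bicor,
    bicor_matrix,
    compute_kme,
    detect_modules,
    flag_outlier_samples,
    merge_modules,
    module_eigengene,
    module_trait_test,
)


def expr_from(values, groups=None):
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    if groups is None:
        groups = pd.Series(["x"] * len(samples), index=samples)
    else:
        groups = pd.Series(groups, index=samples)
    return ExpressionMatrix(values=df, groups=groups)


class TestBicor:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(0, 1, 20)
        assert bicor(x, x) == pytest.approx(1.0)

    def test_negation_and_affine_invariance(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        r = bicor(x, y)
        assert bicor(x, -y) == pytest.approx(-r, abs=1e-12)
        assert bicor(3.0 * x + 7.0, y) == pytest.approx(r, abs=1e-12)

    def test_close_to_pearson_on_gaussian(self, rng):
        x = rng.standard_normal(1000)
        y = 0.6 * x + 0.8 * rng.standard_normal(1000)
        assert bicor(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=0.02)

    def test_robust_to_single_gross_outlier(self, rng):
        """One of 100 points moved to 10 sd: bicor barely moves while
        Pearson shifts substantially."""
        x = rng.standard_normal(100)
        y = 0.6 * x + 0.5 * rng.standard_normal(100)
        b0, p0 = bicor(x, y), np.corrcoef(x, y)[0, 1]
        x2 = x.copy()
        x2[int(np.argmin(np.abs(x)))] = 10.0
        assert abs(bicor(x2, y) - b0) < 0.05
        assert abs(np.corrcoef(x2, y)[0, 1] - p0) > 0.2

    def test_zero_mad_falls_back_to_pearson(self, rng, caplog):
        x = np.zeros(11)
        x[0] = 1.0  # median-absolute deviation is 0
        y = rng.normal(0, 1, 11)
        with caplog.at_level("WARNING"):
            r = bicor(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1])
        assert "Pearson" in caplog.text

    def test_constant_vector_undefined(self):
        assert np.isnan(bicor(np.ones(5), np.arange(5.0)))

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounded_and_symmetric(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(0, 1, 12), r.normal(0, 1, 12)
        v = bicor(x, y)
        assert -1.0 <= v <= 1.0
        assert v == pytest.approx(bicor(y, x), abs=1e-12)


class TestBicorMatrix:
    def test_matches_looped_oracle(self, rng):
        X = rng.normal(0, 1, (20, 10))
        M = bicor_matrix(pd.DataFrame(X))
        for i in range(20):
            for j in range(i + 1, 20):
                assert M.iloc[i, j] == pytest.approx(bicor(X[i], X[j]),
                                                     abs=1e-12)

    def test_duplicate_rows_give_unit_offdiagonal(self, rng):
        x = rng.normal(0, 1, 8)
        M = bicor_matrix(pd.DataFrame([x, x]))
        assert M.iloc[0, 1] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self, rng):
        X = rng.normal(0, 1, (15, 6))
        M = bicor_matrix(pd.DataFrame(X)).to_numpy()
        assert np.allclose(M, M.T, atol=1e-12)
        assert np.allclose(np.diag(M), 1.0)


class TestOutlierSamples:
    def test_coherent_samples_not_excluded(self, rng):
        base = rng.normal(8, 2, 200)
        X = base[:, None] + rng.normal(0, 0.3, (200, 8))
        assert flag_outlier_samples(pd.DataFrame(X)) == []

    def test_noise_sample_flagged(self, rng):
        base = rng.normal(8, 2, 300)
        X = base[:, None] + rng.normal(0, 0.3, (300, 10))
        X[:, 4] = rng.normal(8, 2, 300)  # unrelated profile
        df = pd.DataFrame(X, columns=[f"s{j}" for j in range(10)])
        assert flag_outlier_samples(df) == ["s4"]

    def test_infinite_threshold_excludes_nothing(self, rng):
        X = rng.normal(0, 1, (50, 6))
        assert flag_outlier_samples(pd.DataFrame(X), z_cutoff=-np.inf) == []


def planted_expression(seed=0, **overrides):
    from syndromics.de import normalize_counts
    from syndromics.simulate import ExprSimConfig, simulate_expression

    cfg = ExprSimConfig(seed=seed, n_injury_genes=0, n_reversal_genes=0,
                        **overrides)
    counts, groups, truth = simulate_expression(cfg)
    return ExpressionMatrix(normalize_counts(counts), groups), truth


class TestDetectModules:
    def test_small_correlated_block_below_min_size_unassigned(self, rng):
        """11 near-identical genes among independent noise: no module."""
        shared = rng.normal(0, 1, 30)
        block = shared[None, :] + rng.normal(0, 0.01, (11, 30))
        noise = rng.normal(0, 1, (25, 30))
        mods = detect_modules(expr_from(np.vstack([block, noise])),
                              NetworkParams())
        assert mods.module_ids == []
        assert (mods.labels == "unassigned").all()

    def test_planted_modules_detected_pure(self):
        expr, truth = planted_expression(seed=0)
        mods = merge_modules(detect_modules(expr, NetworkParams()), expr, 0.85)
        assert len(mods.module_ids) == 3
        true = pd.Series(truth["module_label"])
        for m in mods.module_ids:
            members = mods.labels.index[mods.labels == m]
            top = true[members].value_counts()
            assert top.iloc[0] / len(members) > 0.9  # near-pure
            assert top.index[0] != "background"

    def test_matches_scipy_complete_linkage_merge_for_merge(self, rng):
        """15-gene toy matrix: agglomeration agrees with a brute-force
        O(n^3) complete-linkage oracle at every merge."""
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        X = rng.normal(0, 1, (15, 8))
        R = bicor_matrix(pd.DataFrame(X))
        D = 1 - R.to_numpy()
        np.fill_diagonal(D, 0.0)

        # brute force: repeatedly merge the pair of clusters with the
        # smallest maximum cross-distance
        clusters = [{i} for i in range(15)]
        merges = []
        while len(clusters) > 1:
            best, best_d = None, np.inf
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    d = max(D[i, j] for i in clusters[a] for j in clusters[b])
                    if d < best_d:
                        best_d, best = d, (a, b)
            a, b = best
            merged = clusters[a] | clusters[b]
            merges.append((frozenset(merged), best_d))
            clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
            clusters.append(merged)

        Z = linkage(squareform(D, checks=False), method="complete")
        live = {i: frozenset([i]) for i in range(15)}
        for step, row in enumerate(Z):
            a, b = int(row[0]), int(row[1])
            merged = live[a] | live[b]
            live[15 + step] = merged
            assert merged == merges[step][0]
            assert row[2] == pytest.approx(merges[step][1], abs=1e-12)

    def test_gene_order_invariance(self):
        expr, _ = planted_expression(seed=1)
        perm = np.random.default_rng(0).permutation(expr.values.shape[0])
        shuffled = ExpressionMatrix(expr.values.iloc[perm], expr.groups)
        m1 = detect_modules(expr, NetworkParams())
        m2 = detect_modules(shuffled, NetworkParams())
        sets1 = sorted(frozenset(m1.labels.index[m1.labels == m])
                       for m in m1.module_ids)
        sets2 = sorted(frozenset(m2.labels.index[m2.labels == m])
                       for m in m2.module_ids)
        assert sets1 == sets2


class TestEigengene:
    def test_identical_profiles_reproduced(self, rng):
        x = rng.normal(0, 1, 6)
        module = pd.DataFrame(np.tile(x, (5, 1)) * rng.uniform(1, 3, (5, 1)))
        eg, ve = module_eigengene(module)
        assert ve == pytest.approx(1.0)
        assert np.corrcoef(eg.to_numpy(), x)[0, 1] == pytest.approx(1.0)

    def test_matches_svd_oracle_with_positive_orientation(self, rng):
        X = rng.normal(0, 1, (12, 6))
        eg, ve = module_eigengene(pd.DataFrame(X))
        Xz = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1,
                                                         keepdims=True)
        U, s, Vt = np.linalg.svd(Xz)
        v = Vt[0] / Vt[0].std(ddof=1)
        assert ve == pytest.approx(s[0] ** 2 / (s ** 2).sum())
        assert (np.allclose(eg.to_numpy(), v, atol=1e-8)
                or np.allclose(eg.to_numpy(), -v, atol=1e-8))
        cors = [np.corrcoef(eg, row)[0, 1] for row in Xz]
        assert np.mean(cors) > 0

    def test_negating_members_negates_eigengene(self, rng):
        X = rng.normal(0, 1, (8, 6)) + rng.normal(0, 1, 6)[None, :] * 2
        eg1, _ = module_eigengene(pd.DataFrame(X))
        eg2, _ = module_eigengene(pd.DataFrame(-X))
        assert np.allclose(eg1.to_numpy(), -eg2.to_numpy(), atol=1e-10)


class TestMerge:
    def _moduleset_from_blocks(self, blocks, samples=12):
        genes = np.vstack(blocks)
        df = pd.DataFrame(genes,
                          index=[f"g{i}" for i in range(genes.shape[0])],
                          columns=[f"s{j}" for j in range(samples)])
        labels = pd.Series(
            sum(([f"M{k + 1}"] * b.shape[0] for k, b in enumerate(blocks)), []),
            index=df.index)
        egs, ves = {}, {}
        for k in range(len(blocks)):
            eg, ve = module_eigengene(df.loc[labels == f"M{k + 1}"])
            egs[f"M{k + 1}"] = eg
            ves[f"M{k + 1}"] = ve
        from syndromics.coexpression import ModuleSet

        return df, ModuleSet(labels=labels,
                             eigengenes=pd.DataFrame(egs).T,
                             variance_explained=ves)

    def _block(self, base, n_genes, noise, rng):
        return base[None, :] + noise * rng.normal(0, 1, (n_genes, len(base)))

    def test_highly_correlated_pair_merged(self, rng):
        base = rng.normal(0, 1, 12)
        b1 = self._block(base, 6, 0.05, rng)
        b2 = self._block(base + rng.normal(0, 0.3, 12), 6, 0.05, rng)
        b3 = self._block(rng.normal(0, 1, 12), 6, 0.05, rng)
        df, ms = self._moduleset_from_blocks([b1, b2, b3])
        r12 = np.corrcoef(ms.eigengenes.loc["M1"], ms.eigengenes.loc["M2"])[0, 1]
        assert r12 > 0.85
        merged = merge_modules(ms, df, 0.85)
        assert len(merged.module_ids) == 2
        assert merged.merge_log[0][:2] == ("M1", "M2")

    def test_uncorrelated_modules_unchanged(self, rng):
        blocks = [self._block(rng.normal(0, 1, 12), 5, 0.05, rng)
                  for _ in range(3)]
        df, ms = self._moduleset_from_blocks(blocks)
        C = np.corrcoef(ms.eigengenes.to_numpy())
        assert np.abs(C[np.triu_indices(3, 1)]).max() < 0.85
        merged = merge_modules(ms, df, 0.85)
        assert merged.merge_log == []
        pd.testing.assert_series_equal(merged.labels, ms.labels)

    def test_merge_order_follows_hand_stepped_oracle(self, rng):
        """Engineered eigengene correlations (~0.95, ~0.90, low): the
        most correlated pair merges first, eigengenes are recomputed,
        and the loop re-tests before any further merge."""
        base = rng.normal(0, 1, 12)
        b1 = self._block(base, 8, 0.10, rng)
        b2 = self._block(base, 8, 0.30, rng)       # r(M1,M2) highest
        b3 = self._block(base, 8, 0.55, rng)       # r with others lower
        df, ms = self._moduleset_from_blocks([b1, b2, b3])
        E = ms.eigengenes
        r = {(a, b): abs(np.corrcoef(E.loc[a], E.loc[b])[0, 1])
             for a, b in [("M1", "M2"), ("M1", "M3"), ("M2", "M3")]}
        order = sorted(r, key=r.get, reverse=True)
        merged = merge_modules(ms, df, 0.85)

        # hand-stepped oracle
        labels = ms.labels.copy()
        egs = {m: ms.eigengenes.loc[m].copy() for m in ms.module_ids}
        log = []
        while len(egs) > 1:
            mods = sorted(egs)
            pairs = [(a, b) for i, a in enumerate(mods) for b in mods[i + 1:]]
            rr = {p: np.corrcoef(egs[p[0]], egs[p[1]])[0, 1] for p in pairs}
            top = max(rr, key=rr.get)
            if rr[top] <= 0.85:
                break
            keep, absorb = top
            labels[labels == absorb] = keep
            egs[keep], _ = module_eigengene(df.loc[labels == keep])
            del egs[absorb]
            log.append((keep, absorb, rr[top]))
        assert [m[:2] for m in merged.merge_log] == [m[:2] for m in log]
        for got, exp in zip(merged.merge_log, log):
            assert got[2] == pytest.approx(exp[2], abs=1e-10)

    def test_post_merge_correlations_below_threshold(self):
        expr, _ = planted_expression(seed=2)
        mods = merge_modules(detect_modules(expr, NetworkParams()), expr, 0.85)
        E = mods.eigengenes.to_numpy()
        if len(E) > 1:
            C = np.corrcoef(E)
            assert C[np.triu_indices(len(E), 1)].max() <= 0.85


class TestKME:
    def test_gene_equal_to_eigengene_scores_one(self, rng):
        expr, _ = planted_expression(seed=3)
        mods = merge_modules(detect_modules(expr, NetworkParams()), expr, 0.85)
        df = expr.values.copy()
        df.loc["g0001"] = mods.eigengenes.iloc[0]
        kme = compute_kme(df, mods.eigengenes)
        assert kme.loc["g0001", mods.module_ids[0]] == pytest.approx(1.0)
        assert (kme.to_numpy() >= -1 - 1e-12).all()
        assert (kme.to_numpy() <= 1 + 1e-12).all()

    def test_matches_looped_pearson_oracle(self, rng):
        X = rng.normal(0, 1, (20, 9))
        E = rng.normal(0, 1, (3, 9))
        kme = compute_kme(pd.DataFrame(X),
                          pd.DataFrame(E, index=["M1", "M2", "M3"]))
        for i in range(20):
            for k, m in enumerate(["M1", "M2", "M3"]):
                assert kme.iloc[i, k] == pytest.approx(
                    np.corrcoef(X[i], E[k])[0, 1], abs=1e-10)

    def test_members_have_higher_kme_than_nonmembers(self):
        expr, truth = planted_expression(seed=4)
        mods = merge_modules(detect_modules(expr, NetworkParams()), expr, 0.85)
        kme = compute_kme(expr, mods.eigengenes)
        for m in mods.module_ids:
            inside = kme.loc[mods.labels == m, m].mean()
            outside = kme.loc[mods.labels != m, m].mean()
            assert inside > outside


class TestBatchCentering:
    def test_per_batch_medians_removed(self, rng):
        from syndromics.coexpression import median_center_batches

        X = rng.normal(0, 1, (30, 8))
        X[:, 4:] += 3.0  # batch offset
        samples = [f"s{j}" for j in range(8)]
        expr = ExpressionMatrix(
            values=pd.DataFrame(X, columns=samples),
            groups=pd.Series(["x"] * 8, index=samples),
            batch=pd.Series(["b1"] * 4 + ["b2"] * 4, index=samples),
        )
        centered = median_center_batches(expr)
        for b in ("b1", "b2"):
            cols = centered.batch.index[centered.batch == b]
            med = centered.values[cols].median(axis=1)
            assert np.allclose(med, 0.0, atol=1e-12)

    def test_requires_batch_labels(self, rng):
        from syndromics.coexpression import median_center_batches

        expr = expr_from(rng.normal(0, 1, (5, 4)))
        with pytest.raises(ValueError):
            median_center_batches(expr)


class TestModuleTrait:
    GROUPS = ("sham", "vehicle", "treated")

    def _series(self, means, rng, sd=0.2, n=5):
        vals = np.concatenate([rng.normal(m, sd, n) for m in means])
        idx = [f"{g}_{i}" for g in self.GROUPS for i in range(n)]
        return (pd.Series(vals, index=idx),
                pd.Series([g for g in self.GROUPS for _ in range(n)], index=idx))

    def test_flat_eigengene_not_flagged(self, rng):
        eg, groups = self._series((0.0, 0.0, 0.0), rng)
        res = module_trait_test(eg, groups, self.GROUPS)
        assert res["p"] > 0.05 and not res["reversion"]

    def test_partial_reversion_flagged(self, rng):
        eg, groups = self._series((0.0, 2.0, 1.0), rng)
        res = module_trait_test(eg, groups, self.GROUPS)
        assert res["p"] < 0.01 and res["reversion"]

    def test_exaggerated_shift_not_reversion(self, rng):
        eg, groups = self._series((0.0, 2.0, 3.0), rng)
        res = module_trait_test(eg, groups, self.GROUPS)
        assert res["p"] < 0.01 and not res["reversion"]
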