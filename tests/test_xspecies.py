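import dataclasses
import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import conservatome as cv
from conservatome.xspecies import RankedList, path_slope, smooth_profiles

from conftest import null_config, species_view


# ---------------------------------------------------------------------------
# pi0 / pi1


class TestPi0:
    def test_uniform_null_near_one(self):
        p = np.linspace(1e-4, 1 - 1e-4, 800)
        assert cv.estimate_pi0(p).pi0 >= 0.95

    def test_mixture_recovery(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p = np.concatenate([rng.uniform(size=1400), rng.beta(0.1, 1.0, size=600)])
            vals.append(cv.estimate_pi0(p).pi0)
        assert 0.6 <= np.median(vals) <= 0.8

    def test_saturated_alternative(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 0.001, size=500)
        assert cv.estimate_pi0(p).pi0 <= 0.05

    def test_degenerate_collection_conservative(self):
        est = cv.estimate_pi0(np.full(100, 0.5))
        assert est.pi0 == 1.0


# ---------------------------------------------------------------------------
# ranking and RRHO


def fake_de(rows):
    """rows: list of (id, p, coef)"""
    ids, ps, coefs = zip(*rows)
    table = pd.DataFrame({"p": ps, "coef": coefs, "testable": True}, index=list(ids))
    return cv.DEResult(table=table, prior=cv.EBPrior(1, 1), design=cv.DesignSpec("x"))


class TestRankByDE:
    def test_sign_then_magnitude(self):
        de = fake_de([("A", 0.001, 1.0), ("B", 0.01, 0.5), ("C", 0.001, -1.0)])
        assert cv.rank_by_de(de).ids == ["A", "B", "C"]

    def test_ties_break_by_coef_then_id(self):
        de = fake_de([("B", 0.01, 1.0), ("A", 0.01, 1.0), ("C", 0.01, 2.0)])
        assert cv.rank_by_de(de).ids == ["C", "A", "B"]

    def test_p_zero_floored_and_first(self):
        de = fake_de([("A", 0.0, 1.0), ("B", 1e-30, 1.0)])
        ranked = cv.rank_by_de(de)
        assert ranked.ids[0] == "A" and np.isfinite(ranked.scores).all()


def brute_hyper_upper(n, K, k, o):
    """P(X >= o) for X ~ Hypergeom(n, K, k) by direct summation."""
    return sum(comb(K, x) * comb(n - K, k - x) / comb(n, k)
               for x in range(o, min(K, k) + 1))


class TestRRHOMap:
    def _ranked(self, ids):
        return RankedList(ids=list(ids), scores=np.arange(len(ids), 0, -1, dtype=float))

    def test_identical_rankings_diagonal_max_and_corner_zero(self):
        ids = [f"P{i}" for i in range(12)]
        r = cv.rrho_map(self._ranked(ids), self._ranked(ids), step=1)
        g = r.grid.to_numpy()
        assert g[-1, -1] == pytest.approx(0.0, abs=1e-12)  # full lists: o=n, p=1
        for i in range(len(ids) - 1):
            assert g[i, i] == np.max(g[i, :])

    def test_exact_tail_value(self):
        # n=10, i=j=4, full overlap
        ids = [f"P{i}" for i in range(10)]
        r = cv.rrho_map(self._ranked(ids), self._ranked(ids), step=1)
        assert r.grid.loc[4, 4] == pytest.approx(-np.log10(1 / 210), abs=1e-10)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        ids = [f"P{i}" for i in range(9)]
        for _ in range(5):
            order_b = list(rng.permutation(ids))
            r = cv.rrho_map(self._ranked(ids), self._ranked(order_b), step=1)
            pos_b = {pid: i for i, pid in enumerate(order_b)}
            for i, j in itertools.product(range(1, 10), repeat=2):
                o = sum(1 for pid in ids[:i] if pos_b[pid] < j)
                expected = -np.log10(max(brute_hyper_upper(9, i, j, o), 1e-300))
                assert r.grid.loc[i, j] == pytest.approx(expected, abs=1e-9)

    def test_shared_permutation_invariance_and_swap_transpose(self):
        rng = np.random.default_rng(1)
        ids = [f"P{i}" for i in range(30)]
        a = self._ranked(list(rng.permutation(ids)))
        b = self._ranked(list(rng.permutation(ids)))
        g1 = cv.rrho_map(a, b, step=1).grid
        # relabel every protein consistently in both lists
        relabel = {pid: f"Q{i}" for i, pid in enumerate(ids)}
        a2 = RankedList(ids=[relabel[x] for x in a.ids], scores=a.scores)
        b2 = RankedList(ids=[relabel[x] for x in b.ids], scores=b.scores)
        np.testing.assert_allclose(cv.rrho_map(a2, b2, step=1).grid, g1)
        np.testing.assert_allclose(cv.rrho_map(b, a, step=1).grid, g1.T)

    def test_universe_mismatch_names_ids(self):
        with pytest.raises(ValueError, match="P2"):
            cv.rrho_map(self._ranked(["P0", "P1", "P2"]), self._ranked(["P0", "P1", "P3"]))


class TestRRHOPermutation:
    def _study(self, seed, de_fraction):
        cfg = null_config(seed, n_proteins=120)
        cfg = dataclasses.replace(cfg, de_fraction=de_fraction, effect_size_sd=2.0,
                                  shared_protein_fraction=1.0, shared_effect_fraction=1.0,
                                  warp_factor=1.0, module_sizes=())
        human, pig, samples, truth = cv.generate_study(cfg)
        hm, hmeta = species_view(human, samples, "human")
        pm, pmeta = species_view(pig, samples, "pig")
        return hm, pm, hmeta, pmeta

    def test_planted_shared_signal_significant(self):
        hm, pm, hmeta, pmeta = self._study(0, de_fraction=0.4)
        res = cv.rrho_permutation_test(
            hm, pm, hmeta, pmeta,
            cv.DesignSpec("injured", "binary"),
            cv.DesignSpec("injured", "binary", paired_subject="subject_id"),
            shared_map={pid: pid for pid in hm.protein_ids},
            step=4, n_perm=99, seed=0)
        assert res.perm_p <= 0.02

    def test_b_zero_returns_observed_only(self):
        hm, pm, hmeta, pmeta = self._study(1, de_fraction=0.0)
        res = cv.rrho_permutation_test(
            hm, pm, hmeta, pmeta,
            cv.DesignSpec("injured", "binary"),
            cv.DesignSpec("injured", "binary", paired_subject="subject_id"),
            shared_map={pid: pid for pid in hm.protein_ids},
            step=4, n_perm=0, seed=0)
        assert res.perm_p is None and res.observed_max > 0

    def test_null_perm_p_uniform(self):
        ps = []
        for seed in range(25):
            hm, pm, hmeta, pmeta = self._study(seed, de_fraction=0.0)
            res = cv.rrho_permutation_test(
                hm, pm, hmeta, pmeta,
                cv.DesignSpec("injured", "binary"),
                cv.DesignSpec("injured", "binary", paired_subject="subject_id"),
                shared_map={pid: pid for pid in hm.protein_ids},
                step=6, n_perm=39, seed=seed + 1000)
            ps.append(res.perm_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# NACC


def zscore_rows(x):
    return (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)


def combined_from_blocks(hvals, pvals):
    h = zscore_rows(np.asarray(hvals, float))
    p = zscore_rows(np.asarray(pvals, float))
    ids = [f"P{i:03d}" for i in range(h.shape[0])]
    hcols = [f"H{i}" for i in range(h.shape[1])]
    pcols = [f"G{i}" for i in range(p.shape[1])]
    data = pd.DataFrame(np.hstack([h, p]), index=ids, columns=hcols + pcols)
    m = cv.AbundanceMatrix(data=data, scale_tag="zscored")
    return m, {"human": hcols, "pig": pcols}


class TestNACC:
    def test_hand_worked_tiny_instance(self):
        rng = np.random.default_rng(0)
        hvals = rng.normal(size=(4, 5))
        pvals = rng.normal(size=(4, 5))
        m, blocks = combined_from_blocks(hvals, pvals)
        res = cv.nacc_scores(m, blocks, k=1)
        # brute force: for each protein find the single best human partner,
        # take its pig correlation, and vice versa
        ch = np.corrcoef(zscore_rows(hvals))
        cp = np.corrcoef(zscore_rows(pvals))
        for g in range(4):
            others = [i for i in range(4) if i != g]
            nh = max(others, key=lambda i: ch[g, i])
            np_ = max(others, key=lambda i: cp[g, i])
            expected = 0.5 * (cp[g, nh] + ch[g, np_])
            assert res.table["nacc_score"].iloc[g] == pytest.approx(expected, abs=1e-12)

    def test_identical_networks_score_is_own_neighbor_mean(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(20, 10))
        m, blocks = combined_from_blocks(vals, vals.copy())
        res = cv.nacc_scores(m, blocks, k=3)
        ch = np.corrcoef(zscore_rows(vals))
        for g in range(20):
            corr = ch[g].copy()
            corr[g] = -np.inf
            top = np.sort(corr)[-3:]
            assert res.table["nacc_score"].iloc[g] == pytest.approx(top.mean(), abs=1e-10)

    def test_unstructured_null_centered_at_zero(self):
        means = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m, blocks = combined_from_blocks(rng.normal(size=(100, 15)),
                                             rng.normal(size=(100, 15)))
            means.append(cv.nacc_scores(m, blocks, k=10).table["nacc_score"].mean())
        assert abs(np.mean(means)) < 0.05

    def test_score_bounded_and_species_symmetric(self):
        rng = np.random.default_rng(2)
        m, blocks = combined_from_blocks(rng.normal(size=(30, 8)), rng.normal(size=(30, 8)))
        res = cv.nacc_scores(m, blocks, k=5)
        assert res.table["nacc_score"].between(-1, 1).all()
        swapped = cv.nacc_scores(m, dict(reversed(list(blocks.items()))), k=5)
        np.testing.assert_allclose(res.table["nacc_score"], swapped.table["nacc_score"])

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(3)
        m, blocks = combined_from_blocks(rng.normal(size=(6, 5)), rng.normal(size=(6, 5)))
        res = cv.nacc_scores(m, blocks, k=4)
        with pytest.raises(ValueError, match="k"):
            cv.nacc_permutation_test(dataclasses.replace(res, k=5), n_perm=10)


class TestNACCPermutation:
    def test_conserved_module_members_detected(self):
        cfg = cv.default_config(seed=21, n_proteins=200, within_module_corr=0.8,
                                module_sizes=(25, 25, 25, 25))
        human, pig, samples, truth = cv.generate_study(cfg)
        hm, hmeta = species_view(human, samples, "human")
        pm, pmeta = species_view(pig, samples, "pig")
        hp = cv.impute_half_min(cv.filter_detection(hm))
        pp = cv.impute_half_min(cv.filter_detection(pm))
        shared = hp.protein_ids.intersection(pp.protein_ids)
        combined, blocks = cv.zscore_within_species(hp, pp, {i: i for i in shared})
        res = cv.nacc_permutation_test(cv.nacc_scores(combined, blocks, k=10),
                                       n_perm=200, seed=0)
        mods = truth.modules()
        cons = [pid for m_, mem in mods.items() if truth.module_conserved[m_]
                for pid in mem if pid in set(combined.protein_ids)]
        power = (res.table.loc[cons, "perm_p"] < 0.05).mean()
        assert power >= 0.9
        assert (res.table.loc[cons, "z"] > 2).mean() >= 0.9
        # gene-set level: conserved and divergent tails
        sets = cv.nacc_gene_set_test(res, {f"mod{m_}": mem for m_, mem in mods.items()},
                                     n_perm=200, seed=0).set_index("set_id")
        for m_, flag in truth.module_conserved.items():
            row = sets.loc[f"mod{m_}"]
            if flag:
                assert row["p_conserved"] < 0.05
            else:
                assert row["p_divergent"] < 0.05

    def test_observed_below_null_gives_p_one(self):
        rng = np.random.default_rng(4)
        m, blocks = combined_from_blocks(rng.normal(size=(30, 10)), rng.normal(size=(30, 10)))
        res = cv.nacc_scores(m, blocks, k=5)
        res.table["nacc_score"] = -1.0  # force below every achievable null
        out = cv.nacc_permutation_test(res, n_perm=50, seed=0)
        assert (out.table["perm_p"] == 1.0).all()

    def test_null_perm_p_uniform_across_realizations(self):
        # one protein followed across independent unstructured datasets;
        # per-protein perm-p's within one dataset share a correlation
        # realization and are not independent, so the null check tracks a
        # fixed protein across seeds instead
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            m, blocks = combined_from_blocks(rng.normal(size=(60, 12)),
                                             rng.normal(size=(60, 12)))
            out = cv.nacc_permutation_test(cv.nacc_scores(m, blocks, k=6),
                                           n_perm=99, seed=seed + 500)
            ps.append(out.table["perm_p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_size_filter_for_gene_sets(self):
        rng = np.random.default_rng(6)
        m, blocks = combined_from_blocks(rng.normal(size=(30, 8)), rng.normal(size=(30, 8)))
        res = cv.nacc_scores(m, blocks, k=3)
        ids = list(m.protein_ids)
        table = cv.nacc_gene_set_test(res, {"tiny": ids[:2], "ok": ids[:5]},
                                      size_bounds=(3, 50), n_perm=20, seed=0)
        assert table["set_id"].tolist() == ["ok"]


# ---------------------------------------------------------------------------
# smoothing and DTW


class TestSmoothing:
    def test_constant_series_reproduced(self):
        t = [0.0, 24.0, 48.0, 72.0]
        vals = pd.DataFrame([[3.0] * 4], index=["P0"], columns=t)
        out = smooth_profiles(t, vals, upsample_factor=5)
        np.testing.assert_allclose(out.to_numpy(), 3.0, atol=1e-10)

    def test_quadratic_exact(self):
        t = np.array([0.0, 10.0, 25.0, 40.0, 60.0])
        y = 0.5 * t**2 - 3 * t + 2
        out = smooth_profiles(t, pd.DataFrame([y], index=["P0"], columns=t), upsample_factor=8)
        grid = out.columns.to_numpy(float)
        np.testing.assert_allclose(out.to_numpy()[0], 0.5 * grid**2 - 3 * grid + 2, atol=1e-6)

    def test_noisy_sine_better_than_linear_interp(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 120, 13)
        truth_f = lambda x: np.sin(2 * np.pi * x / 120)
        rmses_smooth, rmses_lin = [], []
        for _ in range(10):
            y = truth_f(t) + rng.normal(0, 0.3, len(t))
            out = smooth_profiles(t, pd.DataFrame([y], columns=t), upsample_factor=4,
                                  bandwidth=45.0)
            grid = out.columns.to_numpy(float)
            rmses_smooth.append(np.sqrt(np.mean((out.to_numpy()[0] - truth_f(grid)) ** 2)))
            lin = np.interp(grid, t, y)
            rmses_lin.append(np.sqrt(np.mean((lin - truth_f(grid)) ** 2)))
        assert np.mean(rmses_smooth) < np.mean(rmses_lin)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="3 timepoints"):
            smooth_profiles([0.0, 24.0], pd.DataFrame([[1.0, 2.0]], columns=[0.0, 24.0]), 2)


def brute_force_dtw(cost):
    """Minimum total cost over all admissible monotone boundary paths."""
    nh, np_ = cost.shape
    best = [np.inf]

    def walk(i, j, acc):
        acc = acc + cost[i, j]
        if acc >= best[0]:
            return
        if (i, j) == (nh - 1, np_ - 1):
            best[0] = acc
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            if i + di < nh and j + dj < np_:
                walk(i + di, j + dj, acc)

    walk(0, 0, 0.0)
    return best[0]


class TestDTW:
    def _profiles(self, mat, cols):
        return pd.DataFrame(mat, index=[f"P{i}" for i in range(mat.shape[0])], columns=cols)

    def test_identity_alignment(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 6))
        h = self._profiles(vals, np.arange(6.0))
        res = cv.dtw_align(h, h.copy())
        assert res.total_cost == pytest.approx(0.0, abs=1e-12)
        assert res.path == [(i, i) for i in range(6)]

    def test_three_by_three_diagonal(self):
        # profiles engineered so the local cost matrix is [[1,5,5],[5,1,5],[5,5,1]]
        # checked against exhaustive enumeration
        cost = np.array([[1.0, 5, 5], [5, 1, 5], [5, 5, 1]])
        # use 1-protein profiles whose pairwise distances realize this cost
        h = self._profiles(np.array([[0.0, 4.0, 8.0]]), [0, 1, 2])
        p = self._profiles(np.array([[1.0, 5.0, 9.0]]), [0, 1, 2])
        res = cv.dtw_align(h, p)
        np.testing.assert_allclose(res.cost.to_numpy(), np.abs(
            np.array([[0.0, 4, 8]]).T - np.array([[1.0, 5, 9]])))
        assert res.path == [(0, 0), (1, 1), (2, 2)]
        assert res.total_cost == pytest.approx(3.0)
        assert res.total_cost == pytest.approx(brute_force_dtw(res.cost.to_numpy()))

    def test_matches_exhaustive_minimum_small_grids(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            nh, np_ = rng.integers(2, 7, size=2)
            h = self._profiles(rng.normal(size=(4, nh)), np.arange(float(nh)))
            p = self._profiles(rng.normal(size=(4, np_)), np.arange(float(np_)))
            res = cv.dtw_align(h, p)
            assert res.total_cost == pytest.approx(
                brute_force_dtw(res.cost.to_numpy()), abs=1e-9)
            # path admissibility
            assert res.path[0] == (0, 0) and res.path[-1] == (nh - 1, np_ - 1)
            steps = {(b[0] - a[0], b[1] - a[1]) for a, b in zip(res.path, res.path[1:])}
            assert steps <= {(1, 0), (0, 1), (1, 1)}

    def test_warp_factor_recovered_from_generator(self):
        slopes = []
        for seed in (1, 4):
            cfg = cv.default_config(seed=seed, n_proteins=250, de_fraction=0.35,
                                    effect_size_sd=1.5, warp_factor=2.0)
            specs = dict(cfg.species_specs)
            specs["human"] = dataclasses.replace(
                specs["human"], timepoints=tuple(np.linspace(24, 120, 9)))
            specs["pig"] = dataclasses.replace(
                specs["pig"], timepoints=tuple(np.linspace(12, 60, 9)))
            cfg = dataclasses.replace(cfg, species_specs=specs)
            human, pig, samples, _ = cv.generate_study(cfg)
            hm, hmeta = species_view(human, samples, "human")
            pm, pmeta = species_view(pig, samples, "pig")
            prep = lambda m, mm: cv.impute_half_min(
                cv.filter_detection(cv.remove_batch_effect(m, mm)))
            hp, pp = prep(hm, hmeta), prep(pm, pmeta)
            shared = hp.protein_ids.intersection(pp.protein_ids)
            combined, blocks = cv.zscore_within_species(hp, pp, {i: i for i in shared})
            from conservatome.pipeline import _mean_by_timepoint
            ht = _mean_by_timepoint(combined.subset_samples(blocks["human"]), hmeta, None)
            pt = _mean_by_timepoint(combined.subset_samples(blocks["pig"]), pmeta, None)
            hs = smooth_profiles(ht.columns.to_numpy(float), ht, 10)
            ps = smooth_profiles(pt.columns.to_numpy(float), pt, 10)
            slopes.append(path_slope(cv.dtw_align(hs, ps)))
        for s in slopes:
            assert 1.5 <= s <= 2.5
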