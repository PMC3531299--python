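"""Model-based stability: variance decomposition, shrinkage, ranking, pairs."""

import numpy as np
import pandas as pd
import pytest

from ecref.errors import DataError
from ecref.normfinder import (best_pair, group_differences, intra_group_variance,
                              pair_stability, run_normfinder, shrunk_variance,
                              within_group_residuals)


def _frame(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


def _groups(n1, n2, cols):
    return pd.Series(["case"] * n1 + ["control"] * n2, index=cols)


def _sim(rng, k, n1, n2, sigma, shift=None):
    """Additive-model draw: gene effects + sample loadings + noise (+ group shift)."""
    y = rng.normal(0, 2, (k, 1)) + rng.normal(0, 1, (1, n1 + n2))
    y = y + rng.normal(0, 1, (k, n1 + n2)) * np.asarray(sigma).reshape(-1, 1)
    if shift is not None:
        y[:, :n1] += np.asarray(shift).reshape(-1, 1)
    return _frame(y)


class TestResiduals:
    def test_perfect_additivity_gives_zero(self):
        y = _frame(np.add.outer([1.0, 2, 3], [10.0, 20, 30, 40]))
        r = within_group_residuals(y, _groups(2, 2, y.columns))
        for block in r.values():
            assert np.allclose(block, 0, atol=1e-12)

    def test_sample_loading_absorbed(self, rng):
        y = _frame(rng.normal(0, 1, (4, 6)))
        g = _groups(3, 3, y.columns)
        r1 = within_group_residuals(y, g)
        y2 = y + pd.Series(rng.normal(0, 5, 6), index=y.columns)  # per-sample constant
        r2 = within_group_residuals(y2, g)
        for grp in r1:
            assert np.allclose(r1[grp], r2[grp], atol=1e-10)

    def test_gene_constant_absorbed(self, rng):
        y = _frame(rng.normal(0, 1, (4, 6)))
        g = _groups(3, 3, y.columns)
        y2 = y.copy()
        y2.loc["g1"] += 11.0
        r1, r2 = within_group_residuals(y, g), within_group_residuals(y2, g)
        for grp in r1:
            assert np.allclose(r1[grp], r2[grp], atol=1e-10)

    def test_too_few_genes_rejected(self):
        y = _frame(np.zeros((2, 4)))
        with pytest.raises(DataError, match="not identifiable"):
            within_group_residuals(y, _groups(2, 2, y.columns))


class TestIntraGroupVariance:
    def test_zero_residuals_zero_variance(self):
        y = _frame(np.add.outer([1.0, 2, 3], [1.0, 2, 3, 4]))
        sig = intra_group_variance(within_group_residuals(y, _groups(2, 2, y.columns)))
        assert (sig.to_numpy() == 0).all()

    def test_scaling_deviations_quadruples_variance(self, rng):
        y = _frame(rng.normal(0, 0.5, (5, 10)))
        g = _groups(5, 5, y.columns)
        s1 = intra_group_variance(within_group_residuals(y, g))
        s2 = intra_group_variance(within_group_residuals(2 * y, g))
        assert np.allclose(s2, 4 * s1, atol=1e-10)

    def test_unbiased_at_moderate_size(self):
        # true sigma2 = 0.04 for all genes; k=10, n_g=20
        rng = np.random.default_rng(1)
        est = []
        for _ in range(400):
            y = _sim(rng, 10, 20, 20, np.full(10, 0.2))
            sig = intra_group_variance(
                within_group_residuals(y, _groups(20, 20, y.columns)))
            est.append(sig.to_numpy().mean())
        assert 0.037 <= np.mean(est) <= 0.043


class TestGroupDifferences:
    def test_two_group_antisymmetry(self, rng):
        y = _sim(rng, 6, 5, 4, np.full(6, 0.3), shift=rng.normal(0, 1, 6))
        g = _groups(5, 4, y.columns)
        sig = intra_group_variance(within_group_residuals(y, g))
        d, gamma2, shrunk = group_differences(y, g, sig)
        assert np.allclose(d.iloc[:, 0], -d.iloc[:, 1], atol=1e-10)
        assert np.allclose(d.sum(axis=0), 0, atol=1e-10)  # centred over genes
        assert np.allclose(d.sum(axis=1), 0, atol=1e-10)  # centred over groups

    def test_shrinkage_contracts(self, rng):
        y = _sim(rng, 8, 9, 4, np.full(8, 0.5), shift=rng.normal(0, 1.5, 8))
        g = _groups(9, 4, y.columns)
        sig = intra_group_variance(within_group_residuals(y, g))
        d, gamma2, shrunk = group_differences(y, g, sig)
        assert (shrunk.abs().to_numpy() <= d.abs().to_numpy() + 1e-12).all()

    def test_null_gamma2_vanishes_with_n(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(200):
            y = _sim(rng, 8, 50, 50, np.full(8, 0.3))
            g = _groups(50, 50, y.columns)
            sig = intra_group_variance(within_group_residuals(y, g))
            _, gamma2, _ = group_differences(y, g, sig)
            vals.append(gamma2)
        assert np.median(vals) < 0.005

    def test_large_shift_barely_shrunk(self):
        rng = np.random.default_rng(4)
        shift = np.zeros(8)
        shift[0] = 4.0
        y = _sim(rng, 8, 20, 20, np.full(8, 0.1), shift=shift)
        g = _groups(20, 20, y.columns)
        sig = intra_group_variance(within_group_residuals(y, g))
        d, _, shrunk = group_differences(y, g, sig)
        ratio = shrunk.loc["g0"].abs() / d.loc["g0"].abs()
        assert (ratio > 0.95).all()


class TestStability:
    def test_identical_genes_all_zero(self):
        y = _frame(np.tile([[ -20.0, -21, -22, -23, -24, -25]], (4, 1)))
        res = run_normfinder(y, _groups(3, 3, y.columns))
        assert np.allclose(res.stability, 0, atol=1e-12)

    def test_shifted_gene_ranks_last(self):
        rng = np.random.default_rng(5)
        worst_last = 0
        n_sim = 300
        for _ in range(n_sim):
            shift = np.zeros(10)
            shift[3] = 1.0  # one gene with a +1 log2 group shift
            y = _sim(rng, 10, 9, 4, np.full(10, 0.15), shift=shift)
            res = run_normfinder(y, _groups(9, 4, y.columns))
            worst_last += res.ranking[-1] == "g3"
        assert worst_last / n_sim >= 0.99

    def test_designed_most_stable_ranks_first(self):
        # winner: tiny variance, zero shift; competitors: large variance and
        # balanced +/- shifts (so gene-centring leaves the winner's truth at 0)
        rng = np.random.default_rng(6)
        hits = 0
        n_sim = 200
        k = 9
        for _ in range(n_sim):
            sigma = np.full(k, 0.8)
            sigma[2] = 0.1
            mags = rng.uniform(0.5, 1.5, 4)
            shift = np.concatenate([[0.0], mags, -mags])
            shift = np.roll(shift, 2)            # winner lands at index 2
            y = _sim(rng, k, 9, 4, sigma, shift=shift)
            res = run_normfinder(y, _groups(9, 4, y.columns))
            hits += res.ranking[0] == "g2"
        assert hits / n_sim >= 0.95

    def test_equivariance_under_relabeling_and_permutation(self, rng):
        y = _sim(rng, 6, 6, 4, np.full(6, 0.4), shift=rng.normal(0, 0.5, 6))
        g = _groups(6, 4, y.columns)
        res = run_normfinder(y, g)
        perm_genes = list(rng.permutation(y.index))
        res_g = run_normfinder(y.loc[perm_genes], g)
        assert np.allclose(res_g.stability[res.stability.index], res.stability, atol=1e-10)
        case_perm = list(rng.permutation(y.columns[:6])) + list(y.columns[6:])
        res_s = run_normfinder(y[case_perm], g[case_perm])
        assert np.allclose(res_s.stability[res.stability.index], res.stability, atol=1e-10)

    def test_sample_loading_changes_nothing(self, rng):
        y = _sim(rng, 6, 6, 4, np.full(6, 0.4), shift=rng.normal(0, 0.5, 6))
        g = _groups(6, 4, y.columns)
        y2 = y + pd.Series(rng.normal(0, 3, 10), index=y.columns)
        r1, r2 = run_normfinder(y, g), run_normfinder(y2, g)
        assert np.allclose(r1.stability, r2.stability, atol=1e-10)
        assert r1.ranking == r2.ranking


class TestPairs:
    def test_self_pair_rejected(self, rng):
        y = _sim(rng, 4, 4, 4, np.full(4, 0.3))
        res = run_normfinder(y, _groups(4, 4, y.columns))
        with pytest.raises(DataError):
            pair_stability(res.shrunk_diff, shrunk_variance(res), "g0", "g0")

    def test_null_pair_beats_singles(self):
        rng = np.random.default_rng(8)
        # equal-variance null genes: averaging halves the variance term
        wins = 0
        for _ in range(50):
            y = _sim(rng, 6, 8, 8, np.full(6, 0.5), shift=rng.normal(0, 0.8, 6))
            res = run_normfinder(y, _groups(8, 8, y.columns))
            if res.best_pair is not None:
                v = shrunk_variance(res)
                val = pair_stability(res.shrunk_diff, v, *res.best_pair)
                wins += val <= res.stability[res.best_gene] + 1e-12
        assert wins >= 45

    def test_reported_pair_never_less_stable_than_best_single(self, preset_seed1):
        from ecref.cq import collapse_replicates, impute_cq_ceiling
        table, _ = preset_seed1
        mats = collapse_replicates(impute_cq_ceiling(table))
        for mat in mats.values():
            res = run_normfinder(mat)
            if res.best_pair is not None:
                assert res.pair_stability <= res.stability[res.best_gene] + 1e-12

    def test_best_pair_search_matches_exhaustive(self, rng):
        y = _sim(rng, 7, 6, 5, rng.uniform(0.2, 0.8, 7), shift=rng.normal(0, 0.7, 7))
        res = run_normfinder(y, _groups(6, 5, y.columns))
        v = shrunk_variance(res)
        import itertools
        vals = {pair: pair_stability(res.shrunk_diff, v, *pair)
                for pair in itertools.combinations(res.ranking, 2)}
        exhaustive_best = min(vals, key=vals.get)
        pair, val = best_pair(res.shrunk_diff, v, res.ranking)
        assert val == pytest.approx(vals[exhaustive_best], abs=1e-12)
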