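"""Quantile normalization, fold change, rank product vs enumeration oracle,
null p-value uniformity, and planted-regulation recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mircircuit as mc
from mircircuit.formats import ExpressionMatrix, parse_sample_labels


def make_matrix(values, columns):
    df = pd.DataFrame(values, index=[f"p{i}" for i in range(len(values))], columns=columns)
    return ExpressionMatrix(df, *parse_sample_labels(columns))


GM_DM = ["GM_1", "GM_2", "DM3_1", "DM3_2"]


class TestQuantileNormalization:
    def test_identical_columns_unchanged(self):
        m = make_matrix([[1, 1], [5, 5], [2, 2]], ["GM_1", "DM3_1"])
        out = mc.normalize_quantile(m)
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_hand_computed_3x2(self):
        m = make_matrix([[1, 10], [2, 20], [3, 30]], ["GM_1", "DM3_1"])
        out = mc.normalize_quantile(m).values.to_numpy()
        expected = np.array([[5.5, 5.5], [11.0, 11.0], [16.5, 16.5]])
        assert np.allclose(out, expected)

    def test_sorted_columns_identical_and_idempotent(self, rng):
        m = make_matrix(rng.uniform(1, 100, size=(30, 4)), GM_DM)
        out = mc.normalize_quantile(m)
        arr = out.values.to_numpy()
        ref = np.sort(arr[:, 0])
        for j in range(arr.shape[1]):
            assert np.allclose(np.sort(arr[:, j]), ref)
        again = mc.normalize_quantile(out)
        assert np.allclose(again.values.to_numpy(), arr)

    def test_ties_handled(self):
        m = make_matrix([[1, 4], [1, 2], [7, 9]], ["GM_1", "DM3_1"])
        out = mc.normalize_quantile(m).values.to_numpy()
        assert np.isfinite(out).all()
        assert out[0, 0] == out[1, 0]  # tied inputs stay tied


class TestFoldChanges:
    def test_ratio_of_means(self):
        m = make_matrix([[2, 2, 8, 8], [4, 4, 4, 4]], GM_DM)
        fc = mc.fold_changes(m)
        assert fc["p0"] == pytest.approx(4.0)
        assert fc["p1"] == pytest.approx(1.0)

    def test_swap_inverts(self):
        m = make_matrix([[2, 3, 9, 11]], GM_DM)
        fwd = mc.fold_changes(m, "DM3", "GM")
        rev = mc.fold_changes(m, "GM", "DM3")
        assert fwd["p0"] == pytest.approx(1.0 / rev["p0"])

    def test_missing_condition(self):
        m = make_matrix([[1, 2]], ["GM_1", "GM_2"])
        with pytest.raises(KeyError):
            mc.fold_changes(m)


def rank_product_oracle(values, direction):
    """Enumerate all within-pair probe-label permutations for p-values.

    Independent re-derivation: per pair (DM rep x GM rep) rank the fold
    changes, RP = geometric mean, p = (1 + #null RP <= observed)/(total + 1).
    """
    n = values.shape[0]
    gm, dm = values[:, :2], values[:, 2:]
    pair_ranks = []
    for i in range(gm.shape[1]):  # matched pairing: r-th DM with r-th GM
        fc = dm[:, i] / gm[:, i]
        order = sorted(range(n), key=lambda a: -fc[a] if direction == "up" else fc[a])
        ranks = [0.0] * n
        # average ties
        vals = sorted(((-fc[a] if direction == "up" else fc[a]), a) for a in order)
        pos = 0
        while pos < n:
            end = pos
            while end + 1 < n and vals[end + 1][0] == vals[pos][0]:
                end += 1
            avg = (pos + end) / 2 + 1
            for q in range(pos, end + 1):
                ranks[vals[q][1]] = avg
            pos = end + 1
        pair_ranks.append(ranks)
    k = len(pair_ranks)
    rp = [float(np.prod([pair_ranks[j][i] for j in range(k)]) ** (1 / k)) for i in range(n)]
    counts = [0] * n
    total = 0
    for perms in itertools.product(list(itertools.permutations(range(n))), repeat=k):
        total += 1
        for i in range(n):
            null_rp = np.prod([pair_ranks[j][perms[j][i]] for j in range(k)]) ** (1 / k)
            if null_rp <= rp[i] + 1e-12:
                counts[i] += 1
    pvals = [(c + 1) / (total + 1) for c in counts]
    return rp, pvals, total


class TestRankProduct:
    def test_consistent_winner_has_rp_one(self):
        m = make_matrix([[1, 1, 99, 99], [5, 5, 5, 5], [9, 9, 1, 1]], GM_DM)
        res = mc.rank_product(m, "up", n_perm=50, seed=0)
        assert res.at["p0", "RP"] == pytest.approx(1.0)
        res_dn = mc.rank_product(m, "down", n_perm=50, seed=0)
        assert res_dn.at["p2", "RP"] == pytest.approx(1.0)

    def test_exhaustive_enumeration_matches_oracle(self):
        """3 probes x 2 replicate pairs: all (3!)^2 = 36 label permutations."""
        values = np.array([[2.0, 4.0, 9.0, 16.0], [3.0, 3.0, 3.0, 4.0], [8.0, 6.0, 2.0, 1.0]])
        m = make_matrix(values, GM_DM)
        rp_o, p_o, total = rank_product_oracle(values, "up")
        assert total == 36
        res = mc.rank_product(m, "up", exact=True)
        assert res.attrs["n_perm"] == 36
        assert np.allclose(res["RP"].to_numpy(), rp_o)
        assert np.allclose(res["p_value"].to_numpy(), p_o)

    def test_null_pvalues_uniform(self):
        """No-signal simulation at N = 500: permutation p-values ~ U(0,1)."""
        rng = np.random.default_rng(12345)
        values = np.exp2(rng.normal(8, 1, size=(500, 1)) + rng.normal(0, 0.25, size=(500, 4)))
        m = make_matrix(values, GM_DM)
        res = mc.rank_product(mc.normalize_quantile(m), "up", n_perm=250, seed=9)
        ks = stats.kstest(res["p_value"], "uniform").statistic
        assert ks < 0.1

    def test_n_perm_validation(self):
        m = make_matrix([[1, 2, 3, 4]], GM_DM)
        with pytest.raises(ValueError):
            mc.rank_product(m, "up", n_perm=0)


class TestSelectRegulated:
    def _results(self, rows):
        table = pd.DataFrame(rows, columns=["fold_change", "p_up", "p_down"],
                             index=[f"p{i}" for i in range(len(rows))])
        return table

    def test_boundary_candidate_retained(self):
        # mirrors the weakest published up-candidate: FC 2.34 at p = 0.05
        up, down = mc.select_regulated(self._results([[2.34, 0.05, 0.9]]))
        assert up == ["p0"] and down == []

    def test_fc_below_threshold_excluded(self):
        up, _ = mc.select_regulated(self._results([[1.99, 0.01, 0.9]]))
        assert up == []

    def test_down_uses_inverse_fold(self):
        _, down = mc.select_regulated(self._results([[0.4, 0.9, 0.01]]))
        assert down == ["p0"]

    def test_degenerate_thresholds_keep_everything(self):
        table = self._results([[5.0, 0.5, 0.5], [0.1, 0.5, 0.5], [1.0, 0.9, 0.9]])
        up, _ = mc.select_regulated(table, fc_threshold=0, p_threshold=1)
        assert up == ["p0", "p1", "p2"]


class TestParameterRecovery:
    def test_planted_up_probes_recovered(self):
        """10% of probes planted up at FC 4 (sigma 0.25, 2 reps): >= 90% of the
        planted probes appear in the selected up list at default thresholds."""
        syn = mc.SyntheticStudyConfig(rng_seed=314)
        targets = []  # plant via de fractions only
        matrix, truth = mc.simulate_expression(syn, targets)
        res = mc.differential_expression(matrix, n_perm=300, seed=314)
        up, down = mc.select_regulated(res)
        planted_up = set(truth.index[truth.regulation == "up"])
        recovered = len(planted_up & set(up))
        assert recovered / len(planted_up) >= 0.9

    def test_no_signal_false_positive_rate(self):
        syn = mc.SyntheticStudyConfig(de_up_fraction=0.0, de_down_fraction=0.0, rng_seed=99)
        matrix, truth = mc.simulate_expression(syn, [])
        res = mc.differential_expression(matrix, n_perm=300, seed=99)
        up, down = mc.select_regulated(res)
        n = len(matrix.probe_ids)
        se = np.sqrt(0.05 * 0.95 / n)
        assert len(up) / n <= 0.05 + 3 * se
        assert len(down) / n <= 0.05 + 3 * se
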