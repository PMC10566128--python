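import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scfrag import FeatureMatrix, auroc, bky_fdr, bky_reject, compare_features, welch_t
from scfrag.group_stats import _bh_reject

from _oracles import auroc_pairs_reference, bky_two_stage_reference, welch_reference


class TestWelchT:
    def test_identical_groups(self):
        t, df, p = welch_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_clear_separation(self):
        _, _, p = welch_t(np.array([1.0, 2, 3]), np.array([11.0, 12, 13]))
        assert p < 0.01

    def test_matches_hand_oracle(self):
        x = [2.1, 2.5, 1.9, 2.3]
        y = [1.1, 1.4, 0.9, 1.2]
        t, df, p = welch_t(np.array(x), np.array(y))
        t0, df0, p0 = welch_reference(x, y)
        assert t == pytest.approx(t0)
        assert df == pytest.approx(df0)
        assert p == pytest.approx(p0)

    def test_swap_symmetry(self, rng):
        x, y = rng.normal(0, 1, 6), rng.normal(1, 2, 9)
        t1, df1, p1 = welch_t(x, y)
        t2, df2, p2 = welch_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
        assert df1 == pytest.approx(df2)

    def test_degenerate_zero_variance_convention(self):
        t, _, p = welch_t(np.array([2.0, 2.0]), np.array([2.0, 2.0]))
        assert (t, p) == (0.0, 1.0)

    def test_nan_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            t, _, p = welch_t(np.array([1.0, 2, np.nan, 3]), np.array([5.0, 6, 7]))
        assert np.isfinite(p)


class TestBkyFdr:
    def test_all_p_one(self):
        q, flags = bky_fdr(np.ones(8), 0.05)
        assert not flags.any()

    def test_all_tiny_p(self):
        for Q in (0.01, 0.05, 0.2):
            assert bky_reject(np.full(6, 1e-12), Q).all()

    def test_worked_vector_matches_enumeration(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.27, 0.60])
        got = bky_reject(p, 0.05)
        ref = bky_two_stage_reference(list(p), 0.05)
        assert got.tolist() == ref

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 30))
            p = rng.random(m) ** rng.uniform(0.5, 4)
            for Q in (0.01, 0.05, 0.1):
                assert bky_reject(p, Q).tolist() == bky_two_stage_reference(list(p), Q)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            m = int(rng.integers(2, 40))
            p = rng.random(m) ** 2
            got = bky_reject(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            assert np.array_equal(got, ref)

    def test_contains_bh_at_stage_one_level(self, rng):
        """Two-stage rejections contain BH run at the deflated stage-1 level
        Q/(1+Q) (stage 2, when reached, only raises the level).  Containment
        of BH at Q itself does not hold in general: a p value rejected by BH
        exactly at threshold can leave stage 1 empty."""
        Q = 0.05
        for _ in range(100):
            m = int(rng.integers(1, 50))
            p = rng.random(m) ** rng.uniform(0.5, 4)
            bky = bky_reject(p, Q)
            bh_deflated = _bh_reject(p, Q / (1 + Q))
            assert np.all(bky | ~bh_deflated)
        # counterexample to the naive "⊇ BH at Q" claim
        p = np.array([0.9877, 0.2425, 0.1548, 0.0916, 0.6817, 0.1323, 0.1392,
                      0.0282, 0.00537])
        assert _bh_reject(p, Q).any() and not bky_reject(p, Q).any()

    def test_q_values_are_rejection_threshold_infima(self, rng):
        for _ in range(30):
            m = int(rng.integers(1, 20))
            p = rng.random(m) ** 2
            q, flags = bky_fdr(p, 0.05)
            assert np.array_equal(flags, q <= 0.05 + 1e-12)
            for Q in (0.02, 0.1, 0.3):
                assert np.array_equal(bky_reject(p, Q), q <= Q + 1e-12)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            bky_reject(np.array([0.5, 1.2]), 0.05)
        with pytest.raises(ValueError):
            bky_reject(np.array([]), 0.05)

    def test_empirical_fdr_controlled_under_null(self, rng):
        """Mixed null/signal p vectors: mean false-discovery proportion ≤ Q."""
        Q = 0.05
        n_sims, m, m_true = 200, 40, 8
        fdp = []
        for _ in range(n_sims):
            p_null = rng.random(m - m_true)
            p_alt = rng.random(m_true) * 1e-5
            p = np.concatenate([p_alt, p_null])
            flags = bky_reject(p, Q)
            n_disc = flags.sum()
            fdp.append(flags[m_true:].sum() / max(n_disc, 1))
        se = np.std(fdp, ddof=1) / np.sqrt(n_sims)
        assert np.mean(fdp) <= Q + 3 * se


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc(np.array([5.0, 6, 7, 1, 2]), np.array([1, 1, 1, 0, 0])) == 1.0

    def test_all_ties(self):
        assert auroc(np.ones(10), np.array([1] * 5 + [0] * 5)) == 0.5

    def test_hand_counted_pairs(self):
        # pos scores (3, 2), neg scores (1, 4): 2 of 4 pairs concordant
        assert auroc(np.array([3.0, 2, 1, 4]), np.array([1, 1, 0, 0])) == 0.5

    def test_matches_bruteforce_and_mannwhitney(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 30))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n - 1))] = 1
            rng.shuffle(labels)
            scores = np.round(rng.normal(labels, 1.0), 1)  # ties likely
            a = auroc(scores, labels)
            assert a == pytest.approx(auroc_pairs_reference(scores, labels))
            u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                                   alternative="two-sided").statistic
            assert a == pytest.approx(u / ((labels == 1).sum() * (labels == 0).sum()))

    def test_complement_symmetry(self, rng):
        scores = rng.normal(size=20)
        labels = (rng.random(20) < 0.4).astype(int)
        labels[0], labels[1] = 0, 1
        assert auroc(scores, labels) + auroc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestCompareFeatures:
    @staticmethod
    def _matrix(rng, n_per=6, n_feat=10, shift_first=0.0):
        data = rng.normal(size=(2 * n_per, n_feat))
        data[:n_per, 0] += shift_first
        idx = [f"A{i}" for i in range(n_per)] + [f"B{i}" for i in range(n_per)]
        groups = pd.Series(["A"] * n_per + ["B"] * n_per, index=idx)
        values = pd.DataFrame(data, index=idx,
                              columns=[f"f{i}" for i in range(n_feat)])
        return FeatureMatrix(values=values, groups=groups)

    def test_identical_groups_no_discoveries(self, rng):
        fm = self._matrix(rng, shift_first=0.0)
        fm.values.iloc[6:] = fm.values.iloc[:6].to_numpy()  # B == A
        out = compare_features(fm, Q=0.05)
        assert out["discovery"].sum() == 0

    def test_planted_effect_discovered(self, rng):
        fm = self._matrix(rng, n_per=8, shift_first=4.0)  # ≈ 3σ of the group mean
        out = compare_features(fm, Q=0.05)
        assert bool(out.set_index("feature").loc["f0", "discovery"])

    def test_difference_sign_is_a_minus_b(self, rng):
        fm = self._matrix(rng, shift_first=5.0)
        out = compare_features(fm).set_index("feature")
        assert out.loc["f0", "difference"] == pytest.approx(
            out.loc["f0", "mean_A"] - out.loc["f0", "mean_B"]
        )
        assert out.loc["f0", "difference"] > 0

    def test_undefined_features_excluded_and_listed(self, rng):
        fm = self._matrix(rng)
        fm.values.loc[fm.values.index[0], "f3"] = np.nan
        out = compare_features(fm).set_index("feature")
        assert not out.loc["f3", "tested"]
        assert np.isnan(out.loc["f3", "q"])

    def test_permuted_labels_control_discovery_rate(self, rng):
        n_sims, Q = 200, 0.05
        rates = []
        for _ in range(n_sims):
            fm = self._matrix(rng, n_per=5, n_feat=20)
            out = compare_features(fm, Q=Q)
            rates.append(out["discovery"].mean())
        se = np.std(rates, ddof=1) / np.sqrt(n_sims)
        assert np.mean(rates) <= Q + 3 * max(se, 1e-4)

    def test_no_testable_features_errors(self):
        idx = ["A1", "A2", "B1", "B2"]
        fm = FeatureMatrix(
            values=pd.DataFrame({"f": [np.nan] * 4}, index=idx),
            groups=pd.Series(["A", "A", "B", "B"], index=idx),
        )
        with pytest.raises(ValueError):
            compare_features(fm)
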