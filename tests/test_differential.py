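"""Differential screening: exact Kruskal-Wallis, effect scores, the
multi-class screen and Welch two-group comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codigest import (
    FeatureTable,
    ValidationError,
    kruskal_wallis,
    lda_effect_size,
    lefse_screen,
    normalize_per_million,
    welch_two_group,
)
from codigest.differential import kruskal_wallis_permutation


def _labelled(values, classes, kind="pathway"):
    values = np.asarray(values, dtype=float)
    idx = [f"s{i}" for i in range(values.shape[0])]
    return FeatureTable(
        pd.DataFrame(values, index=idx,
                     columns=[f"f{j}" for j in range(values.shape[1])]),
        kind=kind,
        classes=pd.Series(classes, index=idx),
    )


class TestKruskalWallis:
    def test_identical_values_give_null_result(self):
        h, p = kruskal_wallis([5.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert (h, p) == (0.0, 1.0)

    def test_fully_separated_three_groups_exact_p(self):
        h, p = kruskal_wallis(
            [1, 2, 3, 4, 5, 6, 7, 8, 9], ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        )
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(6 / 1680, abs=1e-12)

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=9)
            x[rng.integers(0, 9)] = x[0]  # occasional tie
            h, _ = kruskal_wallis(x, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
            h_ref = stats.kruskal(x[:3], x[3:6], x[6:]).statistic
            assert h == pytest.approx(h_ref, rel=1e-12)

    def test_large_samples_use_chi_square(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=30)
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        h, p = kruskal_wallis(x, labels)
        ref = stats.kruskal(x[:10], x[10:20], x[20:])
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_small_class_rejected(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            kruskal_wallis([1, 2, 3, 4, 5], ["a", "a", "b", "b", "c"])

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="two classes"):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_chi_square_close_to_permutation_at_n10(self):
        """At 10 samples/class the asymptotic tail tracks the Monte-Carlo
        permutation tail to within 0.01 in median."""
        rng = np.random.default_rng(13)
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        deltas = []
        for _ in range(40):
            x = rng.normal(size=30) + np.repeat(rng.normal(0, 0.5, 3), 10)
            _, p_chi = kruskal_wallis(x, labels)
            _, p_perm = kruskal_wallis_permutation(
                x, labels, n_resamples=4000, rng=rng
            )
            deltas.append(abs(p_chi - p_perm))
        assert float(np.median(deltas)) < 0.01


class TestEffectSize:
    def test_log10_of_extreme_contrast(self):
        t = _labelled(
            [[100000.0], [100000.0], [0.0], [0.0], [0.0], [0.0]],
            ["hi", "hi", "lo", "lo", "mid", "mid"],
        )
        out = lda_effect_size(t)
        assert out.loc["f0", "effect"] == pytest.approx(5.0)
        assert out.loc["f0", "assigned_class"] == "hi"

    def test_identical_class_means_give_zero(self):
        t = _labelled([[10.0], [20.0], [10.0], [20.0]], ["a", "a", "b", "b"])
        assert lda_effect_size(t).loc["f0", "effect"] == 0.0

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(21)
        t = _labelled(rng.uniform(0, 1e5, size=(9, 6)), ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        out = lda_effect_size(t)
        means = t.data.groupby(t.classes).mean()
        for f in t.feature_ids:
            best = 0.0
            for c1 in means.index:
                for c2 in means.index:
                    best = max(best, abs(means.loc[c1, f] - means.loc[c2, f]))
            expected = math.log10(best) if best >= 1 else 0.0
            assert out.loc[f, "effect"] == pytest.approx(expected, rel=1e-12)

    def test_requires_two_classes(self):
        t = _labelled([[1.0], [2.0]], ["a", "a"])
        with pytest.raises(ValidationError):
            lda_effect_size(t)


class TestLefseScreen:
    def test_recovers_planted_horse_pathways(self, reference_fixture):
        results = lefse_screen(reference_fixture.microbiome)
        by_id = {r.feature_id: r for r in results}
        planted = reference_fixture.truth["planted"][0]["features"]
        for name in planted:
            assert by_id[name].significant, name
            assert by_id[name].assigned_class == "horse"
            assert by_id[name].effect_size >= 2.0

    def test_depth_rescaling_invariance(self, reference_fixture):
        t = reference_fixture.microbiome
        rescaled = t.with_data(t.data.mul(
            pd.Series(np.linspace(1, 12, t.n_samples), index=t.data.index), axis=0
        ))
        a = lefse_screen(t)
        b = lefse_screen(rescaled)
        for ra, rb in zip(a, b):
            assert ra.feature_id == rb.feature_id
            assert ra.p_value == pytest.approx(rb.p_value, abs=1e-12)
            assert ra.effect_size == pytest.approx(rb.effect_size, rel=1e-9)
            assert ra.significant == rb.significant

    def test_small_shift_below_effect_threshold_excluded(self):
        # 50 ppm mean difference: even a perfect rank separation fails the
        # effect threshold of 2 (= 100 ppm)
        base = np.full((9, 2), 500_000.0)
        base[6:, 0] += 50.0
        base[6:, 1] -= 50.0
        t = _labelled(base, ["cow"] * 3 + ["pig"] * 3 + ["horse"] * 3)
        jitter = np.random.default_rng(3).uniform(0, 1e-3, size=(9, 2))
        t = t.with_data(t.data + jitter)
        results = lefse_screen(t)
        assert all(not r.significant for r in results)
        assert all(r.effect_size < 2.0 for r in results)

    def test_growing_a_planted_shift_never_deselects(self):
        rng = np.random.default_rng(31)
        labels = ["cow"] * 3 + ["pig"] * 3 + ["horse"] * 3
        for _ in range(15):
            noise = rng.uniform(1000, 2000, size=(9, 5))
            flags = []
            for shift in (5_000.0, 20_000.0, 100_000.0):
                data = noise.copy()
                data[6:, 0] += shift
                t = _labelled(data, labels)
                sig = {r.feature_id for r in lefse_screen(t) if r.significant}
                flags.append("f0" in sig)
            for small, big in zip(flags, flags[1:]):
                assert big or not small  # enlarging the shift never de-selects

    def test_sorted_by_effect_then_id(self, toy_table):
        results = lefse_screen(toy_table)
        keys = [(-r.effect_size, r.feature_id) for r in results]
        assert keys == sorted(keys)

    def test_per_million_idempotent(self, toy_table):
        once = normalize_per_million(toy_table)
        twice = normalize_per_million(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert np.allclose(once.data.sum(axis=1), 1e6, atol=1e-6)


class TestWelchTwoGroup:
    def test_identical_groups_null(self):
        t = _labelled([[1], [2], [3], [1], [2], [3]], ["a"] * 3 + ["b"] * 3)
        (r,) = welch_two_group(t, "a", "b")
        assert r.welch_t == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_label_swap_antisymmetry(self, toy_table):
        fwd = welch_two_group(toy_table, "a", "b")
        rev = welch_two_group(toy_table, "b", "a")
        for f, r in zip(fwd, rev):
            assert f.welch_t == pytest.approx(-r.welch_t, rel=1e-12)
            assert f.p_value == pytest.approx(r.p_value, rel=1e-12)

    def test_hand_computed_example(self):
        # groups (10,12,14) vs (1,2,3) on a two-feature table so proportions
        # stay proportional to the raw values
        data = np.array(
            [[10, 90], [12, 88], [14, 86], [1, 99], [2, 98], [3, 97]], dtype=float
        )
        t = _labelled(data, ["a"] * 3 + ["b"] * 3)
        r = welch_two_group(t, "a", "b")[0]
        assert r.welch_t == pytest.approx(7.7460, abs=1e-3)
        assert r.welch_df == pytest.approx(50 / 17, rel=1e-3)
        assert r.significant

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(41)
        values = rng.uniform(1, 100, size=(8, 5))
        t = _labelled(values, ["a"] * 4 + ["b"] * 4)
        results = welch_two_group(t, "a", "b")
        pct = values / values.sum(axis=1, keepdims=True) * 100
        for j, r in enumerate(results):
            ref = stats.ttest_ind(pct[:4, j], pct[4:, j], equal_var=False)
            assert r.welch_t == pytest.approx(ref.statistic, rel=1e-10)
            assert r.p_value == pytest.approx(ref.pvalue, rel=1e-10)
            assert r.ci_low <= r.difference <= r.ci_high
            assert r.welch_df > 0

    def test_zero_variance_degeneracies(self):
        equal = _labelled([[5, 5], [5, 5], [5, 5], [5, 5]], ["a", "a", "b", "b"])
        r = welch_two_group(equal, "a", "b")[0]
        assert r.p_value == 1.0 and not r.degenerate
        shifted = _labelled([[5, 5], [5, 5], [9, 1], [9, 1]], ["a", "a", "b", "b"])
        r = welch_two_group(shifted, "a", "b")[0]
        assert r.p_value == 0.0 and r.degenerate and r.significant

    def test_bh_correction_is_conservative(self):
        rng = np.random.default_rng(51)
        values = rng.uniform(1, 100, size=(8, 12))
        t = _labelled(values, ["a"] * 4 + ["b"] * 4)
        raw = welch_two_group(t, "a", "b", correction="none")
        adj = welch_two_group(t, "a", "b", correction="bh")
        assert sum(r.significant for r in adj) <= sum(r.significant for r in raw)

    def test_small_class_rejected(self, toy_table):
        with pytest.raises(ValidationError, match="fewer than 2"):
            welch_two_group(toy_table, "a", "missing")
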