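import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from tsrseg.agreement import (QualityRecord, RaterTable, assign_category,
                              cohens_kappa, deviation_summary, icc_a1,
                              pairwise_icc)
from tsrseg.synthetic import RaterSimConfig, simulate_raters


def _table(arr, obs=None):
    arr = np.asarray(arr, dtype=float)
    obs = obs or [f"o{i}" for i in range(arr.shape[1])]
    return RaterTable(pd.DataFrame(arr, columns=obs))


def _icc_oracle(x):
    """Brute-force two-way ANOVA mean squares via explicit nested loops."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((r - grand) ** 2 for r in row) / (n - 1)
    msc = n * sum((c - grand) ** 2 for c in col) / (k - 1)
    sse = sum((x[i, j] - row[i] - col[j] + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_raters_perfect_agreement(self):
        t = _table(np.column_stack([np.arange(5.0)] * 2) * 10)
        res = icc_a1(t)
        assert res.icc == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_constant_offset_penalized(self):
        base = np.arange(6.0) * 10
        t = _table(np.column_stack([base, base + 10]))
        assert icc_a1(t).icc < 1.0

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.uniform(0, 100, (6, 3))
            assert icc_a1(_table(x)).icc == pytest.approx(
                _icc_oracle(x), abs=1e-10)

    def test_matches_pingouin_point_and_ci(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, (12, 4))
        res = icc_a1(_table(x))
        long = pd.DataFrame({
            "subj": np.repeat(np.arange(12), 4),
            "rater": np.tile(np.arange(4), 12),
            "y": x.ravel()})
        ref = pg.intraclass_corr(long, targets="subj", raters="rater",
                                 ratings="y").set_index("Type")
        row = ref.loc["ICC(A,1)"] if "ICC(A,1)" in ref.index \
            else ref.loc["ICC2"]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-10)
        lo, hi = row.get("CI95", row.get("CI95%"))
        # pingouin prints the CI rounded to 2 decimals
        assert res.ci_low == pytest.approx(lo, abs=0.011)
        assert res.ci_high == pytest.approx(hi, abs=0.011)

    def test_invariances(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 100, (8, 3))
        base = icc_a1(_table(x)).icc
        # subject reordering
        assert icc_a1(_table(x[::-1])).icc == pytest.approx(base, abs=1e-12)
        # adding a common constant to every cell
        assert icc_a1(_table((x * 0.5) + 10)).icc == pytest.approx(
            icc_a1(_table(x * 0.5)).icc, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc_a1(_table(np.zeros((1, 3))))
        with pytest.raises(ValueError):
            icc_a1(_table(np.full((4, 3), 7.0)))  # no subject variance

    def test_missing_cells_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError):
            RaterTable(df)


class TestKappa:
    def test_identical_lists(self):
        assert cohens_kappa(["x", "y", "x"], ["x", "y", "x"]) == 1.0

    def test_chance_level_contingency(self):
        a = ["p", "p", "q", "q"]
        b = ["p", "q", "p", "q"]
        assert cohens_kappa(a, b) == pytest.approx(0.0)

    def test_hand_worked_contingency(self):
        # [[20, 5], [10, 15]] -> p_o = 0.7, p_e = 0.5, kappa = 0.4
        a = ["u"] * 25 + ["v"] * 25
        b = ["u"] * 20 + ["v"] * 5 + ["u"] * 10 + ["v"] * 15
        assert cohens_kappa(a, b) == pytest.approx(0.4, abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(3)
        a = rng.choice(["s", "t", "u"], 60).tolist()
        b = rng.choice(["s", "t", "u"], 60).tolist()
        assert cohens_kappa(a, b) == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-10)

    def test_symmetry_and_relabeling(self):
        rng = np.random.default_rng(4)
        a = rng.choice([0, 1], 40).tolist()
        b = rng.choice([0, 1], 40).tolist()
        k = cohens_kappa(a, b)
        assert cohens_kappa(b, a) == pytest.approx(k, abs=1e-12)
        relab = {0: "L", 1: "M"}
        assert cohens_kappa([relab[v] for v in a],
                            [relab[v] for v in b]) == pytest.approx(
            k, abs=1e-12)

    def test_degenerate_single_category(self):
        assert cohens_kappa(["x", "x"], ["x", "x"]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohens_kappa(["x"], ["x", "y"])


class TestPairwise:
    def test_identical_observers_all_ones(self):
        base = np.arange(6.0) * 10
        t = _table(np.column_stack([base] * 3))
        pw = pairwise_icc(t)
        for i, a in enumerate(t.observers):
            for b in t.observers[i + 1:]:
                assert pw.loc[a, b].icc == pytest.approx(1.0)

    def test_equals_per_pair_icc(self):
        rng = np.random.default_rng(5)
        t = _table(rng.uniform(0, 100, (30, 4)))
        pw = pairwise_icc(t)
        for i, a in enumerate(t.observers):
            for b in t.observers[i + 1:]:
                direct = icc_a1(t.subset([a, b]))
                assert pw.loc[a, b].icc == pytest.approx(direct.icc,
                                                         abs=1e-12)
                # and against the brute-force oracle
                x = t.values[[a, b]].to_numpy()
                assert pw.loc[a, b].icc == pytest.approx(_icc_oracle(x),
                                                         abs=1e-10)


class TestDeviationSummary:
    def _inputs(self, devs, qualities):
        n = len(devs)
        obs = np.full((n, 1), 50.0)
        ai = {i: 50.0 + d for i, d in enumerate(devs)}
        table = RaterTable(pd.DataFrame(obs, columns=["o0"],
                                        index=pd.RangeIndex(n)))
        quality = [QualityRecord(i, q, {}) for i, q in enumerate(qualities)]
        return ai, table, quality

    def test_constant_deviation(self):
        ai, table, quality = self._inputs([5.0] * 4, [9, 9, 8, 10])
        out = deviation_summary(ai, table, quality, quality_min=8.5)
        assert out["per_observer"]["o0"] == pytest.approx(5.0)
        assert out["n_rois"] == 3

    def test_threshold_above_max_quality(self):
        ai, table, quality = self._inputs([1.0, 2.0], [5.0, 6.0])
        with pytest.raises(ValueError, match="quality"):
            deviation_summary(ai, table, quality, quality_min=9.0)

    def test_recovers_configured_observer_bias(self):
        """Observers biased +11 pp, unbiased AI -> mean deviation ~ -11."""
        rng = np.random.default_rng(6)
        truth = rng.uniform(0.25, 0.75, 30)
        table = simulate_raters(truth, RaterSimConfig(
            n_rois=30, n_raters=2, bias_pp=11, noise_sd_pp=5, seed=7))
        ai = {r: 100 * truth[i] for i, r in
              enumerate(table.values.index)}
        quality = [QualityRecord(r, 9.5, {}) for r in table.values.index]
        out = deviation_summary(ai, table, quality, quality_min=9.0)
        for dev in out["per_observer"].values():
            assert dev == pytest.approx(-11, abs=2)


class TestCategories:
    @pytest.mark.parametrize("quality,dev,expected", [
        (1.5, -57.3, "A"),
        (9.0, -26.0, "B"),
        (9.0, 6.8, "C"),
        (5.0, 3.0, "D"),
    ])
    def test_worked_examples(self, quality, dev, expected):
        assert assign_category(dev, quality) == expected

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(-100, 100, allow_nan=False),
           st.floats(1, 10, allow_nan=False))
    def test_partition_of_plane(self, dev, quality):
        assert assign_category(dev, quality) in {"A", "B", "C", "D"}

    def test_quality_range_enforced(self):
        with pytest.raises(ValueError):
            assign_category(0.0, 0.5)
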