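"""Entropy-TOPSIS tests, including a from-scratch oracle of the whole chain."""

import numpy as np
import pandas as pd
import pytest

from rotation_impact import mcda


def brute_force_cei(x: np.ndarray, directions: list[str], weight_on: str = "b"):
    """Step-by-step re-evaluation of the entropy-TOPSIS chain.

    Written independently of the library implementation: plain loops, no
    shared helpers.
    """
    n, m = x.shape
    b = np.zeros_like(x, dtype=float)
    for j in range(m):
        col = x[:, j]
        lo, hi = col.min(), col.max()
        for i in range(n):
            if directions[j] == "positive":
                b[i, j] = (col[i] - lo) / (hi - lo)
            else:
                b[i, j] = (hi - col[i]) / (hi - lo)
    f = np.zeros_like(b)
    for j in range(m):
        col = b[:, j]
        if any(v == 0.0 for v in col):
            col = 1.0 + col
        s = col.sum()
        for i in range(n):
            f[i, j] = col[i] / s
    h = np.zeros(m)
    for j in range(m):
        acc = 0.0
        for i in range(n):
            if f[i, j] > 0:
                acc += f[i, j] * np.log(f[i, j])
        h[j] = -acc / np.log(n)
    w = (1.0 - h) / (1.0 - h).sum()
    base = b if weight_on == "b" else f
    z = base * w
    z_plus, z_minus = z.max(axis=0), z.min(axis=0)
    d_plus = np.sqrt(((z - z_plus) ** 2).sum(axis=1))
    d_minus = np.sqrt(((z - z_minus) ** 2).sum(axis=1))
    return b, f, h, w, d_minus / (d_plus + d_minus)


class TestNormalize:
    def test_hand_column(self):
        m = pd.DataFrame({"c": [2.0, 4.0, 10.0]}, index=list("xyz"))
        b = mcda.normalize_matrix(m, {"c": "positive"})
        assert b["c"].tolist() == pytest.approx([0.0, 0.25, 1.0])

    def test_direction_flip(self):
        m = pd.DataFrame({"c": [2.0, 10.0]}, index=list("xy"))
        pos = mcda.normalize_matrix(m, {"c": "positive"})
        neg = mcda.normalize_matrix(m, {"c": "negative"})
        assert pos.loc["x", "c"] == 0.0
        assert neg.loc["x", "c"] == 1.0

    def test_constant_criterion_named(self):
        m = pd.DataFrame({"flat": [1.0, 1.0], "ok": [0.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            mcda.normalize_matrix(m, {"flat": "positive", "ok": "positive"})


class TestEntropyWeights:
    def test_uniform_column_has_unit_entropy(self):
        b = pd.DataFrame({"u": [0.5, 0.5, 0.5], "v": [1.0, 0.2, 0.4]})
        ew = mcda.entropy_weights(b)
        assert ew.entropy["u"] == pytest.approx(1.0)
        assert ew.weights["u"] == pytest.approx(0.0)
        assert ew.weights["v"] == pytest.approx(1.0)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        b = pd.DataFrame(rng.uniform(0.01, 1, size=(5, 4)))
        assert mcda.entropy_weights(b).weights.sum() == pytest.approx(1.0)

    def test_zero_shift_column_oracle(self):
        b = pd.DataFrame([[1.0, 0.5], [0.0, 0.5], [0.5, 0.5]], columns=["a", "b"])
        ew = mcda.entropy_weights(b)
        # column a contains a zero, so the shifted proportions apply
        f_a = np.array([2.0, 1.0, 1.5]) / 4.5
        np.testing.assert_allclose(ew.proportions["a"].to_numpy(), f_a)
        h_a = -np.sum(f_a * np.log(f_a)) / np.log(3)
        # column b is uniform (entropy 1, zero information), so all weight
        # lands on column a
        assert ew.entropy["a"] == pytest.approx(h_a, abs=1e-12)
        assert ew.entropy["b"] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(ew.weights.to_numpy(), [1.0, 0.0], atol=1e-12)

    def test_single_alternative_rejected(self):
        with pytest.raises(ValueError):
            mcda.entropy_weights(pd.DataFrame({"a": [1.0]}))


class TestTopsis:
    def test_ideal_and_antiideal_alternatives(self):
        m = pd.DataFrame(
            {"c1": [10.0, 0.0, 5.0], "c2": [8.0, 1.0, 3.0]}, index=["best", "worst", "mid"]
        )
        res = mcda.cei_from_matrix(m, {"c1": "positive", "c2": "positive"})
        assert res.cei["best"] == pytest.approx(1.0)
        assert res.cei["worst"] == pytest.approx(0.0)
        assert 0.0 < res.cei["mid"] < 1.0
        assert res.ranks["best"] == 1

    def test_two_alternatives_single_criterion(self):
        m = pd.DataFrame({"c": [3.0, 9.0]}, index=["lo", "hi"])
        res = mcda.cei_from_matrix(m, {"c": "positive"})
        assert res.cei["hi"] == pytest.approx(1.0)
        assert res.cei["lo"] == pytest.approx(0.0)

    def test_hand_matrix_against_bruteforce(self):
        x = np.array([[7.0, 200.0], [3.0, 500.0], [5.0, 350.0]])
        directions = ["positive", "negative"]
        m = pd.DataFrame(x, columns=["yield", "ghg"], index=list("abc"))
        res = mcda.cei_from_matrix(m, {"yield": "positive", "ghg": "negative"})
        *_, cei = brute_force_cei(x, directions)
        np.testing.assert_allclose(res.cei.to_numpy(), cei, atol=1e-12)

    @pytest.mark.parametrize("weight_on", ["b", "f"])
    @pytest.mark.parametrize("seed", range(6))
    def test_random_matrices_against_bruteforce(self, seed, weight_on):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 7)
        m_crit = rng.integers(2, 8)
        x = rng.uniform(0, 100, size=(n, m_crit))
        directions = list(rng.choice(["positive", "negative"], size=m_crit))
        frame = pd.DataFrame(x, columns=[f"c{j}" for j in range(m_crit)])
        res = mcda.cei_from_matrix(
            frame, dict(zip(frame.columns, directions)), weight_on=weight_on
        )
        *_, cei = brute_force_cei(x, directions, weight_on=weight_on)
        np.testing.assert_allclose(res.cei.to_numpy(), cei, atol=1e-12)

    def test_cei_bounds_and_weight_sum(self):
        rng = np.random.default_rng(99)
        frame = pd.DataFrame(rng.uniform(0, 10, size=(6, 7)), columns=list("abcdefg"))
        res = mcda.cei_from_matrix(frame, {c: "positive" for c in frame.columns})
        assert ((res.cei >= 0) & (res.cei <= 1)).all()
        assert res.weights.sum() == pytest.approx(1.0)

    def test_scale_invariance_of_raw_columns(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(1, 10, size=(5, 3))
        frame = pd.DataFrame(x, columns=["a", "b", "c"])
        dirs = {"a": "positive", "b": "negative", "c": "positive"}
        res1 = mcda.cei_from_matrix(frame, dirs)
        scaled = frame.copy()
        scaled["b"] *= 1000.0
        res2 = mcda.cei_from_matrix(scaled, dirs)
        np.testing.assert_allclose(res1.cei.to_numpy(), res2.cei.to_numpy(), atol=1e-12)

    def test_dominance(self):
        # an alternative at least as good on every criterion ranks at least as high
        rng = np.random.default_rng(21)
        for _ in range(20):
            x = rng.uniform(0, 1, size=(4, 3))
            x[0] = x[1] + rng.uniform(0, 0.5, size=3)  # row 0 dominates row 1
            frame = pd.DataFrame(x, columns=["a", "b", "c"])
            res = mcda.cei_from_matrix(frame, {c: "positive" for c in frame.columns})
            assert res.cei.iloc[0] >= res.cei.iloc[1] - 1e-12

    def test_identical_alternatives_rejected(self):
        b = pd.DataFrame({"a": [0.5, 0.5], "b": [0.2, 0.2]})
        ew_weights = pd.Series({"a": 0.5, "b": 0.5})
        ew = mcda.EntropyWeights(weights=ew_weights, entropy=pd.Series({"a": 0.5, "b": 0.5}), proportions=b)
        with pytest.raises(ValueError, match="identical"):
            mcda.topsis_cei(b, ew)
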