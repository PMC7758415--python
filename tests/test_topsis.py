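"""TOPSIS ranking: standardization, closeness, class partitioning."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tomatoflavor.topsis import (
    DecisionMatrix,
    TopsisModel,
    assign_classes,
    evaluate_flavor,
    topsis,
    zscore_standardize,
)


def brute_force_topsis(values, directions, weights):
    """Independent closed-form evaluation, element by element."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    ideal, anti = [], []
    for j in range(m):
        col = values[:, j]
        if directions[j] == "benefit":
            ideal.append(col.max())
            anti.append(col.min())
        else:
            ideal.append(col.min())
            anti.append(col.max())
    out = []
    for i in range(n):
        sp = sum(w[j] ** 2 * (values[i, j] - ideal[j]) ** 2 for j in range(m)) ** 0.5
        sm = sum(w[j] ** 2 * (values[i, j] - anti[j]) ** 2 for j in range(m)) ** 0.5
        out.append(sm / (sp + sm))
    return np.asarray(out)


class TestZscore:
    def test_three_points(self):
        out = zscore_standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert list(out["a"]) == [-1.0, 0.0, 1.0]

    def test_constant_column_zeros_with_warning(self):
        with pytest.warns(UserWarning):
            out = zscore_standardize(pd.DataFrame({"a": [5.0, 5.0, 5.0]}))
        assert (out["a"] == 0).all()

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(rng.normal(5, 2, size=(40, 3)), columns=list("abc"))
        out = zscore_standardize(frame)
        assert np.allclose(out.mean(), 0, atol=1e-12)
        assert np.allclose(out.std(ddof=1), 1, atol=1e-12)

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError):
            zscore_standardize(pd.DataFrame({"a": [1.0, np.nan, 3.0]}))


class TestTopsis:
    def test_extremes_attain_ideal_and_anti_ideal(self):
        res = topsis(pd.DataFrame({"x": [1.0, 0.0]}))
        assert list(res.closeness) == [1.0, 0.0]

    def test_cost_direction_flip(self):
        res = topsis(pd.DataFrame({"x": [1.0, 0.0]}), directions={"x": "cost"})
        assert list(res.closeness) == [0.0, 1.0]

    def test_symmetric_three_by_two(self):
        vals = pd.DataFrame([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]], columns=["a", "b"])
        res = topsis(vals)
        assert np.allclose(res.closeness, 0.5)

    def test_identical_alternatives_rejected(self):
        with pytest.raises(ValueError):
            topsis(pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}))

    def test_oracle_equivalence_small_matrices(self):
        rng = np.random.default_rng(17)
        for n, m in itertools.product((2, 3, 4), (1, 2, 3)):
            values = rng.uniform(-2, 2, size=(n, m))
            for dirs in itertools.product(("benefit", "cost"), repeat=m):
                weights = rng.uniform(0.1, 1.0, size=m)
                frame = pd.DataFrame(values, columns=[f"c{j}" for j in range(m)])
                res = topsis(
                    frame,
                    directions={f"c{j}": d for j, d in enumerate(dirs)},
                    weights={f"c{j}": w for j, w in enumerate(weights)},
                )
                expected = brute_force_topsis(values, dirs, weights)
                assert np.allclose(res.closeness, expected, atol=1e-12)

    @given(arrays(float, (5, 3), elements=st.floats(-10, 10)))
    def test_closeness_always_in_unit_interval(self, values):
        frame = pd.DataFrame(values, columns=list("abc"))
        if any(frame[c].nunique() == 1 for c in frame.columns):
            frame = frame + np.arange(15).reshape(5, 3) * 1e-3
        if (frame.nunique() == 1).all():
            return
        try:
            res = topsis(frame)
        except ValueError:
            return
        assert ((res.closeness >= 0) & (res.closeness <= 1)).all()

    def test_benefit_monotonicity(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.uniform(0, 1, size=(6, 3)), columns=list("abc"))
        base = topsis(frame).closeness
        bumped = frame.copy()
        # improve a non-ideal alternative without moving the ideal point
        col = "a"
        loser = bumped[col].idxmin()
        bumped.loc[loser, col] = bumped[col].median()
        after = topsis(bumped).closeness
        assert after[loser] >= base[loser] - 1e-12

    def test_direction_symmetry_negate_and_flip(self):
        rng = np.random.default_rng(9)
        frame = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        std = zscore_standardize(frame)
        res_benefit = topsis(std)
        # negate column b and flag it cost: closeness unchanged
        neg = std.copy()
        neg["b"] = -neg["b"]
        res_neg = topsis(neg, directions={"b": "cost"})
        assert np.allclose(res_neg.closeness, res_benefit.closeness, atol=1e-12)

    def test_uniform_weights_equal_unweighted(self):
        rng = np.random.default_rng(21)
        frame = pd.DataFrame(rng.uniform(size=(5, 4)), columns=list("abcd"))
        res_none = topsis(frame)
        res_unif = topsis(frame, weights={c: 0.25 for c in "abcd"})
        assert np.allclose(res_none.closeness, res_unif.closeness, atol=1e-15)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(
            rng.uniform(size=(7, 3)), columns=list("abc"),
            index=[f"acc{i}" for i in range(7)],
        )
        res = topsis(frame)
        perm = frame.sample(frac=1, random_state=4)
        res_perm = topsis(perm)
        assert np.allclose(res_perm.closeness[res.closeness.index], res.closeness)

    def test_results_surface(self):
        frame = pd.DataFrame({"a": [1.0, 0.0, 0.5], "b": [0.2, 0.9, 0.4]})
        res = TopsisModel(frame).fit()
        summary = res.summary()
        assert list(summary.columns) == ["s_plus", "s_minus", "closeness", "closeness_z", "rank"]
        assert sorted(res.rank) == [1, 2, 3]
        assert abs(res.closeness_z.mean()) < 1e-12


class TestAssignClasses:
    def test_published_partition_sizes(self):
        rng = np.random.default_rng(13)
        scores = pd.Series(rng.uniform(size=71), index=[f"a{i}" for i in range(71)])
        labels = assign_classes(scores, sizes=(10, 20, 28, 13))
        counts = labels.value_counts()
        assert counts["I"] == 10 and counts["II"] == 20
        assert counts["III"] == 28 and counts["IV"] == 13
        # class I holds exactly the top-10 scores
        top10 = set(scores.sort_values(ascending=False).index[:10])
        assert set(labels[labels == "I"].index) == top10

    def test_single_winner(self):
        scores = pd.Series([0.9, 0.1, 0.5, 0.3])
        labels = assign_classes(scores, sizes=(1, 3, 0, 0))
        assert labels.iloc[0] == "I"
        assert (labels.iloc[1:] == "II").all()

    def test_tie_broken_by_stable_input_order(self):
        scores = pd.Series([0.5, 0.5, 0.1], index=["first", "second", "third"])
        labels = assign_classes(scores, sizes=(1, 2, 0, 0))
        assert labels["first"] == "I" and labels["second"] == "II"

    def test_sizes_must_sum(self):
        with pytest.raises(ValueError):
            assign_classes(pd.Series([1.0, 2.0]), sizes=(1, 2))

    def test_interval_breaks(self):
        scores = pd.Series([0.9, 0.6, 0.3, 0.05])
        labels = assign_classes(scores, breaks=(0.75, 0.5, 0.2))
        assert list(labels) == ["I", "II", "III", "IV"]


class TestEvaluateFlavor:
    def test_dominating_accession_scores_one(self):
        taste = pd.DataFrame(
            {"sweetness": [8.0, 4.0, 2.0], "sourness": [1.0, 3.0, 5.0]},
            index=["best", "mid", "worst"],
        )
        odor = pd.DataFrame(
            {"fruity": [10.0, 5.0, 1.0], "irritant": [0.0, 2.0, 4.0]},
            index=taste.index,
        )
        scores = evaluate_flavor(taste, odor)
        assert scores.loc["best", "c_overall"] == pytest.approx(1.0)
        assert scores.loc["worst", "c_overall"] == pytest.approx(0.0)

    def test_independent_blocks_give_uncorrelated_scores(self):
        rng = np.random.default_rng(31)
        idx = [f"a{i}" for i in range(71)]
        taste = pd.DataFrame(
            rng.normal(size=(71, 3)), columns=["sweetness", "sourness", "overall"], index=idx
        )
        odor = pd.DataFrame(
            rng.normal(size=(71, 3)), columns=["fruity", "green", "irritant"], index=idx
        )
        scores = evaluate_flavor(taste, odor)
        r = np.corrcoef(scores["c_taste"], scores["c_odor"])[0, 1]
        assert abs(r) < 0.3

    def test_mismatched_blocks_rejected(self):
        taste = pd.DataFrame({"sweetness": [1.0, 2.0]}, index=["a", "b"])
        odor = pd.DataFrame({"fruity": [1.0, 2.0]}, index=["a", "c"])
        with pytest.raises(ValueError):
            evaluate_flavor(taste, odor)


class TestDecisionMatrix:
    def test_weights_normalized(self):
        dm = DecisionMatrix(
            pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]}),
            weights={"a": 2.0, "b": 6.0},
        )
        assert dm.weight_row.sum() == pytest.approx(1.0)
        assert dm.weight_row["b"] == pytest.approx(0.75)

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            DecisionMatrix(pd.DataFrame({"a": [1.0, 2.0]}), directions={"a": "up"})

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            DecisionMatrix(pd.DataFrame({"a": [1.0]}))
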