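"""TOPSIS multi-criteria flavor ranking.

Accessions are ranked by closeness to an ideal flavor. For a decision
matrix R (alternatives x criteria) with per-criterion direction (benefit or
cost) and nonnegative weights w_j summing to one, the ideal point X+_j is
the column maximum for benefit criteria and the column minimum for cost
criteria; the anti-ideal X-_j is the opposite. Weighted Euclidean distances

    S_i+ = sqrt( sum_j w_j^2 (R_ij - X+_j)^2 )
    S_i- = sqrt( sum_j w_j^2 (R_ij - X-_j)^2 )

give the closeness coefficient C_i = S_i- / (S_i+ + S_i-) in [0, 1]; C_i = 1
exactly when the alternative attains the ideal on every criterion.

Criteria are Z-score standardized before ranking (the decision matrix is on
sensory and odor scales of very different magnitude). A Z-scored version of
C_i is also reported for comparison across runs; the canonical C_i stays in
[0, 1].

The surface follows the model/results convention: build a
:class:`TopsisModel` from a data frame plus directions and weights, call
``fit()`` and read estimates off the returned :class:`TopsisResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "zscore_standardize",
    "DecisionMatrix",
    "TopsisModel",
    "TopsisResults",
    "topsis",
    "evaluate_flavor",
    "assign_classes",
    "TASTE_CRITERIA",
    "ODOR_CRITERIA",
    "COST_CRITERIA",
]

TASTE_CRITERIA = (
    "sweetness",
    "sourness",
    "sweet_sour_ratio",
    "characteristic_flavor",
    "overall_acceptability",
)
ODOR_CRITERIA = ("green", "floral", "fruity", "vegetable", "fatty", "irritant")
COST_CRITERIA = ("sourness", "irritant")


def zscore_standardize(frame: pd.DataFrame) -> pd.DataFrame:
    """Column-wise Z-scores (sample SD). Zero-SD columns map to all zeros."""
    if len(frame) < 2:
        raise ValueError("standardization needs at least 2 rows per column")
    if frame.isna().any().any():
        raise ValueError("decision matrix has missing cells")
    out = {}
    for col in frame.columns:
        x = frame[col].astype(float)
        sd = x.std(ddof=1)
        if sd == 0:
            warnings.warn(f"column {col!r} has zero variance; standardized to zeros")
            out[col] = x * 0.0
        else:
            out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=frame.index)


@dataclass
class DecisionMatrix:
    """Alternatives x criteria values with direction flags and weights.

    ``directions`` maps each criterion to "benefit" or "cost"; unlisted
    criteria default to benefit. Weights are normalized to sum to one;
    omitted weights are uniform.
    """

    values: pd.DataFrame
    directions: dict = field(default_factory=dict)
    weights: dict | None = None

    def __post_init__(self) -> None:
        if self.values.shape[0] < 2 or self.values.shape[1] < 1:
            raise ValueError("need at least 2 alternatives and 1 criterion")
        if self.values.isna().any().any():
            raise ValueError("decision matrix has missing cells")
        bad = set(self.directions.values()) - {"benefit", "cost"}
        if bad:
            raise ValueError(f"unknown criterion directions: {sorted(bad)}")

    @property
    def direction_row(self) -> pd.Series:
        return pd.Series(
            {c: self.directions.get(c, "benefit") for c in self.values.columns}
        )

    @property
    def weight_row(self) -> pd.Series:
        cols = self.values.columns
        if self.weights is None:
            w = pd.Series(1.0, index=cols)
        else:
            w = pd.Series({c: float(self.weights.get(c, 0.0)) for c in cols})
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        return w / total


class TopsisModel:
    """TOPSIS ranking model over a prepared decision matrix.

    The matrix is used exactly as supplied (standardize beforehand, e.g.
    with :func:`zscore_standardize`, when criteria are on different scales).
    """

    def __init__(
        self,
        values: pd.DataFrame | DecisionMatrix,
        directions: dict | None = None,
        weights: dict | None = None,
    ) -> None:
        if isinstance(values, DecisionMatrix):
            self.matrix = values
        else:
            self.matrix = DecisionMatrix(values, directions or {}, weights)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        cost_criteria: tuple = (),
        weights: dict | None = None,
        standardize: bool = True,
    ) -> "TopsisModel":
        """Build a model from raw criteria, optionally Z-standardizing first."""
        values = zscore_standardize(frame) if standardize else frame
        directions = {c: "cost" for c in cost_criteria if c in frame.columns}
        return cls(values, directions, weights)

    def fit(self) -> "TopsisResults":
        m = self.matrix
        vals = m.values.astype(float)
        w = m.weight_row
        benefit = m.direction_row == "benefit"

        ideal = vals.max(axis=0).where(benefit, vals.min(axis=0))
        anti = vals.min(axis=0).where(benefit, vals.max(axis=0))
        if (ideal == anti).all():
            raise ValueError(
                "all alternatives identical on every criterion; closeness undefined"
            )

        w2 = (w**2).to_numpy()
        s_plus = np.sqrt(((vals - ideal) ** 2 * w2).sum(axis=1))
        s_minus = np.sqrt(((vals - anti) ** 2 * w2).sum(axis=1))
        closeness = s_minus / (s_plus + s_minus)
        return TopsisResults(
            model=self,
            s_plus=s_plus,
            s_minus=s_minus,
            closeness=closeness,
            ideal=ideal,
            anti_ideal=anti,
        )


@dataclass
class TopsisResults:
    """Fitted TOPSIS scores: distances, closeness, ranks, class labels."""

    model: TopsisModel
    s_plus: pd.Series
    s_minus: pd.Series
    closeness: pd.Series
    ideal: pd.Series
    anti_ideal: pd.Series

    @property
    def closeness_z(self) -> pd.Series:
        """Z-scored closeness, for cross-run comparison (may be negative)."""
        c = self.closeness
        sd = c.std(ddof=1)
        return (c - c.mean()) / sd if sd > 0 else c * 0.0

    @property
    def rank(self) -> pd.Series:
        """Rank 1 = closest to the ideal; ties broken by stable input order."""
        order = np.argsort(-self.closeness.to_numpy(), kind="stable")
        ranks = np.empty(len(order), dtype=int)
        ranks[order] = np.arange(1, len(order) + 1)
        return pd.Series(ranks, index=self.closeness.index, name="rank")

    def assign_classes(self, sizes=None, breaks=None) -> pd.Series:
        return assign_classes(self.closeness, sizes=sizes, breaks=breaks)

    def summary(self) -> pd.DataFrame:
        """Per-alternative S+, S-, C_i, Z-scored C_i and rank, best first."""
        out = pd.DataFrame(
            {
                "s_plus": self.s_plus,
                "s_minus": self.s_minus,
                "closeness": self.closeness,
                "closeness_z": self.closeness_z,
                "rank": self.rank,
            }
        )
        return out.sort_values("rank")

    def plot_ranking(self, ax=None):
        """Horizontal bar chart of closeness scores, best at the top."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, max(2, 0.25 * len(self.closeness))))
        ordered = self.closeness.sort_values()
        ax.barh(ordered.index.astype(str), ordered.to_numpy())
        ax.set_xlabel("closeness to ideal flavor $C_i$")
        return ax


def topsis(
    values: pd.DataFrame, directions: dict | None = None, weights: dict | None = None
) -> TopsisResults:
    """Functional one-shot TOPSIS on an already-prepared matrix."""
    return TopsisModel(values, directions, weights).fit()


def _roman(n: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    return numerals[n - 1]


def assign_classes(scores: pd.Series, sizes=None, breaks=None) -> pd.Series:
    """Partition scores into ordered classes I, II, ... (I = best).

    Exactly one of ``sizes`` (top-k class cardinalities after a descending
    stable sort) or ``breaks`` (descending interval cut points on the score)
    must be given. Ties are broken by stable input order.
    """
    if (sizes is None) == (breaks is None):
        raise ValueError("give exactly one of sizes or breaks")
    labels = pd.Series(index=scores.index, dtype=object)
    if sizes is not None:
        sizes = [int(s) for s in sizes]
        if any(s < 0 for s in sizes):
            raise ValueError("class sizes must be nonnegative")
        if sum(sizes) != len(scores):
            raise ValueError(
                f"class sizes sum to {sum(sizes)} but there are {len(scores)} scores"
            )
        order = np.argsort(-scores.to_numpy(), kind="stable")
        start = 0
        for k, size in enumerate(sizes, start=1):
            for pos in order[start : start + size]:
                labels.iloc[pos] = _roman(k)
            start += size
    else:
        cuts = sorted(float(b) for b in breaks)[::-1]
        for idx, val in scores.items():
            k = 1
            for cut in cuts:
                if val < cut:
                    k += 1
            labels.loc[idx] = _roman(k)
    return labels


def evaluate_flavor(
    taste: pd.DataFrame,
    odor: pd.DataFrame,
    cost_criteria: tuple = COST_CRITERIA,
    weights: dict | None = None,
) -> pd.DataFrame:
    """Taste-only, odor-only, and combined TOPSIS closeness per accession.

    Runs three independent rankings: the taste block, the odor block, and
    their concatenation, each Z-standardized; sourness and irritant odor are
    cost criteria throughout. Returns columns c_taste, c_odor, c_overall.
    """
    if not taste.index.equals(odor.index):
        raise ValueError("taste and odor blocks must cover the same accessions")
    out = {}
    for name, block in (
        ("c_taste", taste),
        ("c_odor", odor),
        ("c_overall", pd.concat([taste, odor], axis=1)),
    ):
        res = TopsisModel.from_dataframe(
            block, cost_criteria=cost_criteria, weights=weights
        ).fit()
        out[name] = res.closeness
    return pd.DataFrame(out)
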