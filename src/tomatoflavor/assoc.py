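"""Compound-versus-sensory association statistics.

Pearson correlations with two-level significance stars ("*" for p < 0.05,
"**" for p < 0.01, per-cell, uncorrected by default to match the starred
published convention; Benjamini-Hochberg adjustment is available), and a
one-way ANOVA of a flavor variable across the four fruit types (pink/red x
cherry/large-fruited).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_with_flags",
    "significance_flag",
    "CorrelationTable",
    "correlation_table",
    "anova_by_type",
]


def significance_flag(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_with_flags(x, y) -> tuple[float, float, str]:
    """Pearson r, two-sided p (t-test), and its significance star.

    Zero variance in either vector leaves r and p undefined (NaN, "").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance input; correlation undefined")
        return float("nan"), float("nan"), ""
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), significance_flag(p)


@dataclass
class CorrelationTable:
    """Correlation surface between two blocks of variables.

    ``r``, ``p`` and ``flag`` are (rows x columns) frames; ``to_frame``
    yields the compact published style "0.551**".
    """

    r: pd.DataFrame
    p: pd.DataFrame
    flag: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        formatted = self.r.round(3).astype(str) + self.flag
        return formatted.mask(self.r.isna(), "")

    def to_long(self) -> pd.DataFrame:
        rows = []
        for row in self.r.index:
            for col in self.r.columns:
                rows.append(
                    {
                        "row": row,
                        "column": col,
                        "r": self.r.loc[row, col],
                        "p": self.p.loc[row, col],
                        "flag": self.flag.loc[row, col],
                    }
                )
        return pd.DataFrame(rows)


def correlation_table(
    x_block: pd.DataFrame, y_block: pd.DataFrame, adjust: str | None = None
) -> CorrelationTable:
    """Pearson correlations of every x variable against every y variable.

    ``adjust="bh"`` applies Benjamini-Hochberg across all cells before
    flagging; the default flags raw per-cell p values.
    """
    if not x_block.index.equals(y_block.index):
        raise ValueError("blocks must share the same observations")
    r = pd.DataFrame(index=x_block.columns, columns=y_block.columns, dtype=float)
    p = r.copy()
    for xc in x_block.columns:
        for yc in y_block.columns:
            xv = x_block[xc].to_numpy(dtype=float)
            yv = y_block[yc].to_numpy(dtype=float)
            if np.std(xv) == 0 or np.std(yv) == 0:
                r.loc[xc, yc] = np.nan
                p.loc[xc, yc] = np.nan
            else:
                rr, pp = stats.pearsonr(xv, yv)
                r.loc[xc, yc] = rr
                p.loc[xc, yc] = pp
    p_for_flags = p
    if adjust == "bh":
        flat = p.to_numpy().ravel()
        ok = ~np.isnan(flat)
        adjusted = flat.copy()
        adjusted[ok] = stats.false_discovery_control(flat[ok])
        p_for_flags = pd.DataFrame(
            adjusted.reshape(p.shape), index=p.index, columns=p.columns
        )
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    flag = p_for_flags.map(significance_flag)
    return CorrelationTable(r=r, p=p_for_flags, flag=flag)


def anova_by_type(values, labels) -> tuple[float, float]:
    """One-way ANOVA F and p of ``values`` across group ``labels``.

    Groups with fewer than 2 members are excluded with a warning. When the
    within-group sum of squares is zero but group means differ, F is
    reported as infinity with p = 0.
    """
    ser = pd.Series(np.asarray(values, dtype=float))
    lab = pd.Series(list(labels))
    if len(ser) != len(lab):
        raise ValueError("values and labels must align")
    groups = []
    for name, idx in lab.groupby(lab).groups.items():
        member = ser.loc[idx].to_numpy()
        if member.size < 2:
            logger.warning("group %r has < 2 members; excluded from ANOVA", name)
            continue
        groups.append(member)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")

    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = sum(g.size for g in groups) - len(groups)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p
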