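"""GC-MS quantification: retention indices, identification filtering,
internal-standard relative quantification, and calibration correction.

The quantification chain for one chromatographic run is

1. reject identifications whose NIST forward or reverse match score is not
   strictly above 800 (of 1000),
2. convert each retained peak area to an internal-standard-relative
   concentration ``m_n = S_n * m_t / (S_t * m_0)`` where ``S_t``/``m_t`` are
   the internal-standard (3-nonanone) area and spiked concentration and
   ``m_0`` is the sample mass in kg (1 L of tomato homogenate weighs about
   1 kg, so concentrations come out in 1e-9 kg L^-1), and
3. invert the per-compound calibration line ``y = a x + b`` to correct the
   relative concentration to an absolute one, flooring small negative
   corrections at zero.

Retention indices follow the Kovats convention: every n-alkane C_n is
anchored at 100 n and a query eluting between two ladder alkanes is
interpolated, on log retention time by default or on raw retention time for
temperature-programmed runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AlkaneLadder",
    "PeakTable",
    "UnbracketedRetentionTime",
    "kovats_ri",
    "filter_identifications",
    "relative_concentration",
    "apply_calibration",
    "CalibrationFit",
    "fit_calibration",
    "quantify_run",
]

MATCH_CUTOFF = 800.0
R2_FLAG_LEVEL = 0.99


class UnbracketedRetentionTime(ValueError):
    """The query retention time is not strictly inside an alkane bracket."""


@dataclass(frozen=True)
class AlkaneLadder:
    """Ordered (carbon number, retention time) anchors of the n-alkane ladder."""

    carbons: tuple[int, ...]
    retention_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.carbons) != len(self.retention_times):
            raise ValueError("carbons and retention_times must have equal length")
        if len(self.carbons) < 2:
            raise ValueError("ladder needs at least two alkanes")
        if any(b <= a for a, b in zip(self.carbons, self.carbons[1:])):
            raise ValueError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(self.retention_times, self.retention_times[1:])):
            raise ValueError("retention times must be strictly increasing")
        if self.retention_times[0] <= 0:
            raise ValueError("retention times must be positive")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AlkaneLadder":
        frame = frame.sort_values("carbon")
        return cls(
            carbons=tuple(int(c) for c in frame["carbon"]),
            retention_times=tuple(float(t) for t in frame["retention_time"]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"carbon": self.carbons, "retention_time": self.retention_times})


@dataclass
class PeakTable:
    """Integrated peak areas of one GC-MS run.

    ``peaks`` columns: compound_id, area, retention_time, match_forward,
    match_reverse. ``istd_area``/``istd_conc`` describe the 3-nonanone
    internal standard; ``sample_mass`` is in kg.
    """

    sample_id: str
    sample_mass: float
    istd_area: float
    istd_conc: float
    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        if self.sample_mass <= 0:
            raise ValueError("sample_mass must be positive")
        if self.istd_area <= 0:
            raise ValueError("internal-standard area must be positive (run invalid)")
        if self.istd_conc <= 0:
            raise ValueError("internal-standard concentration must be positive")
        if (self.peaks["area"] <= 0).any():
            raise ValueError("peak areas must be positive")


def kovats_ri(
    rt_x: float, ladder: AlkaneLadder, mode: str = "log", boundary: str = "alkane"
) -> float:
    """Kovats retention index of a peak at retention time ``rt_x`` minutes.

    A query whose retention time coincides with a ladder alkane scores
    exactly 100 * carbon when ``boundary="alkane"`` (the query is the alkane
    itself); with ``boundary="reject"`` such a coincidence for a non-alkane
    query is reported as unbracketed. Otherwise the query must fall strictly
    between two consecutive alkanes; no extrapolation is attempted.
    """
    if mode not in ("log", "linear"):
        raise ValueError(f"unknown RI mode {mode!r}")
    if boundary not in ("alkane", "reject"):
        raise ValueError(f"unknown boundary policy {boundary!r}")
    times = ladder.retention_times
    carbons = ladder.carbons
    for z, t in zip(carbons, times):
        if rt_x == t:
            if boundary == "alkane":
                return 100.0 * z
            raise UnbracketedRetentionTime(
                f"retention time {rt_x} min coincides with the C{z} alkane; "
                "a non-alkane query is not bracketed"
            )
    if not (times[0] < rt_x < times[-1]):
        raise UnbracketedRetentionTime(
            f"retention time {rt_x} min outside alkane ladder span "
            f"[{times[0]}, {times[-1]}]"
        )
    i = int(np.searchsorted(times, rt_x)) - 1
    z, t_z, t_z1 = carbons[i], times[i], times[i + 1]
    if carbons[i + 1] != z + 1:
        raise UnbracketedRetentionTime(
            f"bracketing alkanes C{z} and C{carbons[i + 1]} are not consecutive"
        )
    if mode == "log":
        frac = (math.log(rt_x) - math.log(t_z)) / (math.log(t_z1) - math.log(t_z))
    else:
        frac = (rt_x - t_z) / (t_z1 - t_z)
    return 100.0 * z + 100.0 * frac


def filter_identifications(
    peaks: pd.DataFrame, with_reasons: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Retain peaks whose forward AND reverse match scores exceed 800 strictly.

    Peaks with missing match scores are rejected with a logged reason.
    The retained set is invariant to input row order.
    """
    fwd = pd.to_numeric(peaks["match_forward"], errors="coerce")
    rev = pd.to_numeric(peaks["match_reverse"], errors="coerce")
    missing = fwd.isna() | rev.isna()
    keep = (fwd > MATCH_CUTOFF) & (rev > MATCH_CUTOFF) & ~missing

    reasons = pd.Series("", index=peaks.index, dtype=object)
    reasons[missing] = "missing match score"
    reasons[~keep & ~missing] = "match score <= 800"
    rejected = peaks.loc[~keep].assign(reason=reasons[~keep])
    for _, row in rejected.iterrows():
        logger.info("rejected peak %s: %s", row.get("compound_id", "?"), row["reason"])
    retained = peaks.loc[keep]
    if with_reasons:
        return retained, rejected
    return retained


def relative_concentration(area, istd_area: float, istd_conc: float, sample_mass: float = 1.0):
    """Internal-standard-relative concentration m_n = S_n * m_t / (S_t * m_0).

    ``area`` may be a scalar or array of peak areas; the result is in the
    internal standard's concentration units (1e-9 kg L^-1) per kg sample.
    """
    if istd_area <= 0:
        raise ValueError("internal-standard area must be positive (run invalid)")
    if sample_mass <= 0:
        raise ValueError("sample mass must be positive")
    return np.asarray(area, dtype=float) * istd_conc / (istd_area * sample_mass)


def apply_calibration(rel_conc, slope: float, intercept: float):
    """Correct a relative concentration via the calibration line inverse.

    Returns ``x = (y - b) / a``. Negative corrections (possible with
    negative intercepts at small signals) are floored at zero; the number of
    floored values is logged.
    """
    if slope == 0:
        raise ValueError("calibration slope must be nonzero")
    x = (np.asarray(rel_conc, dtype=float) - intercept) / slope
    n_floored = int(np.sum(x < 0))
    if n_floored:
        logger.warning("floored %d negative corrected concentration(s) at 0", n_floored)
    out = np.clip(x, 0.0, None)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CalibrationFit:
    """OLS calibration line y = slope * x + intercept with its r-squared."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def flagged(self) -> bool:
        """True when the fit misses the r^2 >= 0.99 quality gate."""
        return self.r_squared < R2_FLAG_LEVEL


def fit_calibration(true_conc, measured) -> CalibrationFit:
    """Fit the calibration line from a standard dilution series by OLS."""
    x = np.asarray(true_conc, dtype=float)
    y = np.asarray(measured, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("calibration needs at least 3 distinct concentration levels")
    res = stats.linregress(x, y)
    fit = CalibrationFit(float(res.slope), float(res.intercept), float(res.rvalue) ** 2)
    if fit.flagged:
        logger.warning("calibration r^2 = %.4f below %.2f", fit.r_squared, R2_FLAG_LEVEL)
    return fit


def quantify_run(
    table: PeakTable,
    refs: dict,
    ladder: AlkaneLadder | None = None,
    ri_mode: str = "log",
) -> pd.DataFrame:
    """Quantify one run: filter, normalize to the internal standard, calibrate.

    Returns a frame indexed by compound id with columns ``rel_conc``,
    ``concentration`` (both 1e-9 kg L^-1) and, when a ladder is given,
    ``retention_index``. Peaks without a reference record are dropped with a
    logged reason.
    """
    retained = filter_identifications(table.peaks)
    rows = []
    for _, peak in retained.iterrows():
        cid = str(peak["compound_id"])
        ref = refs.get(cid)
        if ref is None:
            logger.info("no reference record for %s; dropped", cid)
            continue
        rel = float(
            relative_concentration(
                peak["area"], table.istd_area, table.istd_conc, table.sample_mass
            )
        )
        conc = apply_calibration(rel, ref.slope, ref.intercept)
        row = {"compound_id": cid, "rel_conc": rel, "concentration": conc}
        if ladder is not None:
            try:
                row["retention_index"] = kovats_ri(float(peak["retention_time"]), ladder, ri_mode)
            except UnbracketedRetentionTime:
                row["retention_index"] = float("nan")
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["rel_conc", "concentration"])
    return out.set_index("compound_id")
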