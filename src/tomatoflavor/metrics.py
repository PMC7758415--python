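"""Odor activity values, taste metrics, and aggregate flavor summaries.

The odor activity value (OAV) of a volatile is its concentration divided by
its human olfactory detection threshold; volatiles with OAV > 1 are
odor-impact compounds. Published tables report OAVs as integers rounded
half-up, with sub-one values shown as "<1"; the raw float is always kept
internally. Volatiles without a published threshold have an undefined OAV
and are excluded from every aggregate, never counted as zero.

Descriptor-based odor categories (green, floral, fruity, vegetable, fatty,
irritant) aggregate member OAVs by summation; a volatile whose descriptors
span several categories contributes its full OAV to each.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "odor_activity_value",
    "format_oav",
    "sugar_acid_ratio",
    "descriptive_stats",
    "aggregate_by_class",
    "DEFAULT_CATEGORY_KEYWORDS",
    "ODOR_CATEGORIES",
    "categorize_descriptors",
    "odor_category_oav",
    "oav_table",
    "odor_impact_set",
]

ODOR_CATEGORIES = ("green", "floral", "fruity", "vegetable", "fatty", "irritant")

# Default descriptor-word -> odor-category map, configuration rather than
# ground truth. Keywords are matched as substrings of whole descriptor
# phrases, lower-cased.
DEFAULT_CATEGORY_KEYWORDS: dict[str, tuple[str, ...]] = {
    "green": ("green", "grassy", "lettuce"),
    "floral": ("floral", "rose", "violet", "hyacinth", "gardenia"),
    "fruity": ("fruity", "apple", "citrus", "pears", "litchi", "grape", "orange"),
    "vegetable": ("vegetable", "mushroom", "earthy", "tomato vine"),
    "fatty": ("fatty", "deep-fried", "wax", "grease"),
    "irritant": (
        "irritant", "smoky", "herbal", "herbs", "spicy", "metallic",
        "wintergreen", "lilac", "cinnamon", "woody",
    ),
}


def odor_activity_value(conc: float, threshold: float | None) -> float:
    """OAV = concentration / odor threshold (same units, 1e-9 kg L^-1).

    Returns NaN when the threshold is absent: the OAV is undefined, not 0.
    """
    if threshold is None or (isinstance(threshold, float) and math.isnan(threshold)):
        return float("nan")
    if threshold <= 0:
        raise ValueError("odor threshold must be positive")
    return float(conc) / float(threshold)


def format_oav(oav: float) -> str:
    """Reporting form of an OAV: round half-up to integer, "<1" below 1."""
    if math.isnan(oav):
        return ""
    rounded = math.floor(oav + 0.5)
    return str(rounded) if rounded >= 1 else "<1"


def sugar_acid_ratio(fructose: float, glucose: float, citric: float, malic: float) -> float:
    """(fructose + glucose) / (citric + malic); undefined for zero total acid."""
    acid = citric + malic
    if acid <= 0:
        raise ValueError("total acid must be positive")
    return (fructose + glucose) / acid


def descriptive_stats(values) -> tuple[float, float, float]:
    """Mean, sample SD (n-1 denominator) and CV = SD / mean of a vector."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return mean, sd, sd / mean


def aggregate_by_class(
    mean_concs: pd.Series, refs: Mapping, label: str = "functional_class"
) -> pd.DataFrame:
    """Component counts and summed mean concentrations per compound class.

    ``mean_concs`` is indexed by compound id; ``label`` selects the grouping
    attribute ("functional_class" or "precursor_class"). Volatiles without a
    reference label fall into "other"/"unknown" with a warning.
    """
    fallback = "other" if label == "functional_class" else "unknown"
    groups: dict[str, list[float]] = {}
    for cid, conc in mean_concs.items():
        ref = refs.get(cid)
        if ref is None:
            logger.warning("volatile %s has no reference label; assigned %r", cid, fallback)
            cls = fallback
        else:
            cls = getattr(ref, label)
        groups.setdefault(cls, []).append(float(conc))
    out = pd.DataFrame(
        {
            "components": {k: len(v) for k, v in groups.items()},
            "total_concentration": {k: float(np.sum(v)) for k, v in groups.items()},
        }
    )
    out.index.name = label
    return out


def categorize_descriptors(
    descriptors: Iterable[str],
    keywords: Mapping[str, tuple[str, ...]] = DEFAULT_CATEGORY_KEYWORDS,
) -> frozenset[str]:
    """Odor categories whose keywords appear in any of the descriptor phrases."""
    cats = set()
    for phrase in descriptors:
        low = str(phrase).lower()
        for cat, words in keywords.items():
            if any(w in low for w in words):
                cats.add(cat)
    return frozenset(cats)


def odor_category_oav(
    oavs: Mapping[str, float],
    refs: Mapping,
    keywords: Mapping[str, tuple[str, ...]] = DEFAULT_CATEGORY_KEYWORDS,
) -> dict[str, float]:
    """Summed member OAVs per odor category.

    Undefined OAVs (missing thresholds) are skipped; a volatile matching no
    category contributes nowhere and is logged.
    """
    sums = {cat: 0.0 for cat in keywords}
    for cid, oav in oavs.items():
        if oav is None or (isinstance(oav, float) and math.isnan(oav)):
            continue
        ref = refs.get(cid)
        if ref is None:
            logger.info("volatile %s has no reference record; not categorized", cid)
            continue
        cats = categorize_descriptors(ref.descriptors, keywords)
        if not cats:
            logger.info("volatile %s (%s) matches no odor category", cid, ref.name)
            continue
        for cat in cats:
            sums[cat] += float(oav)
    return sums


def oav_table(concentrations: pd.DataFrame, refs: Mapping) -> pd.DataFrame:
    """Per-accession OAVs for a (accessions x compounds) concentration frame.

    Columns without a defined threshold come out as NaN.
    """
    thresholds = {}
    for cid in concentrations.columns:
        ref = refs.get(cid)
        thresholds[cid] = ref.threshold if ref is not None and ref.threshold else np.nan
    thr = pd.Series(thresholds)
    return concentrations.div(thr, axis=1)


def odor_impact_set(oavs: Mapping[str, float]) -> frozenset[str]:
    """Volatiles with OAV strictly above 1 (odor-impact compounds)."""
    return frozenset(
        cid
        for cid, v in oavs.items()
        if v is not None and not (isinstance(v, float) and math.isnan(v)) and v > 1
    )
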