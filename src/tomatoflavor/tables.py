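"""Built-in reference tables for the 71-accession tomato flavor panel.

Two curated tables ship with the package:

* ``taste_compounds.csv`` — per-accession taste chemistry of the 71 inbred
  tomato accessions (soluble solids in %, fructose/glucose/citric/malic in
  mg 100 g^-1) together with the published sugar-and-acid ratio and flavor
  class (I–IV).
* ``volatile_reference.csv`` — the 60-volatile reference: per-compound
  calibration line (measured relative concentration y versus true
  concentration x, both in 1e-9 kg L^-1), regression coefficient, retention
  time (min) and WAX retention index, odor descriptors, human olfactory
  threshold (1e-9 kg L^-1; empty when no threshold is published), the
  panel-mean concentration with its range and coefficient of variation, and
  the published integer odor-activity value.

The metabolic-precursor labels (lipid / carotenoid / Phe / amino-acid) are a
curated chemistry-based assignment, not a published per-compound table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "CompoundRef",
    "load_taste_table",
    "load_volatile_reference",
    "compound_refs",
    "FUNCTIONAL_CLASSES",
    "PRECURSOR_CLASSES",
]

FUNCTIONAL_CLASSES = ("alcohol", "aldehyde", "ketone", "ester", "phenol", "other")
PRECURSOR_CLASSES = ("lipid", "carotenoid", "Phe", "amino-acid", "unknown")


@dataclass(frozen=True)
class CompoundRef:
    """Per-volatile reference record.

    ``slope``/``intercept`` parameterize the calibration line
    ``y = slope * x + intercept`` mapping true concentration x to the
    internal-standard-relative concentration y measured by GC-MS; correction
    inverts it. ``threshold`` is the olfactory detection threshold in
    1e-9 kg L^-1, or ``None`` when no threshold is published (the odor
    activity value is then undefined, never zero).
    """

    compound_id: str
    name: str
    functional_class: str
    precursor_class: str
    slope: float
    intercept: float
    r2: float
    retention_time: float
    reference_ri: float
    descriptors: tuple[str, ...] = field(default=())
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError(f"{self.compound_id}: calibration slope must be nonzero")
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError(f"{self.compound_id}: threshold must be positive")


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("tomatoflavor.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_taste_table() -> pd.DataFrame:
    """Return the 71-accession taste-compound table, indexed by accession."""
    df = _read_packaged_csv("taste_compounds.csv").set_index("accession")
    df["fruit_type"] = [a[:2] for a in df.index]
    return df


def load_volatile_reference() -> pd.DataFrame:
    """Return the 60-volatile reference table, indexed by compound id."""
    df = _read_packaged_csv("volatile_reference.csv").set_index("compound_id")
    df["descriptors"] = df["descriptors"].fillna("")
    df["printed_oav"] = df["printed_oav"].fillna("")
    return df


def compound_refs(frame: pd.DataFrame | None = None) -> dict[str, CompoundRef]:
    """Build :class:`CompoundRef` records from a reference frame.

    With no argument, uses the packaged 60-volatile table.
    """
    if frame is None:
        frame = load_volatile_reference()
    refs: dict[str, CompoundRef] = {}
    for cid, row in frame.iterrows():
        desc = row.get("descriptors", "")
        descriptors = tuple(d.strip() for d in str(desc).split(";") if d.strip())
        threshold = row.get("threshold")
        threshold = None if pd.isna(threshold) else float(threshold)
        refs[str(cid)] = CompoundRef(
            compound_id=str(cid),
            name=str(row.get("name", cid)),
            functional_class=str(row.get("functional_class", "other")),
            precursor_class=str(row.get("precursor_class", "unknown")),
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
            r2=float(row.get("r2", float("nan"))),
            retention_time=float(row.get("retention_time", float("nan"))),
            reference_ri=float(row.get("reference_ri", float("nan"))),
            descriptors=descriptors,
            threshold=threshold,
        )
    return refs
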