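"""Synthetic tomato flavor panels with the statistical structure the
analysis assumes.

The generator emulates a 71-accession panel in four fruit types (8 pink
cherry, 11 red cherry, 15 pink large-fruited, 37 red large-fruited), 60
volatiles with log-normal concentration spread (per-volatile CVs drawn from
0.3-2.5), linear GC-MS calibration responses, a 3-nonanone internal
standard, and 50-panelist hedonic scores on a 0-8 scale with a planted
positive dependence of sweetness on fructose + glucose.

Peak areas are forward-simulated through the same physics the
quantification stage inverts:

    S_n = (a * x + b) * S_t * m_0 / m_t * exp(eps),

so at zero noise the pipeline recovers the true concentrations exactly.
Sensory scores are a latent per-accession score plus per-panelist Gaussian
noise, averaged, clipped to [0, score_max], and rounded to quarter points.

One root seed spawns independent sub-streams per stage, so each stage is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import ODOR_CATEGORIES, oav_table, odor_category_oav
from .quant import AlkaneLadder, PeakTable
from .tables import FUNCTIONAL_CLASSES, CompoundRef

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticPanel",
    "generate_panel",
    "generate_alkane_ladder",
    "default_rt_model",
]

FRUIT_TYPES = ("PC", "RC", "PL", "RL")
SENSORY_ATTRIBUTES = (
    "sweetness",
    "sourness",
    "characteristic_flavor",
    "overall_acceptability",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a synthetic flavor panel.

    Defaults reproduce the published study conditions: 71 accessions split
    8/11/15/37 over the four fruit types, 60 volatiles with concentration
    CVs in 0.3-2.5, calibration slopes spanning the reference-table range,
    thresholds log-uniform over 3.5-2e6 (1e-9 kg L^-1), 50 panelists on an
    8-point hedonic scale. ``noise_sd`` is the per-panelist score SD in
    score units; ``area_noise_cv`` the multiplicative peak-area noise.
    """

    n_accessions: int = 71
    type_proportions: tuple[float, float, float, float] = (8 / 71, 11 / 71, 15 / 71, 37 / 71)
    n_volatiles: int = 60
    concentration_cv_range: tuple[float, float] = (0.3, 2.5)
    calibration_slope_range: tuple[float, float] = (0.02, 5.0)
    calibration_intercept_range: tuple[float, float] = (-0.5, 0.5)
    threshold_range: tuple[float, float] = (3.5, 2.0e6)
    n_panelists: int = 50
    score_max: float = 8.0
    noise_sd: float = 0.8
    area_noise_cv: float = 0.05
    istd_conc: float = 65.68
    istd_area: float = 1.0e6
    sample_mass: float = 1.0
    n_decoy_peaks: int = 2
    sweetness_effect: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 2:
            raise ValueError("need at least 2 accessions")
        if abs(sum(self.type_proportions) - 1.0) > 1e-9:
            raise ValueError("type proportions must sum to 1")
        if any(p < 0 for p in self.type_proportions):
            raise ValueError("type proportions must be nonnegative")
        if self.score_max <= 0:
            raise ValueError("score_max must be positive")
        for name in (
            "concentration_cv_range",
            "calibration_slope_range",
            "calibration_intercept_range",
            "threshold_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low must be <= high")
        lo, hi = self.calibration_slope_range
        if lo <= 0 <= hi:
            raise ValueError("calibration slope range must not contain 0 (non-invertible)")
        if self.threshold_range[0] <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_panelists < 1:
            raise ValueError("need at least one panelist")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Latent state of a simulated panel, kept for recovery oracles."""

    true_concentrations: pd.DataFrame
    true_calibrations: pd.DataFrame
    true_taste: pd.DataFrame
    latent_flavor: pd.Series
    latent_scores: pd.DataFrame


@dataclass
class SyntheticPanel:
    """A generated panel: ground truth, accession profiles, GC-MS runs."""

    truth: GroundTruth
    profiles: pd.DataFrame
    peak_tables: list[PeakTable]
    refs: dict[str, CompoundRef]
    ladder: AlkaneLadder
    config: SimulationConfig


def default_rt_model(carbon: np.ndarray | float):
    """Retention time (min) of an n-alkane on the simulated polar column.

    Affine in carbon number, spanning roughly 2-38 min over C4-C26; strictly
    increasing, as any physical retention model must be.
    """
    return 2.0 + 1.6 * (np.asarray(carbon, dtype=float) - 4.0)


def generate_alkane_ladder(c_min: int, c_max: int, rt_model=default_rt_model) -> pd.DataFrame:
    """One (carbon, retention time) row per alkane from C_min to C_max."""
    if c_min >= c_max:
        raise ValueError("c_min must be < c_max")
    carbons = np.arange(c_min, c_max + 1)
    rts = np.asarray([float(rt_model(c)) for c in carbons])
    if np.any(np.diff(rts) <= 0):
        raise ValueError("rt_model must be strictly increasing over the ladder")
    return pd.DataFrame({"carbon": carbons, "retention_time": rts})


def _type_counts(config: SimulationConfig) -> dict[str, int]:
    # largest-remainder apportionment of n_accessions over the 4 types
    quotas = np.asarray(config.type_proportions) * config.n_accessions
    counts = np.floor(quotas).astype(int)
    short = config.n_accessions - counts.sum()
    for i in np.argsort(-(quotas - counts))[:short]:
        counts[i] += 1
    return dict(zip(FRUIT_TYPES, counts.tolist()))


def _lognormal(rng, mean: float, cv: float, size) -> np.ndarray:
    """Log-normal draws with the requested arithmetic mean and CV."""
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _quarter_round(x):
    return np.round(np.asarray(x) * 4.0) / 4.0


def _simulate_compound_library(config: SimulationConfig, rng) -> pd.DataFrame:
    n = config.n_volatiles
    lo, hi = config.concentration_cv_range
    cvs = rng.uniform(lo, hi, size=n)
    mean_conc = np.exp(rng.uniform(np.log(20.0), np.log(2000.0), size=n))
    s_lo, s_hi = config.calibration_slope_range
    slopes = rng.uniform(s_lo, s_hi, size=n)
    b_lo, b_hi = config.calibration_intercept_range
    intercepts = rng.uniform(b_lo, b_hi, size=n)
    t_lo, t_hi = config.threshold_range
    thresholds = np.exp(rng.uniform(np.log(t_lo), np.log(t_hi), size=n))
    # a handful of volatiles have no published threshold, mirroring the "-" rows
    n_absent = max(1, n // 12) if n >= 12 else 0
    absent = rng.choice(n, size=n_absent, replace=False) if n_absent else []
    thresholds = thresholds.astype(object)
    for i in absent:
        thresholds[i] = None
    rts = np.sort(rng.uniform(6.6, 35.0, size=n))
    classes = [FUNCTIONAL_CLASSES[i % len(FUNCTIONAL_CLASSES)] for i in range(n)]
    categories = [ODOR_CATEGORIES[i % len(ODOR_CATEGORIES)] for i in range(n)]
    return pd.DataFrame(
        {
            "compound_id": [f"SV{i + 1:02d}" for i in range(n)],
            "mean_conc": mean_conc,
            "cv": cvs,
            "slope": slopes,
            "intercept": intercepts,
            "threshold": thresholds,
            "retention_time": rts,
            "functional_class": classes,
            "descriptor": categories,
        }
    ).set_index("compound_id")


def generate_panel(config: SimulationConfig) -> SyntheticPanel:
    """Simulate a full flavor panel under ``config``.

    Deterministic for a fixed seed. Returns ground truth (for recovery
    oracles), per-accession profiles (taste chemistry, sensory scores, odor
    category OAVs), and one forward-simulated GC-MS peak table per
    accession.
    """
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_lib, rng_conc, rng_taste, rng_sens, rng_peak = (
        np.random.default_rng(s) for s in streams
    )

    counts = _type_counts(config)
    accessions = [
        f"{ftype}{i + 1}" for ftype in FRUIT_TYPES for i in range(counts[ftype])
    ]
    fruit_type = pd.Series(
        [a[:2] for a in accessions], index=accessions, name="fruit_type"
    )

    library = _simulate_compound_library(config, rng_lib)
    refs = {
        cid: CompoundRef(
            compound_id=cid,
            name=cid,
            functional_class=row["functional_class"],
            precursor_class="unknown",
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
            r2=1.0,
            retention_time=float(row["retention_time"]),
            reference_ri=float("nan"),
            descriptors=(row["descriptor"],),
            threshold=None if row["threshold"] is None else float(row["threshold"]),
        )
        for cid, row in library.iterrows()
    }

    # --- true volatile concentrations: per-volatile log-normal spread with a
    # shared per-accession odor-richness factor creating covariance
    n_acc, n_vol = config.n_accessions, config.n_volatiles
    richness = _lognormal(rng_conc, 1.0, 0.3, n_acc)
    conc = np.empty((n_acc, n_vol))
    for j, (cid, row) in enumerate(library.iterrows()):
        conc[:, j] = _lognormal(rng_conc, row["mean_conc"], row["cv"], n_acc)
    conc *= richness[:, None]
    # keep the forward calibration response a*x+b strictly positive so the
    # quantification stage can invert it (intercepts may be negative)
    for j, (_, row) in enumerate(library.iterrows()):
        a, b = row["slope"], row["intercept"]
        floor = (0.01 - b) / a if b < 0.01 else 0.0
        conc[:, j] = np.maximum(conc[:, j], max(floor, 1e-6))
    true_conc = pd.DataFrame(conc, index=accessions, columns=library.index)

    # --- taste chemistry: population means from the 71-accession panel, with
    # a cherry-fruit sugar premium
    cherry = np.isin([a[:2] for a in accessions], ("PC", "RC"))
    fructose = _lognormal(rng_taste, 1350.0, 0.18, n_acc) * np.where(cherry, 1.25, 1.0)
    glucose = fructose * 0.62 * _lognormal(rng_taste, 1.0, 0.05, n_acc)
    citric = _lognormal(rng_taste, 280.0, 0.30, n_acc)
    malic = citric / 1.77 * _lognormal(rng_taste, 1.0, 0.15, n_acc)
    true_taste = pd.DataFrame(
        {"fructose": fructose, "glucose": glucose, "citric_acid": citric, "malic_acid": malic},
        index=accessions,
    )

    # --- latent sensory structure: sweetness planted on fructose + glucose,
    # sourness on total acid, overall flavor on sugars plus odor richness
    z_sugar = _zscore(fructose + glucose)
    z_acid = _zscore(citric + malic)
    z_odor = _zscore(np.log(true_conc.sum(axis=1).to_numpy()))
    latent_flavor = 0.6 * z_sugar + 0.4 * z_odor
    latent_scores = pd.DataFrame(
        {
            "sweetness": 4.33 + config.sweetness_effect * z_sugar,
            "sourness": 4.13 + 1.0 * z_acid,
            "characteristic_flavor": 5.00 + 0.8 * latent_flavor,
            "overall_acceptability": 4.97 + 0.9 * latent_flavor,
        },
        index=accessions,
    )

    # --- panel scores: latent + per-panelist noise, averaged, clipped,
    # quarter-rounded
    scores = {}
    for attr in SENSORY_ATTRIBUTES:
        latent = latent_scores[attr].to_numpy()
        noise = rng_sens.normal(0.0, config.noise_sd, size=(config.n_panelists, n_acc))
        panel = np.clip(latent[None, :] + noise, 0.0, config.score_max)
        scores[attr] = _quarter_round(np.clip(panel.mean(axis=0), 0.0, config.score_max))
    sensory = pd.DataFrame(scores, index=accessions)
    sensory["sweet_sour_ratio"] = sensory["sweetness"] / sensory["sourness"].replace(0, np.nan)

    # --- odor category OAVs from the true concentrations
    oavs = oav_table(true_conc, refs)
    category_rows = {
        acc: odor_category_oav(oavs.loc[acc].to_dict(), refs) for acc in accessions
    }
    categories = pd.DataFrame.from_dict(category_rows, orient="index").loc[accessions]

    profiles = pd.concat(
        [fruit_type, true_taste, sensory, categories.add_prefix("oav_")], axis=1
    )
    profiles["sugar_acid_ratio"] = (profiles["fructose"] + profiles["glucose"]) / (
        profiles["citric_acid"] + profiles["malic_acid"]
    )

    # --- forward-simulated GC-MS runs
    ladder = AlkaneLadder.from_frame(generate_alkane_ladder(4, 26))
    peak_tables = []
    for acc in accessions:
        x = true_conc.loc[acc].to_numpy()
        a = library["slope"].to_numpy()
        b = library["intercept"].to_numpy()
        y = a * x + b
        areas = y * config.istd_area * config.sample_mass / config.istd_conc
        if config.area_noise_cv > 0:
            sigma2 = np.log(1.0 + config.area_noise_cv**2)
            areas = areas * rng_peak.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=n_vol)
        rows = pd.DataFrame(
            {
                "compound_id": library.index,
                "area": areas,
                "retention_time": library["retention_time"].to_numpy(),
                "match_forward": rng_peak.uniform(820, 1000, size=n_vol).round(0),
                "match_reverse": rng_peak.uniform(820, 1000, size=n_vol).round(0),
            }
        )
        if config.n_decoy_peaks:
            decoys = pd.DataFrame(
                {
                    "compound_id": [
                        f"decoy{k + 1}" for k in range(config.n_decoy_peaks)
                    ],
                    "area": rng_peak.uniform(1e3, 1e5, size=config.n_decoy_peaks),
                    "retention_time": rng_peak.uniform(7, 35, size=config.n_decoy_peaks),
                    "match_forward": rng_peak.uniform(400, 800, size=config.n_decoy_peaks).round(0),
                    "match_reverse": rng_peak.uniform(400, 800, size=config.n_decoy_peaks).round(0),
                }
            )
            rows = pd.concat([rows, decoys], ignore_index=True)
        peak_tables.append(
            PeakTable(
                sample_id=acc,
                sample_mass=config.sample_mass,
                istd_area=config.istd_area,
                istd_conc=config.istd_conc,
                peaks=rows,
            )
        )

    truth = GroundTruth(
        true_concentrations=true_conc,
        true_calibrations=library[["slope", "intercept"]].copy(),
        true_taste=true_taste,
        latent_flavor=pd.Series(latent_flavor, index=accessions, name="latent_flavor"),
        latent_scores=latent_scores,
    )
    return SyntheticPanel(
        truth=truth,
        profiles=profiles,
        peak_tables=peak_tables,
        refs=refs,
        ladder=ladder,
        config=config,
    )
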