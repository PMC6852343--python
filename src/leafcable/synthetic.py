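"""Synthetic drought experiments with known ground truth.

Emulates a glasshouse tank-bromeliad drought study: cohorts of plants
measured under wet, dry and rewetted tank conditions, with the dry
treatment degrading the outside-xylem pathway (halving k_ox by default)
while the xylem anatomy is untouched and embolism shows up only in the
stained-vein fractions.  Every generated plant carries a full set of raw
"measurements" (balance mass series, water potential, tracheid
diameters, vein census, stain counts, anatomical traits) plus the
generating truth, so the whole analysis pipeline can be validated by
parameter recovery.

Default effect sizes and noise reflect the emulated study design:
a 0.5 dry-treatment multiplier on k_ox, stained-vein probabilities of
0.815 / 0.648 / 0.765 and water potentials of -0.46 / -0.78 / -0.42 MPa
for wet / dry / rewetted, Table-2-style anatomical trait means, and a
wet-condition cable parameter alpha*l centred near 0.8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cable import LeafGeometry, alpha_length, forward_kleaf
from .flux import LeafEnvironment, MassTimeSeries, saturation_vapor_concentration
from .units import (
    WATER_MOLAR_MASS_KG_MOL,
    volumetric_to_molar,
    water_viscosity,
)
from .xylem import StainSurvey, VeinAnatomy, hagen_poiseuille_kx

__all__ = [
    "CONDITIONS",
    "TABLE_TRAIT_STATS",
    "TreatmentConfig",
    "PlantRecord",
    "GroundTruth",
    "generate_dataset",
    "true_parameter_table",
]

CONDITIONS = ("wet", "dry", "rewetted")

# Anatomical trait distributions per condition: trait -> condition -> (mean, SE).
# SEs are converted to per-plant SDs with the reference cohort size below.
TABLE_TRAIT_STATS = {
    "AER_leaf_pct": {"wet": (17.4, 0.33), "dry": (15.0, 0.60), "rewetted": (15.8, 0.72)},
    "AER_mesophyll_pct": {"wet": (41.0, 0.53), "dry": (33.7, 1.12), "rewetted": (37.6, 1.26)},
    "CHL_leaf_pct": {"wet": (25.0, 0.46), "dry": (29.4, 0.78), "rewetted": (26.3, 1.74)},
    "HYD_leaf_pct": {"wet": (57.5, 0.64), "dry": (55.7, 0.96), "rewetted": (57.9, 0.96)},
    "leaf_thickness_mm": {"wet": (0.40, 0.08), "dry": (0.38, 0.09), "rewetted": (0.38, 0.11)},
    "DVE_um": {"wet": (164.4, 4.5), "dry": (158.8, 5.4), "rewetted": (161.6, 5.5)},
    "DIV_um": {"wet": (287.9, 10.4), "dry": (277.8, 10.5), "rewetted": (288.4, 9.4)},
    "VLA_mm_mm2": {"wet": (3.91, 0.09), "dry": (3.80, 0.12), "rewetted": (3.92, 0.12)},
}
_TRAIT_REF_N = 7  # cohort size behind the SEs above


def _cv_to_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _mean_one_lognormal(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative factor with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return 1.0
    sigma = _cv_to_sigma(cv)
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise RuntimeError("could not draw a positive value; check mean/sd")


@dataclass(frozen=True)
class TreatmentConfig:
    """Study design and generative parameters for one synthetic experiment.

    Per-condition mappings are keyed by ``wet``/``dry``/``rewetted``.
    ``kleaf_multiplier`` expresses the treatment effect on whole-leaf
    conductance and is applied through the outside-xylem pathway (the
    truth k_ox is scaled), leaving xylem anatomy untouched.
    """

    n_plants: int = 7
    conditions: tuple = CONDITIONS
    kleaf_multiplier: dict = field(
        default_factory=lambda: {"wet": 1.0, "dry": 0.5, "rewetted": 1.0}
    )
    stain_probability: dict = field(
        default_factory=lambda: {"wet": 0.815, "dry": 0.648, "rewetted": 0.765}
    )
    psi_mean_mpa: dict = field(
        default_factory=lambda: {"wet": -0.46, "dry": -0.78, "rewetted": -0.42}
    )
    psi_sd_mpa: float = 0.08
    # lognormal tracheid lumen diameters (um scale): median ~10 um
    tracheid_log_mean: float = math.log(10.0)
    tracheid_log_sd: float = 0.25
    tracheids_per_vein: int = 5
    n_sampled_veins: int = 20
    vein_density_mean_per_mm: float = 3.47  # ~1000/288 um interveinal distance
    vein_density_sd_per_mm: float = 0.12
    # blade geometry (m); projected area = area_fill * width * length
    width_mean_m: float = 0.03
    width_sd_m: float = 0.003
    length_mean_m: float = 0.25
    length_sd_m: float = 0.02
    area_fill: float = 0.85
    # cable baseline: wet-condition alpha*l and biological spread of k_ox
    wet_alpha_l: float = 0.8
    kox_biological_cv: float = 0.10
    # measurement noise (multiplicative, on fluxes)
    noise_cv: float = 0.15
    # cuticular conductance truth (m s^-1) per condition
    gmin_mean_m_s: dict = field(
        default_factory=lambda: {"wet": 5.0e-5, "dry": 2.0e-5, "rewetted": 2.5e-5}
    )
    # bench environment for g_min
    t_leaf_c: float = 25.0
    t_air_c: float = 25.0
    rh_mean: float = 0.50
    rh_sd: float = 0.05
    # balance protocols (s)
    kleaf_stabilization_s: float = 600.0
    kleaf_record_s: float = 1800.0
    kleaf_step_s: float = 10.0
    gmin_record_s: float = 3600.0
    gmin_step_s: float = 60.0
    temperature_c: float = 20.0
    seed: int = 0

    def __post_init__(self):
        errors = []
        if self.n_plants < 2:
            errors.append("n_plants must be >= 2")
        for name in ("kleaf_multiplier", "stain_probability", "psi_mean_mpa", "gmin_mean_m_s"):
            mapping = getattr(self, name)
            missing = [c for c in self.conditions if c not in mapping]
            if missing:
                errors.append(f"{name} missing conditions {missing}")
        for c, v in self.kleaf_multiplier.items():
            if v <= 0:
                errors.append(f"kleaf_multiplier[{c!r}] must be > 0")
        for c, p in self.stain_probability.items():
            if not (0.0 <= p <= 1.0):
                errors.append(f"stain_probability[{c!r}] must be in [0, 1]")
        for c, p in self.psi_mean_mpa.items():
            if p >= 0:
                errors.append(f"psi_mean_mpa[{c!r}] must be < 0")
        if self.noise_cv < 0:
            errors.append("noise_cv must be >= 0")
        if self.wet_alpha_l <= 0:
            errors.append("wet_alpha_l must be > 0")
        if not (0 < self.area_fill <= 1):
            errors.append("area_fill must be in (0, 1]")
        if min(self.tracheids_per_vein, self.n_sampled_veins) < 1:
            errors.append("tracheids_per_vein and n_sampled_veins must be >= 1")
        if not (0.0 <= self.rh_mean <= 1.0):
            errors.append("rh_mean must be in [0, 1]")
        if errors:
            raise ValueError("invalid TreatmentConfig: " + "; ".join(errors))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreatmentConfig":
        d = dict(d)
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)


@dataclass(frozen=True)
class PlantRecord:
    """All raw measurements for one plant under one condition."""

    plant_id: str
    condition: str
    geometry: LeafGeometry
    anatomy: VeinAnatomy
    kleaf_series: MassTimeSeries
    gmin_series: MassTimeSeries
    psi_mpa: float
    stain: StainSurvey
    env: LeafEnvironment
    traits: dict


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters per plant, for recovery tests.

    ``table`` has one row per plant: true axial conductance, true k_ox
    (volumetric), true K_leaf (volumetric and molar), cable alpha*l,
    noiseless transpiration and g_min.
    """

    table: pd.DataFrame

    def __post_init__(self):
        if len(self.table) == 0:
            raise ValueError("ground truth must be non-empty")


def true_parameter_table(truth: GroundTruth) -> pd.DataFrame:
    """Tabular truth export, one row per plant, join key ``plant_id``."""
    return truth.table.copy()


def _linear_series(
    t0: float, span: float, step: float, m0: float, slope_g_s: float,
    stab_span: float, stab_slope_g_s: float, area_m2: float,
) -> MassTimeSeries:
    """Piecewise-linear mass record: a stabilization segment then the steady slope."""
    times = np.arange(t0, t0 + stab_span + span + 0.5 * step, step)
    masses = np.where(
        times <= stab_span,
        m0 + stab_slope_g_s * times,
        m0 + stab_slope_g_s * stab_span + slope_g_s * (times - stab_span),
    )
    return MassTimeSeries(times_s=times, masses_g=masses, leaf_area_m2=area_m2)


def generate_dataset(config: TreatmentConfig) -> tuple[list[PlantRecord], GroundTruth]:
    """Draw a complete synthetic experiment.

    Reproducible: a single global seed, with per-plant substreams derived
    from ``(seed, plant index)`` so any subset regenerates identically.

    Returns the plant records (raw measurements only, as the lab would see
    them) and the :class:`GroundTruth` table of generating parameters.
    """
    eta = water_viscosity(config.temperature_c)
    records: list[PlantRecord] = []
    truth_rows: list[dict] = []
    global_index = 0

    for condition in config.conditions:
        for i in range(config.n_plants):
            rng = np.random.default_rng([int(config.seed), global_index])
            global_index += 1
            plant_id = f"{condition}_{i + 1:02d}"

            width = _positive_normal(rng, config.width_mean_m, config.width_sd_m)
            length = _positive_normal(rng, config.length_mean_m, config.length_sd_m)
            geom = LeafGeometry(
                width_m=width, length_m=length, area_m2=config.area_fill * width * length
            )
            vein_density = _positive_normal(
                rng, config.vein_density_mean_per_mm, config.vein_density_sd_per_mm
            )
            diameters = tuple(
                tuple(
                    float(d)
                    for d in np.exp(
                        rng.normal(
                            config.tracheid_log_mean,
                            config.tracheid_log_sd,
                            config.tracheids_per_vein,
                        )
                    )
                )
                for _ in range(config.n_sampled_veins)
            )
            anatomy = VeinAnatomy(
                vein_density_per_mm=vein_density,
                leaf_width_mm=width * 1e3,
                tracheid_diameters_um=diameters,
            )
            kx_raw = hagen_poiseuille_kx(anatomy, eta)

            # k_ox truth: wet baseline centred on the target alpha*l for this
            # plant's own geometry and xylem, scaled by the treatment effect.
            kox_base = (config.wet_alpha_l / length) ** 2 * kx_raw / width
            k_ox = (
                kox_base
                * _mean_one_lognormal(rng, config.kox_biological_cv)
                * config.kleaf_multiplier[condition]
            )
            al = alpha_length(k_ox, kx_raw, geom)
            k_leaf_vol = forward_kleaf(k_ox, al)
            k_leaf_mmol = volumetric_to_molar(k_leaf_vol, config.temperature_c)

            psi = -abs(rng.normal(config.psi_mean_mpa[condition], config.psi_sd_mpa))
            psi = min(psi, -0.05)
            e_true = k_leaf_mmol * -psi  # mmol m^-2 s^-1
            e_obs = e_true * _mean_one_lognormal(rng, config.noise_cv)
            slope_g_s = -e_obs * 1e-3 * WATER_MOLAR_MASS_KG_MOL * 1e3 * geom.area_m2
            kleaf_series = _linear_series(
                0.0,
                config.kleaf_record_s,
                config.kleaf_step_s,
                m0=20.0,
                slope_g_s=slope_g_s,
                stab_span=config.kleaf_stabilization_s,
                stab_slope_g_s=1.3 * slope_g_s,
                area_m2=geom.area_m2,
            )

            rh = float(np.clip(rng.normal(config.rh_mean, config.rh_sd), 0.05, 0.95))
            env = LeafEnvironment(t_leaf_c=config.t_leaf_c, t_air_c=config.t_air_c, rh=rh)
            gmin_true = config.gmin_mean_m_s[condition] * _mean_one_lognormal(
                rng, config.kox_biological_cv
            )
            dc = saturation_vapor_concentration(env.t_leaf_c) - rh * saturation_vapor_concentration(env.t_air_c)
            gmin_rate_kg_s = (
                gmin_true
                * 2.0
                * geom.area_m2
                * dc
                * _mean_one_lognormal(rng, config.noise_cv)
            )
            gmin_series = _linear_series(
                0.0,
                config.gmin_record_s,
                config.gmin_step_s,
                m0=10.0,
                slope_g_s=-gmin_rate_kg_s * 1e3,
                stab_span=config.kleaf_stabilization_s,
                stab_slope_g_s=-1.3 * gmin_rate_kg_s * 1e3,
                area_m2=geom.area_m2,
            )

            total_veins = anatomy.n_veins
            stain = StainSurvey(
                stained=int(rng.binomial(total_veins, config.stain_probability[condition])),
                total=total_veins,
            )
            traits = {
                name: float(
                    rng.normal(
                        by_cond[condition][0],
                        by_cond[condition][1] * math.sqrt(_TRAIT_REF_N),
                    )
                )
                for name, by_cond in TABLE_TRAIT_STATS.items()
            }

            records.append(
                PlantRecord(
                    plant_id=plant_id,
                    condition=condition,
                    geometry=geom,
                    anatomy=anatomy,
                    kleaf_series=kleaf_series,
                    gmin_series=gmin_series,
                    psi_mpa=float(psi),
                    stain=stain,
                    env=env,
                    traits=traits,
                )
            )
            truth_rows.append(
                {
                    "plant_id": plant_id,
                    "condition": condition,
                    "kx_raw_m4": kx_raw,
                    "k_ox_vol": k_ox,
                    "k_leaf_vol": k_leaf_vol,
                    "k_leaf_mmol": k_leaf_mmol,
                    "alpha_l": al,
                    "e_true_mmol": e_true,
                    "psi_mpa": float(psi),
                    "gmin_true_m_s": gmin_true,
                }
            )

    return records, GroundTruth(table=pd.DataFrame(truth_rows))
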