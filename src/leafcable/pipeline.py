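"""End-to-end analysis: raw records -> conductances, partitions, summaries.

For every plant the pipeline computes the transpiration rate and K_leaf
from the balance record, the theoretical axial conductance from tracheid
anatomy, the embolism-adjusted (stained) axial conductance, the inferred
outside-xylem conductance (plain and stained) from the leaky-cable
inverse solve, the cable parameter alpha*l, resistance percentages, and
cuticular g_min.  Per-treatment reporting mirrors the conventions of the
ecophysiology literature: trait means +/- SE with one-way ANOVA F and p,
and Pearson correlation matrices between conductances and anatomical
traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import flux, units, xylem
from .cable import CableState, resistance_fractions, sensitivity_curve, solve_kox
from .synthetic import PlantRecord

__all__ = [
    "AnalysisSettings",
    "GroupSummary",
    "analyze",
    "group_summary",
    "pearson_matrix",
    "summarize_groups",
]

log = logging.getLogger(__name__)

#: Conductance columns reported in mmol m^-2 s^-1 MPa^-1.
MOLAR_COLUMNS = ("k_leaf", "kx_norm", "kx_stained_norm", "k_ox", "k_ox_stained")


@dataclass(frozen=True)
class AnalysisSettings:
    """Knobs of the per-plant computation."""

    stabilization_s: float = flux.DEFAULT_STABILIZATION_S
    temperature_c: float = 20.0
    sensitivity_fractions: np.ndarray | None = None


@dataclass(frozen=True)
class GroupSummary:
    """Per-condition means +/- SE with a one-way ANOVA across conditions."""

    name: str
    means: dict
    ses: dict
    ns: dict
    f_statistic: float
    p_value: float


def _analyze_one(r: PlantRecord, s: AnalysisSettings) -> dict:
    eta = units.water_viscosity(s.temperature_c)
    e = flux.transpiration_rate(r.kleaf_series, stabilization_s=s.stabilization_s)
    k_leaf_mmol = flux.kleaf_from_flux(e, r.psi_mpa)
    k_leaf_vol = units.molar_to_volumetric(k_leaf_mmol, s.temperature_c)

    kx_raw = xylem.hagen_poiseuille_kx(r.anatomy, eta)
    kx_norm = units.normalize_axial(
        kx_raw, r.geometry.length_m, r.geometry.area_m2, s.temperature_c
    )
    stained_fraction = r.stain.stained_fraction
    kx_stained_raw = xylem.stain_adjusted_kx(kx_raw, stained_fraction)
    kx_stained_norm = xylem.stain_adjusted_kx(kx_norm, stained_fraction)

    state = solve_kox(k_leaf_vol, kx_raw, r.geometry)
    state_stained = (
        solve_kox(k_leaf_vol, kx_stained_raw, r.geometry)
        if kx_stained_raw > 0
        else None
    )

    k_ox_mmol = units.volumetric_to_molar(state.k_ox, s.temperature_c)
    rx_pct, rox_pct = resistance_fractions(kx_norm, k_ox_mmol)
    row = {
        "plant_id": r.plant_id,
        "condition": r.condition,
        "e_mmol": e,
        "psi_mpa": r.psi_mpa,
        "k_leaf": k_leaf_mmol,
        "kx_raw_m4": kx_raw,
        "kx_norm": kx_norm,
        "stained_fraction": stained_fraction,
        "percent_embolism": xylem.percent_embolism(r.stain),
        "kx_stained_norm": kx_stained_norm,
        "k_ox_vol": state.k_ox,
        "k_ox": k_ox_mmol,
        "alpha_l": state.alpha_l,
        "rx_pct": rx_pct,
        "rox_pct": rox_pct,
    }
    if state_stained is not None:
        k_ox_st_mmol = units.volumetric_to_molar(state_stained.k_ox, s.temperature_c)
        rx_st, rox_st = resistance_fractions(kx_stained_norm, k_ox_st_mmol)
        row.update(
            {
                "k_ox_stained_vol": state_stained.k_ox,
                "k_ox_stained": k_ox_st_mmol,
                "alpha_l_stained": state_stained.alpha_l,
                "rx_pct_stained": rx_st,
                "rox_pct_stained": rox_st,
            }
        )
    else:
        row.update(
            {
                "k_ox_stained_vol": np.nan,
                "k_ox_stained": np.nan,
                "alpha_l_stained": np.nan,
                "rx_pct_stained": np.nan,
                "rox_pct_stained": np.nan,
            }
        )
    try:
        gmin_rate = -flux.mass_loss_slope(
            r.gmin_series, stabilization_s=s.stabilization_s
        ) * 1e-3  # g/s -> kg/s
        row["gmin_m_s"] = flux.gmin(gmin_rate, r.geometry.area_m2, r.env)
    except (flux.FluxError, units.DomainError) as exc:
        log.warning("g_min skipped for %s: %s", r.plant_id, exc)
        row["gmin_m_s"] = np.nan
    row.update(r.traits)
    return row


def analyze(
    records: list[PlantRecord], settings: AnalysisSettings | None = None
) -> dict:
    """Run the full per-plant computation and the wet-baseline sensitivity.

    Returns a dict with:

    ``conductances``
        One row per plant (sorted by condition then plant_id) with all
        conductances, the cable solution, resistance percentages and
        traits.  Solver or flux failures skip the row with a logged
        warning; they never abort the run.
    ``sensitivity``
        K_leaf ratio vs K_x fraction for the mean wet-condition alpha*l
        (empty if no wet plant solved).
    """
    s = settings or AnalysisSettings()
    rows = []
    for r in records:
        try:
            rows.append(_analyze_one(r, s))
        except (units.DomainError, flux.FluxError, RuntimeError) as exc:
            log.warning("plant %s skipped: %s", r.plant_id, exc)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["condition", "plant_id"]).reset_index(drop=True)

    sens = pd.DataFrame(columns=["fraction", "kleaf_ratio", "baseline_alpha_l"])
    wet = table[table["condition"] == "wet"] if len(table) else table
    if len(wet):
        alpha_l0 = float(wet["alpha_l"].mean())
        curve = sensitivity_curve(alpha_l0, s.sensitivity_fractions)
        sens = pd.DataFrame(
            {
                "fraction": curve.fractions,
                "kleaf_ratio": curve.kleaf_ratio,
                "baseline_alpha_l": curve.baseline_alpha_l,
            }
        )
    return {"conductances": table, "sensitivity": sens}


def group_summary(values_by_condition: dict, name: str = "") -> GroupSummary:
    """Means +/- SE per condition and classical one-way ANOVA across them.

    Requires at least two groups with at least two values each.
    """
    groups = {c: np.asarray(v, dtype=float) for c, v in values_by_condition.items()}
    groups = {c: v[~np.isnan(v)] for c, v in groups.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("group_summary needs >= 2 groups with >= 2 values each")
    f, p = stats.f_oneway(*groups.values())
    if not np.isfinite(f):  # all groups identical/constant
        f, p = 0.0, 1.0
    return GroupSummary(
        name=name,
        means={c: float(np.mean(v)) for c, v in groups.items()},
        ses={c: float(np.std(v, ddof=1) / np.sqrt(len(v))) for c, v in groups.items()},
        ns={c: int(len(v)) for c, v in groups.items()},
        f_statistic=float(f),
        p_value=float(p),
    )


def summarize_groups(
    table: pd.DataFrame, columns: list[str], by: str = "condition"
) -> pd.DataFrame:
    """Tidy per-condition summary (mean, SE, n, ANOVA F/p) for many columns."""
    out = []
    for col in columns:
        gs = group_summary(
            {c: g[col].to_numpy() for c, g in table.groupby(by)}, name=col
        )
        for cond in gs.means:
            out.append(
                {
                    "variable": col,
                    by: cond,
                    "mean": gs.means[cond],
                    "se": gs.ses[cond],
                    "n": gs.ns[cond],
                    "anova_F": gs.f_statistic,
                    "anova_p": gs.p_value,
                }
            )
    return pd.DataFrame(out)


def pearson_matrix(trait_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p between numeric columns.

    Rows with missing data are dropped pairwise; a pair with fewer than 3
    complete rows or a zero-variance member gets NaN (undefined, not 0).
    Returns ``(r, p)`` DataFrames; r is symmetric with unit diagonal.
    """
    cols = list(trait_table.columns)
    r = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    p = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    for i, a in enumerate(cols):
        r.loc[a, a], p.loc[a, a] = 1.0, 0.0
        for b in cols[i + 1 :]:
            pair = trait_table[[a, b]].dropna()
            if len(pair) < 3:
                continue
            x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = float(res.statistic)
            p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return r, p
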