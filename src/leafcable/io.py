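"""CSV dataset round-tripping.

A dataset directory holds one experiment in plain CSV files:

* ``plants.csv`` — plant_id, condition, geometry, vein density and the
  per-plant anatomical trait columns;
* ``tracheids.csv`` — one row per measured tracheid (plant_id, vein_id,
  diameter_um);
* ``stains.csv`` — plant_id, stained, total;
* ``mass_series.csv`` — plant_id, phase (kleaf|gmin), time_s, mass_g;
* ``psi.csv`` — plant_id, psi_MPa;
* ``env.csv`` — plant_id, t_leaf_C, t_air_C, rh;
* ``truth.csv`` — generating parameters (synthetic datasets only).

The same schemas are written by the simulator and read by the analysis,
so real data prepared to these schemas drops straight in.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cable import LeafGeometry
from .flux import LeafEnvironment, MassTimeSeries
from .synthetic import GroundTruth, PlantRecord, TABLE_TRAIT_STATS
from .xylem import StainSurvey, VeinAnatomy

__all__ = ["write_dataset", "read_dataset"]

_TRAIT_COLUMNS = list(TABLE_TRAIT_STATS)


def write_dataset(
    records: list[PlantRecord], out_dir: str | Path, truth: GroundTruth | None = None
) -> None:
    """Write an experiment to ``out_dir`` (created if needed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    plants, tracheids, stains, series, psi, env = [], [], [], [], [], []
    for r in records:
        row = {
            "plant_id": r.plant_id,
            "condition": r.condition,
            "width_m": r.geometry.width_m,
            "length_m": r.geometry.length_m,
            "area_m2": r.geometry.area_m2,
            "vein_density_per_mm": r.anatomy.vein_density_per_mm,
        }
        row.update({k: r.traits.get(k) for k in _TRAIT_COLUMNS})
        plants.append(row)
        for vein_id, vein in enumerate(r.anatomy.tracheid_diameters_um):
            for d in vein:
                tracheids.append(
                    {"plant_id": r.plant_id, "vein_id": vein_id, "diameter_um": d}
                )
        stains.append(
            {"plant_id": r.plant_id, "stained": r.stain.stained, "total": r.stain.total}
        )
        for phase, s in (("kleaf", r.kleaf_series), ("gmin", r.gmin_series)):
            for t, m in zip(s.times_s, s.masses_g):
                series.append(
                    {"plant_id": r.plant_id, "phase": phase, "time_s": t, "mass_g": m}
                )
        psi.append({"plant_id": r.plant_id, "psi_MPa": r.psi_mpa})
        env.append(
            {
                "plant_id": r.plant_id,
                "t_leaf_C": r.env.t_leaf_c,
                "t_air_C": r.env.t_air_c,
                "rh": r.env.rh,
            }
        )

    pd.DataFrame(plants).to_csv(out / "plants.csv", index=False)
    pd.DataFrame(tracheids).to_csv(out / "tracheids.csv", index=False)
    pd.DataFrame(stains).to_csv(out / "stains.csv", index=False)
    pd.DataFrame(series).to_csv(out / "mass_series.csv", index=False)
    pd.DataFrame(psi).to_csv(out / "psi.csv", index=False)
    pd.DataFrame(env).to_csv(out / "env.csv", index=False)
    if truth is not None:
        truth.table.to_csv(out / "truth.csv", index=False)


def read_dataset(in_dir: str | Path) -> tuple[list[PlantRecord], GroundTruth | None]:
    """Load an experiment written by :func:`write_dataset`.

    Returns the plant records sorted by (condition, plant_id) and the
    ground truth if a ``truth.csv`` is present.
    """
    src = Path(in_dir)
    plants = pd.read_csv(src / "plants.csv")
    tracheids = pd.read_csv(src / "tracheids.csv")
    stains = pd.read_csv(src / "stains.csv").set_index("plant_id")
    series = pd.read_csv(src / "mass_series.csv")
    psi = pd.read_csv(src / "psi.csv").set_index("plant_id")
    env = pd.read_csv(src / "env.csv").set_index("plant_id")

    records = []
    for _, p in plants.sort_values(["condition", "plant_id"]).iterrows():
        pid = p["plant_id"]
        geom = LeafGeometry(
            width_m=p["width_m"], length_m=p["length_m"], area_m2=p["area_m2"]
        )
        tr = tracheids[tracheids["plant_id"] == pid]
        diameters = tuple(
            tuple(g["diameter_um"].to_list())
            for _, g in tr.groupby("vein_id", sort=True)
        )
        anatomy = VeinAnatomy(
            vein_density_per_mm=p["vein_density_per_mm"],
            leaf_width_mm=p["width_m"] * 1e3,
            tracheid_diameters_um=diameters,
        )
        by_phase = {}
        for phase, g in series[series["plant_id"] == pid].groupby("phase"):
            g = g.sort_values("time_s")
            by_phase[phase] = MassTimeSeries(
                times_s=g["time_s"].to_numpy(),
                masses_g=g["mass_g"].to_numpy(),
                leaf_area_m2=geom.area_m2,
            )
        st = stains.loc[pid]
        ev = env.loc[pid]
        records.append(
            PlantRecord(
                plant_id=pid,
                condition=p["condition"],
                geometry=geom,
                anatomy=anatomy,
                kleaf_series=by_phase["kleaf"],
                gmin_series=by_phase["gmin"],
                psi_mpa=float(psi.loc[pid, "psi_MPa"]),
                stain=StainSurvey(stained=int(st["stained"]), total=int(st["total"])),
                env=LeafEnvironment(
                    t_leaf_c=float(ev["t_leaf_C"]),
                    t_air_c=float(ev["t_air_C"]),
                    rh=float(ev["rh"]),
                ),
                traits={k: float(p[k]) for k in _TRAIT_COLUMNS if k in p},
            )
        )

    truth = None
    if (src / "truth.csv").exists():
        truth = GroundTruth(table=pd.read_csv(src / "truth.csv"))
    return records, truth
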