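"""CSV dialects and serialization for all fluxlens inputs and outputs.

All interchange formats are plain-text CSV/JSON. Flow-cytometry event
tables use the CSV dialect ``sample_id,fl1,fl3``; binary FCS containers are
not parsed here — export events to CSV first.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from fluxlens.calibration import ConditionDataset
from fluxlens.cytometry import EventTable
from fluxlens.errors import ConfigError, InvalidInputError
from fluxlens.binding import GelLane, MeltCurve, TmSeries
from fluxlens.physiology import BatchTimecourse
from fluxlens.timelapse import CellTrace, PhaseProfile


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigError(f"{what}: missing column(s) {', '.join(missing)}")


# -- binding ----------------------------------------------------------------

def read_melt_curves(path: str | Path) -> List[MeltCurve]:
    """Read melt curves: ``ligand_mM,replicate,temperature_C,fluorescence``."""
    df = pd.read_csv(path)
    _require_columns(df, ["ligand_mM", "replicate", "temperature_C", "fluorescence"], str(path))
    curves = []
    for (lig, rep), grp in df.groupby(["ligand_mM", "replicate"], sort=True):
        grp = grp.sort_values("temperature_C")
        curves.append(
            MeltCurve(
                ligand_concentration=float(lig),
                temperatures=grp["temperature_C"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
                replicate_id=str(rep),
            )
        )
    return curves


def read_tm_series(path: str | Path) -> TmSeries:
    """Read a Tm table: ``ligand_mM,replicate,tm_C``."""
    df = pd.read_csv(path)
    _require_columns(df, ["ligand_mM", "tm_C"], str(path))
    return TmSeries(df["ligand_mM"].to_numpy(float), df["tm_C"].to_numpy(float))


def write_tm_series(series: TmSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "ligand_mM": series.ligand_concentrations,
            "replicate": np.arange(series.tm_values.size),
            "tm_C": series.tm_values,
        }
    ).to_csv(path, index=False)


def read_gel_lanes(path: str | Path) -> List[GelLane]:
    """Read gel lanes: ``fbp_mM,complex_au,free_au``."""
    df = pd.read_csv(path)
    _require_columns(df, ["fbp_mM", "complex_au", "free_au"], str(path))
    return [
        GelLane(float(r.fbp_mM), float(r.complex_au), float(r.free_au))
        for r in df.itertuples()
    ]


# -- calibration ------------------------------------------------------------

def read_conditions(measurements_path: str | Path, summary_path: str | Path) -> List[ConditionDataset]:
    """Read per-measurement FBP plus per-condition flux/growth summaries.

    Measurements CSV: ``condition_id,strain,carbon_source,fbp_mM`` (one row
    per measurement; strain/carbon_source optional). Summary CSV:
    ``condition_id,flux_mean,flux_sd,growth_mean,growth_sd``.
    """
    meas = pd.read_csv(measurements_path)
    summ = pd.read_csv(summary_path)
    _require_columns(meas, ["condition_id", "fbp_mM"], str(measurements_path))
    _require_columns(summ, ["condition_id", "flux_mean", "flux_sd"], str(summary_path))
    summ = summ.set_index("condition_id")
    conditions = []
    for cid, grp in meas.groupby("condition_id", sort=True):
        if cid not in summ.index:
            raise ConfigError(f"summary: missing condition {cid!r}")
        row = summ.loc[cid]
        conditions.append(
            ConditionDataset(
                condition_id=str(cid),
                fbp_measurements=grp["fbp_mM"].to_numpy(float),
                flux_mean=float(row["flux_mean"]),
                flux_sd=float(row["flux_sd"]),
                growth_mean=float(row.get("growth_mean", np.nan)),
                growth_sd=float(row.get("growth_sd", np.nan)),
            )
        )
    return conditions


def write_conditions(
    conditions: Sequence[ConditionDataset],
    measurements_path: str | Path,
    summary_path: str | Path,
) -> None:
    rows = [
        {"condition_id": c.condition_id, "fbp_mM": v}
        for c in conditions
        for v in c.fbp_measurements
    ]
    pd.DataFrame(rows).to_csv(measurements_path, index=False)
    pd.DataFrame(
        [
            {
                "condition_id": c.condition_id,
                "flux_mean": c.flux_mean,
                "flux_sd": c.flux_sd,
                "growth_mean": c.growth_mean,
                "growth_sd": c.growth_sd,
            }
            for c in conditions
        ]
    ).to_csv(summary_path, index=False)


# -- physiology -------------------------------------------------------------

def read_batch_timecourse(
    path: str | Path, roles: Dict[str, str] | None = None
) -> BatchTimecourse:
    """Read ``time_h,biomass_gdw_l,<metabolite>_g_l,...``.

    Roles default to 'uptake' for glucose/maltose/galactose and 'product'
    otherwise; pass ``roles`` to override.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["time_h", "biomass_gdw_l"], str(path))
    default_uptake = {"glucose", "maltose", "galactose", "pyruvate"}
    metabolites, role_map = {}, {}
    for col in df.columns:
        if col.endswith("_g_l") and col != "biomass_gdw_l":
            name = col[: -len("_g_l")]
            metabolites[name] = df[col].to_numpy(float)
            if roles and name in roles:
                role_map[name] = roles[name]
            else:
                role_map[name] = "uptake" if name in default_uptake else "product"
    return BatchTimecourse(
        times=df["time_h"].to_numpy(float),
        biomass=df["biomass_gdw_l"].to_numpy(float),
        metabolites=metabolites,
        roles=role_map,
    )


def write_batch_timecourse(tc: BatchTimecourse, path: str | Path) -> None:
    out = {"time_h": tc.times, "biomass_gdw_l": tc.biomass}
    for name, series in tc.metabolites.items():
        out[f"{name}_g_l"] = series
    pd.DataFrame(out).to_csv(path, index=False)


# -- cytometry --------------------------------------------------------------

def read_events(path: str | Path) -> EventTable:
    """Read a cytometry event table from CSV (``sample_id,fl1,fl3``).

    Binary FCS files are not supported; export the FL1-A/FL3-A channels to
    this CSV dialect first.
    """
    path = Path(path)
    if path.suffix.lower() == ".fcs":
        raise InvalidInputError(
            "binary FCS input is not supported; export channels FL1-A/FL3-A "
            "to CSV with columns sample_id,fl1,fl3"
        )
    df = pd.read_csv(path)
    _require_columns(df, ["fl1", "fl3"], str(path))
    sample_id = str(df["sample_id"].iloc[0]) if "sample_id" in df.columns else path.stem
    return EventTable(df["fl1"].to_numpy(float), df["fl3"].to_numpy(float), sample_id)


def write_events(events: EventTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": events.sample_id, "fl1": events.fl1, "fl3": events.fl3}
    ).to_csv(path, index=False)


# -- timelapse --------------------------------------------------------------

_TRACE_COLS = [
    "cell_id",
    "time_min",
    "mother_R_um",
    "mother_r_um",
    "daughter_R_um",
    "daughter_r_um",
    "yfp_au",
    "mcherry_au",
]


def read_traces(traces_path: str | Path, events_path: str | Path) -> List[CellTrace]:
    """Read trace and event CSVs into :class:`CellTrace` objects.

    Traces: ``cell_id,time_min,mother_R_um,mother_r_um,daughter_R_um,
    daughter_r_um,yfp_au,mcherry_au`` with empty daughter fields where the
    bud was not segmentable. Events: ``cell_id,event,time_min`` with event
    one of budding|cytokinesis.
    """
    tdf = pd.read_csv(traces_path)
    edf = pd.read_csv(events_path)
    _require_columns(tdf, _TRACE_COLS, str(traces_path))
    _require_columns(edf, ["cell_id", "event", "time_min"], str(events_path))
    traces = []
    for cid, grp in tdf.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_min")
        ev = edf[edf["cell_id"] == cid]
        traces.append(
            CellTrace(
                cell_id=str(cid),
                times=grp["time_min"].to_numpy(float),
                mother_major=grp["mother_R_um"].to_numpy(float),
                mother_minor=grp["mother_r_um"].to_numpy(float),
                daughter_major=grp["daughter_R_um"].to_numpy(float),
                daughter_minor=grp["daughter_r_um"].to_numpy(float),
                yfp_mean=grp["yfp_au"].to_numpy(float),
                mcherry_mean=grp["mcherry_au"].to_numpy(float),
                budding_times=ev.loc[ev["event"] == "budding", "time_min"].to_numpy(float),
                cytokinesis_times=ev.loc[
                    ev["event"] == "cytokinesis", "time_min"
                ].to_numpy(float),
            )
        )
    return traces


def write_traces(
    traces: Sequence[CellTrace], traces_path: str | Path, events_path: str | Path
) -> None:
    rows, ev_rows = [], []
    for tr in traces:
        for i, t in enumerate(tr.times):
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "time_min": t,
                    "mother_R_um": tr.mother_major[i],
                    "mother_r_um": tr.mother_minor[i],
                    "daughter_R_um": tr.daughter_major[i],
                    "daughter_r_um": tr.daughter_minor[i],
                    "yfp_au": tr.yfp_mean[i],
                    "mcherry_au": tr.mcherry_mean[i],
                }
            )
        ev_rows.extend(
            {"cell_id": tr.cell_id, "event": "budding", "time_min": t}
            for t in tr.budding_times
        )
        ev_rows.extend(
            {"cell_id": tr.cell_id, "event": "cytokinesis", "time_min": t}
            for t in tr.cytokinesis_times
        )
    pd.DataFrame(rows).to_csv(traces_path, index=False)
    pd.DataFrame(ev_rows).to_csv(events_path, index=False)


def write_phase_profile(profile: PhaseProfile, csv_path: str | Path, json_path: str | Path) -> None:
    """Write the profile curve to CSV and its metadata to JSON."""
    pd.DataFrame(
        {
            "phase": profile.phase,
            "mean": profile.mean,
            "ci_low": profile.ci_low,
            "ci_high": profile.ci_high,
        }
    ).to_csv(csv_path, index=False)
    meta = {
        "n_cycles": profile.n_cycles,
        "mean_budding_phase": profile.mean_budding_phase,
        "seed": profile.seed,
        "exclusions": [list(e) for e in profile.exclusions],
        "peak_phase": profile.peak_phase(),
    }
    Path(json_path).write_text(json.dumps(meta, indent=2))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
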