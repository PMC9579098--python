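"""Exposure, vessel, and environment explanatory variables per bin.

Impact covariates follow the whale along its track at a 30-s cadence:
SEL_30s per source type (seismic vs vessel kept separate throughout; the
pile channel exists but is excluded from default models), the accumulated
cSEL (energy sum from track start), closest vessel and closest seismic
vessel distances, vessel count, and ROW (relative orientation whale ->
vessel, 0 = toward, 180 = away). Natural covariates (depth, tide, station,
date/time, sea state, visibility, behavior state) come from the environment
at the bin midpoint.

Bin summaries: SEL_30s is the energy mean of the bin's 30-s steps (which
keeps it on the same energy scale as cSEL and is bounded by the step min and
max); cSEL is the value at bin end; distances are bin minima.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .soundfield import SOURCE_TYPES, SoundField
from .trackmetrics import azimuth_deg, fold_angle_deg, vessel_positions_at

EPOCH_S = 30.0


def exposure_series(times, xs, ys, field: SoundField,
                    whale_id: str | None = None) -> pd.DataFrame:
    """Per-type SEL_30s/SPL at every 30-s epoch of an interpolated whale path."""
    times = np.asarray(times, dtype=float)
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    many = field.evaluate_many(xs, ys, times)
    out = pd.DataFrame({"t_s": times, "x_m": xs, "y_m": ys})
    from .soundfield import TEN_LOG_30
    for typ in SOURCE_TYPES:
        out[f"sel30_{typ}"] = many[typ]
        out[f"spl_{typ}"] = many[typ] - TEN_LOG_30
    out["sel30_combined"] = many["combined"]
    if whale_id is not None:
        out["whale_id"] = whale_id
    return out


def accumulate_csel(sel_db) -> np.ndarray:
    """Accumulated SEL: cSEL_k = 10 log10 sum_{i<=k} 10^(SEL_i/10).

    Missing (NaN) steps are skipped: cSEL carries the running energy total
    forward and stays NaN until the first finite step. Restarts belong to the
    caller (cSEL accumulates per track, not per bin).
    """
    sel = np.asarray(sel_db, dtype=float)
    energy = np.where(np.isfinite(sel), 10.0 ** (sel / 10.0), 0.0)
    cum = np.cumsum(energy)
    with np.errstate(divide="ignore"):
        out = 10.0 * np.log10(cum)
    out[cum <= 0] = np.nan
    return out


def energy_mean_db(levels_db) -> float:
    """Energy mean: 10 log10(mean 10^(L/10)) over finite entries."""
    lv = np.asarray(levels_db, dtype=float)
    lv = lv[np.isfinite(lv)]
    if lv.size == 0:
        return float("nan")
    return float(10.0 * np.log10(np.mean(10.0 ** (lv / 10.0))))


def vessel_covariates(x: float, y: float, movement_azimuth_deg: float,
                      fleet: pd.DataFrame) -> dict:
    """Distances, count, and ROW for one whale position against the fleet.

    ``fleet`` holds one row per vessel with x_m, y_m, vessel_type. An empty
    fleet yields NaN distances/ROW and count 0.
    """
    if fleet is None or len(fleet) == 0:
        return {"ves_distance_km": float("nan"), "sv_distance_km": float("nan"),
                "n_vessels": 0, "row_cv_deg": float("nan"),
                "row_sv_deg": float("nan")}
    d = np.hypot(fleet["x_m"].to_numpy(float) - x,
                 fleet["y_m"].to_numpy(float) - y) / 1000.0
    bearing = azimuth_deg(fleet["x_m"].to_numpy(float) - x,
                          fleet["y_m"].to_numpy(float) - y)
    i_cv = int(np.argmin(d))
    out = {"ves_distance_km": float(d[i_cv]), "n_vessels": int(len(fleet)),
           "row_cv_deg": float(fold_angle_deg(movement_azimuth_deg - bearing[i_cv]))
           if np.isfinite(movement_azimuth_deg) else float("nan")}
    seismic = fleet["vessel_type"].to_numpy() == "seismic"
    if seismic.any():
        i_sv = int(np.argmin(np.where(seismic, d, np.inf)))
        out["sv_distance_km"] = float(d[i_sv])
        out["row_sv_deg"] = (float(fold_angle_deg(movement_azimuth_deg -
                                                  bearing[i_sv]))
                             if np.isfinite(movement_azimuth_deg) else float("nan"))
    else:
        out["sv_distance_km"] = float("nan")
        out["row_sv_deg"] = float("nan")
    return out


def assemble_bin_covariates(bins: pd.DataFrame, exposure: pd.DataFrame,
                            vessels: pd.DataFrame | None,
                            environment=None,
                            station_id: str | None = None) -> pd.DataFrame:
    """Attach impact and natural covariates to every movement bin.

    ``bins`` is one sub-track's movement-bin table (bin_start_s/bin_end_s and
    midpoints present); ``exposure`` the 30-s exposure series of the same
    track. cSEL accumulates over the exposure series of the whole track and
    is read at each bin's end.
    """
    exposure = exposure.sort_values("t_s", kind="stable").reset_index(drop=True)
    csel = {typ: accumulate_csel(exposure[f"sel30_{typ}"].to_numpy())
            for typ in SOURCE_TYPES}
    t_exp = exposure["t_s"].to_numpy(float)
    x_exp = exposure["x_m"].to_numpy(float)
    y_exp = exposure["y_m"].to_numpy(float)
    # precompute whale->vessel distances at every epoch (epochs x vessels)
    if vessels is not None and len(vessels):
        v_ids, v_types, vxs, vys = [], [], [], []
        for vid, grp in vessels.groupby("vessel_id"):
            ts = grp["t_s"].to_numpy(float)
            v_ids.append(vid)
            v_types.append(grp["vessel_type"].iloc[0])
            vxs.append(np.interp(t_exp, ts, grp["x_m"].to_numpy(float)))
            vys.append(np.interp(t_exp, ts, grp["y_m"].to_numpy(float)))
        d_all = np.hypot(np.column_stack(vxs) - x_exp[:, None],
                         np.column_stack(vys) - y_exp[:, None]) / 1000.0
        seismic_cols = np.asarray(v_types) == "seismic"
    rows = []
    for _, b in bins.iterrows():
        in_bin = (t_exp >= b["bin_start_s"]) & (t_exp < b["bin_end_s"])
        row = dict(b)
        for typ in SOURCE_TYPES:
            row[f"sel30_{typ}"] = energy_mean_db(
                exposure.loc[in_bin, f"sel30_{typ}"])
            ix = np.where(in_bin)[0]
            row[f"csel_{typ}"] = float(csel[typ][ix[-1]]) if ix.size else float("nan")
        t_mid = 0.5 * (b["bin_start_s"] + b["bin_end_s"])
        if vessels is not None and len(vessels):
            fleet_mid = vessel_positions_at(vessels, t_mid)
            vc_mid = vessel_covariates(b["x_mid_m"], b["y_mid_m"],
                                       b.get("direction_deg", float("nan")),
                                       fleet_mid)
            if in_bin.any():
                row["ves_distance_km"] = float(d_all[in_bin].min())
                row["sv_distance_km"] = float(
                    d_all[np.ix_(in_bin, seismic_cols)].min()) \
                    if seismic_cols.any() else float("nan")
            else:
                row["ves_distance_km"] = vc_mid["ves_distance_km"]
                row["sv_distance_km"] = vc_mid["sv_distance_km"]
            row["n_vessels"] = vc_mid["n_vessels"]
            row["ROW_CV"] = vc_mid["row_cv_deg"]
            row["ROW_SV"] = vc_mid["row_sv_deg"]
        else:
            row["ves_distance_km"] = row["sv_distance_km"] = float("nan")
            row["n_vessels"] = 0
        if environment is not None:
            row["depth_m"] = float(environment.depth(b["x_mid_m"], b["y_mid_m"]))
            row["tide_m"] = float(environment.tide(t_mid))
        if station_id is not None:
            row["station_id"] = station_id
        row["time_of_day_h"] = (t_mid / 3600.0) % 24.0
        rows.append(row)
    return pd.DataFrame(rows)
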