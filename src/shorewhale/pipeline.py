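"""End-to-end pipeline: simulate -> geolocate -> metrics -> covariates ->
prey -> models, with a run manifest, checksum-based caching, and a case-study
timeline export.

Every stage reads and writes plain CSV/JSON under one output directory, so a
run is resumable and each stage is independently testable. The manifest
records the seed, per-stage input signatures, row counts, and sha256
checksums of every output; rerunning with an unchanged config and seed
reproduces byte-identical outputs and skips stages whose inputs are
unchanged.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig, STATES
from .covariates import assemble_bin_covariates, accumulate_csel, exposure_series
from .geodesy import LocalGrid, Station, fix_to_position
from .models import bic_stepwise, ht_weights, pca_scores
from .prey import bin_max_biomass, biomass_anova, build_interpolators
from .respiration import compute_respiration_bins, segment_cycles
from .soundfield import TEN_LOG_30
from .synthetic import (build_sound_field, simulate_environment,
                        simulate_scenario)
from .trackmetrics import compute_movement_bins, resample_track

FLOAT_FMT = "%.10g"

#: response -> (column, transform) for the default model suite
MOVEMENT_RESPONSES = {
    "Speed": ("SPD", "ln"),
    "Reorientation rate": ("RR", "identity"),
    "Linearity": ("LIN", "logit"),
    "Mean direction": ("MDIR", "logit"),
    "Range": ("Range", "identity"),
    "Distance from shore": ("dist_shore_km", "ln"),
    "cos(direction)": ("cos_dir", "identity"),
    "sin(direction)": ("sin_dir", "identity"),
    "ROW_CV": ("ROW_CV", "identity"),
    "ROW_SV": ("ROW_SV", "identity"),
}
RESPIRATION_RESPONSES = {
    "Respiration interval": ("resp_interval_s", "ln"),
    "Surface time": ("surface_time_s", "ln"),
    "Dive time": ("dive_time_s", "ln"),
    "Blows per surfacing": ("blows_per_surfacing", "ln"),
    "Surface blow rate": ("surface_blow_rate", "ln"),
    "Dive-surface blow rate": ("dive_surface_blow_rate", "ln"),
    "Time at surface": ("time_at_surface_pct", "identity"),
}
NATURAL_CANDIDATES = ["behavior_state", "depth_m", "tide_m", "time_of_day_h"]
IMPACT_CANDIDATES = ["sel30_seismic", "sv_distance_km", "sel30_vessel",
                     "csel_vessel", "ves_distance_km"]
MOVEMENT_PCA_COLS = ["SPD", "Range", "TRK_R", "LIN", "RR", "MDIR",
                     "ROW_CV", "ROW_SV", "cos_dir", "sin_dir"]
RESPIRATION_PCA_COLS = ["surface_blow_rate", "dive_time_s",
                        "blows_per_surfacing", "surface_time_s",
                        "time_at_surface_pct", "resp_interval_s",
                        "dive_surface_blow_rate"]


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


class PipelineError(RuntimeError):
    pass


class Pipeline:
    """Orchestrates the stages over one output directory."""

    STAGES = ("simulate", "geolocate", "metrics", "covariates", "prey", "models")

    def __init__(self, config: SimConfig, outdir):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = {"seed": config.seed, "stages": {}, "checksums": {},
                         "row_counts": {}}
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())

    # -- caching -----------------------------------------------------------

    def _config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def _signature(self, input_files) -> str:
        h = hashlib.sha256(self._config_hash().encode())
        for f in input_files:
            p = self.outdir / f
            if p.exists():
                h.update(sha256_file(p).encode())
            else:
                h.update(b"missing")
        return h.hexdigest()

    def _cached(self, stage: str, inputs, outputs) -> bool:
        sig = self._signature(inputs)
        rec = self.manifest["stages"].get(stage)
        ok = (rec is not None and rec.get("signature") == sig and
              all((self.outdir / f).exists() for f in outputs))
        if ok:
            self.manifest["stages"][stage]["cached"] = True
        return ok

    def _record(self, stage: str, inputs, outputs) -> None:
        self.manifest["stages"][stage] = {
            "signature": self._signature(inputs), "cached": False,
            "outputs": list(outputs),
        }
        for f in outputs:
            self.manifest["checksums"][f] = sha256_file(self.outdir / f)
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1,
                                                 sort_keys=True))

    # -- stages ------------------------------------------------------------

    def stage_simulate(self) -> None:
        outputs = ["fixes.csv", "events.csv", "vessels.csv", "shots.csv",
                   "prey.csv", "tide.csv", "shoreline.geojson", "truth.json"]
        if self._cached("simulate", [], outputs):
            return
        scn = simulate_scenario(self.config)
        _write_csv(scn.fixes, self.outdir / "fixes.csv")
        _write_csv(scn.events, self.outdir / "events.csv")
        _write_csv(scn.vessels, self.outdir / "vessels.csv")
        _write_csv(scn.shots, self.outdir / "shots.csv")
        _write_csv(scn.prey, self.outdir / "prey.csv")
        duration_s = self.config.duration_h * 3600.0
        _write_csv(scn.environment.tide_series(duration_s),
                   self.outdir / "tide.csv")
        shoreline = {"type": "Feature", "properties": {"name": "shoreline"},
                     "geometry": {"type": "LineString",
                                  "coordinates": [list(map(float, p)) for p in
                                                  scn.environment.shoreline_xy]}}
        (self.outdir / "shoreline.geojson").write_text(
            json.dumps(shoreline, sort_keys=True))
        truth = {"seed": self.config.seed,
                 "response": vars(self.config.response),
                 "n_suppressed_fixes": scn.n_suppressed,
                 "n_tracks": len(scn.tracks),
                 "state_speeds_kmh": {s: self.config.movement[s].speed_mean_kmh
                                      for s in STATES}}
        (self.outdir / "truth.json").write_text(json.dumps(truth, indent=1,
                                                           sort_keys=True))
        self.manifest["row_counts"]["fixes"] = len(scn.fixes)
        self.manifest["row_counts"]["events"] = len(scn.events)
        self._record("simulate", [], outputs)

    def stage_geolocate(self) -> None:
        inputs = ["fixes.csv", "tide.csv"]
        outputs = ["positions.csv"]
        if self._cached("geolocate", inputs, outputs):
            return
        fixes = pd.read_csv(self.outdir / "fixes.csv")
        tide = pd.read_csv(self.outdir / "tide.csv")
        grid = LocalGrid(self.config.anchor_lat, self.config.anchor_lon)
        stations = {s.station_id: Station(s.station_id, s.lat, s.lon,
                                          s.height_m, s.ref_azimuth_deg,
                                          s.max_range_km)
                    for s in self.config.stations}
        rows = []
        for _, fx in fixes.iterrows():
            st = stations[fx["station_id"]]
            tide_m = float(np.interp(fx["t_s"], tide["t_s"], tide["tide_m"]))
            x, y = fix_to_position(fx["vertical_angle_deg"],
                                   fx["horizontal_angle_deg"], st, grid,
                                   tide_height_m=tide_m,
                                   k=self.config.refraction_k)
            lat, lon = grid.to_latlon(x, y)
            rows.append((fx["whale_id"], fx["t_s"], x, y, float(lat),
                         float(lon), fx["behavior_state"], fx["station_id"]))
        positions = pd.DataFrame(rows, columns=[
            "whale_id", "t_s", "x_m", "y_m", "lat", "lon", "behavior_state",
            "station_id"])
        _write_csv(positions, self.outdir / "positions.csv")
        self.manifest["row_counts"]["positions"] = len(positions)
        self._record("geolocate", inputs, outputs)

    def stage_metrics(self) -> None:
        inputs = ["positions.csv", "events.csv", "vessels.csv",
                  "shoreline.geojson"]
        outputs = ["movement_bins.csv", "respiration_bins.csv"]
        if self._cached("metrics", inputs, outputs):
            return
        positions = pd.read_csv(self.outdir / "positions.csv")
        events = pd.read_csv(self.outdir / "events.csv")
        vessels = pd.read_csv(self.outdir / "vessels.csv")
        shoreline = np.asarray(json.loads(
            (self.outdir / "shoreline.geojson").read_text()
        )["geometry"]["coordinates"], dtype=float)
        mv_frames, rs_frames = [], []
        for wid, grp in positions.groupby("whale_id"):
            for seg in resample_track(grp):
                bins = compute_movement_bins(seg, vessels, shoreline)
                if len(bins) == 0:
                    continue
                bins["track_id"] = f"{wid}-{seg['segment'].iloc[0]}"
                mv_frames.append(bins)
                ev = events[events["whale_id"] == wid]
                cycles = segment_cycles(ev)
                rbins = compute_respiration_bins(
                    cycles, bins["bin_start_s"].to_numpy())
                if len(rbins):
                    rbins["whale_id"] = wid
                    rbins["track_id"] = f"{wid}-{seg['segment'].iloc[0]}"
                    rs_frames.append(rbins)
        movement = pd.concat(mv_frames, ignore_index=True) if mv_frames \
            else pd.DataFrame()
        resp = pd.concat(rs_frames, ignore_index=True) if rs_frames \
            else pd.DataFrame()
        _write_csv(movement, self.outdir / "movement_bins.csv")
        _write_csv(resp, self.outdir / "respiration_bins.csv")
        self.manifest["row_counts"]["movement_bins"] = len(movement)
        self.manifest["row_counts"]["respiration_bins"] = len(resp)
        self._record("metrics", inputs, outputs)

    def stage_covariates(self) -> None:
        inputs = ["positions.csv", "movement_bins.csv", "respiration_bins.csv",
                  "vessels.csv", "shots.csv"]
        outputs = ["bin_table.csv"]
        if self._cached("covariates", inputs, outputs):
            return
        positions = pd.read_csv(self.outdir / "positions.csv")
        movement = pd.read_csv(self.outdir / "movement_bins.csv")
        resp = pd.read_csv(self.outdir / "respiration_bins.csv")
        vessels = pd.read_csv(self.outdir / "vessels.csv")
        shots = pd.read_csv(self.outdir / "shots.csv")
        env = simulate_environment(self.config)
        field = build_sound_field(self.config, vessels, shots)
        frames = []
        for (wid,), grp in positions.groupby(["whale_id"]):
            bins = movement[movement["whale_id"] == wid]
            if len(bins) == 0:
                continue
            t = grp["t_s"].to_numpy(dtype=float)
            epochs = np.arange(t.min(), t.max(), 30.0)
            xs = np.interp(epochs, t, grp["x_m"].to_numpy(dtype=float))
            ys = np.interp(epochs, t, grp["y_m"].to_numpy(dtype=float))
            exp = exposure_series(epochs, xs, ys, field, whale_id=wid)
            station = grp["station_id"].iloc[0]
            frames.append(assemble_bin_covariates(bins, exp, vessels, env,
                                                  station_id=station))
        table = pd.concat(frames, ignore_index=True)
        if len(resp):
            table = table.merge(
                resp.drop(columns=["bin_end_s", "track_id"], errors="ignore"),
                on=["whale_id", "bin_start_s"], how="left")
        _write_csv(table, self.outdir / "bin_table.csv")
        self.manifest["row_counts"]["bin_table"] = len(table)
        self._record("covariates", inputs, outputs)

    def stage_prey(self) -> None:
        inputs = ["prey.csv", "bin_table.csv", "positions.csv"]
        outputs = ["prey_bins.csv", "prey_anova.csv"]
        if self._cached("prey", inputs, outputs):
            return
        prey = pd.read_csv(self.outdir / "prey.csv")
        table = pd.read_csv(self.outdir / "bin_table.csv")
        positions = pd.read_csv(self.outdir / "positions.csv")
        env = simulate_environment(self.config)
        rows = []
        for method in ("idw", "kriging"):
            interp = build_interpolators(prey, method=method)
            for _, b in table.iterrows():
                grp = positions[positions["whale_id"] == b["whale_id"]]
                t = grp["t_s"].to_numpy(dtype=float)
                epochs = np.arange(b["bin_start_s"], b["bin_end_s"] + 1e-9, 90.0)
                epochs = epochs[(epochs >= t.min()) & (epochs <= t.max())]
                if epochs.size == 0:
                    continue
                xs = np.interp(epochs, t, grp["x_m"])
                ys = np.interp(epochs, t, grp["y_m"])
                xy = np.column_stack([xs, ys])
                maxima = bin_max_biomass(xy, env.depth(xs), interp)
                rows.append({"whale_id": b["whale_id"],
                             "bin_start_s": b["bin_start_s"],
                             "behavior_state": b["behavior_state"],
                             "method": method, **maxima})
        prey_bins = pd.DataFrame(rows)
        _write_csv(prey_bins, self.outdir / "prey_bins.csv")
        anova_frames = []
        for method, grp in prey_bins.groupby("method"):
            try:
                rep = biomass_anova(grp.dropna())
            except ValueError:
                continue
            rep.insert(0, "method", method)
            anova_frames.append(rep)
        anova = pd.concat(anova_frames, ignore_index=True) if anova_frames \
            else pd.DataFrame()
        _write_csv(anova, self.outdir / "prey_anova.csv")
        self._record("prey", inputs, outputs)

    def stage_models(self, include_prey: bool = False) -> None:
        inputs = ["bin_table.csv"]
        outputs = ["coefficients.csv", "pca_movement.csv",
                   "pca_respiration.csv", "selection_paths.json"]
        if self._cached("models", inputs, outputs):
            return
        table = pd.read_csv(self.outdir / "bin_table.csv")
        table = prepare_model_table(table, self.config)
        coef_rows, paths = [], {}
        responses = dict(MOVEMENT_RESPONSES)
        if "resp_interval_s" in table.columns:
            responses.update(RESPIRATION_RESPONSES)
        pca_out = {}
        for label, cols in (("movement", MOVEMENT_PCA_COLS),
                            ("respiration", RESPIRATION_PCA_COLS)):
            have = [c for c in cols if c in table.columns]
            if len(have) >= 3 and table[have].dropna().shape[0] > len(have):
                try:
                    scores, fracs, loadings = pca_scores(table, have)
                except ValueError:
                    continue
                for c in scores.columns:
                    table.loc[scores.index, f"{label}_{c}"] = scores[c]
                    responses[f"{label} {c}"] = (f"{label}_{c}", "identity")
                out = loadings.copy()
                out.loc["variance_fraction"] = list(fracs)
                pca_out[label] = out
        for label, (col, transform) in responses.items():
            if col not in table.columns or table[col].dropna().empty:
                continue
            try:
                fitted = bic_stepwise(
                    table, col, NATURAL_CANDIDATES, IMPACT_CANDIDATES,
                    group_col="track_id", weight_col="ht_weight",
                    correlation="ar1", transform=transform)
            except Exception as exc:   # stage halts cleanly per response
                paths[label] = [("error", str(exc), float("nan"))]
                continue
            paths[label] = fitted.selection_path
            for row in fitted.coef_table().to_dict("records"):
                coef_rows.append({"response": label, "structure": fitted.structure,
                                  "bic": fitted.bic, "n": fitted.n, **row})
        _write_csv(pd.DataFrame(coef_rows), self.outdir / "coefficients.csv")
        for label in ("movement", "respiration"):
            out = pca_out.get(label, pd.DataFrame())
            out.to_csv(self.outdir / f"pca_{label}.csv",
                       float_format=FLOAT_FMT)
        (self.outdir / "selection_paths.json").write_text(
            json.dumps(paths, indent=1, sort_keys=True, default=str))
        self._record("models", inputs, outputs)

    def run(self, stages=None) -> dict:
        for stage in stages or self.STAGES:
            if stage not in self.STAGES:
                raise PipelineError(f"unknown stage {stage!r}")
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        return self.manifest


def prepare_model_table(table: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Model-ready bin table: HT weights and ambient-filled exposure.

    Bins with no emission from a source type received ambient sound; their
    SEL/cSEL covariates are set to the ambient floor rather than treated as
    missing, so unexposed bins stay in the models.
    """
    table = table.copy()
    floor = config.propagation.ambient_floor_db
    for c in ("sel30_seismic", "sel30_vessel", "csel_seismic", "csel_vessel"):
        if c in table.columns:
            table[c] = table[c].fillna(floor)
    table["ht_weight"] = ht_weights(table["track_id"])
    return table


def run_pipeline(config: SimConfig, outdir, stages=None) -> dict:
    """Run the configured stages; returns the run manifest."""
    return Pipeline(config, outdir).run(stages)


def case_timeline(outdir, whale_id: str, config: SimConfig) -> pd.DataFrame:
    """Fig.-4-style aligned series for one whale at a 30-s cadence.

    Columns: cSEL (combined), SEL_30s, SPL, closest vessel distance (km),
    speed (km/h), and displacement — the squared distance (km^2) from the
    track's point of origin.
    """
    outdir = Path(outdir)
    positions = pd.read_csv(outdir / "positions.csv")
    grp = positions[positions["whale_id"] == whale_id]
    if len(grp) == 0:
        raise PipelineError(f"unknown whale id {whale_id!r}")
    vessels = pd.read_csv(outdir / "vessels.csv")
    shots = pd.read_csv(outdir / "shots.csv")
    field = build_sound_field(config, vessels, shots)
    t = grp["t_s"].to_numpy(dtype=float)
    epochs = np.arange(t.min(), t.max(), 30.0)
    xs = np.interp(epochs, t, grp["x_m"].to_numpy(dtype=float))
    ys = np.interp(epochs, t, grp["y_m"].to_numpy(dtype=float))
    exp = exposure_series(epochs, xs, ys, field)
    sel = exp["sel30_combined"].to_numpy()
    csel = accumulate_csel(sel)
    from .trackmetrics import vessel_positions_at
    dist = np.array([
        float(np.hypot(f["x_m"] - x, f["y_m"] - y).min()) / 1000.0
        if len(f) else np.nan
        for (f, x, y) in ((vessel_positions_at(vessels, float(tt)), x, y)
                          for tt, x, y in zip(epochs, xs, ys))])
    dx = np.gradient(xs, epochs)
    dy = np.gradient(ys, epochs)
    speed = np.hypot(dx, dy) * 3.6
    disp = ((xs - xs[0]) ** 2 + (ys - ys[0]) ** 2) / 1e6
    return pd.DataFrame({
        "t_s": epochs, "sel30_db": sel, "csel_db": csel,
        "spl_db": sel - TEN_LOG_30, "closest_vessel_km": dist,
        "speed_kmh": speed, "displacement_km2": disp,
    })
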