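"""Synthetic study generator: whales, vessels, observation process, prey.

Everything downstream of the field protocol is testable against known ground
truth generated here: state-switching correlated-random-walk whale tracks
with surfacing/dive respiration cycles, seismic vessels acquiring parallel
lines on a shot clock, support-vessel traffic, a theodolite observation
process with angular noise and range cutoffs, tide and linear bathymetry, and
log-normal spatially correlated benthic prey fields.

Geometry is a local planar grid anchored near the stations: x is metres east
of the (north-south) shoreline, y metres north of the anchor. The sea is
x > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (STATES, SimConfig, ConfigError)
from .geodesy import LocalGrid, Station, position_to_angles
from .soundfield import SoundField, SoundSource

ARCSEC_TO_DEG = 1.0 / 3600.0
SHORE_BUFFER_M = 100.0
OFFSHORE_LIMIT_M = 6_000.0
PREY_TAXA = ("amphipods", "isopods", "cumaceans", "polychaetes", "bivalves")


# ---------------------------------------------------------------------------
# ground-truth containers


@dataclass
class Surfacing:
    start: float
    end: float
    blow_times: np.ndarray


@dataclass
class TrueTrack:
    """Ground-truth whale track: stepwise path plus continuous-time respiration."""

    whale_id: str
    t: np.ndarray                 # step epochs, s from sim start
    x: np.ndarray                 # m east
    y: np.ndarray                 # m north
    state: np.ndarray             # int state codes per step epoch
    surfacings: list = field(default_factory=list)
    dive_starts: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    @property
    def blow_times(self) -> np.ndarray:
        if not self.surfacings:
            return np.empty(0)
        return np.concatenate([s.blow_times for s in self.surfacings])

    def at_surface(self, times) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.zeros(times.shape, dtype=bool)
        for s in self.surfacings:
            out |= (times >= s.start) & (times <= s.end)
        return out

    def position_at(self, times) -> tuple[np.ndarray, np.ndarray]:
        times = np.asarray(times, dtype=float)
        return (np.interp(times, self.t, self.x),
                np.interp(times, self.t, self.y))

    def state_at(self, times) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.clip(np.searchsorted(self.t, times, side="right") - 1,
                      0, len(self.t) - 1)
        return self.state[idx]


def whale_rng(seed: int, whale_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 7919, whale_index]))


# ---------------------------------------------------------------------------
# whale movement + respiration


def _simulate_states(rng, transition: np.ndarray, n: int, initial: int | None) -> np.ndarray:
    p = np.asarray(transition, dtype=float)
    if p.shape != (4, 4) or np.abs(p.sum(axis=1) - 1.0).max() > 1e-9:
        raise ConfigError("transition matrix must be 4x4 row-stochastic")
    cdf = np.cumsum(p, axis=1)
    states = np.empty(n, dtype=np.int64)
    if initial is None:
        # start from the stationary distribution (left eigenvector)
        w, v = np.linalg.eig(p.T)
        pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
        pi = np.abs(pi) / np.abs(pi).sum()
        states[0] = rng.choice(4, p=pi)
    else:
        states[0] = initial
    u = rng.random(n - 1)
    for i in range(1, n):
        states[i] = np.searchsorted(cdf[states[i - 1]], u[i - 1], side="right")
    return states


def _simulate_path(rng, config: SimConfig, states: np.ndarray,
                   x0: float, y0: float):
    """Correlated random walk: per-state log-normal speeds, wrapped-normal turns."""
    n = len(states)
    dt = config.step_s
    heading = rng.uniform(0.0, 2.0 * math.pi)
    x = np.empty(n + 1)
    y = np.empty(n + 1)
    x[0], y[0] = x0, y0
    speeds = np.empty(n)
    headings = np.empty(n)
    for i in range(n):
        mp = config.movement[STATES[states[i]]]
        sigma = mp.speed_sigma_ln
        mu = math.log(mp.speed_mean_kmh) - 0.5 * sigma * sigma
        v = math.exp(rng.normal(mu, sigma)) / 3.6          # m/s
        heading += rng.normal(0.0, 1.0 / math.sqrt(mp.kappa))
        nx = x[i] + v * dt * math.sin(heading)
        ny = y[i] + v * dt * math.cos(heading)
        # reflect at the shore and at the offshore edge of the feeding ground
        if nx < SHORE_BUFFER_M:
            nx = 2.0 * SHORE_BUFFER_M - nx
            heading = -heading
        elif nx > OFFSHORE_LIMIT_M:
            nx = 2.0 * OFFSHORE_LIMIT_M - nx
            heading = -heading
        x[i + 1], y[i + 1] = nx, ny
        speeds[i] = v
        headings[i] = heading % (2.0 * math.pi)
    return x, y, speeds, headings


def _simulate_respiration(rng, config: SimConfig, states: np.ndarray,
                          duration_s: float):
    """Alternating surfacing (>= 1 blow) / dive cycles in continuous time."""
    surfacings: list[Surfacing] = []
    dive_starts: list[float] = []
    tau = float(rng.uniform(0.0, 30.0))
    step = config.step_s
    nstep = len(states)
    while tau < duration_s:
        st = states[min(int(tau // step), nstep - 1)]
        rp = config.respiration[STATES[st]]
        n_blows = 1 + rng.poisson(max(rp.blows_per_surfacing_mean - 1.0, 0.0))
        shape = 4.0
        gaps = rng.gamma(shape, rp.inter_blow_s / shape, size=max(n_blows - 1, 0))
        blow_times = tau + np.concatenate([[0.0], np.cumsum(gaps)])
        blow_times = blow_times[blow_times < duration_s]
        if blow_times.size == 0:
            break
        surfacings.append(Surfacing(blow_times[0], blow_times[-1], blow_times))
        surf_end = blow_times[-1]
        dive = rng.gamma(rp.dive_shape, rp.dive_mean_s / rp.dive_shape)
        if surf_end + 1.0 < duration_s:
            dive_starts.append(surf_end + 1.0)
        tau = surf_end + 1.0 + dive
    return surfacings, np.asarray(dive_starts)


def simulate_whale_track(config: SimConfig, whale_index: int = 0,
                         initial_state: int | None = None) -> TrueTrack:
    """Simulate one whale's ground-truth track, fully reproducible from seed."""
    config.validate()
    rng = whale_rng(config.seed, whale_index)
    duration_s = config.duration_h * 3600.0
    n = int(round(duration_s / config.step_s))
    if n < 1:
        raise ConfigError("zero-duration track")
    states = _simulate_states(rng, config.transition, n, initial_state)
    lo, hi = config.whale_offshore_band_km
    x0 = rng.uniform(lo, hi) * 1000.0
    y0 = rng.uniform(-10_000.0, 10_000.0)
    x, y, speeds, headings = _simulate_path(rng, config, states, x0, y0)
    surfacings, dive_starts = _simulate_respiration(rng, config, states, duration_s)
    t = np.arange(n + 1) * config.step_s
    state_path = np.concatenate([states, states[-1:]])
    return TrueTrack(
        whale_id=f"W{whale_index:03d}", t=t, x=x, y=y, state=state_path,
        surfacings=surfacings, dive_starts=dive_starts,
        meta={"seed": config.seed, "whale_index": whale_index,
              "speeds_ms": speeds, "headings_rad": headings},
    )


# ---------------------------------------------------------------------------
# vessels and the sound field


def _racetrack_waypoints(config: SimConfig, vessel_index: int):
    """Seismic lines run perpendicular to shore (east-west), inshore end at
    ``line_offset_km``; successive lines step north by ``line_spacing_km``.
    Each vessel's block is offset alongshore so fleets don't overlap."""
    vp = config.vessels
    x_in = vp.line_offset_km * 1000.0
    x_out = x_in + vp.line_length_km * 1000.0
    y0 = (vessel_index - (max(vp.n_seismic, 1) - 1) / 2.0) * 10_000.0
    wps = []
    for line in range(vp.n_lines):
        y = y0 + line * vp.line_spacing_km * 1000.0
        if line % 2 == 0:
            wps.append(((x_in, y), (x_out, y), True))
        else:
            wps.append(((x_out, y), (x_in, y), True))
    return wps


def simulate_vessels(config: SimConfig):
    """Seismic fleet on parallel lines plus support traffic.

    Returns (vessels AIS-like DataFrame at 30-s cadence, shot schedule
    DataFrame). Shots fire at the configured interval only while a seismic
    vessel is on-line; line turns are silent transits.
    """
    vp = config.vessels
    vp.validate()
    duration_s = config.duration_h * 3600.0
    cadence = 30.0
    records = []
    shots = []
    speed = vp.speed_kmh / 3.6
    for v in range(vp.n_seismic):
        vid = f"SV{v + 1}"
        t_cursor = 0.0
        path_t, path_x, path_y = [], [], []
        segments = _racetrack_waypoints(config, v)
        seg_idx = 0
        pos = segments[0][0]
        while t_cursor < duration_s and seg_idx < len(segments):
            (p0, p1, on_line) = segments[seg_idx]
            seg_len = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
            seg_dur = seg_len / speed
            path_t.append(t_cursor); path_x.append(p0[0]); path_y.append(p0[1])
            if on_line:
                shot_t = np.arange(t_cursor, min(t_cursor + seg_dur, duration_s),
                                   vp.shot_interval_s)
                frac = (shot_t - t_cursor) / seg_dur
                for st, f in zip(shot_t, frac):
                    shots.append((vid, st,
                                  p0[0] + f * (p1[0] - p0[0]),
                                  p0[1] + f * (p1[1] - p0[1])))
            t_cursor += seg_dur
            # silent transit to the start of the next line
            if seg_idx + 1 < len(segments):
                nxt = segments[seg_idx + 1][0]
                path_t.append(t_cursor); path_x.append(p1[0]); path_y.append(p1[1])
                transit = math.hypot(nxt[0] - p1[0], nxt[1] - p1[1]) / speed
                t_cursor += transit
                pos = nxt
            else:
                path_t.append(t_cursor); path_x.append(p1[0]); path_y.append(p1[1])
            seg_idx += 1
        if path_t and path_t[-1] < duration_s:
            path_t.append(duration_s); path_x.append(path_x[-1]); path_y.append(path_y[-1])
        tt = np.arange(0.0, duration_s + cadence, cadence)
        records.append(pd.DataFrame({
            "vessel_id": vid, "vessel_type": "seismic", "t_s": tt,
            "x_m": np.interp(tt, path_t, path_x),
            "y_m": np.interp(tt, path_t, path_y),
        }))
    sp = vp.support_speed_kmh / 3.6
    for v in range(vp.n_support):
        vid = f"TUG{v + 1}"
        x = 3000.0 + 1000.0 * v
        half = 8000.0
        tt = np.arange(0.0, duration_s + cadence, cadence)
        # shuttle north-south along the shore with a per-vessel phase
        period = 4.0 * half / sp
        phase = tt / period + 0.31 * (v + 1)
        tri = 2.0 * np.abs(phase % 1.0 - 0.5) - 0.5   # in [-0.5, 0.5]
        records.append(pd.DataFrame({
            "vessel_id": vid, "vessel_type": "support", "t_s": tt,
            "x_m": x, "y_m": 2.0 * half * tri,
        }))
    vessels = (pd.concat(records, ignore_index=True) if records
               else pd.DataFrame(columns=["vessel_id", "vessel_type",
                                          "t_s", "x_m", "y_m"]))
    shot_df = pd.DataFrame(shots, columns=["vessel_id", "t_s", "x_m", "y_m"])
    return vessels, shot_df


def build_sound_field(config: SimConfig, vessels: pd.DataFrame,
                      shots: pd.DataFrame) -> SoundField:
    """Assemble the parametric sound field from simulated vessel activity."""
    sources = []
    for vid, grp in vessels.groupby("vessel_id"):
        grp = grp.sort_values("t_s")
        vtype = grp["vessel_type"].iloc[0]
        if vtype == "seismic":
            vshots = shots.loc[shots["vessel_id"] == vid, "t_s"].to_numpy()
            sources.append(SoundSource(
                vid, "seismic", grp["t_s"].to_numpy(), grp["x_m"].to_numpy(),
                grp["y_m"].to_numpy(), config.vessels.source_sel_db,
                shot_times=np.sort(vshots)))
        else:
            sources.append(SoundSource(
                vid, "vessel", grp["t_s"].to_numpy(), grp["x_m"].to_numpy(),
                grp["y_m"].to_numpy(), config.vessels.support_sl_db,
                shot_times=None,
                active=(0.0, config.duration_h * 3600.0)))
    return SoundField(sources, config.propagation)


# ---------------------------------------------------------------------------
# injected dose-response effects


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def inject_response(track: TrueTrack, field: SoundField,
                    config: SimConfig) -> TrueTrack:
    """Apply the configured dose-response effect above the SEL threshold.

    'speed' multiplies step speed by exp(slope * (SEL - thr)); 'heading-bias'
    pulls the step heading toward the bearing away from the loudest source by
    a per-dB weight; 'respiration' scales inter-blow intervals. Ground truth
    is recorded in ``track.meta['injected']``. effect='none' returns the
    input unchanged.
    """
    eff = config.response
    eff.validate()
    if eff.effect == "none":
        return track
    t_steps = track.t[:-1]
    sel = field.combined_sel(track.x[:-1], track.y[:-1], t_steps)
    over = np.where(np.isfinite(sel), np.maximum(sel - eff.threshold_db, 0.0), 0.0)
    meta = dict(track.meta)
    meta["injected"] = {"effect": eff.effect, "threshold_db": eff.threshold_db,
                        "slope": eff.slope, "sel_db": sel, "over_db": over}

    if eff.effect == "respiration":
        new_surf = []
        for s in track.surfacings:
            i = min(int(s.start // (track.t[1] - track.t[0])), len(over) - 1)
            factor = math.exp(eff.slope * over[i])
            gaps = np.diff(s.blow_times) * factor
            bt = s.blow_times[0] + np.concatenate([[0.0], np.cumsum(gaps)])
            new_surf.append(Surfacing(bt[0], bt[-1], bt))
        return TrueTrack(track.whale_id, track.t, track.x, track.y, track.state,
                         new_surf, track.dive_starts, meta)

    dx = np.diff(track.x)
    dy = np.diff(track.y)
    if eff.effect == "speed":
        factor = np.exp(eff.slope * over)
        dx = dx * factor
        dy = dy * factor
    else:  # heading-bias
        for i in range(len(dx)):
            if over[i] <= 0:
                continue
            # bearing from the whale to the nearest active source
            best_r, best_b = None, None
            for src in field.sources:
                sx, sy = src.position_at(t_steps[i])
                r = math.hypot(float(sx) - track.x[i], float(sy) - track.y[i])
                if best_r is None or r < best_r:
                    best_r = r
                    best_b = math.atan2(float(sx) - track.x[i],
                                        float(sy) - track.y[i])
            away = best_b + math.pi
            head = math.atan2(dx[i], dy[i])
            w = min(eff.slope * over[i], 1.0)
            new_head = head + w * _wrap_angle(away - head)
            step = math.hypot(dx[i], dy[i])
            dx[i] = step * math.sin(new_head)
            dy[i] = step * math.cos(new_head)
    x = np.concatenate([[track.x[0]], track.x[0] + np.cumsum(dx)])
    y = np.concatenate([[track.y[0]], track.y[0] + np.cumsum(dy)])
    return TrueTrack(track.whale_id, track.t, x, y, track.state,
                     track.surfacings, track.dive_starts, meta)


# ---------------------------------------------------------------------------
# the theodolite observation process


def observe_track(track: TrueTrack, station: Station, grid: LocalGrid,
                  config: SimConfig, tide_fn=None, seed: int | None = None,
                  cadence: str = "surfacing"):
    """Observe a true track from a shore station.

    Positions are observable only when the whale is at the surface: one fix
    per surfacing (at the first blow; ``cadence='blow'`` emits one per blow).
    Angles come from the exact inverse geodesy plus Gaussian angular noise
    (default 5 arc-sec, the instrument precision class). Fixes beyond the
    station's maximum tracking range are suppressed and counted, not raised.
    Returns (fixes DataFrame, focal events DataFrame, n_suppressed).
    """
    if cadence not in ("surfacing", "blow"):
        raise ConfigError(f"unknown observation cadence {cadence!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 104729,
                                int(track.meta.get("whale_index", 0))]))
    sigma_deg = config.theodolite_noise_arcsec * ARCSEC_TO_DEG
    sx, sy = grid.to_xy(station.lat, station.lon)
    rows = []
    suppressed = 0
    for s in track.surfacings:
        fix_times = s.blow_times if cadence == "blow" else s.blow_times[:1]
        for ft in fix_times:
            px, py = track.position_at(ft)
            rng_m = math.hypot(float(px) - float(sx), float(py) - float(sy))
            if rng_m > station.max_range_km * 1000.0:
                suppressed += 1
                continue
            tide = float(tide_fn(ft)) if tide_fn is not None else 0.0
            vert, horiz = position_to_angles(float(px), float(py), station, grid,
                                             tide_height_m=tide,
                                             k=config.refraction_k)
            vert += rng.normal(0.0, sigma_deg)
            horiz = (horiz + rng.normal(0.0, sigma_deg)) % 360.0
            st = int(track.state_at(ft)[0])
            if config.state_misclassification > 0 and \
                    rng.random() < config.state_misclassification:
                st = int(rng.choice([k for k in range(4) if k != st]))
            rows.append((station.station_id, float(ft), vert, horiz,
                         track.whale_id, STATES[st]))
    fixes = pd.DataFrame(rows, columns=["station_id", "t_s", "vertical_angle_deg",
                                        "horizontal_angle_deg", "whale_id",
                                        "behavior_state"])
    events = []
    for bt in track.blow_times:
        events.append((track.whale_id, float(bt), "blow"))
    for dt_ in track.dive_starts:
        events.append((track.whale_id, float(dt_), "dive_start"))
    events_df = pd.DataFrame(events, columns=["whale_id", "t_s", "event"])
    events_df = events_df.sort_values("t_s", kind="stable").reset_index(drop=True)
    return fixes, events_df, suppressed


# ---------------------------------------------------------------------------
# environment and prey


@dataclass
class Environment:
    """Tide series, linear bathymetry, and a straight north-south shoreline."""

    tide_amplitude_m: float
    tide_period_h: float
    depth_gradient_m_per_km: float
    shoreline_xy: np.ndarray

    def tide(self, t_s) -> np.ndarray:
        om = 2.0 * math.pi / (self.tide_period_h * 3600.0)
        return self.tide_amplitude_m * np.sin(om * np.asarray(t_s, dtype=float))

    def depth(self, x_m, y_m=None) -> np.ndarray:
        return self.depth_gradient_m_per_km * np.maximum(
            np.asarray(x_m, dtype=float), 0.0) / 1000.0

    def tide_series(self, duration_s: float, step_s: float = 600.0) -> pd.DataFrame:
        t = np.arange(0.0, duration_s + step_s, step_s)
        return pd.DataFrame({"t_s": t, "tide_m": self.tide(t)})


def simulate_environment(config: SimConfig) -> Environment:
    shoreline = np.array([[0.0, -30_000.0], [0.0, 30_000.0]])
    return Environment(config.tide_amplitude_m, config.tide_period_h,
                       config.depth_gradient_m_per_km, shoreline)


#: log-median biomass (g/m^2) and per-metre depth trend of ln biomass
PREY_FIELD_PARAMS = {
    "amphipods": (math.log(38.0), -0.02),
    "isopods": (math.log(8.0), 0.00),
    "cumaceans": (math.log(0.5), 0.00),
    "polychaetes": (math.log(2.5), 0.01),
    "bivalves": (math.log(15.0), 0.01),
}


def simulate_prey_samples(config: SimConfig, env: Environment | None = None,
                          corr_length_km: float = 3.0, sigma_ln: float = 0.6,
                          grid_spacing_km: tuple = (1.0, 1.5),
                          seed_offset: int = 0) -> pd.DataFrame:
    """Benthic point samples on the < 20-m nearshore grid.

    Each taxon is a log-normal field: ln biomass = ln median + depth trend +
    a Gaussian random field with exponential covariance (range
    ``corr_length_km``, sd ``sigma_ln``); total is the sum of the five taxa.
    ``corr_length_km=np.inf`` yields a spatially constant residual field.
    """
    env = env or simulate_environment(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 15485863, seed_offset]))
    x_max_km = 20.0 / config.depth_gradient_m_per_km
    xs = np.arange(0.5, x_max_km, grid_spacing_km[0]) * 1000.0
    ys = np.arange(-12.0, 12.0 + 1e-9, grid_spacing_km[1]) * 1000.0
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    n = gx.size
    d = np.hypot(gx[:, None] - gx[None, :], gy[:, None] - gy[None, :]) / 1000.0
    if np.isinf(corr_length_km):
        cov = np.ones((n, n))
    else:
        cov = np.exp(-d / corr_length_km)
    cov = sigma_ln ** 2 * cov + 1e-10 * np.eye(n)
    chol = np.linalg.cholesky(cov)
    depth = env.depth(gx)
    mean_depth = float(depth.mean())
    out = {"station_id": [f"P{i:03d}" for i in range(n)],
           "x_m": gx, "y_m": gy, "depth_m": depth}
    total = np.zeros(n)
    for taxon in PREY_TAXA:
        ln_med, beta = PREY_FIELD_PARAMS[taxon]
        z = chol @ rng.standard_normal(n)
        biomass = np.exp(ln_med + beta * (depth - mean_depth) + z)
        out[taxon] = biomass
        total += biomass
    out["total"] = total
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# scenario assembly


@dataclass
class Scenario:
    """One fully simulated study: ground truth plus the observed data."""

    config: SimConfig
    grid: LocalGrid
    environment: Environment
    tracks: list
    vessels: pd.DataFrame
    shots: pd.DataFrame
    field: SoundField
    fixes: pd.DataFrame
    events: pd.DataFrame
    prey: pd.DataFrame
    stations: list
    n_suppressed: int


def simulate_scenario(config: SimConfig) -> Scenario:
    """Run the full generator: tracks, fleet, field, observations, prey."""
    config.validate()
    grid = LocalGrid(config.anchor_lat, config.anchor_lon)
    env = simulate_environment(config)
    vessels, shots = simulate_vessels(config)
    field = build_sound_field(config, vessels, shots)
    stations = [Station(s.station_id, s.lat, s.lon, s.height_m,
                        s.ref_azimuth_deg, s.max_range_km)
                for s in config.stations]
    tracks = []
    all_fixes, all_events = [], []
    n_suppressed = 0
    for w in range(config.n_whales):
        track = simulate_whale_track(config, w)
        track = inject_response(track, field, config)
        tracks.append(track)
        # each whale is followed from its nearest station
        sx = np.array([grid.to_xy(s.lat, s.lon)[0] for s in stations])
        sy = np.array([grid.to_xy(s.lat, s.lon)[1] for s in stations])
        dist0 = np.hypot(sx - track.x[0], sy - track.y[0])
        station = stations[int(np.argmin(dist0))]
        fixes, events, supp = observe_track(track, station, grid, config,
                                            tide_fn=env.tide)
        n_suppressed += supp
        all_fixes.append(fixes)
        all_events.append(events)
    all_fixes = [f for f in all_fixes if len(f)] or all_fixes[:1]
    all_events = [e for e in all_events if len(e)] or all_events[:1]
    fixes = pd.concat(all_fixes, ignore_index=True)
    events = pd.concat(all_events, ignore_index=True)
    prey = simulate_prey_samples(config, env)
    return Scenario(config, grid, env, tracks, vessels, shots, field,
                    fixes, events, prey, stations, n_suppressed)
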