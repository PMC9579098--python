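"""Model-validation simulators: grouped bin datasets with known truth.

Two levels of ground truth support the statistical checks:

* :func:`simulate_bin_dataset` draws analysis-ready bin tables directly at
  the model layer (track grouping, natural covariates, AR1 within-track
  residuals, an optional linear impact effect) for type-I-error, BIC and
  selection studies where thousands of fits are needed.
* :func:`speed_recovery_dataset` runs the actual generator -> metrics ->
  covariate path with an injected above-threshold log-speed dose-response
  and returns the bin table plus the injected slope, for end-to-end
  parameter-recovery checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import STATES, SimConfig, ResponseEffect
from .covariates import assemble_bin_covariates, exposure_series
from .models import ht_weights
from .synthetic import (build_sound_field, inject_response,
                        simulate_environment, simulate_vessels,
                        simulate_whale_track)
from .trackmetrics import RESAMPLE_S, compute_movement_bins


def _ar1_noise(rng, m: int, rho: float, sd: float) -> np.ndarray:
    e = np.empty(m)
    e[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    for i in range(1, m):
        e[i] = rho * e[i - 1] + rng.normal(0.0, innov_sd)
    return e


def simulate_bin_dataset(rng, n_tracks: int = 20, bins_mean: int = 10,
                         rho: float = 0.0, sd: float = 1.0,
                         beta_impact: float = 0.0,
                         state_effects=(0.0, 0.3, 1.0, 0.5),
                         beta_depth: float = 0.05,
                         n_noise_covariates: int = 0) -> pd.DataFrame:
    """A grouped bin table with AR1 residuals and known coefficients.

    The impact covariate ``sel30_seismic`` varies mostly between tracks
    (different whales sit at different ranges) with a slow within-track
    drift, mimicking the exposure structure of the field data. Optional
    standard-normal noise covariates (``noise_0`` ...) support null
    selection studies.
    """
    rows = []
    for j in range(n_tracks):
        m = max(int(rng.poisson(bins_mean)), 2)
        state_idx = rng.integers(0, 4)
        depth = rng.uniform(5.0, 25.0) + rng.normal(0.0, 1.0, m)
        sel = rng.uniform(90.0, 160.0) + np.cumsum(rng.normal(0.0, 1.0, m))
        noise = _ar1_noise(rng, m, rho, sd)
        y = (1.0 + state_effects[state_idx] + beta_depth * depth +
             beta_impact * sel + noise)
        for i in range(m):
            row = {"track_id": f"T{j:03d}", "bin_start_s": 630.0 * i,
                   "behavior_state": STATES[state_idx],
                   "depth_m": depth[i], "sel30_seismic": sel[i],
                   "response": y[i]}
            for k in range(n_noise_covariates):
                row[f"noise_{k}"] = rng.normal()
            rows.append(row)
    table = pd.DataFrame(rows)
    table["ht_weight"] = ht_weights(table["track_id"])
    return table


def speed_recovery_dataset(seed: int, n_whales: int = 8,
                           duration_h: float = 6.0, slope: float = 0.02,
                           threshold_db: float = 90.0) -> tuple[pd.DataFrame, float]:
    """Generator-through-metrics bin table with an injected speed effect.

    Returns (bin table with ln-ready SPD and the per-bin mean combined
    SEL_30s dose, the injected slope per dB). The threshold sits below every
    simulated exposure so the injected log-speed shift is linear in the dose
    over the whole table.
    """
    cfg = SimConfig(seed=seed, duration_h=duration_h, n_whales=n_whales)
    cfg.response = ResponseEffect("speed", threshold_db=threshold_db,
                                  slope=slope)
    vessels, shots = simulate_vessels(cfg)
    field = build_sound_field(cfg, vessels, shots)
    env = simulate_environment(cfg)
    frames = []
    for w in range(n_whales):
        track = simulate_whale_track(cfg, w)
        track = inject_response(track, field, cfg)
        epochs = np.arange(track.t[0], track.t[-1] + 1e-9, RESAMPLE_S)
        xs, ys = track.position_at(epochs)
        resampled = pd.DataFrame({"t_s": epochs, "x_m": xs, "y_m": ys,
                                  "behavior_state":
                                  [STATES[s] for s in track.state_at(epochs)]})
        bins = compute_movement_bins(resampled, vessels)
        if not len(bins):
            continue
        e30 = np.arange(track.t[0], track.t[-1], 30.0)
        ex, ey = track.position_at(e30)
        exp = exposure_series(e30, ex, ey, field)
        table = assemble_bin_covariates(bins, exp, vessels, env)
        # the generator records the exact per-step dose the injection used
        sel = track.meta["injected"]["sel_db"]
        t_steps = track.t[:-1]
        dose = [float(np.nanmean(sel[(t_steps >= b0) & (t_steps < b0 + 630.0)]))
                for b0 in table["bin_start_s"]]
        table["dose_db"] = dose
        table["track_id"] = f"W{w:03d}"
        frames.append(table)
    out = pd.concat(frames, ignore_index=True)
    out["ht_weight"] = ht_weights(out["track_id"])
    return out, slope
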