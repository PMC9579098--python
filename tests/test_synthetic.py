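"""Generator ground truth: state switching, fleet geometry, sound energy,
injected effects, and the theodolite observation process."""

import math

import numpy as np
import pandas as pd
import pytest

from shorewhale import (LocalGrid, SimConfig, Station, build_sound_field,
                        energy_sum_db, inject_response, observe_track,
                        simulate_environment, simulate_prey_samples,
                        simulate_vessels, simulate_whale_track)
from shorewhale.config import (ConfigError, STATES, VesselParams,
                               ResponseEffect, transition_matrix_from_budget)
from shorewhale.soundfield import SoundField, SoundSource
from shorewhale.synthetic import _simulate_states, whale_rng


# ---------------------------------------------------------------------------
# behavioral-state dynamics


def test_identity_transition_keeps_state_constant():
    cfg = SimConfig(seed=5, duration_h=1.0)
    cfg.transition = np.eye(4)
    cfg.movement["traveling"].kappa = 1e9    # no turning
    tr = simulate_whale_track(cfg, 0, initial_state=2)
    assert (tr.state == 2).all()
    # straight line: consecutive headings all equal
    dx, dy = np.diff(tr.x), np.diff(tr.y)
    heads = np.arctan2(dx, dy)
    assert np.ptp(heads) < 1e-3
    # every blow falls inside a surfacing interval
    for s in tr.surfacings:
        assert ((s.blow_times >= s.start) & (s.blow_times <= s.end)).all()
    assert tr.at_surface(tr.blow_times).all()


def test_state_occupancy_matches_eigenvector_oracle():
    """Empirical occupancy of a long chain within 3 sigma of the stationary
    distribution from an independent eigen-decomposition."""
    p = transition_matrix_from_budget((0.25, 0.25, 0.25, 0.25), 0.06)
    rng = whale_rng(123, 0)
    n = 100_000
    states = _simulate_states(rng, p, n, None)
    # oracle: left eigenvector of the transition matrix
    w, v = np.linalg.eig(p.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    pi = pi / pi.sum()
    occ = np.bincount(states, minlength=4) / n
    # effective sample size accounts for dwell autocorrelation
    dwell = 1.0 / (1.0 - np.diag(p))
    for k in range(4):
        se = math.sqrt(pi[k] * (1 - pi[k]) / (n / dwell[k].mean()))
        assert abs(occ[k] - pi[k]) < 3.0 * se + 1e-3


def test_default_budget_is_stationary():
    p = transition_matrix_from_budget()
    pi = np.array([0.26, 0.33, 0.30, 0.11])
    assert np.allclose(pi @ p, pi, atol=1e-12)


def test_per_state_speed_recovery():
    """Empirical mean speed per state within 5% of configured means."""
    cfg = SimConfig(seed=7, duration_h=48.0, n_whales=1)
    tr = simulate_whale_track(cfg, 0)
    speeds = tr.meta["speeds_ms"] * 3.6
    states = tr.state[:-1]
    for k, name in enumerate(STATES):
        sel = states == k
        if sel.sum() < 300:
            continue
        cfg_mean = cfg.movement[name].speed_mean_kmh
        assert speeds[sel].mean() == pytest.approx(cfg_mean, rel=0.05)


def test_nonstochastic_matrix_rejected():
    cfg = SimConfig()
    cfg.transition = np.ones((4, 4))
    with pytest.raises(ConfigError):
        simulate_whale_track(cfg, 0)


def test_reproducibility_bit_identical():
    cfg = SimConfig(seed=42, duration_h=2.0)
    a = simulate_whale_track(cfg, 3)
    b = simulate_whale_track(cfg, 3)
    assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
    assert np.array_equal(a.blow_times, b.blow_times)


# ---------------------------------------------------------------------------
# vessels


def test_single_line_shot_count():
    # one 10-km line at 8 km/h = 4500 s; 10-s interval -> 450 shots
    cfg = SimConfig(seed=1, duration_h=2.0)
    cfg.vessels = VesselParams(n_seismic=1, n_support=0, line_length_km=10.0,
                               n_lines=1, speed_kmh=8.0, shot_interval_s=10.0)
    _, shots = simulate_vessels(cfg)
    assert len(shots) == 450


def test_zero_vessels_empty_fleet():
    cfg = SimConfig(seed=1)
    cfg.vessels = VesselParams(n_seismic=0, n_support=0)
    vessels, shots = simulate_vessels(cfg)
    assert len(vessels) == 0 and len(shots) == 0


def test_negative_vessel_speed_rejected():
    cfg = SimConfig()
    cfg.vessels = VesselParams(speed_kmh=-1.0)
    with pytest.raises(ConfigError):
        simulate_vessels(cfg)


def test_min_distance_matches_bruteforce(scenario):
    """Closest-vessel series equals a brute-force pairwise minimum."""
    from shorewhale.trackmetrics import vessel_positions_at
    tr = scenario.tracks[0]
    vs = scenario.vessels
    for t in tr.t[::40]:
        fleet = vessel_positions_at(vs, float(t))
        px, py = tr.position_at(float(t))
        d_impl = float(np.hypot(fleet["x_m"] - px, fleet["y_m"] - py).min())
        # brute force: interpolate every vessel trajectory by hand
        brute = np.inf
        for vid, grp in vs.groupby("vessel_id"):
            vx = np.interp(t, grp["t_s"], grp["x_m"])
            vy = np.interp(t, grp["t_s"], grp["y_m"])
            brute = min(brute, math.hypot(vx - px, vy - py))
        assert d_impl == pytest.approx(brute, rel=1e-12)


# ---------------------------------------------------------------------------
# sound field


def test_spreading_only_closed_form():
    src = SoundSource("s", "seismic", [0.0, 100.0], [0.0, 0.0], [0.0, 0.0],
                      200.0, shot_times=np.array([10.0]))
    from shorewhale.config import PropagationParams
    prop = PropagationParams(spreading_n=20.0, absorption_db_per_km=0.0,
                             ambient_floor_db=0.0)
    field = SoundField([src], prop)
    sel = field.evaluate(1000.0, 0.0, 0.0)["seismic"][0]
    assert sel == pytest.approx(200.0 - 20.0 * math.log10(1000.0), abs=1e-9)


def test_two_equal_sources_add_3db():
    assert energy_sum_db([120.0, 120.0]) == pytest.approx(123.010, abs=1e-3)


def test_window_energy_sum_matches_oracle(rng):
    """k shots of X dB in a window -> X + 10 log10 k; random levels match a
    direct big-sum oracle to <= 1e-9 dB."""
    k = 7
    shots = np.linspace(0.0, 29.0, k)
    src = SoundSource("s", "seismic", [0.0, 30.0], [0.0, 0.0], [0.0, 0.0],
                      150.0, shot_times=shots)
    from shorewhale.config import PropagationParams
    prop = PropagationParams(spreading_n=20.0, absorption_db_per_km=0.0,
                             ambient_floor_db=0.0)
    field = SoundField([src], prop)
    x = 500.0
    per_shot = 150.0 - 20.0 * math.log10(x)
    sel = field.evaluate(x, 0.0, 0.0)["seismic"][0]
    assert sel == pytest.approx(per_shot + 10.0 * math.log10(k), abs=1e-9)
    levels = rng.uniform(90, 160, 50)
    oracle = 10.0 * math.log10(np.sum(10.0 ** (levels / 10.0)))
    assert energy_sum_db(levels) == pytest.approx(oracle, abs=1e-9)


def test_sel_monotone_in_range(scenario):
    src = [s for s in scenario.field.sources if s.source_type == "vessel"][0]
    single = SoundField([src], scenario.config.propagation)
    sx, sy = src.position_at(15.0)
    rs = np.array([200.0, 500.0, 2000.0, 8000.0])
    sels = [single.evaluate(float(sx) + r, float(sy), 0.0)["vessel"][0]
            for r in rs]
    assert all(a >= b for a, b in zip(sels, sels[1:]))


def test_zero_range_clamped_with_warning():
    src = SoundSource("s", "vessel", [0.0, 100.0], [0.0, 0.0], [0.0, 0.0],
                      170.0, active=(0.0, 100.0))
    field = SoundField([src])
    with pytest.warns(UserWarning):
        out = field.evaluate(0.0, 0.0, 0.0)
    assert np.isfinite(out["vessel"][0])


# ---------------------------------------------------------------------------
# injected dose-response effects


def _const_field(level_db=140.0, x=50_000.0):
    """A stationary continuous source tuned to a roughly flat received level."""
    from shorewhale.config import PropagationParams
    prop = PropagationParams(spreading_n=20.0, absorption_db_per_km=0.0,
                             ambient_floor_db=0.0)
    sl = level_db - 10.0 * math.log10(30.0) + 20.0 * math.log10(x)
    src = SoundSource("s", "vessel", [0.0, 1e6], [x, x], [0.0, 0.0], sl,
                      active=(0.0, 1e6))
    return SoundField([src], prop)


def test_effect_none_is_identity():
    cfg = SimConfig(seed=9, duration_h=1.0)
    tr = simulate_whale_track(cfg, 0)
    out = inject_response(tr, _const_field(), cfg)
    assert out is tr


def test_speed_effect_shifts_log_speed():
    """Constant exposure E: mean log-speed shifts by slope*(E - thr) against
    the paired unexposed simulation."""
    cfg = SimConfig(seed=21, duration_h=8.0, n_whales=1)
    tr = simulate_whale_track(cfg, 0)
    field = _const_field(140.0)
    cfg.response = ResponseEffect("speed", threshold_db=120.0, slope=0.01)
    out = inject_response(tr, field, cfg)
    steps0 = np.hypot(np.diff(tr.x), np.diff(tr.y))
    steps1 = np.hypot(np.diff(out.x), np.diff(out.y))
    shift = np.mean(np.log(steps1) - np.log(steps0))
    # received level varies slightly with whale x; compare to the actual mean
    sel = field.combined_sel(tr.x[:-1], tr.y[:-1], tr.t[:-1])
    expected = 0.01 * np.mean(np.maximum(sel - 120.0, 0.0))
    assert shift == pytest.approx(expected, rel=1e-9)


def test_heading_bias_turns_away_from_source():
    """Strong heading bias from a source due east concentrates movement west."""
    cfg = SimConfig(seed=31, duration_h=8.0, n_whales=1)
    tr = simulate_whale_track(cfg, 0)
    field = _const_field(150.0, x=50_000.0)   # source far due east
    cfg.response = ResponseEffect("heading-bias", threshold_db=120.0, slope=0.2)
    out = inject_response(tr, field, cfg)
    dx, dy = np.diff(out.x), np.diff(out.y)
    heads = np.arctan2(dx, dy)
    # circular-mean oracle
    mean_dir = math.degrees(math.atan2(np.sin(heads).mean(),
                                       np.cos(heads).mean())) % 360.0
    assert abs(mean_dir - 270.0) < 15.0      # away from due-east source


def test_respiration_effect_scales_interblow_gaps():
    cfg = SimConfig(seed=41, duration_h=4.0, n_whales=1)
    tr = simulate_whale_track(cfg, 0)
    field = _const_field(140.0)
    cfg.response = ResponseEffect("respiration", threshold_db=120.0, slope=0.01)
    out = inject_response(tr, field, cfg)
    g0 = np.concatenate([np.diff(s.blow_times) for s in tr.surfacings
                         if len(s.blow_times) > 1])
    g1 = np.concatenate([np.diff(s.blow_times) for s in out.surfacings
                         if len(s.blow_times) > 1])
    assert np.all(g1 >= g0)                  # intervals stretched, never shrunk
    assert g1.sum() > g0.sum() * 1.1


def test_unknown_effect_rejected():
    cfg = SimConfig()
    cfg.response = ResponseEffect("explode", 120.0, 0.1)
    tr = simulate_whale_track(SimConfig(seed=1, duration_h=1.0), 0)
    with pytest.raises(ConfigError):
        inject_response(tr, _const_field(), cfg)


# ---------------------------------------------------------------------------
# observation process


def test_out_of_range_whale_yields_no_fixes():
    """A whale 13 km from a 10.8-m station with a 6-km cutoff is never fixed."""
    cfg = SimConfig(seed=3, duration_h=1.0)
    grid = LocalGrid(cfg.anchor_lat, cfg.anchor_lon)
    tr = simulate_whale_track(cfg, 0)
    station = Station("LOW", cfg.anchor_lat, cfg.anchor_lon, 10.8,
                      max_range_km=6.0)
    tr.x = tr.x + 13_000.0     # shift whole track beyond the cutoff
    fixes, events, suppressed = observe_track(tr, station, grid, cfg)
    assert len(fixes) == 0
    assert suppressed == len(tr.surfacings)
    assert len(events) > 0     # focal events still recorded


def test_noiseless_observation_roundtrip():
    from shorewhale.geodesy import fix_to_position
    cfg = SimConfig(seed=13, duration_h=1.0)
    cfg.theodolite_noise_arcsec = 0.0
    grid = LocalGrid(cfg.anchor_lat, cfg.anchor_lon)
    station = Station("S", cfg.anchor_lat, cfg.anchor_lon, 20.0)
    tr = simulate_whale_track(cfg, 0)
    fixes, _, _ = observe_track(tr, station, grid, cfg)
    assert len(fixes) > 0
    for _, fx in fixes.iterrows():
        x, y = fix_to_position(fx["vertical_angle_deg"],
                               fx["horizontal_angle_deg"], station, grid)
        px, py = tr.position_at(fx["t_s"])
        assert math.hypot(x - px, y - py) < 1.0


def test_angular_noise_error_propagation():
    """5 arc-sec noise at ~5 km: positional scatter consistent with the
    first-order propagation sigma_range ~ R^2 sigma_theta / h."""
    cfg = SimConfig(seed=17, duration_h=1.0)
    cfg.transition = np.eye(4)
    grid = LocalGrid(cfg.anchor_lat, cfg.anchor_lon)
    station = Station("S", cfg.anchor_lat, cfg.anchor_lon, 20.0)
    tr = simulate_whale_track(cfg, 0, initial_state=0)
    # park the whale at a fixed point 5 km east
    tr.x = np.full_like(tr.x, 5000.0)
    tr.y = np.zeros_like(tr.y)
    errs = []
    from shorewhale.geodesy import fix_to_position
    for rep in range(60):
        fixes, _, _ = observe_track(tr, station, grid, cfg, seed=1000 + rep)
        for _, fx in fixes.iterrows():
            x, y = fix_to_position(fx["vertical_angle_deg"],
                                   fx["horizontal_angle_deg"], station, grid)
            errs.append(x - 5000.0)
    sigma_theta = math.radians(5.0 / 3600.0)
    sigma_pred = 5000.0 ** 2 * sigma_theta / 20.0     # ~30 m
    sd = np.std(errs)
    assert 0.5 * sigma_pred < sd < 1.5 * sigma_pred


def test_fixes_only_during_surfacings(scenario):
    for tr in scenario.tracks:
        wf = scenario.fixes[scenario.fixes["whale_id"] == tr.whale_id]
        if len(wf):
            assert tr.at_surface(wf["t_s"].to_numpy()).all()


# ---------------------------------------------------------------------------
# prey and environment


def test_prey_total_is_sum_of_taxa():
    cfg = SimConfig(seed=2)
    prey = simulate_prey_samples(cfg)
    taxa_sum = prey[list(("amphipods", "isopods", "cumaceans",
                          "polychaetes", "bivalves"))].sum(axis=1)
    assert np.allclose(prey["total"], taxa_sum, atol=1e-9)
    assert (prey[["amphipods", "isopods", "cumaceans", "polychaetes",
                  "bivalves", "total"]] >= 0).all().all()


def test_infinite_correlation_length_gives_constant_residual_field():
    cfg = SimConfig(seed=2)
    prey = simulate_prey_samples(cfg, corr_length_km=np.inf)
    # remove the depth trend per taxon: residual ln-field must be constant
    for taxon in ("isopods", "cumaceans"):   # taxa with zero depth trend
        lnz = np.log(prey[taxon])
        assert np.ptp(lnz) < 1e-3   # up to the solver's diagonal jitter


def test_environment_tide_and_depth():
    cfg = SimConfig(seed=1)
    env = simulate_environment(cfg)
    assert env.depth(5000.0) == pytest.approx(20.0)   # 4 m/km * 5 km
    t = np.linspace(0, cfg.tide_period_h * 3600.0, 1000)
    tide = env.tide(t)
    assert abs(tide).max() == pytest.approx(cfg.tide_amplitude_m, rel=1e-3)
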