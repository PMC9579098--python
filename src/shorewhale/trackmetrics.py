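"""Movement response variables: 90-s resampling and 10.5-min bin metrics.

Raw theodolite positions arrive at irregular surfacing times, so tracks are
first resampled to a uniform 90-s step (linear interpolation along the chord,
never extrapolating) to standardize step lengths. Response variables are then
computed on consecutive, non-overlapping bins of 7 steps (8 positions,
10.5 min):

SPD   cumulative step length / bin duration, km/h
LIN   net displacement / cumulative length, in [0, 1]
RR    mean absolute heading change per minute over consecutive step pairs
MDIR  mean resultant length of the 7 step headings, in [0, 1]
TRK_R mean resultant length of the 6 turning angles (directionality index)
Range maximum pairwise distance among the 8 positions, km
cos_dir, sin_dir  direction of net displacement (azimuth clockwise from north)
ROW_CV, ROW_SV    |whale net-movement azimuth - bearing to closest (seismic)
                  vessel| folded to [0, 180]: 0 = toward, 180 = away

Azimuths are degrees clockwise from true north. Behavior state per bin is the
modal state of the 8 positions, ties resolved to "mixed".
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd

RESAMPLE_S = 90.0
STEPS_PER_BIN = 7
BIN_S = RESAMPLE_S * STEPS_PER_BIN          # 630 s = 10.5 min
MAX_GAP_S = 600.0


def split_on_gaps(times: np.ndarray, max_gap_s: float = MAX_GAP_S) -> list:
    """Index slices of segments whose internal fix gaps are <= max_gap_s."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return []
    breaks = np.where(np.diff(times) > max_gap_s)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [times.size]])
    return [slice(a, b) for a, b in zip(starts, ends)]


def resample_track(positions: pd.DataFrame, interval_s: float = RESAMPLE_S,
                   max_gap_s: float = MAX_GAP_S) -> list[pd.DataFrame]:
    """Resample one whale's position series onto exact ``interval_s`` epochs.

    ``positions`` must hold columns t_s, x_m, y_m (and optionally
    behavior_state). Returns one DataFrame per gap-free sub-track; sub-tracks
    with fewer than two raw fixes are dropped. Interpolation is linear in
    time between neighbouring fixes (on the chord) and never extrapolates.
    """
    pos = positions.sort_values("t_s", kind="stable")
    t = pos["t_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("fix timestamps must be strictly increasing")
    out = []
    for i, sl in enumerate(split_on_gaps(t, max_gap_s)):
        seg = pos.iloc[sl]
        ts = seg["t_s"].to_numpy(dtype=float)
        if ts.size < 2:
            continue
        epochs = np.arange(ts[0], ts[-1] + 1e-9, interval_s)
        sub = pd.DataFrame({
            "t_s": epochs,
            "x_m": np.interp(epochs, ts, seg["x_m"].to_numpy(dtype=float)),
            "y_m": np.interp(epochs, ts, seg["y_m"].to_numpy(dtype=float)),
        })
        if "behavior_state" in seg.columns:
            idx = np.clip(np.searchsorted(ts, epochs), 0, ts.size - 1)
            near_prev = idx > 0
            prev = np.maximum(idx - 1, 0)
            choose_prev = near_prev & (np.abs(epochs - ts[prev]) <=
                                       np.abs(ts[idx] - epochs))
            nearest = np.where(choose_prev, prev, idx)
            sub["behavior_state"] = seg["behavior_state"].to_numpy()[nearest]
        if "whale_id" in seg.columns:
            sub["whale_id"] = seg["whale_id"].iloc[0]
        sub["segment"] = i
        out.append(sub)
    return out


def azimuth_deg(dx, dy):
    """Planar azimuth, degrees clockwise from north."""
    return np.degrees(np.arctan2(dx, dy)) % 360.0


def fold_angle_deg(a):
    """Fold an angular difference to [0, 180]."""
    return np.abs((np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)


def mean_resultant_length(angles_deg) -> float:
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        return float("nan")
    return float(np.hypot(np.cos(a).mean(), np.sin(a).mean()))


def _modal_state(states) -> str:
    counts = Counter(states)
    best = counts.most_common()
    if len(best) > 1 and best[0][1] == best[1][1]:
        return "mixed"
    return best[0][0]


def vessel_positions_at(vessels: pd.DataFrame, t: float) -> pd.DataFrame:
    """Interpolated fleet positions at time t (one row per vessel)."""
    rows = []
    for vid, grp in vessels.groupby("vessel_id"):
        ts = grp["t_s"].to_numpy(dtype=float)
        rows.append((vid, grp["vessel_type"].iloc[0],
                     float(np.interp(t, ts, grp["x_m"].to_numpy(dtype=float))),
                     float(np.interp(t, ts, grp["y_m"].to_numpy(dtype=float)))))
    return pd.DataFrame(rows, columns=["vessel_id", "vessel_type", "x_m", "y_m"])


def compute_movement_bins(resampled: pd.DataFrame,
                          vessels: pd.DataFrame | None = None,
                          shoreline_xy: np.ndarray | None = None,
                          range_mode: str = "max_pairwise") -> pd.DataFrame:
    """Movement response variables for every full 7-step bin of one sub-track.

    Trailing partial bins are discarded. Zero-net-displacement bins keep
    LIN = 0 and get NaN direction (flagged via ``dir_defined``).
    """
    if range_mode not in ("max_pairwise", "net_displacement"):
        raise ValueError(f"unknown range mode {range_mode!r}")
    t = resampled["t_s"].to_numpy(dtype=float)
    x = resampled["x_m"].to_numpy(dtype=float)
    y = resampled["y_m"].to_numpy(dtype=float)
    if t.size and not np.allclose(np.diff(t), RESAMPLE_S):
        raise ValueError("input must be resampled at the 90-s criterion")
    n_bins = (t.size - 1) // STEPS_PER_BIN
    rows = []
    for b in range(n_bins):
        i0 = b * STEPS_PER_BIN
        xs = x[i0:i0 + STEPS_PER_BIN + 1]
        ys = y[i0:i0 + STEPS_PER_BIN + 1]
        dx = np.diff(xs)
        dy = np.diff(ys)
        steps = np.hypot(dx, dy)
        cum = float(steps.sum())
        net = float(math.hypot(xs[-1] - xs[0], ys[-1] - ys[0]))
        spd = cum / 1000.0 / (BIN_S / 3600.0)
        lin = net / cum if cum > 0 else 0.0
        heads = azimuth_deg(dx, dy)
        turns = (np.diff(heads) + 180.0) % 360.0 - 180.0
        rr = float(np.abs(turns).mean()) / (RESAMPLE_S / 60.0)
        mdir = mean_resultant_length(heads)
        trk_r = mean_resultant_length(turns)
        dxy = np.hypot(xs[:, None] - xs[None, :], ys[:, None] - ys[None, :])
        if range_mode == "max_pairwise":
            rng_km = float(dxy.max()) / 1000.0
        else:
            rng_km = net / 1000.0
        dir_defined = net > 0
        if dir_defined:
            direction = float(azimuth_deg(xs[-1] - xs[0], ys[-1] - ys[0]))
            cos_dir = math.cos(math.radians(direction))
            sin_dir = math.sin(math.radians(direction))
        else:
            direction = cos_dir = sin_dir = float("nan")
        t_mid = t[i0] + BIN_S / 2.0
        x_mid = float(np.interp(t_mid, t, x))
        y_mid = float(np.interp(t_mid, t, y))
        row = {
            "bin_start_s": t[i0], "bin_end_s": t[i0] + BIN_S,
            "SPD": spd, "LIN": lin, "RR": rr, "MDIR": mdir, "TRK_R": trk_r,
            "Range": rng_km, "direction_deg": direction,
            "cos_dir": cos_dir, "sin_dir": sin_dir, "dir_defined": dir_defined,
            "net_km": net / 1000.0, "x_mid_m": x_mid, "y_mid_m": y_mid,
        }
        if shoreline_xy is not None:
            from .geodesy import distance_from_shore_km
            row["dist_shore_km"] = float(distance_from_shore_km(
                x_mid, y_mid, shoreline_xy))
        if vessels is not None and len(vessels):
            fleet = vessel_positions_at(vessels, t_mid)
            d = np.hypot(fleet["x_m"] - x_mid, fleet["y_m"] - y_mid) / 1000.0
            bearings = azimuth_deg(fleet["x_m"] - x_mid, fleet["y_m"] - y_mid)
            i_cv = int(np.argmin(d))
            row["ROW_CV"] = (float(fold_angle_deg(direction - bearings.iloc[i_cv]))
                             if dir_defined else float("nan"))
            seismic = fleet["vessel_type"].to_numpy() == "seismic"
            if seismic.any():
                ds = d.to_numpy()[seismic]
                bs = bearings.to_numpy()[seismic]
                i_sv = int(np.argmin(ds))
                row["ROW_SV"] = (float(fold_angle_deg(direction - bs[i_sv]))
                                 if dir_defined else float("nan"))
            else:
                row["ROW_SV"] = float("nan")
        else:
            row["ROW_CV"] = row["ROW_SV"] = float("nan")
        if "behavior_state" in resampled.columns:
            row["behavior_state"] = _modal_state(
                list(resampled["behavior_state"].iloc[i0:i0 + STEPS_PER_BIN + 1]))
        if "whale_id" in resampled.columns:
            row["whale_id"] = resampled["whale_id"].iloc[0]
        if "segment" in resampled.columns:
            row["segment"] = resampled["segment"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
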