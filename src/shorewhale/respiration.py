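"""Respiration response variables from focal-follow event streams.

A focal follow records timed behavioral events (blows, dive starts) for one
individual. Events are segmented into surfacing/dive cycles: a surfacing is a
maximal run of blows whose inter-blow gaps stay at or below the dive
threshold (default 60 s) and that is not split by a recorded dive_start; the
interval between consecutive surfacings is a dive. Seven response variables
are then averaged over the same 10.5-min bins as the movement metrics:

respiration interval   mean gap between successive blows within surfacings, s
surface time           mean surfacing duration (last blow - first blow), s
dive time              mean dive duration, s
blows per surfacing    mean blow count per surfacing
surface blow rate      blows per minute of surface time
dive-surface blow rate blows per minute of the full dive + surfacing cycle
time at surface        100 * surface / (surface + dive), percent

Cycles are assigned to the bin containing the cycle midpoint; bins with no
complete cycle yield no row (never zero-filled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DIVE_THRESHOLD_S = 60.0


@dataclass
class Cycle:
    """One surfacing and the dive that follows it (dive NaN if absent)."""

    surf_start: float
    surf_end: float
    n_blows: int
    blow_gaps: np.ndarray
    dive_s: float           # NaN when the record ends at the surface
    complete: bool          # False for clipped leading/trailing cycles

    @property
    def surface_s(self) -> float:
        return self.surf_end - self.surf_start

    @property
    def midpoint(self) -> float:
        end = self.surf_end + (self.dive_s if np.isfinite(self.dive_s) else 0.0)
        return 0.5 * (self.surf_start + end)


def segment_cycles(events: pd.DataFrame,
                   dive_threshold_s: float = DIVE_THRESHOLD_S) -> list[Cycle]:
    """Segment a focal event stream into surfacing/dive cycles.

    ``events`` holds columns t_s and event ('blow' | 'dive_start'), strictly
    increasing in time. A blow run is split where the gap exceeds
    ``dive_threshold_s`` or where a dive_start event intervenes. The leading
    cycle and the trailing cycle are flagged incomplete (their dives may be
    clipped by the session boundaries).
    """
    if len(events) == 0:
        return []
    ev = events.sort_values("t_s", kind="stable")
    t = ev["t_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("event timestamps must be non-decreasing")
    kinds = ev["event"].to_numpy()
    blow_t = t[kinds == "blow"]
    dive_t = t[kinds == "dive_start"]
    if blow_t.size == 0:
        return []
    # boundaries between consecutive blows: long gap or an intervening dive_start
    runs = [[blow_t[0]]]
    for prev, cur in zip(blow_t[:-1], blow_t[1:]):
        gap_break = (cur - prev) > dive_threshold_s
        dive_break = np.any((dive_t > prev) & (dive_t < cur))
        if gap_break or dive_break:
            runs.append([cur])
        else:
            runs[-1].append(cur)
    cycles = []
    for i, run in enumerate(runs):
        run = np.asarray(run)
        if i + 1 < len(runs):
            dive = runs[i + 1][0] - run[-1]
        else:
            dive = float("nan")
        cycles.append(Cycle(
            surf_start=float(run[0]), surf_end=float(run[-1]),
            n_blows=int(run.size), blow_gaps=np.diff(run),
            dive_s=float(dive),
            complete=not (i == 0 or i == len(runs) - 1),
        ))
    if len(cycles) == 1:
        cycles[0].complete = False
    return cycles


def compute_respiration_bins(cycles: list[Cycle], bin_starts,
                             bin_s: float = 630.0,
                             include_incomplete: bool = True) -> pd.DataFrame:
    """Average the seven respiration variables over fixed bins.

    ``bin_starts`` are the bin left edges (s). A cycle belongs to the bin
    containing its midpoint. Incomplete boundary cycles contribute their
    surfacing statistics but never a clipped dive; bins with no contributing
    cycle produce no row.
    """
    bin_starts = np.asarray(bin_starts, dtype=float)
    rows = []
    for b0 in bin_starts:
        members = [c for c in cycles if b0 <= c.midpoint < b0 + bin_s
                   and (include_incomplete or c.complete)]
        if not members:
            continue
        gaps = np.concatenate([c.blow_gaps for c in members]) \
            if any(c.blow_gaps.size for c in members) else np.empty(0)
        surface = np.array([c.surface_s for c in members])
        blows = np.array([c.n_blows for c in members], dtype=float)
        total_surface = float(surface.sum())
        total_blows = float(blows.sum())
        surf_min = total_surface / 60.0
        # dive-dependent rates use only cycles whose dive was observed, so a
        # record that ends at the surface cannot bias them
        dived = [c for c in members if np.isfinite(c.dive_s)]
        dives = np.array([c.dive_s for c in dived])
        dived_surface = float(sum(c.surface_s for c in dived))
        dived_blows = float(sum(c.n_blows for c in dived))
        total_dive = float(dives.sum())
        cyc_min = (dived_surface + total_dive) / 60.0
        if not dived and surf_min > 0:      # all-surface bin: rate over surface
            cyc_min = surf_min
            dived_blows = total_blows
            dived_surface = total_surface
        rows.append({
            "bin_start_s": float(b0),
            "bin_end_s": float(b0 + bin_s),
            "resp_interval_s": float(gaps.mean()) if gaps.size else float("nan"),
            "surface_time_s": float(surface.mean()),
            "dive_time_s": float(dives.mean()) if dives.size else float("nan"),
            "blows_per_surfacing": float(blows.mean()),
            "surface_blow_rate": total_blows / surf_min if surf_min > 0
            else float("nan"),
            "dive_surface_blow_rate": dived_blows / cyc_min if cyc_min > 0
            else float("nan"),
            "time_at_surface_pct": 100.0 * dived_surface /
            (dived_surface + total_dive) if (dived_surface + total_dive) > 0
            else float("nan"),
            "n_cycles": len(members),
        })
    return pd.DataFrame(rows)


RESPIRATION_VARS = ("resp_interval_s", "surface_time_s", "dive_time_s",
                    "blows_per_surfacing", "surface_blow_rate",
                    "dive_surface_blow_rate", "time_at_surface_pct")
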