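"""Parametric sound field: per-source-type SEL_30s and SPL at any position-time.

Sound exposure level (SEL, dB re 1 uPa^2 s) is time-integrated squared
pressure; SEL_30s is the SEL accumulated over a 30-s window. SPL (dB re
1 uPa^2) is the RMS pressure level. For an impulsive (seismic airgun) source
each shot contributes a per-shot SEL at the receiver and the window SEL_30s
is the energy sum of the shots in the window:

    SEL_30s = 10 log10( sum_i 10**(SEL_i / 10) )

For a continuous (vessel) source characterized by an SPL source level,
SEL_30s = SPL(r) + 10 log10(30).

Transmission loss is a simple monotone law TL(r) = N log10(r[m]) + alpha r[km]
with the range clamped to the 1-m reference. Received levels below the
ambient floor are reported at the floor (the exposure is then ambient-masked,
not absent); windows in which a source type emits nothing yield NaN for that
type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import PropagationParams

SOURCE_TYPES = ("seismic", "vessel", "pile")
TEN_LOG_30 = 10.0 * np.log10(30.0)


def energy_sum_db(levels_db) -> float:
    """Energy (incoherent) sum of dB levels: 10 log10 sum 10^(L/10)."""
    levels_db = np.asarray(levels_db, dtype=float)
    levels_db = levels_db[np.isfinite(levels_db)]
    if levels_db.size == 0:
        return float("nan")
    return float(10.0 * np.log10(np.sum(10.0 ** (levels_db / 10.0))))


def transmission_loss_db(range_m, prop: PropagationParams) -> np.ndarray:
    """TL(r) = N log10(r) + alpha r; r clamped to the 1-m reference."""
    r = np.asarray(range_m, dtype=float)
    if np.any(r <= 0):
        warnings.warn("range clamped to 1-m reference", stacklevel=2)
    r = np.maximum(r, 1.0)
    return prop.spreading_n * np.log10(r) + prop.absorption_db_per_km * r / 1000.0


@dataclass
class SoundSource:
    """One moving source with a sampled trajectory.

    ``shot_times`` is None for continuous sources (``source_level_db`` is then
    an SPL at 1 m); for impulsive sources it is the shot schedule and
    ``source_level_db`` is the per-shot SEL at 1 m.
    """

    source_id: str
    source_type: str
    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    source_level_db: float
    shot_times: np.ndarray | None = None
    active: tuple | None = None   # (t_on, t_off) for continuous sources

    def __post_init__(self) -> None:
        if self.source_type not in SOURCE_TYPES:
            raise ValueError(f"unknown source type {self.source_type!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)

    def position_at(self, t) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(t, dtype=float)
        return (np.interp(t, self.times, self.xs),
                np.interp(t, self.times, self.ys))


@dataclass
class SoundField:
    """A set of sources plus a propagation law; the exposure evaluator."""

    sources: list
    propagation: PropagationParams = field(default_factory=PropagationParams)
    window_s: float = 30.0

    def _source_window_sel(self, src: SoundSource, x: float, y: float,
                           t0: float) -> float:
        """SEL over [t0, t0 + window) from one source at receiver (x, y)."""
        t1 = t0 + self.window_s
        if src.shot_times is not None:
            shots = src.shot_times[(src.shot_times >= t0) & (src.shot_times < t1)]
            if shots.size == 0:
                return float("nan")
            sx, sy = src.position_at(shots)
            r = np.hypot(sx - x, sy - y)
            per_shot = src.source_level_db - transmission_loss_db(r, self.propagation)
            return energy_sum_db(per_shot)
        if src.active is not None and not (src.active[0] < t1 and t0 < src.active[1]):
            return float("nan")
        sx, sy = src.position_at(t0 + 0.5 * self.window_s)
        r = float(np.hypot(sx - x, sy - y))
        spl = src.source_level_db - float(transmission_loss_db(r, self.propagation))
        return spl + TEN_LOG_30

    def evaluate(self, x: float, y: float, t0: float) -> dict:
        """Per-type and combined (SEL_30s, SPL) at a receiver for one window.

        Returns ``{type: (sel, spl), ..., "combined": (sel, spl)}``; NaN where
        no source of a type emitted during the window. Levels are floored at
        the ambient level.
        """
        floor = self.propagation.ambient_floor_db
        out = {}
        all_sels = []
        for typ in SOURCE_TYPES:
            sels = [self._source_window_sel(s, x, y, t0)
                    for s in self.sources if s.source_type == typ]
            sel = energy_sum_db(sels)
            if np.isfinite(sel):
                sel = max(sel, floor)
                all_sels.append(sel)
                out[typ] = (sel, sel - TEN_LOG_30)
            else:
                out[typ] = (float("nan"), float("nan"))
        combined = energy_sum_db(all_sels)
        if np.isfinite(combined):
            out["combined"] = (combined, combined - TEN_LOG_30)
        else:
            out["combined"] = (float("nan"), float("nan"))
        return out

    def _source_window_sel_many(self, src: SoundSource, xs, ys, t0s):
        """Vectorized per-window SEL from one source along a receiver path."""
        n = len(t0s)
        if src.shot_times is not None:
            a = np.searchsorted(src.shot_times, t0s)
            b = np.searchsorted(src.shot_times, t0s + self.window_s)
            counts = b - a
            out = np.full(n, np.nan)
            hit = counts > 0
            if not hit.any():
                return out
            # flatten all (epoch, shot) pairs, energy-sum with reduceat
            idx = np.concatenate([np.arange(ai, bi) for ai, bi
                                  in zip(a[hit], b[hit])])
            rep = np.repeat(np.where(hit)[0], counts[hit])
            shots = src.shot_times[idx]
            sx = np.interp(shots, src.times, src.xs)
            sy = np.interp(shots, src.times, src.ys)
            r = np.hypot(sx - xs[rep], sy - ys[rep])
            e = 10.0 ** ((src.source_level_db -
                          transmission_loss_db(r, self.propagation)) / 10.0)
            starts = np.concatenate([[0], np.cumsum(counts[hit])[:-1]])
            sums = np.add.reduceat(e, starts)
            out[hit] = 10.0 * np.log10(sums)
            return out
        mid = t0s + 0.5 * self.window_s
        sx = np.interp(mid, src.times, src.xs)
        sy = np.interp(mid, src.times, src.ys)
        r = np.hypot(sx - xs, sy - ys)
        sel = (src.source_level_db - transmission_loss_db(r, self.propagation)
               + TEN_LOG_30)
        if src.active is not None:
            off = ~((src.active[0] < t0s + self.window_s) &
                    (t0s < src.active[1]))
            sel[off] = np.nan
        return sel

    def evaluate_many(self, xs, ys, t0s) -> dict:
        """Per-type and combined SEL_30s arrays along a sampled path."""
        xs = np.atleast_1d(np.asarray(xs, dtype=float))
        ys = np.atleast_1d(np.asarray(ys, dtype=float))
        t0s = np.atleast_1d(np.asarray(t0s, dtype=float))
        floor = self.propagation.ambient_floor_db
        out = {}
        energy_total = np.zeros(len(t0s))
        any_total = np.zeros(len(t0s), dtype=bool)
        for typ in SOURCE_TYPES:
            energy = np.zeros(len(t0s))
            any_src = np.zeros(len(t0s), dtype=bool)
            for s in self.sources:
                if s.source_type != typ:
                    continue
                sel = self._source_window_sel_many(s, xs, ys, t0s)
                fin = np.isfinite(sel)
                energy[fin] += 10.0 ** (sel[fin] / 10.0)
                any_src |= fin
            with np.errstate(divide="ignore"):
                sel_t = np.where(any_src, 10.0 * np.log10(
                    np.maximum(energy, 1e-300)), np.nan)
            sel_t = np.where(any_src, np.maximum(sel_t, floor), np.nan)
            out[typ] = sel_t
            fin = np.isfinite(sel_t)
            energy_total[fin] += 10.0 ** (sel_t[fin] / 10.0)
            any_total |= fin
        with np.errstate(divide="ignore"):
            comb = np.where(any_total, 10.0 * np.log10(
                np.maximum(energy_total, 1e-300)), np.nan)
        out["combined"] = comb
        return out

    def combined_sel(self, xs, ys, t0s) -> np.ndarray:
        """Vectorized combined SEL_30s along a sampled path (one value per epoch)."""
        return self.evaluate_many(xs, ys, t0s)["combined"]
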