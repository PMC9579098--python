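"""Benthic prey biomass interpolation and behavior-state contrasts.

Point samples of per-taxon biomass (g/m^2) on the nearshore (< 20-m isobath)
grid are interpolated to whale locations two ways:

* inverse distance weighting (IDW): z_hat = sum w_i z_i / sum w_i with
  w_i = d_i**-p over the k nearest samples (default p = 2, k = 12); exact at
  sample points.
* regression kriging: a linear depth trend is removed by OLS, the residuals
  are kriged ordinarily under an exponential variogram fitted by weighted
  least squares to the empirical semivariogram, and the prediction is
  trend + kriged residual. With zero nugget the predictor honours the data
  exactly at sample points.

Per bin the response is the maximum interpolated biomass over the bin's 8
resampled positions; one-way ANOVA compares biomass across behavior states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .synthetic import PREY_TAXA


def idw_interpolate(sample_xy: np.ndarray, sample_z: np.ndarray,
                    query_xy: np.ndarray, power: float = 2.0,
                    k_neighbors: int = 12, eps_m: float = 1e-9) -> np.ndarray:
    """IDW prediction at query points; returns the sample value at d <= eps."""
    sxy = np.asarray(sample_xy, dtype=float)
    z = np.asarray(sample_z, dtype=float)
    if sxy.shape[0] == 0:
        raise ValueError("IDW requires at least one sample")
    q = np.atleast_2d(np.asarray(query_xy, dtype=float))
    out = np.empty(q.shape[0])
    k = min(k_neighbors, sxy.shape[0])
    for i, p in enumerate(q):
        d = np.hypot(sxy[:, 0] - p[0], sxy[:, 1] - p[1])
        hit = d <= eps_m
        if hit.any():
            out[i] = z[np.argmax(hit)]
            continue
        idx = np.argpartition(d, k - 1)[:k]
        w = d[idx] ** -power
        out[i] = float(np.sum(w * z[idx]) / np.sum(w))
    return out


@dataclass
class Variogram:
    """Exponential semivariogram gamma(h) = nugget + sill(1 - exp(-h/range))."""

    nugget: float
    sill: float
    range_m: float

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        g = self.nugget + self.sill * (1.0 - np.exp(-h / self.range_m))
        return np.where(h <= 0, 0.0, g)


def empirical_variogram(xy: np.ndarray, z: np.ndarray, n_bins: int = 12,
                        max_dist: float | None = None):
    """Binned empirical semivariogram: (lag centres, semivariances, pair counts)."""
    xy = np.asarray(xy, dtype=float)
    z = np.asarray(z, dtype=float)
    iu = np.triu_indices(len(z), k=1)
    d = np.hypot(xy[iu[0], 0] - xy[iu[1], 0], xy[iu[0], 1] - xy[iu[1], 1])
    sq = 0.5 * (z[iu[0]] - z[iu[1]]) ** 2
    if max_dist is None:
        max_dist = float(d.max()) / 2.0
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    which = np.digitize(d, edges) - 1
    centres, gammas, counts = [], [], []
    for b in range(n_bins):
        m = which == b
        if m.sum() < 2:
            continue
        centres.append(0.5 * (edges[b] + edges[b + 1]))
        gammas.append(float(sq[m].mean()))
        counts.append(int(m.sum()))
    return np.asarray(centres), np.asarray(gammas), np.asarray(counts)


def fit_variogram(xy: np.ndarray, z: np.ndarray, nugget: bool = False) -> Variogram:
    """WLS fit of the exponential model to the empirical semivariogram.

    Weights are pair counts / gamma_model^2 (Cressie). Falls back to a
    variance-scale default when the fit fails to converge.
    """
    h, g, n = empirical_variogram(xy, z)
    var = float(np.var(np.asarray(z, dtype=float)))
    fallback = Variogram(0.0, max(var, 1e-12), max(float(h[-1]) / 3.0, 1.0)
                         if h.size else 1000.0)
    if h.size < 3:
        return fallback
    def resid(p):
        nug = p[2] if nugget else 0.0
        model = Variogram(nug, p[0], p[1])(h)
        return np.sqrt(n) * (g - model) / np.maximum(model, 1e-12)
    p0 = [max(var, 1e-12), max(float(h[-1]) / 3.0, 1.0)]
    lb = [1e-12, 1.0]
    ub = [np.inf, np.inf]
    if nugget:
        p0, lb, ub = p0 + [1e-12], lb + [0.0], ub + [np.inf]
    try:
        sol = least_squares(resid, p0, bounds=(lb, ub), max_nfev=200)
        if not sol.success and not np.isfinite(sol.cost):
            return fallback
        nug = float(sol.x[2]) if nugget else 0.0
        return Variogram(nug, float(sol.x[0]), float(sol.x[1]))
    except Exception:
        return fallback


@dataclass
class RegressionKriging:
    """Depth-detrended ordinary kriging of one taxon's (log) biomass field."""

    sample_xy: np.ndarray
    sample_z: np.ndarray
    sample_depth: np.ndarray
    variogram: Variogram
    trend_coef: np.ndarray        # [intercept, slope on depth]
    residuals: np.ndarray
    ridge: float = 0.0

    @classmethod
    def fit(cls, sample_xy, sample_z, sample_depth,
            variogram: Variogram | None = None,
            nugget: bool = False) -> "RegressionKriging":
        xy = np.asarray(sample_xy, dtype=float)
        z = np.asarray(sample_z, dtype=float)
        depth = np.asarray(sample_depth, dtype=float)
        if len(z) < 5:
            raise ValueError("kriging requires at least 5 samples")
        X = np.column_stack([np.ones_like(depth), depth])
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        resid = z - X @ beta
        vg = variogram or fit_variogram(xy, resid, nugget=nugget)
        return cls(xy, z, depth, vg, beta, resid)

    def _kriging_matrix(self) -> np.ndarray:
        n = len(self.residuals)
        d = np.hypot(self.sample_xy[:, None, 0] - self.sample_xy[None, :, 0],
                     self.sample_xy[:, None, 1] - self.sample_xy[None, :, 1])
        gamma = self.variogram(d)
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = gamma
        A[:n, n] = 1.0
        A[n, :n] = 1.0
        A[n, n] = 0.0
        return A

    def predict(self, query_xy, query_depth):
        """Returns (prediction, ordinary-kriging variance of the residual)."""
        q = np.atleast_2d(np.asarray(query_xy, dtype=float))
        qd = np.atleast_1d(np.asarray(query_depth, dtype=float))
        n = len(self.residuals)
        A = self._kriging_matrix()
        try:
            lu = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            import warnings
            warnings.warn("singular kriging system; ridge-stabilized",
                          stacklevel=2)
            lu = np.linalg.inv(A + 1e-8 * np.eye(n + 1))
        preds = np.empty(q.shape[0])
        var = np.empty(q.shape[0])
        for i, p in enumerate(q):
            d0 = np.hypot(self.sample_xy[:, 0] - p[0],
                          self.sample_xy[:, 1] - p[1])
            b = np.concatenate([self.variogram(d0), [1.0]])
            lam = lu @ b
            resid_hat = float(lam[:n] @ self.residuals)
            trend = self.trend_coef[0] + self.trend_coef[1] * qd[i]
            preds[i] = trend + resid_hat
            var[i] = max(float(lam @ b), 0.0)
        return preds, var


def bin_max_biomass(bin_positions_xy: np.ndarray, depths,
                    interpolators: dict, max_depth_m: float = 20.0) -> dict:
    """Per-taxon maximum interpolated biomass over a bin's resampled positions.

    Positions deeper than ``max_depth_m`` fall outside the sampled prey
    domain; if every position is outside the result is NaN for all taxa.
    """
    xy = np.atleast_2d(np.asarray(bin_positions_xy, dtype=float))
    depths = np.atleast_1d(np.asarray(depths, dtype=float))
    inside = depths <= max_depth_m
    out = {}
    for taxon, interp in interpolators.items():
        if not inside.any():
            out[taxon] = float("nan")
            continue
        if isinstance(interp, RegressionKriging):
            z, _ = interp.predict(xy[inside], depths[inside])
        else:
            z = interp(xy[inside])
        out[taxon] = float(np.max(z))
    return out


def biomass_anova(bin_table: pd.DataFrame, taxa=PREY_TAXA + ("total",),
                  state_col: str = "behavior_state") -> pd.DataFrame:
    """One-way ANOVA of per-bin biomass across behavior states, per taxon.

    Returns df/F/p per taxon plus the per-state medians (the Table-1-style
    summary). Requires >= 2 states with >= 2 bins each.
    """
    states = [s for s, grp in bin_table.groupby(state_col) if len(grp) >= 2]
    if len(states) < 2:
        raise ValueError("ANOVA needs at least two behavior states with n >= 2")
    rows = []
    for taxon in taxa:
        groups = [bin_table.loc[bin_table[state_col] == s, taxon].dropna()
                  for s in states]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            continue
        if all(g.var(ddof=1) == 0 for g in groups) and \
                len({float(g.iloc[0]) for g in groups}) == 1:
            f, p = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*groups)
        row = {"taxon": taxon, "df_between": len(groups) - 1,
               "df_within": sum(len(g) for g in groups) - len(groups),
               "F": float(f), "p": float(p)}
        for s, g in zip(states, groups):
            row[f"median_{s}"] = float(np.median(g))
        rows.append(row)
    return pd.DataFrame(rows)


def build_interpolators(prey: pd.DataFrame, method: str = "idw",
                        taxa=PREY_TAXA + ("total",), **kw) -> dict:
    """Fit one interpolator per taxon from a prey sample table."""
    xy = prey[["x_m", "y_m"]].to_numpy(dtype=float)
    depth = prey["depth_m"].to_numpy(dtype=float)
    out = {}
    for taxon in taxa:
        z = prey[taxon].to_numpy(dtype=float)
        if method == "idw":
            out[taxon] = (lambda q, z=z: idw_interpolate(xy, z, q, **kw))
        elif method == "kriging":
            out[taxon] = RegressionKriging.fit(xy, z, depth, **kw)
        else:
            raise ValueError(f"unknown interpolation method {method!r}")
    return out
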