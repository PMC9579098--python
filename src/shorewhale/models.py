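"""Weighted marginal mixed models for behavioral dose-response analysis.

Responses (movement and respiration bin variables, or their principal
component scores) are modelled as Gaussian linear functions of natural
covariates (behavior state with feeding as the reference level, depth, tide,
time of day, station) and impact covariates (seismic/vessel SEL_30s and
cSEL, closest-vessel distances, ROW terms). Sequential 10.5-min bins of one
track are autocorrelated and tracks contribute unequal bin counts, so the
model is a weighted feasible GLS:

    y = X beta + e,   e ~ N(0, sigma^2 V),
    V = blockdiag_j( W_j^{-1/2} R_j(theta) W_j^{-1/2} )

with per-bin Horvitz-Thompson style weights w (variance proportional to
1/w) and a within-track residual correlation R chosen from independence,
compound symmetry ("constant"; the exact marginal of a track random
intercept), AR1, or a stationary per-lag ("unstructured") estimate.
Correlation parameters are moment-estimated from OLS residuals and the fit
iterated once. BIC uses the Gaussian ML likelihood so that models with
different fixed effects are comparable; stepwise selection runs forward over
natural covariates, then forward over impact covariates, then a backward
pass, with BIC ties (< 0.01) resolved toward the smaller model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, solve_triangular, toeplitz

STATE_REFERENCE = "feeding"
CORRELATION_STRUCTURES = ("independence", "constant", "ar1", "unstructured")


class TransformError(ValueError):
    pass


# ---------------------------------------------------------------------------
# response transforms


def transform_response(values, kind: str, n: int | None = None) -> np.ndarray:
    """Transform a response to an approximately normal scale.

    'logit' applies the boundary squeeze x -> (x (n-1) + 0.5) / n before
    ln(x / (1-x)) so indices that touch 0 or 1 stay finite; 'ln' is the
    natural log; 'cos'/'sin' take degrees; 'identity' passes through.
    """
    x = np.asarray(values, dtype=float)
    if kind == "identity":
        return x.copy()
    if kind == "ln":
        if np.any(x[np.isfinite(x)] <= 0):
            bad = np.where(x <= 0)[0]
            raise TransformError(f"ln transform of non-positive value at rows {bad[:5]}")
        return np.log(x)
    if kind == "logit":
        n = n or np.isfinite(x).sum()
        xs = (x * (n - 1) + 0.5) / n
        if np.any((xs <= 0) | (xs >= 1)):
            raise TransformError("logit input outside (0,1) after boundary squeeze")
        return np.log(xs / (1.0 - xs))
    if kind == "cos":
        return np.cos(np.radians(x))
    if kind == "sin":
        return np.sin(np.radians(x))
    raise TransformError(f"unknown transform {kind!r}")


def inverse_transform(values, kind: str, n: int | None = None) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if kind == "identity":
        return x.copy()
    if kind == "ln":
        return np.exp(x)
    if kind == "logit":
        if n is None:
            raise TransformError("inverse logit needs the squeeze sample size n")
        xs = 1.0 / (1.0 + np.exp(-x))
        return (xs * n - 0.5) / (n - 1)
    raise TransformError(f"no inverse for transform {kind!r}")


# ---------------------------------------------------------------------------
# collinearity screening


def collinearity_screen(table: pd.DataFrame, columns=None,
                        threshold: float = 0.60,
                        prefer: tuple = ("sel30", "csel")) -> dict:
    """Pairwise Pearson screen of continuous covariates.

    Pairs with |r| > threshold are flagged. Within flagged pairs the member
    whose name matches a preferred acoustic metric (SEL_30s / cSEL families)
    is retained and the other (e.g. an SPL or PK duplicate) dropped;
    otherwise the first column wins. Constant columns are flagged as
    undefined and dropped.
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    sub = table[cols].astype(float)
    constant = [c for c in cols if np.nanstd(sub[c].to_numpy()) == 0]
    usable = [c for c in cols if c not in constant]
    corr = sub[usable].corr()
    flagged = []
    dropped: list[str] = []
    for i, a in enumerate(usable):
        for b_ in usable[i + 1:]:
            r = float(corr.loc[a, b_])
            if np.isfinite(r) and abs(r) > threshold:
                flagged.append((a, b_, r))
    for a, b_, _r in flagged:
        if a in dropped or b_ in dropped:
            continue
        a_pref = any(p in a.lower() for p in prefer)
        b_pref = any(p in b_.lower() for p in prefer)
        if a_pref and not b_pref:
            dropped.append(b_)
        elif b_pref and not a_pref:
            dropped.append(a)
        else:
            dropped.append(b_)
    retained = [c for c in usable if c not in dropped]
    return {"flagged_pairs": flagged, "retained": retained,
            "dropped": dropped, "constant": constant, "correlations": corr}


# ---------------------------------------------------------------------------
# inverse-probability weights


def ht_weights(track_ids) -> np.ndarray:
    """Per-bin weights inversely proportional to track bin counts.

    Every track receives equal total weight mass and the weights sum to the
    number of bins; all-equal track lengths give unit weights.
    """
    ids = pd.Series(track_ids)
    n = len(ids)
    counts = ids.map(ids.value_counts())
    n_tracks = ids.nunique()
    w = n / (n_tracks * counts.to_numpy(dtype=float))
    return w


# ---------------------------------------------------------------------------
# design matrices


def build_design(table: pd.DataFrame, covariates,
                 state_col: str = "behavior_state") -> tuple[np.ndarray, list]:
    """Design matrix with intercept; categoricals dummy-coded.

    The behavior-state column is expanded against the 'feeding' reference.
    """
    cols = [np.ones(len(table))]
    names = ["B0"]
    for cov in covariates:
        if cov == state_col:
            levels = [s for s in ("feed/travel", "traveling", "mixed")
                      if (table[state_col] == s).any()]
            for lv in levels:
                cols.append((table[state_col] == lv).to_numpy(dtype=float))
                names.append(f"state[{lv}]")
        elif ":" in cov:
            a, b = cov.split(":")
            cols.append(table[a].to_numpy(dtype=float) *
                        table[b].to_numpy(dtype=float))
            names.append(cov)
        else:
            cols.append(table[cov].to_numpy(dtype=float))
            names.append(cov)
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# correlation structures


def _estimate_rho_ar1(resid_groups) -> float:
    num = den = 0.0
    for r in resid_groups:
        if len(r) >= 2:
            num += float(np.sum(r[:-1] * r[1:]))
            den += float(np.sum(r[:-1] ** 2))
    rho = num / den if den > 0 else 0.0
    return float(np.clip(rho, -0.95, 0.95))


def _estimate_rho_cs(resid_groups) -> float:
    num = den = 0.0
    npairs = 0
    for r in resid_groups:
        m = len(r)
        if m >= 2:
            s = float(r.sum())
            num += 0.5 * (s * s - float(np.sum(r * r)))
            npairs += m * (m - 1) // 2
        den += float(np.sum(r * r))
    if den <= 0 or npairs == 0:
        return 0.0
    sigma2 = den / sum(len(r) for r in resid_groups)
    rho = (num / npairs) / sigma2
    return float(np.clip(rho, 0.0, 0.95))


def _estimate_lag_corr(resid_groups, max_lag: int) -> np.ndarray:
    """Stationary per-lag correlations for the 'unstructured' (Toeplitz) mode."""
    den = sum(float(np.sum(r * r)) for r in resid_groups)
    ntot = sum(len(r) for r in resid_groups)
    sigma2 = den / ntot if ntot else 1.0
    out = np.zeros(max_lag + 1)
    out[0] = 1.0
    for lag in range(1, max_lag + 1):
        num = cnt = 0.0
        for r in resid_groups:
            if len(r) > lag:
                num += float(np.sum(r[:-lag] * r[lag:]))
                cnt += len(r) - lag
        out[lag] = np.clip(num / (cnt * sigma2), -0.9, 0.9) if cnt else 0.0
    return out


def _correlation_matrix(structure: str, m: int, params) -> np.ndarray:
    if structure == "independence" or m == 1:
        return np.eye(m)
    if structure == "ar1":
        rho = params
        return rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    if structure == "constant":
        rho = params
        return np.full((m, m), rho) + (1.0 - rho) * np.eye(m)
    if structure == "unstructured":
        lags = params
        idx = np.minimum(np.abs(np.subtract.outer(np.arange(m), np.arange(m))),
                         len(lags) - 1)
        r = lags[idx]
        np.fill_diagonal(r, 1.0)
        # guarantee positive definiteness of the Toeplitz estimate
        w, v = np.linalg.eigh(r)
        if w.min() < 1e-6:
            r = v @ np.diag(np.maximum(w, 1e-6)) @ v.T
            d = np.sqrt(np.diag(r))
            r = r / np.outer(d, d)
        return r
    raise ValueError(f"unknown correlation structure {structure!r}")


# ---------------------------------------------------------------------------
# the fit


@dataclass
class ModelFit:
    """A fitted weighted GLS response model (one Tables-2/3-style row)."""

    response: str
    names: list
    params: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    significant: np.ndarray          # p < 0.05 (the tables' bold flags)
    sigma2: float
    loglik: float
    bic: float
    structure: str
    corr_param: object
    n: int
    df_resid: int
    n_dropped: int
    covariates: list = field(default_factory=list)
    selection_path: list = field(default_factory=list)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.names, "coef": self.params, "se": self.se,
            "t": self.tvalues, "p": self.pvalues,
            "significant": self.significant,
        })

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        return np.column_stack([self.params - tcrit * self.se,
                                self.params + tcrit * self.se])


class FitError(RuntimeError):
    pass


def _whiten_blocks(groups, X, y, w, structure, params):
    """Per-track whitening A_j = L_j^{-1} W_j^{1/2}, stacked; also log|R_j|."""
    Xw = np.empty_like(X)
    yw = np.empty_like(y)
    logdet = 0.0
    for sl in groups:
        m = sl.stop - sl.start
        R = _correlation_matrix(structure, m, params)
        L = cholesky(R, lower=True)
        logdet += 2.0 * float(np.sum(np.log(np.diag(L))))
        sw = np.sqrt(w[sl])
        Xw[sl] = solve_triangular(L, X[sl] * sw[:, None], lower=True)
        yw[sl] = solve_triangular(L, y[sl] * sw, lower=True)
    return Xw, yw, logdet


def fit_mixed(table: pd.DataFrame, response: str, covariates,
              group_col: str = "track_id", weight_col: str | None = None,
              correlation: str = "ar1", transform: str = "identity",
              state_col: str = "behavior_state",
              n_iter: int = 2) -> ModelFit:
    """Fit one weighted marginal mixed model by feasible GLS.

    Listwise deletion over response + covariates; the dropped count is
    recorded on the fit. ``correlation`` selects the within-track residual
    structure; a singular or failed structure falls back to independence.
    A track-random-intercept fit is requested via correlation='constant'
    (its exact marginal form).
    """
    if correlation not in CORRELATION_STRUCTURES:
        raise FitError(f"unknown correlation structure {correlation!r}")
    needed = [response, group_col] + [c for cov in covariates
                                      for c in (cov.split(":") if ":" in cov
                                                else [cov])]
    if weight_col:
        needed.append(weight_col)
    needed = list(dict.fromkeys(needed))
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise FitError(f"missing columns {missing}")
    data = table[needed].copy()
    n_before = len(data)
    data = data.dropna()
    n_dropped = n_before - len(data)
    if len(data) == 0:
        raise FitError("no complete cases")
    data = data.sort_values([group_col], kind="stable").reset_index(drop=True)
    y = transform_response(data[response].to_numpy(dtype=float), transform)
    X, names = build_design(data, covariates, state_col=state_col)
    n, p = X.shape
    if n <= p:
        raise FitError(f"{n} rows for {p} parameters")
    w = (data[weight_col].to_numpy(dtype=float) if weight_col
         else np.ones(n))
    gid = data[group_col].to_numpy()
    bounds = np.concatenate([[0], np.where(gid[1:] != gid[:-1])[0] + 1, [n]])
    groups = [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]

    # OLS start, then iterate the moment estimator and GLS
    params: object = 0.0
    structure = correlation
    beta, *_ = np.linalg.lstsq(X * np.sqrt(w)[:, None],
                               y * np.sqrt(w), rcond=None)
    n_corr_param = 0
    for _ in range(n_iter):
        resid = (y - X @ beta) * np.sqrt(w)
        resid_groups = [resid[sl] for sl in groups]
        if structure == "ar1":
            params = _estimate_rho_ar1(resid_groups)
            n_corr_param = 1
        elif structure == "constant":
            params = _estimate_rho_cs(resid_groups)
            n_corr_param = 1
        elif structure == "unstructured":
            max_lag = min(max(len(r) for r in resid_groups) - 1, 6)
            params = _estimate_lag_corr(resid_groups, max(max_lag, 1))
            n_corr_param = len(params) - 1
        else:
            params = 0.0
        try:
            Xw, yw, logdet = _whiten_blocks(groups, X, y, w, structure, params)
        except np.linalg.LinAlgError:
            structure, params, n_corr_param = "independence", 0.0, 0
            Xw, yw, logdet = _whiten_blocks(groups, X, y, w, structure, params)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)

    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    sigma2 = rss / (n - p)
    xtx_inv = np.linalg.pinv(Xw.T @ Xw)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), n - p)
    sigma2_ml = rss / n
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet
                     - float(np.sum(np.log(w))) + n)
    k = p + 1 + n_corr_param
    bic = -2.0 * loglik + k * np.log(n)
    return ModelFit(response=response, names=names, params=beta, se=se,
                    tvalues=tvals, pvalues=pvals, significant=pvals < 0.05,
                    sigma2=sigma2, loglik=float(loglik), bic=float(bic),
                    structure=structure, corr_param=params, n=n,
                    df_resid=n - p, n_dropped=n_dropped,
                    covariates=list(covariates))


# ---------------------------------------------------------------------------
# BIC stepwise selection


def bic_stepwise(table: pd.DataFrame, response: str, natural, impact,
                 tie_tol: float = 0.01, **fit_kw) -> ModelFit:
    """Forward (natural, then impact) + backward BIC stepwise selection.

    BIC ties within ``tie_tol`` resolve toward the smaller model; the
    selection path is recorded on the returned fit.
    """
    path = []

    def fit(covs):
        return fit_mixed(table, response, covs, **fit_kw)

    selected: list = []
    current = fit(selected)
    path.append(("start", list(selected), current.bic))
    for phase, candidates in (("natural", list(natural)), ("impact", list(impact))):
        improved = True
        while improved:
            improved = False
            best_bic, best_cov, best_fit = current.bic, None, None
            for cov in candidates:
                if cov in selected:
                    continue
                try:
                    trial = fit(selected + [cov])
                except FitError:
                    continue
                if trial.bic < best_bic - tie_tol:
                    best_bic, best_cov, best_fit = trial.bic, cov, trial
            if best_cov is not None:
                selected.append(best_cov)
                current = best_fit
                path.append((f"forward-{phase}", best_cov, best_bic))
                improved = True
    # backward pass over everything selected
    improved = True
    while improved and selected:
        improved = False
        best_bic, drop_cov, best_fit = current.bic + tie_tol, None, None
        for cov in selected:
            try:
                trial = fit([c for c in selected if c != cov])
            except FitError:
                continue
            # a tie favours the smaller model, so <= with tolerance
            if trial.bic <= best_bic:
                best_bic, drop_cov, best_fit = trial.bic, cov, trial
        if drop_cov is not None:
            selected.remove(drop_cov)
            current = best_fit
            path.append(("backward", drop_cov, best_bic))
            improved = True
    current.selection_path = path
    return current


# ---------------------------------------------------------------------------
# PCA of response variables


def pca_scores(table: pd.DataFrame, columns, n_components: int = 3):
    """Correlation-matrix PCA of (standardized) response variables.

    Returns (scores DataFrame PC1..PCk over complete-case rows, variance
    fractions, loadings DataFrame). Each loading vector is oriented so its
    largest-magnitude element is positive.
    """
    cols = list(columns)
    if len(cols) < n_components:
        raise ValueError("need at least n_components response columns")
    sub = table[cols].dropna()
    z = sub.to_numpy(dtype=float)
    sd = z.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("degenerate (constant) response column in PCA input")
    z = (z - z.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    fractions = evals / evals.sum()
    scores = z @ evecs[:, :n_components]
    score_df = pd.DataFrame(scores, index=sub.index,
                            columns=[f"PC{i + 1}" for i in range(n_components)])
    loadings = pd.DataFrame(evecs[:, :n_components], index=cols,
                            columns=score_df.columns)
    return score_df, fractions[:n_components], loadings
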