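"""Response models: transforms, screening, weights, GLS, stepwise, PCA."""

import numpy as np
import pandas as pd
import pytest

from shorewhale.models import (CORRELATION_STRUCTURES, FitError,
                               TransformError, bic_stepwise,
                               collinearity_screen, fit_mixed, ht_weights,
                               inverse_transform, pca_scores,
                               transform_response)
from shorewhale.validation import simulate_bin_dataset


# ---------------------------------------------------------------------------
# transforms


def test_logit_and_ln_anchors():
    assert transform_response([0.5], "logit", n=1000)[0] == \
        pytest.approx(0.0, abs=1e-3)
    assert transform_response([1.0], "ln")[0] == 0.0


def test_boundary_squeeze_keeps_unit_interval_finite():
    out = transform_response([0.0, 1.0], "logit", n=100)
    assert np.isfinite(out).all()


def test_roundtrip_random_values(rng):
    x = rng.uniform(0.001, 0.999, 1000)
    n = len(x)
    back = inverse_transform(transform_response(x, "logit", n=n), "logit", n=n)
    assert np.max(np.abs(back - x)) < 1e-12
    y = rng.uniform(0.1, 50.0, 1000)
    assert np.max(np.abs(inverse_transform(
        transform_response(y, "ln"), "ln") - y)) < 1e-12


def test_ln_of_nonpositive_reports_rows():
    with pytest.raises(TransformError):
        transform_response([1.0, -2.0], "ln")


# ---------------------------------------------------------------------------
# collinearity


def test_duplicated_column_flagged():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
    df["b"] = df["a"]
    out = collinearity_screen(df)
    assert any(abs(r) == pytest.approx(1.0) for _, _, r in out["flagged_pairs"])
    assert out["dropped"]


def test_independent_columns_not_flagged(rng):
    df = pd.DataFrame(rng.normal(size=(10_000, 4)),
                      columns=["a", "b", "c", "d"])
    out = collinearity_screen(df)
    assert out["flagged_pairs"] == []
    assert out["retained"] == ["a", "b", "c", "d"]


def test_constructed_correlation_095_flagged(rng):
    x = rng.normal(size=5000)
    rho = 0.95
    y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=5000)
    out = collinearity_screen(pd.DataFrame({"x": x, "y": y}))
    assert len(out["flagged_pairs"]) == 1


def test_acoustic_metric_preference(rng):
    sel = rng.normal(size=2000)
    spl = sel + rng.normal(0, 0.05, 2000)     # SPL duplicates SEL
    df = pd.DataFrame({"sel30_seismic": sel, "spl_seismic": spl})
    out = collinearity_screen(df)
    assert "sel30_seismic" in out["retained"]
    assert "spl_seismic" in out["dropped"]


def test_constant_column_flagged_undefined():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
    out = collinearity_screen(df)
    assert out["constant"] == ["c"]


# ---------------------------------------------------------------------------
# weights


def test_equal_tracks_unit_weights():
    w = ht_weights(["A"] * 5 + ["B"] * 5)
    assert np.allclose(w, 1.0)


def test_unbalanced_tracks_equal_mass():
    w = ht_weights(["A"] + ["B"] * 9)
    assert w.sum() == pytest.approx(10.0)
    assert w[0] == pytest.approx(5.0)
    assert np.sum(w[1:]) == pytest.approx(5.0)


def test_random_structure_weight_identities(rng):
    ids = rng.choice([f"T{i}" for i in range(17)], size=400)
    w = ht_weights(ids)
    assert w.sum() == pytest.approx(400.0, abs=1e-9)
    sums = pd.Series(w).groupby(pd.Series(ids)).sum()
    assert np.allclose(sums, sums.iloc[0])


# ---------------------------------------------------------------------------
# GLS fitting


def small_balanced_table(rng, rho=0.4, n_tracks=2, m=4):
    rows = []
    for j in range(n_tracks):
        x = rng.normal(size=m)
        e = rng.normal(size=m)
        # constant (compound-symmetry) correlated noise
        shared = rng.normal()
        noise = np.sqrt(rho) * shared + np.sqrt(1 - rho) * e
        for i in range(m):
            rows.append({"track_id": f"T{j}", "x": x[i],
                         "response": 2.0 + 1.5 * x[i] + noise[i]})
    return pd.DataFrame(rows)


def test_constant_structure_matches_direct_gls_solve(rng):
    """Tiny balanced dataset: estimates equal the explicit generalized
    least-squares matrix solution built from the same correlation."""
    table = small_balanced_table(rng)
    fit = fit_mixed(table, "response", ["x"], correlation="constant")
    rho = float(fit.corr_param)
    m = 4
    R = np.full((m, m), rho) + (1 - rho) * np.eye(m)
    V = np.kron(np.eye(2), R)
    X = np.column_stack([np.ones(8), table["x"].to_numpy()])
    y = table["response"].to_numpy()
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    assert np.allclose(fit.params, beta, atol=1e-10)


def test_equal_weights_equal_unweighted(rng):
    table = simulate_bin_dataset(rng, n_tracks=10)
    table["unit_w"] = 1.0
    a = fit_mixed(table, "response", ["depth_m"], correlation="ar1")
    b = fit_mixed(table, "response", ["depth_m"], weight_col="unit_w",
                  correlation="ar1")
    assert np.allclose(a.params, b.params)
    assert np.allclose(a.se, b.se)


def test_independence_matches_statsmodels_wls(rng):
    """Independence + weights: coefficients and SEs equal statsmodels WLS."""
    import statsmodels.api as sm
    table = simulate_bin_dataset(rng, n_tracks=12)
    fit = fit_mixed(table, "response", ["depth_m", "sel30_seismic"],
                    weight_col="ht_weight", correlation="independence")
    X = sm.add_constant(table[["depth_m", "sel30_seismic"]].to_numpy())
    sm_fit = sm.WLS(table["response"].to_numpy(), X,
                    weights=table["ht_weight"].to_numpy()).fit()
    assert np.allclose(fit.params, sm_fit.params, atol=1e-9)
    assert np.allclose(fit.se, sm_fit.bse, atol=1e-9)
    assert np.allclose(fit.pvalues, sm_fit.pvalues, atol=1e-9)


def test_state_reference_is_feeding(rng):
    table = simulate_bin_dataset(rng, n_tracks=30)
    fit = fit_mixed(table, "response", ["behavior_state"],
                    correlation="independence")
    assert fit.names[0] == "B0"
    assert all(n.startswith("state[") for n in fit.names[1:])
    assert "state[feeding]" not in fit.names


def test_ar1_improves_bic_on_autocorrelated_data(rng):
    table = simulate_bin_dataset(rng, n_tracks=30, bins_mean=12, rho=0.5)
    ar1 = fit_mixed(table, "response", ["depth_m"], correlation="ar1")
    ind = fit_mixed(table, "response", ["depth_m"], correlation="independence")
    assert ar1.bic < ind.bic
    assert 0.2 < float(ar1.corr_param) < 0.8


def test_unstructured_structure_runs(rng):
    table = simulate_bin_dataset(rng, n_tracks=20, bins_mean=8, rho=0.4)
    fit = fit_mixed(table, "response", ["depth_m"], correlation="unstructured")
    assert np.isfinite(fit.bic)
    lags = np.asarray(fit.corr_param)
    assert lags[0] == 1.0


def test_recovers_injected_coefficients(rng):
    table = simulate_bin_dataset(rng, n_tracks=120, bins_mean=12, rho=0.3,
                                 beta_impact=0.05)
    fit = fit_mixed(table, "response",
                    ["behavior_state", "depth_m", "sel30_seismic"],
                    weight_col="ht_weight", correlation="ar1")
    i = fit.names.index("sel30_seismic")
    lo, hi = fit.conf_int()[i]
    assert lo < 0.05 < hi
    i_d = fit.names.index("depth_m")
    assert fit.params[i_d] == pytest.approx(0.05, abs=0.03)


def test_unknown_structure_rejected(rng):
    table = simulate_bin_dataset(rng, n_tracks=4)
    with pytest.raises(FitError):
        fit_mixed(table, "response", ["depth_m"], correlation="toeplitz2")


def test_listwise_deletion_counted(rng):
    table = simulate_bin_dataset(rng, n_tracks=10)
    table.loc[table.index[:7], "depth_m"] = np.nan
    fit = fit_mixed(table, "response", ["depth_m"])
    assert fit.n_dropped == 7


# ---------------------------------------------------------------------------
# stepwise selection


def test_strong_predictor_always_selected(rng):
    for _ in range(10):
        table = simulate_bin_dataset(rng, n_tracks=25, state_effects=(0,) * 4,
                                     beta_depth=0.0)
        x = rng.normal(size=len(table))
        table["strong"] = x
        table["weak"] = rng.normal(size=len(table))
        table["response"] = table["response"] + 1.0 * x   # standardized effect 1
        fit = bic_stepwise(table, "response", [], ["strong", "weak"],
                           correlation="independence")
        assert "strong" in fit.covariates


def test_stepwise_not_worse_than_exhaustive(rng):
    """Stepwise BIC is never better than the exhaustive-subset optimum and
    matches it when the greedy path is consistent."""
    from itertools import combinations
    table = simulate_bin_dataset(rng, n_tracks=20, beta_impact=0.03,
                                 n_noise_covariates=3)
    cands = ["depth_m", "sel30_seismic", "noise_0", "noise_1", "noise_2"]
    fit = bic_stepwise(table, "response", ["depth_m"],
                       [c for c in cands if c != "depth_m"],
                       correlation="independence")
    best = np.inf
    for k in range(len(cands) + 1):
        for sub in combinations(cands, k):
            trial = fit_mixed(table, "response", list(sub),
                              correlation="independence")
            best = min(best, trial.bic)
    assert fit.bic >= best - 1e-9
    assert fit.bic <= best + 10.0      # greedy stays near the optimum


def test_null_candidates_mostly_yield_null_model(rng):
    picked = 0
    n_sim = 20
    for _ in range(n_sim):
        table = simulate_bin_dataset(rng, n_tracks=20,
                                     state_effects=(0,) * 4, beta_depth=0.0,
                                     n_noise_covariates=3)
        fit = bic_stepwise(table, "response", [],
                           ["noise_0", "noise_1", "noise_2"],
                           correlation="independence")
        if not fit.covariates:
            picked += 1
    assert picked >= int(0.7 * n_sim)


def test_selection_path_recorded(rng):
    table = simulate_bin_dataset(rng, n_tracks=20, beta_impact=0.05)
    fit = bic_stepwise(table, "response", ["depth_m", "behavior_state"],
                       ["sel30_seismic"], correlation="independence")
    assert fit.selection_path[0][0] == "start"
    assert len(fit.selection_path) >= 2


# ---------------------------------------------------------------------------
# PCA


def test_two_perfectly_correlated_columns(rng):
    x = rng.normal(size=500)
    df = pd.DataFrame({"a": x, "b": 2.0 * x, "c": rng.normal(size=500)})
    scores, fracs, loadings = pca_scores(df, ["a", "b"], n_components=2)
    assert fracs[0] == pytest.approx(1.0, abs=1e-9)


def test_independent_columns_isotropic(rng):
    df = pd.DataFrame(rng.normal(size=(20_000, 5)),
                      columns=list("abcde"))
    _, fracs, _ = pca_scores(df, list("abcde"), n_components=5)
    assert np.allclose(fracs, 0.2, atol=0.02)


def test_eigenvalues_match_direct_eigendecomposition(rng):
    df = pd.DataFrame(rng.normal(size=(300, 6)) @ rng.normal(size=(6, 6)),
                      columns=list("abcdef"))
    scores, fracs, loadings = pca_scores(df, list("abcdef"), n_components=6)
    corr = np.corrcoef(((df - df.mean()) / df.std(ddof=1)).to_numpy(),
                       rowvar=False)
    evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
    assert np.allclose(fracs, evals[:6] / evals.sum(), atol=1e-9)
    assert fracs.sum() == pytest.approx(1.0, abs=1e-9)
    # sign convention: dominant loading positive
    for c in loadings.columns:
        v = loadings[c].to_numpy()
        assert v[np.argmax(np.abs(v))] > 0


def test_pca_matches_sklearn_scores(rng):
    from sklearn.decomposition import PCA
    df = pd.DataFrame(rng.normal(size=(200, 4)) @ rng.normal(size=(4, 4)),
                      columns=list("abcd"))
    scores, fracs, _ = pca_scores(df, list("abcd"))
    z = ((df - df.mean()) / df.std(ddof=1)).to_numpy()
    sk = PCA(n_components=3).fit(z)
    # compare up to per-component sign
    sk_scores = sk.transform(z)
    for j in range(3):
        r = np.corrcoef(scores.iloc[:, j], sk_scores[:, j])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)


def test_degenerate_columns_rejected(rng):
    df = pd.DataFrame({"a": np.ones(50), "b": rng.normal(size=50),
                       "c": rng.normal(size=50)})
    with pytest.raises(ValueError):
        pca_scores(df, ["a", "b", "c"])
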