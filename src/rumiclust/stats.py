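"""Phenotype derivation and between-cluster statistics.

Three analyses compare the low- and high-rumination clusters:

* linear mixed models on per-cow-day phenotypes (cluster fixed effect, cow
  random intercept, REML), reporting least-squares means, SEs and the
  cluster-contrast p-value with between-within denominator df (cows - 2);
* an additive model of hourly behaviour: cluster fixed effect, a periodic
  (period-24) smooth of hour, a smooth of date and a cow intercept, with
  smoothness chosen by generalized cross-validation;
* Pearson correlations between enteric methane and behaviour within 2-hour
  bins, across cows, collectively and per cluster.

Efficiency ratios (CH4/DMI, CH4/MY, MY/DMI) are formed per cow-day and then
modelled; they are not ratios of modelled means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LMMResult",
    "GAMResult",
    "derive_daily",
    "fit_lmm",
    "fit_gam",
    "correlate_2h",
    "RESPONSES",
]

# response name -> column of the daily phenotype table
RESPONSES = {
    "ch4": "ch4", "co2": "co2", "h2": "h2",
    "ch4_per_dmi": "ch4_per_dmi", "ch4_per_my": "ch4_per_my",
    "dmi": "dmi", "refusal_dm": "refusal_dm", "my": "my",
    "feed_eff": "feed_eff", "rt_min": "rt_min", "et_min": "et_min",
}


def _cluster_levels(values) -> list[str]:
    uniq = set(str(v) for v in values)
    if uniq == {"LR", "HR"}:
        return ["LR", "HR"]       # keep the field's conventional order
    return sorted(uniq)


def derive_daily(sensor: pd.DataFrame, emissions: pd.DataFrame,
                 production: pd.DataFrame,
                 cohort: list[str] | None = None) -> pd.DataFrame:
    """Merge the three streams into one row per cow-day.

    rt_min/et_min are the day's summed sensor seconds / 60; daily gas rates
    are the mean of that cow-day's hourly records; CH4/DMI, CH4/MY and MY/DMI
    are computed per cow-day (missing when the denominator is absent or 0,
    the row is kept for the other responses).
    """
    if cohort is not None:
        cohort = [str(c) for c in cohort]
        missing = sorted(set(cohort) - set(sensor["cow_id"].astype(str)))
        if missing:
            warnings.warn(f"cows with no sensor rows excluded: {missing}")
            cohort = [c for c in cohort if c not in missing]
        sensor = sensor[sensor["cow_id"].isin(cohort)]
        emissions = emissions[emissions["cow_id"].isin(cohort)]
        production = production[production["cow_id"].isin(cohort)]

    behav = (sensor.groupby(["cow_id", "date"], as_index=False)
             .agg(rt_min=("rt_s", "sum"), et_min=("et_s", "sum")))
    behav["rt_min"] /= 60.0
    behav["et_min"] /= 60.0

    gas = (emissions.groupby(["cow_id", "date"], as_index=False)
           .agg(ch4=("ch4_g_d", "mean"), co2=("co2_g_d", "mean"),
                h2=("h2_g_d", "mean")))

    prod = production.rename(columns={"dmi_kg": "dmi",
                                      "refusal_dm_kg": "refusal_dm",
                                      "my_kg": "my"})

    daily = behav.merge(gas, on=["cow_id", "date"], how="outer")
    daily = daily.merge(prod, on=["cow_id", "date"], how="outer")

    def ratio(num, den):
        den = daily[den]
        return np.where(den > 0, daily[num] / den, np.nan)

    daily["ch4_per_dmi"] = ratio("ch4", "dmi")
    daily["ch4_per_my"] = ratio("ch4", "my")
    daily["feed_eff"] = ratio("my", "dmi")
    return daily.sort_values(["cow_id", "date"]).reset_index(drop=True)


@dataclass
class LMMResult:
    """Cluster comparison for one daily response."""

    response: str
    cluster_levels: list[str]
    lsmeans: dict[str, float]
    lsmean_se: dict[str, float]
    difference: float             # second level minus first (HR - LR)
    difference_se: float
    p_value: float
    var_cow: float
    var_resid: float
    n_cows: int
    n_obs: int
    singular: bool = False        # True when the REML fit degenerated


def _lmm_fallback(y: np.ndarray, cluster: np.ndarray, cow: np.ndarray,
                  levels: list[str], response: str) -> LMMResult:
    """Exact balanced-case estimator: OLS on cow means, between-within df.

    Used when the REML fit is singular (e.g. zero residual variance in
    noiseless worked examples); reported with ``singular=True`` and cow
    variance 0 per the degenerate-fit policy.
    """
    df = pd.DataFrame({"y": y, "cluster": cluster, "cow": cow})
    cow_means = df.groupby(["cow", "cluster"], as_index=False)["y"].mean()
    g = cow_means.groupby("cluster")["y"]
    means = g.mean()
    counts = g.size()
    n_cows = int(counts.sum())
    dof = n_cows - 2
    sse = float(((cow_means["y"]
                  - cow_means["cluster"].map(means)) ** 2).sum())
    s2 = sse / dof if dof > 0 else 0.0
    ses = {lev: float(np.sqrt(s2 / counts[lev])) for lev in levels}
    diff = float(means[levels[1]] - means[levels[0]])
    diff_se = float(np.sqrt(s2 * (1.0 / counts[levels[0]]
                                  + 1.0 / counts[levels[1]])))
    if diff_se > 0:
        p = float(2 * sps.t.sf(abs(diff) / diff_se, dof))
    else:
        p = 0.0 if diff != 0 else 1.0
    return LMMResult(response, levels, {l: float(means[l]) for l in levels},
                     ses, diff, diff_se, p, var_cow=0.0, var_resid=s2,
                     n_cows=n_cows, n_obs=len(y), singular=True)


def fit_lmm(daily: pd.DataFrame, response: str) -> LMMResult:
    """Linear mixed model: response ~ cluster + (1 | cow), REML.

    ``daily`` needs columns ``cow_id``, ``cluster`` and the response (a
    column name or a key of :data:`RESPONSES`).  Least-squares means are the
    marginal means at each cluster level; the cluster p-value uses a t
    statistic on between-within denominator df (n_cows - 2).
    """
    col = RESPONSES.get(response, response)
    if col not in daily.columns:
        raise ValueError(f"unknown response {response!r}")
    data = daily[["cow_id", "cluster", col]].dropna()
    levels = _cluster_levels(data["cluster"])
    if len(levels) < 2:
        raise ValueError("need at least 2 clusters to compare")
    if len(levels) > 2:
        raise ValueError("the cluster contrast is defined for 2 clusters")
    counts = data.groupby("cluster")["cow_id"].nunique()
    if (counts < 2).any():
        raise ValueError("need at least 2 cows per cluster")
    obs_per_cow = data.groupby("cow_id").size()
    if (obs_per_cow < 2).any():
        warnings.warn("some cows have a single observation; "
                      "variance components may be poorly identified")

    y = data[col].to_numpy(float)
    cluster = data["cluster"].astype(str).to_numpy()
    cow = data["cow_id"].astype(str).to_numpy()
    n_cows = int(data["cow_id"].nunique())
    dof = n_cows - 2

    import statsmodels.api as sm

    X = np.column_stack([np.ones(len(y)), (cluster == levels[1]).astype(float)])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=cow)
            fit = model.fit(reml=True)
        beta = np.asarray(fit.fe_params, float)
        cov = np.asarray(fit.cov_params(), float)[:2, :2]
        ok = (np.all(np.isfinite(beta)) and np.all(np.isfinite(cov))
              and fit.scale > 1e-10)
    except Exception:
        ok = False
    if not ok:
        return _lmm_fallback(y, cluster, cow, levels, response)

    ls = {levels[0]: float(beta[0]), levels[1]: float(beta[0] + beta[1])}
    L0 = np.array([1.0, 0.0])
    L1 = np.array([1.0, 1.0])
    ses = {levels[0]: float(np.sqrt(L0 @ cov @ L0)),
           levels[1]: float(np.sqrt(L1 @ cov @ L1))}
    diff = float(beta[1])
    diff_se = float(np.sqrt(cov[1, 1]))
    p = float(2 * sps.t.sf(abs(diff) / diff_se, dof)) if diff_se > 0 else \
        (0.0 if diff != 0 else 1.0)
    var_cow = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
    return LMMResult(response, levels, ls, ses, diff, diff_se, p,
                     var_cow=var_cow, var_resid=float(fit.scale),
                     n_cows=n_cows, n_obs=len(y))


# --------------------------------------------------------------------------
# Additive model of hourly behaviour


@dataclass
class GAMResult:
    response: str
    cluster_levels: list[str]
    cluster_effect: float         # second level minus first
    cluster_se: float
    p_value: float
    curves: pd.DataFrame          # cluster, hour (0..24), fitted
    date_curve: pd.DataFrame      # date, fitted smooth component
    edf: dict[str, float]
    lambdas: dict[str, float]
    sigma2: float


def _fourier_basis(hours: np.ndarray, n_harmonics: int = 4) -> np.ndarray:
    h = np.asarray(hours, float)
    cols = []
    for k in range(1, n_harmonics + 1):
        cols.append(np.sin(2 * np.pi * k * h / 24.0))
        cols.append(np.cos(2 * np.pi * k * h / 24.0))
    return np.column_stack(cols)


def _bspline_basis(t: np.ndarray, n_basis: int, degree: int = 3):
    """B-spline design matrix with equally spaced knots over the data range,
    plus the P-spline second-difference penalty."""
    from scipy.interpolate import BSpline

    t = np.asarray(t, float)
    lo, hi = t.min(), t.max()
    if hi <= lo:
        hi = lo + 1.0
    inner = np.linspace(lo, hi, n_basis - degree + 1)
    knots = np.concatenate([[lo] * degree, inner, [hi] * degree])
    B = BSpline.design_matrix(np.clip(t, lo, hi), knots, degree).toarray()
    D2 = np.diff(np.eye(n_basis), 2, axis=0)
    return B, D2.T @ D2, (lo, hi, knots, degree)


def fit_gam(hourly: pd.DataFrame, response: str,
            n_harmonics: int = 4) -> GAMResult:
    """Penalized additive model of an hourly behaviour.

    Model: behaviour ~ cluster + s_cyclic(hour) + s(date) + cow intercept.
    The hour smooth uses a Fourier (harmonic) basis with period 24, so the
    fitted curve is exactly periodic (hour 0 == hour 24); the date smooth is
    a cubic P-spline; cow intercepts are ridge-penalized, the penalized
    least-squares analogue of a random intercept.  The three smoothing
    parameters are chosen jointly by GCV over a log grid.

    ``hourly`` needs columns cow_id, cluster, date, hour and the response
    column ("rt_s"/"et_s", or "RT"/"ET" aliases).
    """
    col = {"RT": "rt_s", "ET": "et_s"}.get(response, response)
    if col not in hourly.columns:
        raise ValueError(f"unknown response {response!r}")
    data = hourly.dropna(subset=[col])
    levels = _cluster_levels(data["cluster"])
    if len(levels) < 2:
        raise ValueError("need at least 2 clusters")
    if data["hour"].nunique() < 24:
        raise ValueError("need observations in all 24 distinct hours")

    y = data[col].to_numpy(float)
    n = len(y)
    hour = data["hour"].to_numpy(float)
    t = pd.to_datetime(data["date"]).map(pd.Timestamp.toordinal).to_numpy(float)
    cluster = data["cluster"].astype(str).to_numpy()
    cows = sorted(data["cow_id"].astype(str).unique())
    cow_idx = data["cow_id"].astype(str).map({c: i for i, c in enumerate(cows)})
    n_cows = len(cows)

    # ---- design blocks
    X_par = np.column_stack([np.ones(n), (cluster == levels[1]).astype(float)])
    X_hour = _fourier_basis(hour, n_harmonics)
    n_dates = len(np.unique(t))
    have_date = n_dates >= 4
    if have_date:
        nb = int(min(6, n_dates))
        X_date, P_date_raw, date_spline = _bspline_basis(t, nb)
        X_date = X_date - X_date.mean(axis=0)  # identifiability vs intercept
        # tiny ridge removes the constant-coefficient null direction
        P_date = P_date_raw + 1e-8 * np.eye(nb)
    else:
        nb = 0
        X_date = np.empty((n, 0))
        P_date = np.empty((0, 0))
        date_spline = None
    Z_cow = np.zeros((n, n_cows))
    Z_cow[np.arange(n), cow_idx] = 1.0

    X = np.hstack([X_par, X_hour, X_date, Z_cow])
    p = X.shape[1]
    s_par = slice(0, 2)
    s_hour = slice(2, 2 + 2 * n_harmonics)
    s_date = slice(s_hour.stop, s_hour.stop + nb)
    s_cow = slice(s_date.stop, p)

    # harmonic k penalized by k^2 (higher frequencies are wigglier)
    k_weights = np.repeat(np.arange(1, n_harmonics + 1) ** 2, 2)
    blocks = [("hour", s_hour, np.diag(k_weights))]
    if nb:
        blocks.append(("date", s_date, P_date))
    blocks.append(("cow", s_cow, np.eye(n_cows)))

    G = X.T @ X
    g = X.T @ y
    yty = float(y @ y)

    def assemble(lams: dict[str, float]) -> np.ndarray:
        A = G.copy()
        for name, sl, P in blocks:
            A[sl, sl] += lams[name] * P
        return A

    def fit_once(lams):
        A = assemble(lams)
        Ainv = np.linalg.pinv(A)
        beta = Ainv @ g
        M = Ainv @ G                       # hat-trace matrix
        edf = float(np.trace(M))
        rss = max(yty - 2 * beta @ g + beta @ (G @ beta), 0.0)
        return beta, Ainv, M, edf, rss

    # grids run from smoothest to wiggliest so GCV ties (e.g. an exactly
    # constant response, RSS = 0 everywhere) resolve to the smoothest fit
    grids = {"hour": np.logspace(8, -2, 6),
             "date": np.logspace(8, -2, 6) if nb else np.array([1.0]),
             "cow": np.logspace(5, -1, 4)}
    best = None
    for lh in grids["hour"]:
        for ld in grids["date"]:
            for lc in grids["cow"]:
                lams = {"hour": lh, "date": ld, "cow": lc}
                _, _, _, edf, rss = fit_once(lams)
                denom = max(n - edf, 1.0)
                gcv = n * rss / denom ** 2
                if best is None or gcv < best[0]:
                    best = (gcv, lams)
    lams = best[1]
    beta, Ainv, M, edf_tot, rss = fit_once(lams)
    sigma2 = rss / max(n - edf_tot, 1.0)
    cov = sigma2 * (Ainv @ G @ Ainv)

    effect = float(beta[1])
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    dof = max(n_cows - 2, 1)
    if se > 0:
        p_val = float(2 * sps.t.sf(abs(effect) / se, dof))
    else:
        p_val = 0.0 if abs(effect) > 1e-10 else 1.0

    # reported smooth edf includes the absorbed constant level
    edf_out = {}
    for name, sl, _ in blocks:
        tr = float(np.trace(M[sl, sl]))
        edf_out[name] = tr if name == "cow" else 1.0 + tr

    # population-level fitted circadian curves per cluster, hours 0..24
    hg = np.arange(25.0)
    Xh = _fourier_basis(hg, n_harmonics)
    if nb:
        from scipy.interpolate import BSpline
        lo, hi, knots, degree = date_spline
        mid = np.full(25, np.clip(t.mean(), lo, hi))
        Bmid = BSpline.design_matrix(mid, knots, degree).toarray()
        # apply the same column centering as the training design
        date_mid = Bmid - np.asarray(_bspline_basis(t, nb)[0].mean(axis=0))
    else:
        date_mid = np.empty((25, 0))
    curve_rows = []
    for lev in levels:
        Xg = np.hstack([np.ones((25, 1)),
                        np.full((25, 1), float(lev == levels[1])),
                        Xh, date_mid])
        fitted = Xg @ beta[:s_date.stop]
        for h, f in zip(hg, fitted):
            curve_rows.append({"cluster": lev, "hour": float(h),
                               "fitted": float(f)})
    curves = pd.DataFrame(curve_rows)

    if nb:
        tg = np.unique(t)
        lo, hi, knots, degree = date_spline
        Bg = BSpline.design_matrix(np.clip(tg, lo, hi), knots, degree).toarray()
        Bg = Bg - np.asarray(_bspline_basis(t, nb)[0].mean(axis=0))
        date_curve = pd.DataFrame({
            "date": [pd.Timestamp.fromordinal(int(v)).strftime("%Y-%m-%d")
                     for v in tg],
            "fitted": Bg @ beta[s_date]})
    else:
        date_curve = pd.DataFrame(columns=["date", "fitted"])

    lam_out = {k: float(v) for k, v in lams.items() if k != "date" or nb}
    return GAMResult(response, levels, effect, se, p_val, curves, date_curve,
                     edf_out, lam_out, float(sigma2))


# --------------------------------------------------------------------------
# 2-hour-bin correlations


def correlate_2h(hourly: pd.DataFrame,
                 scopes: tuple[str, ...] = ("all", "LR", "HR"),
                 behaviors: tuple[str, ...] = ("RT", "ET"),
                 gas_col: str = "ch4_g_d",
                 unit: str = "cow") -> pd.DataFrame:
    """Pearson correlation of methane with RT and ET within 2-h bins.

    ``hourly`` holds merged hourly rows (cow_id, cluster, date, hour, rt_s,
    et_s and the gas rate).  For each even-anchored 2-h bin the behaviour
    and gas values are averaged within bin per cow (``unit="cow"``, across
    all days) or per cow-day (``unit="cow_day"``), and r is computed across
    those units.  Returns bin_start_hour, behavior, scope, r, p, n; bins with
    zero variance report a missing r.
    """
    if unit not in ("cow", "cow_day"):
        raise ValueError("unit must be 'cow' or 'cow_day'")
    beh_cols = {"RT": "rt_s", "ET": "et_s"}
    df = hourly.copy()
    df["bin"] = (df["hour"].astype(int) // 2) * 2

    rows = []
    for scope in scopes:
        sub = df if scope == "all" else df[df["cluster"].astype(str) == scope]
        if sub["cow_id"].nunique() < 3:
            raise ValueError(f"scope {scope!r} has fewer than 3 cows")
        keys = ["cow_id", "bin"] if unit == "cow" else ["cow_id", "date", "bin"]
        agg = sub.groupby(keys, as_index=False).agg(
            rt_s=("rt_s", "mean"), et_s=("et_s", "mean"),
            gas=(gas_col, "mean"))
        for b in range(0, 24, 2):
            chunk = agg[agg["bin"] == b]
            for beh in behaviors:
                x = chunk[beh_cols[beh]].to_numpy(float)
                yv = chunk["gas"].to_numpy(float)
                ok = np.isfinite(x) & np.isfinite(yv)
                x, yv = x[ok], yv[ok]
                n_units = len(x)

                def _degenerate(v):
                    return np.std(v) <= 1e-10 * max(1.0, np.abs(v).max())

                if n_units < 3 or _degenerate(x) or _degenerate(yv):
                    r, p = np.nan, np.nan
                else:
                    r, p = sps.pearsonr(x, yv)
                rows.append({"bin_start_hour": b, "behavior": beh,
                             "scope": scope, "r": float(r) if r == r else np.nan,
                             "p": float(p) if p == p else np.nan,
                             "n": n_units})
    return pd.DataFrame(rows)
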