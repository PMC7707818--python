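"""Behavioral statistics for trial series of produced intervals.

The analyses that discriminate the candidate generative models:

* partial autocorrelation of t_p by trial lag (slow memory drift shows up as
  significant coefficients over tens of lags),
* cross-correlation of t_p between trial types at a given lag (context
  specificity of the drift),
* the mean and standard deviation of the relative error e^n as a function of
  the previous trial's error e^{n-1}: a linear fit mu(e^n) = m0 + m1 e^{n-1}
  and a quadratic fit sigma(e^n) = s0 + s1 e^{n-1} + s2 (e^{n-1})^2.  A
  significantly positive s2 (U-shape) is the signature of reward-regulated
  exploration,
* a two-sample F-test comparing error variance after rewarded vs unrewarded
  trials, and
* the scalar-variability (Weber) regression sigma(t_p) = beta1 * mu(t_p)
  across session/context summaries.

Trial pairing follows the task's exclusion rules: only consecutive completed
trials no more than 7 s apart, with outlier trials (t_p beyond 3 SD of the
context mean) removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tsa.stattools import pacf

from .task import SessionData

__all__ = [
    "ErrorStats",
    "LagCorrelation",
    "partial_correlation",
    "cross_correlation_by_lag",
    "pair_trials",
    "error_stats_by_prev",
    "variance_f_test",
    "scalar_variability_fit",
]


@dataclass
class LagCorrelation:
    lags: np.ndarray
    coefficients: np.ndarray
    null_lower: np.ndarray
    null_upper: np.ndarray
    kind: str  # 'partial' | 'pearson_cross'
    n_pairs: np.ndarray | None = None

    def significant(self) -> np.ndarray:
        """Lags whose coefficient exceeds the upper null bound."""
        return self.lags[self.coefficients > self.null_upper]


@dataclass
class ErrorStats:
    """Binned error statistics vs previous-trial error plus regression fits.

    Confidence intervals are two-sided at the 1%/99% percentiles
    (coefficient +/- t_{.01, N-p} * SE).
    """

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    mu_per_bin: np.ndarray
    sd_per_bin: np.ndarray
    n_per_bin: np.ndarray
    m0: float
    m1: float
    m0_ci: tuple[float, float]
    m1_ci: tuple[float, float]
    s0: float
    s1: float
    s2: float
    s0_ci: tuple[float, float]
    s1_ci: tuple[float, float]
    s2_ci: tuple[float, float]
    pairing: str = "same_type"
    n_pairs: int = 0

    @property
    def s2_significantly_positive(self) -> bool:
        return self.s2_ci[0] > 0.0

    @property
    def m1_significantly_positive(self) -> bool:
        return self.m1_ci[0] > 0.0


def partial_correlation(
    series: Sequence[float],
    max_lag: int = 60,
    n_shuffles: int = 100,
    seed: int = 0,
) -> LagCorrelation:
    """Partial autocorrelation at lags 1..max_lag with a shuffle null.

    Coefficients come from a successive autoregressive (Yule-Walker) fit;
    the null bounds are +/- 2.5 standard deviations of the coefficients
    obtained from shuffled copies of the series.
    """
    x = np.asarray(series, dtype=float)
    if x.size <= max_lag + 10:
        raise ValueError("series too short for the requested maximum lag")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no defined partial correlation")
    coefs = pacf(x, nlags=max_lag, method="ywm")[1:]
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, max_lag))
    for i in range(n_shuffles):
        null[i] = pacf(rng.permutation(x), nlags=max_lag, method="ywm")[1:]
    sd = null.std(axis=0, ddof=1)
    return LagCorrelation(
        lags=np.arange(1, max_lag + 1),
        coefficients=coefs,
        null_lower=-2.5 * sd,
        null_upper=2.5 * sd,
        kind="partial",
    )


def cross_correlation_by_lag(
    sessions: Sequence[SessionData],
    type_a: str,
    type_b: str,
    lags: int | Sequence[int] = 1,
    n_shuffles: int = 100,
    seed: int = 0,
) -> LagCorrelation:
    """Pearson correlation of z-scored t_p between two trial types at given
    session-trial lags, pooled across sessions; null bounds are the 1%/99%
    quantiles over shuffles of trial identity."""
    lag_list = [int(lags)] if np.isscalar(lags) else [int(v) for v in lags]
    rng = np.random.default_rng(seed)

    per_session: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    for s in sessions:
        df = s.to_frame()
        za = np.full(len(df), np.nan)
        zb = np.full(len(df), np.nan)
        for label, z in ((type_a, za), (type_b, zb)):
            m = (df["context"] == label).to_numpy()
            tp = df.loc[m, "t_p"].to_numpy(dtype=float)
            if tp.size >= 2 and tp.std() > 0:
                z[m] = (tp - tp.mean()) / tp.std()
        per_session.append((za, zb, za.copy(), zb.copy()))

    coefs, ns, lo, hi = [], [], [], []
    for lag in lag_list:
        xs, ys = [], []
        for za, zb, *_ in per_session:
            a = za[: len(za) - lag] if lag > 0 else za
            b = zb[lag:] if lag > 0 else zb
            ok = ~np.isnan(a) & ~np.isnan(b)
            xs.append(a[ok])
            ys.append(b[ok])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        n = x.size
        if n < 50:
            warnings.warn(f"only {n} pairs at lag {lag}; coefficient is unreliable", stacklevel=2)
        r = float(np.corrcoef(x, y)[0, 1]) if n >= 2 else np.nan
        null = np.array([
            float(np.corrcoef(rng.permutation(x), y)[0, 1]) for _ in range(n_shuffles)
        ]) if n >= 2 else np.array([np.nan])
        coefs.append(r)
        ns.append(n)
        lo.append(np.nanquantile(null, 0.01))
        hi.append(np.nanquantile(null, 0.99))

    return LagCorrelation(
        lags=np.array(lag_list),
        coefficients=np.array(coefs),
        null_lower=np.array(lo),
        null_upper=np.array(hi),
        kind="pearson_cross",
        n_pairs=np.array(ns),
    )


def pair_trials(
    session: SessionData,
    pairing: str = "same_type",
    max_gap_s: float = 7.0,
    outlier_sd: float = 3.0,
) -> pd.DataFrame:
    """Consecutive-trial pairs (e^{n-1}, e^n) after the exclusion rules.

    Pairs are adjacent completed trials no more than ``max_gap_s`` seconds
    apart; trials with t_p beyond ``outlier_sd`` standard deviations of their
    context mean are dropped.  ``pairing`` selects 'same_type' (identical
    context), 'same_effector' (same effector, any interval) or
    'different_effector'.  Columns: prev_pos/next_pos (0-based positions in
    the session), e_prev, e_next, rewarded_prev.
    """
    if pairing not in ("same_type", "same_effector", "different_effector"):
        raise ValueError(f"unknown pairing {pairing!r}")
    df = session.to_frame()
    ok = np.ones(len(df), dtype=bool)
    for label, grp in df.groupby("context"):
        tp = grp["t_p"]
        if len(grp) >= 2 and tp.std() > 0:
            z = (tp - tp.mean()).abs() / tp.std()
            ok[grp.index[z > outlier_sd]] = False

    rows = []
    for i in range(1, len(df)):
        if not (ok[i - 1] and ok[i]):
            continue
        if df["time_since_prev"].iat[i] > max_gap_s:
            continue
        same_eff = df["effector"].iat[i] == df["effector"].iat[i - 1]
        same_type = df["context"].iat[i] == df["context"].iat[i - 1]
        if pairing == "same_type" and not same_type:
            continue
        if pairing == "same_effector" and not same_eff:
            continue
        if pairing == "different_effector" and same_eff:
            continue
        rows.append(
            {
                "prev_pos": i - 1,
                "next_pos": i,
                "e_prev": df["e"].iat[i - 1],
                "e_next": df["e"].iat[i],
                "rewarded_prev": bool(df["rewarded"].iat[i - 1]),
            }
        )
    return pd.DataFrame(rows, columns=["prev_pos", "next_pos", "e_prev", "e_next", "rewarded_prev"])


def _ci(est: float, se: float, dof: int, alpha: float = 0.01) -> tuple[float, float]:
    t = sps.t.ppf(1.0 - alpha, dof)
    return (est - t * se, est + t * se)


def error_stats_by_prev(
    pairs: pd.DataFrame,
    n_bins: int = 10,
    min_per_bin: int = 20,
    mu_on: str = "pairs",
    weight_sigma_bins: bool = True,
    alpha: float = 0.01,
    pairing: str = "same_type",
) -> ErrorStats:
    """Binned mu/sigma of e^n vs e^{n-1} and the associated regressions.

    e^{n-1} is cut into ``n_bins`` equal-count bins (adjacent bins with fewer
    than ``min_per_bin`` pairs are merged).  The linear mean model is fit on
    raw pairs by default (``mu_on='bins'`` fits the per-bin means); the
    quadratic SD model is fit on per-bin SDs, weighted by bin counts.
    """
    e_prev = pairs["e_prev"].to_numpy(dtype=float)
    e_next = pairs["e_next"].to_numpy(dtype=float)
    n = e_prev.size
    if n < 5 * n_bins:
        raise ValueError("too few pairs for the requested number of bins")

    edges = np.unique(np.quantile(e_prev, np.linspace(0, 1, n_bins + 1)))
    which = np.clip(np.searchsorted(edges, e_prev, side="right") - 1, 0, len(edges) - 2)

    def summarize(which: np.ndarray, k: int):
        centers, mus, sds, ns = [], [], [], []
        for b in range(k):
            m = which == b
            cnt = int(m.sum())
            if cnt == 0:
                continue
            centers.append(e_prev[m].mean())
            mus.append(e_next[m].mean())
            sds.append(e_next[m].std(ddof=1) if cnt > 1 else 0.0)
            ns.append(cnt)
        return map(np.asarray, (centers, mus, sds, ns))

    centers, mus, sds, ns = summarize(which, len(edges) - 1)
    while len(ns) > 2 and ns.min() < min_per_bin:
        warnings.warn("merging under-populated e^{n-1} bins", stacklevel=2)
        b = int(np.argmin(ns))
        tgt = b - 1 if b > 0 else b + 1
        edges = np.delete(edges, max(b, tgt))
        which = np.clip(np.searchsorted(edges, e_prev, side="right") - 1, 0, len(edges) - 2)
        centers, mus, sds, ns = summarize(which, len(edges) - 1)

    # mean model: mu(e^n) = m0 + m1 e^{n-1}
    if mu_on == "pairs":
        X = sm.add_constant(e_prev)
        fit_mu = sm.OLS(e_next, X).fit()
    elif mu_on == "bins":
        X = sm.add_constant(centers)
        fit_mu = sm.WLS(mus, X, weights=ns).fit()
    else:
        raise ValueError("mu_on must be 'pairs' or 'bins'")
    m0, m1 = fit_mu.params
    dof_mu = int(fit_mu.df_resid)

    # SD model: sigma(e^n) = s0 + s1 e^{n-1} + s2 (e^{n-1})^2 on bin summaries
    Xs = sm.add_constant(np.column_stack([centers, centers**2]))
    w = ns if weight_sigma_bins else np.ones_like(ns)
    fit_sd = sm.WLS(sds, Xs, weights=w).fit()
    s0, s1, s2 = fit_sd.params
    dof_sd = int(fit_sd.df_resid)

    return ErrorStats(
        bin_edges=edges,
        bin_centers=centers,
        mu_per_bin=mus,
        sd_per_bin=sds,
        n_per_bin=ns,
        m0=float(m0),
        m1=float(m1),
        m0_ci=_ci(m0, fit_mu.bse[0], dof_mu, alpha),
        m1_ci=_ci(m1, fit_mu.bse[1], dof_mu, alpha),
        s0=float(s0),
        s1=float(s1),
        s2=float(s2),
        s0_ci=_ci(s0, fit_sd.bse[0], dof_sd, alpha),
        s1_ci=_ci(s1, fit_sd.bse[1], dof_sd, alpha),
        s2_ci=_ci(s2, fit_sd.bse[2], dof_sd, alpha),
        pairing=pairing,
        n_pairs=n,
    )


def variance_f_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Two-sample F-test for equal variances: F = var(a)/var(b)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise ValueError("zero variance in the denominator group")
    F = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    dist = sps.f(dfa, dfb)
    if alternative == "two-sided":
        p = 2.0 * min(dist.cdf(F), dist.sf(F))
        p = min(p, 1.0)
    elif alternative == "greater":
        p = dist.sf(F)
    elif alternative == "less":
        p = dist.cdf(F)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(F), float(p)


def scalar_variability_fit(
    summaries: Sequence[tuple[float, float]],
    alpha: float = 0.01,
) -> tuple[float, tuple[float, float]]:
    """Through-origin slope of sigma(t_p) on mu(t_p) (Weber fraction)."""
    arr = np.asarray(summaries, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least three (mu, sigma) summaries")
    mu, sigma = arr[:, 0], arr[:, 1]
    if np.allclose(sigma, 0.0):
        return 0.0, (0.0, 0.0)
    fit = sm.OLS(sigma, mu[:, None]).fit()
    beta1 = float(fit.params[0])
    return beta1, _ci(beta1, float(fit.bse[0]), int(fit.df_resid), alpha)
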