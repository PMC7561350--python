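"""Bivariate Granger-causality connectivity between brain-region traces.

A region F1 Granger-causes F2 if F1's past improves the prediction of F2
beyond F2's own past. Both nested autoregressive models,

    univariate:  F2(t) = sum_k a(k)  F2(t-k) + e1(t)
    bivariate:   F2(t) = sum_k b2(k) F2(t-k) + sum_k b1(k) F1(t-k) + e2(t)

are fitted by ordinary least squares on the identical usable samples
(frames q .. T-1), so the bivariate residual variance can never exceed the
univariate one and the causality measure

    GC(1->2) = ln( var[e1] / var[e2] )

is non-negative by construction. Link strength is quantified by the nested
F-statistic, F = ((RSS1 - RSS2)/q) / (RSS2 / (T_eff - 2q - 1)), whose null
distribution is F(q, T_eff - 2q - 1). The model order is chosen with a
small-sample-corrected Akaike cost on the bivariate residual covariance,
and a common order across fish is the rounded mean of the per-fish optima
(the hunting dataset convention is q = 5 frames at 3.6 Hz). Group
differences per link use Welch's unequal-variance t-test, BH-FDR corrected
across links.

Only strictly pairwise (bivariate) causality is computed; no conditional
or spectral variants, and fluorescence is analyzed directly without
deconvolution of the calcium kinetics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    DegenerateInputError,
    EpochTooShortError,
    ParameterError,
)
from .preprocess import RegionTraces, zscore_trace
from .stats import benjamini_hochberg


@dataclass
class ARFit:
    """One fitted (uni- or bivariate) autoregressive model."""

    order: int
    coefficients: np.ndarray   # a(k), or concatenated [b2(k), b1(k)]
    residuals: np.ndarray
    residual_variance: float   # mean squared residual over usable samples
    T_eff: int

    @property
    def rss(self) -> float:
        return float(self.residual_variance * self.T_eff)


@dataclass
class GCLink:
    source: str
    target: str
    gc_value: float
    f_statistic: float
    p_value: float
    order: int
    condition: str | None = None
    perfect_prediction: bool = False


@dataclass
class GCMatrix:
    """Directed F-statistic matrix; rows are sources, columns targets."""

    regions: list[str]
    f: np.ndarray
    gc: np.ndarray
    p: np.ndarray
    order: int
    condition: str | None = None
    fish_id: str | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, src in enumerate(self.regions):
            for j, tgt in enumerate(self.regions):
                if i == j:
                    continue
                rows.append((src, tgt, self.f[i, j], self.gc[i, j],
                             self.p[i, j]))
        return pd.DataFrame(rows, columns=["source", "target", "F",
                                           "gc_value", "p"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# AR fitting
# ---------------------------------------------------------------------------

def _lagged(x: np.ndarray, q: int) -> np.ndarray:
    """Lag matrix: row t-q has columns x(t-1) .. x(t-q), for t = q..T-1."""
    T = x.size
    return np.column_stack([x[q - k: T - k] for k in range(1, q + 1)])


def _ols(X: np.ndarray, y: np.ndarray):
    coefs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise DegenerateInputError("rank-deficient lag matrix")
    resid = y - X @ coefs
    return coefs, resid


def fit_univariate_ar(x: np.ndarray, q: int) -> ARFit:
    """OLS fit of an order-q autoregression of a z-scored trace on its own
    past. The usable samples are frames q..T-1."""
    x = np.asarray(x, dtype=float)
    if q < 1:
        raise ParameterError("order must be >= 1")
    if x.size <= 3 * q + 2:
        raise ParameterError("trace too short for the requested order")
    X = _lagged(x, q)
    y = x[q:]
    coefs, resid = _ols(X, y)
    return ARFit(q, coefs, resid, float(np.mean(resid ** 2)), y.size)


def fit_bivariate_ar(target: np.ndarray, source: np.ndarray, q: int) -> ARFit:
    """Joint OLS fit of the target on its own past and the source's past,
    on the same usable samples as the univariate fit. Coefficients are
    ordered [own lags b2(1..q), source lags b1(1..q)]."""
    target = np.asarray(target, dtype=float)
    source = np.asarray(source, dtype=float)
    if target.size != source.size:
        raise ParameterError("traces must have equal length")
    if q < 1:
        raise ParameterError("order must be >= 1")
    if target.size <= 3 * q + 2:
        raise ParameterError("trace too short for the requested order")
    X = np.hstack([_lagged(target, q), _lagged(source, q)])
    y = target[q:]
    try:
        coefs, resid = _ols(X, y)
    except DegenerateInputError:
        # collinear regressors (e.g. source identical to target): fall back
        # to the pseudoinverse solution; the variance comparison stays valid
        coefs = np.linalg.pinv(X) @ y
        resid = y - X @ coefs
    return ARFit(q, coefs, resid, float(np.mean(resid ** 2)), y.size)


def granger_link(source: np.ndarray, target: np.ndarray, q: int,
                 source_name: str = "source", target_name: str = "target",
                 condition: str | None = None) -> GCLink:
    """Directed causality source -> target at order q.

    Returns the log variance-ratio GC value, the nested-model F-statistic
    and its p-value under F(q, T_eff − 2q − 1). A bivariate fit with zero
    residual variance yields infinite GC and is flagged.
    """
    uni = fit_univariate_ar(np.asarray(target, dtype=float), q)
    biv = fit_bivariate_ar(np.asarray(target, dtype=float),
                           np.asarray(source, dtype=float), q)
    rss1, rss2 = uni.rss, biv.rss
    T_eff = uni.T_eff
    if rss2 <= 0:
        warnings.warn("perfect bivariate prediction; GC is infinite")
        return GCLink(source_name, target_name, np.inf, np.inf, 0.0, q,
                      condition, perfect_prediction=True)
    gc = max(float(np.log(rss1 / rss2)), 0.0)
    df2 = T_eff - 2 * q - 1
    if df2 <= 0:
        raise ParameterError("not enough samples for the F-test")
    f_stat = max(((rss1 - rss2) / q) / (rss2 / df2), 0.0)
    p = float(sps.f.sf(f_stat, q, df2))
    return GCLink(source_name, target_name, gc, float(f_stat), p, q,
                  condition)


# ---------------------------------------------------------------------------
# order selection
# ---------------------------------------------------------------------------

def akaike_cost(pair: tuple[np.ndarray, np.ndarray], q: int) -> float:
    """Small-sample-corrected Akaike cost for one region pair at order q:
    C_q = T ln det(Sigma2) + T (T N + q N^2) / (T − q N − N − 1), N = 2,
    where Sigma2 is the residual covariance of the bivariate VAR(q)."""
    x1, x2 = (np.asarray(v, dtype=float) for v in pair)
    N = 2
    T = x1.size
    denom = T - q * N - N - 1
    if denom <= 0:
        raise ParameterError("q too large for the trace length")
    X = np.hstack([_lagged(x1, q), _lagged(x2, q)])
    resid = np.column_stack([
        _ols(X, x1[q:])[1],
        _ols(X, x2[q:])[1],
    ])
    sigma2 = resid.T @ resid / resid.shape[0]
    sign, logdet = np.linalg.slogdet(sigma2)
    if sign <= 0:
        raise ParameterError("singular residual covariance")
    return float(T * logdet + T * (T * N + q * N * N) / denom)


def select_order(traces: RegionTraces, q_max: int) -> int:
    """Optimal autoregressive order for one fish.

    The Akaike cost is evaluated for every unordered region pair at each
    order 1..q_max and averaged across pairs; the minimizing order is the
    fish's optimum.
    """
    R = len(traces.regions)
    if R < 2:
        raise ParameterError("need at least two regions")
    T = traces.n_frames
    if q_max >= (T - 3) / 2:
        raise ParameterError("q_max too large for the trace length")
    pairs = [(traces.traces[i], traces.traces[j])
             for i in range(R) for j in range(i + 1, R)]
    costs = np.zeros(q_max)
    for q in range(1, q_max + 1):
        costs[q - 1] = np.mean([akaike_cost(p, q) for p in pairs])
    return int(np.argmin(costs) + 1)


def common_order(fish_orders) -> int:
    """Common model order across fish: rounded mean of per-fish optima."""
    orders = np.asarray(list(fish_orders), dtype=float)
    if orders.size == 0:
        raise ParameterError("no per-fish orders given")
    return int(round(float(orders.mean())))


# ---------------------------------------------------------------------------
# connectivity matrices and group comparison
# ---------------------------------------------------------------------------

def connectivity_matrix(traces: RegionTraces, q: int,
                        condition: str | None = None,
                        epoch: tuple[int, int] | None = None,
                        fish_id: str | None = None) -> GCMatrix:
    """F-statistic / GC matrix over every ordered region pair.

    If ``epoch`` (half-open frame span) is given the traces are sliced to
    it first; each trace is then re-standardized to zero mean and unit
    variance over the analyzed span before fitting.
    """
    data = traces.traces
    if epoch is not None:
        s, e = epoch
        data = data[:, s:e]
    T = data.shape[1]
    if T <= 3 * q + 2:
        raise EpochTooShortError("epoch too short for the requested order")
    z = np.stack([zscore_trace(tr) for tr in data])
    R = len(traces.regions)
    f = np.full((R, R), np.nan)
    gc = np.full((R, R), np.nan)
    p = np.full((R, R), np.nan)
    for i in range(R):
        for j in range(R):
            if i == j:
                continue
            link = granger_link(z[i], z[j], q,
                                source_name=traces.regions[i],
                                target_name=traces.regions[j],
                                condition=condition)
            f[i, j], gc[i, j], p[i, j] = (link.f_statistic, link.gc_value,
                                          link.p_value)
    return GCMatrix(list(traces.regions), f, gc, p, q, condition, fish_id)


def compare_link_groups(matrices_a: list[GCMatrix],
                        matrices_b: list[GCMatrix],
                        q_fdr: float = 0.05) -> pd.DataFrame:
    """Welch's t-test per directed link between two groups of fish,
    BH-FDR corrected across links.

    Links where both groups are degenerate (zero variance) get statistic 0
    and p = 1 when the means agree, or NaN (undefined, excluded from FDR)
    when they differ.
    """
    if len(matrices_a) < 3 or len(matrices_b) < 3:
        raise ParameterError("need at least 3 fish per group")
    regions = matrices_a[0].regions
    for m in matrices_a + matrices_b:
        if m.regions != regions:
            raise ParameterError("all matrices must share the region list")
    rows = []
    R = len(regions)
    for i in range(R):
        for j in range(R):
            if i == j:
                continue
            va = np.array([m.f[i, j] for m in matrices_a])
            vb = np.array([m.f[i, j] for m in matrices_b])
            if va.std() == 0 and vb.std() == 0:
                if np.isclose(va.mean(), vb.mean()):
                    stat, p = 0.0, 1.0
                else:
                    stat, p = np.nan, np.nan
            else:
                stat, p = sps.ttest_ind(va, vb, equal_var=False)
            rows.append((regions[i], regions[j], float(stat), float(p)))
    df = pd.DataFrame(rows, columns=["source", "target", "t_stat", "p"])
    flags = np.zeros(len(df), dtype=bool)
    ok = df["p"].notna().to_numpy()
    if ok.any():
        flags[ok] = benjamini_hochberg(df.loc[ok, "p"].to_numpy(), q=q_fdr)
    df["significant"] = flags
    return df
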