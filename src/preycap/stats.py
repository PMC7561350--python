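"""Bespoke statistics: permutation tests, d-prime, FDR, bootstrap, and the
robust interaction regression linking connectivity to behavior.

The permutation test is the workhorse pairwise comparison throughout the
pipeline: labels are rearranged between the two groups and the difference
in means recomputed to build a null distribution; the two-sided p-value is
the probability of a null statistic at least as extreme in absolute value
as the observed one. For small samples (total n <= 10) the test enumerates
every label assignment exactly; otherwise it is Monte-Carlo with the
add-one estimator (b + 1) / (m + 1), which keeps p strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .exceptions import (
    ConvergenceError,
    ParameterError,
    UnstableEstimateError,
)

EXACT_ENUMERATION_MAX_N = 10


@dataclass
class PermutationResult:
    observed_statistic: float
    p_value: float
    n_permutations: int
    method: str  # "exact" | "monte_carlo"
    seed: int | None


def permutation_test(group_a, group_b, n_perm: int = 100_000,
                     seed: int = 0) -> PermutationResult:
    """Two-sided difference-in-means permutation test.

    Parameters
    ----------
    group_a, group_b
        Observations for the two groups (each needs >= 2 values).
    n_perm
        Monte-Carlo label rearrangements (ignored when the total sample is
        small enough, <= 10, for exact enumeration of all assignments).
    seed
        Seed for the Monte-Carlo shuffles; recorded in the result.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = a.mean() - b.mean()

    if n <= EXACT_ENUMERATION_MAX_N:
        count = total = 0
        for idx in combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            stat = pooled[mask].mean() - pooled[~mask].mean()
            count += abs(stat) >= abs(observed) - 1e-12
            total += 1
        return PermutationResult(float(observed), count / total, total,
                                 "exact", None)

    rng = np.random.default_rng(seed)
    # vectorized shuffles: argsort of uniform noise gives random permutations
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    shuffled = pooled[order]
    null = shuffled[:, :na].mean(axis=1) - shuffled[:, na:].mean(axis=1)
    exceed = int(np.count_nonzero(np.abs(null) >= abs(observed) - 1e-12))
    p = (exceed + 1) / (n_perm + 1)
    return PermutationResult(float(observed), float(p), n_perm,
                             "monte_carlo", seed)


def dprime(hit_rate: float, fa_rate: float, n_trials: int | None = None
           ) -> float:
    """Signal-detection discriminability: Z(hit rate) − Z(false-alarm rate).

    Extreme rates (0 or 1) are clamped to 1/(2N) and 1 − 1/(2N) when the
    trial count is known, otherwise the corresponding z-score is capped at
    ±5 so the index stays finite.
    """
    def z(rate):
        if not 0.0 <= rate <= 1.0:
            raise ParameterError("rates must lie in [0, 1]")
        if n_trials is not None:
            rate = min(max(rate, 1.0 / (2 * n_trials)),
                       1.0 - 1.0 / (2 * n_trials))
            return sps.norm.ppf(rate)
        return float(np.clip(sps.norm.ppf(rate), -5.0, 5.0))

    return float(z(hit_rate) - z(fa_rate))


def benjamini_hochberg(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR selection.

    Returns a boolean rejection flag per input p-value: with the sorted
    p-values p(1) <= ... <= p(m), all hypotheses up to the largest k with
    p(k) <= q k / m are rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= q * (np.arange(1, m + 1) / m)
    flags = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.flatnonzero(below).max())
        flags[order[: k + 1]] = True
    return flags


@dataclass
class BootstrapResult:
    estimate: float        # percent change, observed data
    interval: tuple[float, float]
    n_boot: int
    seed: int


def bootstrap_percent_change(group_a, group_b, n_boot: int = 10_000,
                             seed: int = 0, ci: float = 95.0
                             ) -> BootstrapResult:
    """Bootstrap percent change of group B's mean relative to group A's.

    Each group is resampled with replacement independently; the statistic is
    ``100 * (mean_b − mean_a) / mean_a`` and the interval is the percentile
    interval of its bootstrap distribution. If the reference mean changes
    sign in more than 1% of resamples the ratio is unstable and an error is
    raised.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ParameterError("groups must be non-empty")
    rng = np.random.default_rng(seed)
    ma = a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
    mb = b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
    ref_sign = np.sign(a.mean())
    if ref_sign == 0 or np.mean(np.sign(ma) != ref_sign) > 0.01:
        raise UnstableEstimateError("reference group mean too close to zero")
    boots = 100.0 * (mb - ma) / ma
    alpha = (100.0 - ci) / 2.0
    lo, hi = np.percentile(boots, [alpha, 100.0 - alpha])
    estimate = 100.0 * (b.mean() - a.mean()) / a.mean()
    return BootstrapResult(float(estimate), (float(lo), float(hi)),
                           n_boot, seed)


@dataclass
class RegressionResult:
    """Robust interaction-regression fit.

    Coefficient order: intercept, diet, gc, diet_x_gc (NaN where a term was
    dropped because only one diet level was present). ``r_squared`` is the
    coefficient of determination of the final weighted fit; ``weights`` are
    the bisquare robustness weights per observation.
    """

    params: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    weights: np.ndarray
    converged: bool


def robust_interaction_regression(y, gc, diet, max_iter: int = 50,
                                  tol: float = 1e-8) -> RegressionResult:
    """Robust linear model: ConvergenceFrequency ~ 1 + Diet + GC + Diet*GC.

    Iteratively reweighted least squares with Tukey bisquare weights
    (tuning constant 4.685 x MAD scale), as implemented by statsmodels RLM.
    ``diet`` is a binary group indicator (prey-experienced vs prey-naive).
    With a single diet level the diet and interaction terms are dropped and
    reported as NaN. Coefficient p-values come from the weighted-fit t
    statistics; R-squared is computed on the final weighted fit.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float).ravel()
    gc = np.asarray(gc, dtype=float).ravel()
    diet = np.asarray(diet, dtype=float).ravel()
    if not (y.size == gc.size == diet.size):
        raise ParameterError("y, gc and diet must have equal length")
    if y.size < 6:
        raise ParameterError("need at least 6 observations")
    levels = np.unique(diet)
    terms = ["intercept", "gc"] if levels.size == 1 else [
        "intercept", "diet", "gc", "diet_x_gc"]
    cols = [np.ones_like(y)]
    if levels.size > 1:
        cols += [diet, gc, diet * gc]
    else:
        cols += [gc]
    X = np.column_stack(cols)

    def _pack(params, pvals, resid, w, converged):
        out_p = {t: np.nan for t in
                 ("intercept", "diet", "gc", "diet_x_gc")}
        out_pv = dict(out_p)
        for t, b, pv in zip(terms, params, pvals):
            out_p[t] = float(b)
            out_pv[t] = float(pv)
        yw_mean = np.average(y, weights=w)
        ss_res = float(np.sum(w * resid ** 2))
        ss_tot = float(np.sum(w * (y - yw_mean) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return RegressionResult(out_p, out_pv, r2, np.asarray(w), converged)

    # exact-fit guard: zero residuals break the MAD scale estimate
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    if np.max(np.abs(resid)) < 1e-10 * max(1.0, np.max(np.abs(y))):
        return _pack(beta, np.zeros_like(beta), resid,
                     np.ones_like(y), True)

    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    res = model.fit(maxiter=max_iter, tol=tol)
    history = res.fit_history.get("params", [])
    converged = True
    if len(history) >= max_iter:
        step = np.max(np.abs(np.asarray(history[-1])
                             - np.asarray(history[-2])))
        converged = step <= tol
    result = _pack(res.params, res.pvalues, res.resid, res.weights, converged)
    if not converged:
        raise ConvergenceError("robust regression did not converge",
                               last_result=result)
    return result
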