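"""Pixel-wise prey-position encoding model.

A linearized finite-impulse-response model predicts each pixel's
fluorescence from the prey's position expressed in a polar basis: 19 von
Mises angular bumps (concentration kappa = 20, centres evenly spaced on
the circle) crossed with 5 Gaussian radial bumps (width sigma = 40
radial-coordinate units over a 0-5 mm span) give 95 spatial basis
functions; each basis time series is delay-embedded (default -5..+14
frames, 20 delays) for 1900 features. Weights are estimated per pixel by
ridge regression inside a 10-fold sequential outer cross-validation whose
regularization strength is chosen per fold by an inner block-bootstrap;
held-out predictions are concatenated and their Pearson correlation with
the data is the pixel's cross-validated encoding strength. Significance is
assessed against the null distribution of the correlation of two
independent Gaussian series, FDR-corrected across pixels.

The radial coordinate is kept in basis-space units (default 40 units/mm,
so the 0-5 mm span maps to 0-200 units) because the Gaussian radial width
of 40 is expressed in those units.

All heavy routines accept a ``(T, n_pixels)`` response matrix and share
the stimulus design across pixels, which is what makes whole-brain maps
tractable: the inner loop solves the ridge path for every pixel at once
through a single eigendecomposition of the feature Gram matrix per
resample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import (
    InsufficientDataError,
    InsufficientSamplesError,
    InvalidDelayError,
    ParameterError,
)
from .stats import benjamini_hochberg
from .synthetic import UNITS_PER_MM, PreyTrajectory

#: Default delay embedding, frames. The window nominally spans -5..+15
#: frames (-1.4 to 4.2 s at 3.6 Hz); 20 delays (-5..+14) are used so the
#: feature count is exactly 95 x 20 = 1900. Configurable.
DEFAULT_DELAYS = tuple(range(-5, 15))


# ---------------------------------------------------------------------------
# polar basis
# ---------------------------------------------------------------------------

@dataclass
class BasisConfig:
    """Configuration of the polar spatial basis."""

    n_angle_bins: int = 19
    kappa: float = 20.0
    n_radial_bins: int = 5
    sigma: float = 40.0
    radial_span: tuple[float, float] = (0.0, 200.0)  # basis units (~0-5 mm)
    units_per_mm: float = UNITS_PER_MM

    def __post_init__(self):
        if self.n_angle_bins < 1 or self.n_radial_bins < 1:
            raise ParameterError("bin counts must be positive")
        if self.kappa <= 0 or self.sigma <= 0:
            raise ParameterError("kappa and sigma must be positive")

    @property
    def n_basis(self) -> int:
        return self.n_angle_bins * self.n_radial_bins


class SpatialBasis:
    """The set of two-dimensional (angle x radius) polar basis functions.

    Basis ``j`` is the product of a von Mises density in angle and a
    Gaussian density in radius; bases are ordered angle-major, i.e.
    ``j = i_angle * n_radial + i_radial``.
    """

    def __init__(self, config: BasisConfig):
        self.config = config
        # the circle wraps, so centres exclude the duplicate endpoint;
        # spacing is 2*pi / n (360/19 ~ 18.9 degrees for the default)
        self.angle_centers = -np.pi + 2.0 * np.pi * np.arange(
            config.n_angle_bins) / config.n_angle_bins
        self.radial_centers = np.linspace(*config.radial_span,
                                          config.n_radial_bins)

    @property
    def n_basis(self) -> int:
        return self.config.n_basis

    @property
    def angle_bin_width(self) -> float:
        """Angular spacing between adjacent centres, radians."""
        return 2.0 * np.pi / self.config.n_angle_bins

    def centers(self) -> list[tuple[float, float]]:
        """(angle_center, radial_center) per basis, in evaluation order."""
        return [(a, r) for a in self.angle_centers for r in self.radial_centers]

    def evaluate(self, angle: np.ndarray, radius_units: np.ndarray
                 ) -> np.ndarray:
        """Evaluate every basis at (angle, radius) pairs -> (T, n_basis).

        Each basis is a von Mises bump in angle times a Gaussian bump in
        radius, normalized to peak 1 at its own centre so that feature
        amplitudes are commensurate with z-scored pixel traces (and with
        the default regularization grid). NaN positions (frames with no
        prey) evaluate to zero everywhere.
        """
        angle = np.atleast_1d(np.asarray(angle, dtype=float))
        radius = np.atleast_1d(np.asarray(radius_units, dtype=float))
        cfg = self.config
        ang = np.exp(cfg.kappa
                     * (np.cos(angle[:, None] - self.angle_centers[None, :])
                        - 1.0))
        rad = np.exp(-((radius[:, None] - self.radial_centers[None, :]) ** 2)
                     / (2.0 * cfg.sigma ** 2))
        out = ang[:, :, None] * rad[:, None, :]
        return np.nan_to_num(out.reshape(angle.size, self.n_basis))


def build_spatial_basis(config: BasisConfig | None = None) -> SpatialBasis:
    """Construct the polar basis (default: 19 x 5 = 95 functions)."""
    return SpatialBasis(config or BasisConfig())


def project_trajectory(trajectory: PreyTrajectory, basis: SpatialBasis
                       ) -> np.ndarray:
    """Project the prey trajectory onto the basis -> (T, n_basis) series.

    The value of series ``j`` at frame ``t`` is basis ``j`` evaluated at the
    prey's (angle, radius) that frame: high when the prey is near that
    basis's preferred position, near zero otherwise. Radii outside the
    radial span are clipped with a warning; frames without prey give zeros.
    A warning is also raised if any angular bin is never the nearest bin
    (poor angular coverage degrades the map).
    """
    cfg = basis.config
    radius = np.asarray(trajectory.radius, dtype=float) * cfg.units_per_mm
    lo, hi = cfg.radial_span
    finite = np.isfinite(radius)
    if np.any((radius[finite] < lo) | (radius[finite] > hi)):
        warnings.warn("prey radius outside the radial span; clipping")
        radius = np.clip(radius, lo, hi)
    series = basis.evaluate(trajectory.angle, radius)
    ok = np.isfinite(trajectory.angle)
    if ok.any():
        diff = np.angle(np.exp(1j * (np.asarray(trajectory.angle)[ok, None]
                                     - basis.angle_centers[None, :])))
        visited = np.unique(np.argmin(np.abs(diff), axis=1))
        if visited.size < cfg.n_angle_bins:
            warnings.warn(
                f"only {visited.size}/{cfg.n_angle_bins} angular bins visited")
    return series


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Delay-embedded, column-centred stimulus matrix.

    Columns are ordered delay-major: block ``d`` holds every spatial basis
    at delay ``delays[d]``, so the weight vector reshapes to
    ``(n_delays, n_basis)``. ``feature_map`` lists
    ``(angle_center, radial_center, delay)`` per column when a basis is
    attached.
    """

    X: np.ndarray
    delays: tuple[int, ...]
    n_series: int
    feature_map: list[tuple[float, float, int]] | None = None

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def build_design_matrix(series: np.ndarray,
                        delays=DEFAULT_DELAYS,
                        basis: SpatialBasis | None = None) -> DesignMatrix:
    """Delay-embed basis time series into the model's stimulus matrix.

    A column at delay ``d`` is the series shifted so the feature at time
    ``t`` is the stimulus at ``t - d`` (positive delays let the response lag
    the stimulus, accommodating indicator kinetics); out-of-range samples
    are zero-padded. Every column is then mean-centred so no intercept is
    fitted downstream.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[0] == 1 and series.size > 1:
        series = series.T
    delays = tuple(int(d) for d in delays)
    if not delays:
        raise ParameterError("delays must be non-empty")
    T, B = series.shape
    if any(abs(d) >= T for d in delays):
        raise InvalidDelayError("delay magnitude must be below the length")
    blocks = []
    for d in delays:
        shifted = np.zeros_like(series)
        if d > 0:
            shifted[d:] = series[:-d]
        elif d < 0:
            shifted[:d] = series[-d:]
        else:
            shifted = series.copy()
        blocks.append(shifted)
    X = np.concatenate(blocks, axis=1)
    X -= X.mean(axis=0, keepdims=True)
    fmap = None
    if basis is not None:
        fmap = [(a, r, d) for d in delays for (a, r) in basis.centers()]
    return DesignMatrix(X, delays, B, fmap)


# ---------------------------------------------------------------------------
# ridge machinery
# ---------------------------------------------------------------------------

def ridge_fit(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """L2-regularized least squares: argmin ||y - Xw||^2 + lam ||w||^2.

    ``y`` may be a matrix (one column per pixel). ``lam = 0`` reduces to
    ordinary least squares on a well-conditioned system.
    """
    if lam < 0:
        raise ParameterError("regularization must be non-negative")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    A = X.T @ X + lam * np.eye(p)
    return np.linalg.solve(A, X.T @ y)


def _ridge_path(XtX_eig, XtY, alphas):
    """Ridge weights for many alphas from one eigendecomposition.

    ``XtX_eig`` is ``(eigenvalues, eigenvectors)`` of the feature Gram
    matrix; returns an array (n_alphas, p, n_targets).
    """
    evals, evecs = XtX_eig
    proj = evecs.T @ XtY  # (p, n_targets)
    out = np.empty((len(alphas), proj.shape[0], proj.shape[1]))
    for i, a in enumerate(alphas):
        out[i] = evecs @ (proj / (evals + a)[:, None])
    return out


def _segment_bounds(T: int, n_segments: int) -> list[tuple[int, int]]:
    """Sequential segments of T // n frames; remainder goes to the last."""
    size = T // n_segments
    if size < 1:
        raise ParameterError("more segments than frames")
    bounds = [(i * size, (i + 1) * size) for i in range(n_segments)]
    bounds[-1] = (bounds[-1][0], T)
    return bounds


def _sample_blocks(rng, m: int, n_blocks: int, block_len: int) -> np.ndarray:
    """Indices of ``n_blocks`` blocks of ``block_len`` consecutive positions
    within ``range(m)``, disjoint where possible."""
    if m < block_len:
        raise ParameterError("estimation set shorter than one block")
    chosen: list[int] = []
    starts = rng.permutation(m - block_len + 1)
    for s in starts:
        if all(abs(s - c) >= block_len for c in chosen):
            chosen.append(int(s))
            if len(chosen) == n_blocks:
                break
    while len(chosen) < n_blocks:  # overlap unavoidable for dense requests
        chosen.append(int(rng.integers(0, m - block_len + 1)))
    idx = np.concatenate([np.arange(s, s + block_len) for s in chosen])
    return np.unique(idx)


def _pearson_cols(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of two (n, k) matrices."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a * a).sum(axis=0) * (b * b).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / denom
    return np.where(denom > 0, r, 0.0)


@dataclass
class EncodingModelResult:
    """Per-pixel encoding-model fit.

    ``weights`` are averaged over the outer folds, shape
    (n_pixels, n_delays, n_basis). ``cv_correlation`` is the Pearson r
    between each pixel's concatenated held-out predictions and its data.
    ``preferred_angle`` (radians) is reported only for FDR-significant
    pixels (NaN elsewhere).
    """

    weights: np.ndarray
    cv_correlation: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    preferred_angle: np.ndarray
    fold_alphas: np.ndarray  # (n_pixels, n_outer)
    delays: tuple[int, ...]
    basis: SpatialBasis | None = None
    seed: int | None = None

    @property
    def n_pixels(self) -> int:
        return self.weights.shape[0]

    def receptive_fields(self) -> np.ndarray:
        """Spatial receptive fields (n_pixels, n_angle, n_radial): fold-
        averaged weights averaged across delays."""
        if self.basis is None:
            raise ParameterError("basis required for receptive fields")
        cfg = self.basis.config
        rf = self.weights.mean(axis=1)
        return rf.reshape(self.n_pixels, cfg.n_angle_bins, cfg.n_radial_bins)


def nested_cv_fit(design: DesignMatrix, Y: np.ndarray,
                  n_outer: int = 10,
                  alphas=None,
                  n_inner_reps: int = 50,
                  n_blocks: int = 10,
                  block_len: int = 40,
                  seed: int = 0,
                  basis: SpatialBasis | None = None,
                  fdr_q: float = 0.05) -> EncodingModelResult:
    """Fit the encoding model with nested cross-validation.

    Outer layer: ``n_outer`` sequential temporal segments; each in turn is
    held out while the rest form the estimation set (pixel traces are
    mean-centred on the estimation set; the stimulus matrix is globally
    column-centred, so no intercept is fitted). Inner layer, per fold: for
    each candidate ridge parameter (default 20 values log-spaced on
    [1, 1000]), ``n_inner_reps`` times remove ``n_blocks`` random blocks of
    ``block_len`` consecutive time points, fit on the rest and score
    prediction of the removed points; the alpha with the best mean held-out
    correlation wins (per pixel). Weights are refit on the full estimation
    set, the held-out segment is predicted, predictions are concatenated
    across folds and correlated with the data, and fold weights are
    averaged.
    """
    if alphas is None:
        alphas = np.logspace(0, 3, 20)
    alphas = np.asarray(alphas, dtype=float)
    X = design.X
    Y = np.asarray(Y, dtype=float)
    single = Y.ndim == 1
    if single:
        Y = Y[:, None]
    T, P = Y.shape
    if X.shape[0] != T:
        raise ParameterError("design and responses must have equal length")
    bounds = _segment_bounds(T, n_outer)
    est_sizes = [T - (e - s) for s, e in bounds]
    if min(est_sizes) <= n_blocks * block_len:
        raise ParameterError(
            "holdout blocks would exhaust the estimation set")
    rng = np.random.default_rng(seed)
    p = X.shape[1]

    predictions = np.empty((T, P))
    weight_sum = np.zeros((P, p))
    fold_alphas = np.empty((P, n_outer))

    for f, (s, e) in enumerate(bounds):
        val_idx = np.arange(s, e)
        est_idx = np.concatenate([np.arange(0, s), np.arange(e, T)])
        Xe, Ye = X[est_idx], Y[est_idx]
        mu = Ye.mean(axis=0)
        Yc = Ye - mu
        m = est_idx.size

        scores = np.zeros((alphas.size, P))
        for _ in range(n_inner_reps):
            hold = _sample_blocks(rng, m, n_blocks, block_len)
            train = np.setdiff1d(np.arange(m), hold, assume_unique=True)
            Xt, Yt = Xe[train], Yc[train]
            gram = Xt.T @ Xt
            evals, evecs = np.linalg.eigh(gram)
            W = _ridge_path((evals, evecs), Xt.T @ Yt, alphas)
            Xh = Xe[hold]
            for i in range(alphas.size):
                scores[i] += _pearson_cols(Xh @ W[i], Yc[hold])
        scores /= n_inner_reps
        best = np.argmax(scores, axis=0)  # per pixel
        fold_alphas[:, f] = alphas[best]

        gram = Xe.T @ Xe
        evals, evecs = np.linalg.eigh(gram)
        XtY = Xe.T @ Yc
        proj = evecs.T @ XtY
        W_fold = np.empty((p, P))
        for i in np.unique(best):
            cols = best == i
            W_fold[:, cols] = evecs @ (proj[:, cols]
                                       / (evals + alphas[i])[:, None])
        # predictions stay in the centred space: re-adding the fold's mean
        # would imprint fold-level offsets that bias null correlations
        predictions[val_idx] = X[val_idx] @ W_fold
        weight_sum += W_fold.T

    weights = (weight_sum / n_outer).reshape(P, len(design.delays),
                                             design.n_series)
    cv_corr = _pearson_cols(predictions, Y)
    p_values = np.array([correlation_significance(r, T) for r in cv_corr])
    significant = benjamini_hochberg(p_values, q=fdr_q)

    preferred = np.full(P, np.nan)
    if basis is not None:
        for j in range(P):
            if significant[j]:
                preferred[j] = summarize_receptive_field(
                    weights[j], basis).preferred_angle

    return EncodingModelResult(
        weights=weights, cv_correlation=cv_corr, p_values=p_values,
        significant=significant, preferred_angle=preferred,
        fold_alphas=fold_alphas, delays=design.delays, basis=basis,
        seed=seed)


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def correlation_significance(r: float, T: int) -> float:
    """Two-sided p-value of a sample correlation under the null of two
    independent Gaussian series of length ``T`` (t-transform with T − 2
    degrees of freedom)."""
    if not np.isfinite(r) or abs(r) > 1:
        raise ParameterError("correlation must lie in [-1, 1]")
    if T <= 3:
        raise InsufficientSamplesError("need more than 3 samples")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((T - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=T - 2))


def fdr_select(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg selection across pixels (within fish)."""
    return benjamini_hochberg(p_values, q=q)


# ---------------------------------------------------------------------------
# receptive-field summaries and retinotopy
# ---------------------------------------------------------------------------

@dataclass
class ReceptiveFieldSummary:
    receptive_field: np.ndarray  # (n_angle, n_radial)
    preferred_angle: float       # radians; NaN if undefined
    tie: bool
    undefined: bool


def summarize_receptive_field(weights: np.ndarray, basis: SpatialBasis
                              ) -> ReceptiveFieldSummary:
    """Collapse a (n_delays, n_basis) weight grid into a spatial receptive
    field (mean across delays) and a preferred angle (angular centre
    maximizing the mean across radii and delays).

    An exact tie between angular bins is broken to the lower index and
    flagged; an all-zero grid has no defined preference.
    """
    cfg = basis.config
    w = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ParameterError("weights must be finite")
    rf = w.mean(axis=0).reshape(cfg.n_angle_bins, cfg.n_radial_bins)
    if np.allclose(rf, 0.0):
        return ReceptiveFieldSummary(rf, np.nan, False, True)
    marginal = rf.mean(axis=1)
    best = int(np.argmax(marginal))
    tie = bool(np.count_nonzero(np.isclose(marginal, marginal[best])) > 1)
    return ReceptiveFieldSummary(rf, float(basis.angle_centers[best]),
                                 tie, False)


@dataclass
class RetinotopicProfile:
    axis_positions: np.ndarray   # normalized [0, 1] bin centres
    mean_angles: np.ndarray      # circular mean per bin, radians (NaN = empty)
    axis_vector: np.ndarray      # unit vector in (row, col) coordinates
    isotropic: bool


def retinotopic_gradient(preferred_angle_map: np.ndarray,
                         roi_mask: np.ndarray,
                         n_bins: int = 10) -> RetinotopicProfile:
    """Preferred angle along an ROI's principal anatomical axis.

    The ROI's principal axis comes from the second spatial moments of the
    mask; significant pixels (non-NaN entries of the preferred-angle map)
    are projected onto it, their positions normalized to [0, 1], and the
    circular mean of preferred angle is taken per position bin. A (near)
    isotropic mask has no well-defined axis: the tie is broken to the image
    row axis and flagged.
    """
    angle_map = np.asarray(preferred_angle_map, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if angle_map.shape != mask.shape:
        raise ParameterError("map and mask shapes differ")
    sig = mask & np.isfinite(angle_map)
    if np.count_nonzero(sig) < 10:
        raise InsufficientDataError("need >= 10 significant pixels in ROI")

    coords = np.column_stack(np.nonzero(mask)).astype(float)
    centroid = coords.mean(axis=0)
    coords -= centroid
    cov = coords.T @ coords / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    isotropic = bool(np.isclose(evals[0], evals[1], rtol=1e-6))
    axis = np.array([1.0, 0.0]) if isotropic else evecs[:, -1]

    pix = np.column_stack(np.nonzero(sig)).astype(float)
    proj = (pix - centroid) @ axis
    lo, hi = proj.min(), proj.max()
    span = hi - lo if hi > lo else 1.0
    pos = (proj - lo) / span
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(pos, edges) - 1, 0, n_bins - 1)
    angles = angle_map[sig]
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            means[b] = sps.circmean(angles[sel], high=np.pi, low=-np.pi)
    centres = (edges[:-1] + edges[1:]) / 2.0
    return RetinotopicProfile(centres, means, axis, isotropic)
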