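"""Preprocessing of wide-field calcium fluorescence movies.

Raw (rigid-registered) single-plane movies are turned into analysis-ready
pixel grids and region-of-interest (ROI) traces in three steps, applied in
this order:

1. photobleaching correction — a single or double exponential is fitted to
   the outlier-cleaned ROI mean trace and the decaying part is subtracted
   from every pixel inside the ROI;
2. z-scoring — every trace is expressed in standard deviations away from
   its own mean (``Fz`` units);
3. motion cleaning — frames whose upstream rigid-registration displacement
   exceeds a threshold (default two pixels) are replaced by linear
   interpolation between the nearest valid frames.

Image registration itself is out of scope: the per-frame displacement
magnitude produced by the upstream registration is an input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import (
    DegenerateInputError,
    MissingRegionError,
    ParameterError,
    ShapeError,
)

#: Canonical brain regions imaged in the hunting plane.
CANONICAL_REGIONS = (
    "telencephalon",
    "habenula",
    "pretectum",
    "tectal_neuropil",
    "tectal_pvn",
    "cerebellum",
    "hindbrain",
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FluorescenceMovie:
    """A registered single-plane fluorescence movie.

    Parameters
    ----------
    data
        ``(frames, rows, cols)`` array of fluorescence, arbitrary units.
    frame_rate
        Acquisition rate in Hz (wide-field hunting recordings run at 3.6 Hz).
    displacement
        Per-frame rigid-shift magnitude in pixels, produced by the upstream
        registration step. Defaults to all zeros.
    """

    data: np.ndarray
    frame_rate: float = 3.6
    displacement: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ShapeError("movie data must be (frames, rows, cols)")
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be positive")
        if self.displacement is None:
            self.displacement = np.zeros(self.n_frames)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.shape != (self.n_frames,):
            raise ShapeError("displacement must have one value per frame")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def pixel_traces(self) -> np.ndarray:
        """Return the movie as a ``(frames, n_pixels)`` matrix (row-major)."""
        return self.data.reshape(self.n_frames, -1)

    # -- I/O ---------------------------------------------------------------
    def to_hdf5(self, path, dataset="movie") -> None:
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset(dataset, data=self.data.astype(np.float32))
            ds.attrs["frame_rate"] = self.frame_rate
            f.create_dataset("displacement", data=self.displacement)

    @classmethod
    def from_hdf5(cls, path, dataset="movie") -> "FluorescenceMovie":
        import h5py

        with h5py.File(path, "r") as f:
            data = f[dataset][...]
            rate = float(f[dataset].attrs.get("frame_rate", 3.6))
            disp = f["displacement"][...] if "displacement" in f else None
        return cls(data, frame_rate=rate, displacement=disp)

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.data.astype(np.float32))

    @classmethod
    def from_tiff(cls, path, frame_rate=3.6, displacement=None) -> "FluorescenceMovie":
        import tifffile

        return cls(tifffile.imread(path), frame_rate=frame_rate,
                   displacement=displacement)


@dataclass
class RegionTraces:
    """ROI-averaged traces, one row per region, in ``Fz`` (z-score) units.

    ``condition`` distinguishes the spontaneous (no prey) epoch from the
    evoked (prey present) epoch when traces have been sliced to one epoch.
    """

    regions: list[str]
    traces: np.ndarray
    frame_rate: float = 3.6
    condition: str | None = None

    def __post_init__(self):
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if len(self.regions) != self.traces.shape[0]:
            raise ShapeError("one label per trace row required")

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    def get(self, region: str) -> np.ndarray:
        try:
            return self.traces[self.regions.index(region)]
        except ValueError as exc:
            raise MissingRegionError(region) from exc

    def to_frame(self) -> pd.DataFrame:
        """Long-format ``(frame, region, Fz)`` table."""
        frames = np.tile(np.arange(self.n_frames), len(self.regions))
        regions = np.repeat(self.regions, self.n_frames)
        return pd.DataFrame(
            {"frame": frames, "region": regions, "Fz": self.traces.ravel()}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path, frame_rate=3.6, condition=None) -> "RegionTraces":
        df = pd.read_csv(path)
        regions = list(dict.fromkeys(df["region"]))
        traces = np.stack(
            [df.loc[df["region"] == r].sort_values("frame")["Fz"].to_numpy()
             for r in regions]
        )
        return cls(regions, traces, frame_rate=frame_rate, condition=condition)


@dataclass
class BleachModel:
    """Fitted photobleaching trend.

    ``kind`` is ``"single"``, ``"double"`` or ``"constant"`` (fallback when
    neither exponential converges). ``params`` holds amplitudes ``a*``,
    time constants ``tau*`` (frames) and the offset ``c``. ``goodness_of_fit``
    is the small-sample-corrected Akaike information criterion (lower is
    better), used to arbitrate between the single and double model.
    """

    kind: str
    params: dict
    goodness_of_fit: float

    def trend(self, t: np.ndarray) -> np.ndarray:
        """The decaying part of the fit (offset excluded); what gets
        subtracted during bleach correction."""
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.kind == "single":
            return p["a"] * np.exp(-t / p["tau"])
        if self.kind == "double":
            return p["a1"] * np.exp(-t / p["tau1"]) + p["a2"] * np.exp(-t / p["tau2"])
        return np.zeros_like(t)

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.trend(t) + self.params.get("c", 0.0)


# ---------------------------------------------------------------------------
# bleaching
# ---------------------------------------------------------------------------

def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    else:
        aic = np.inf
    return aic


def _moving_median(x: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def exclude_outliers(trace: np.ndarray, window: int = 31, n_mad: float = 3.0):
    """Flag samples further than ``n_mad`` scaled median absolute deviations
    from a centred moving median. Returns a boolean keep-mask."""
    trace = np.asarray(trace, dtype=float)
    resid = trace - _moving_median(trace, window)
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad == 0:
        return np.ones(trace.size, dtype=bool)
    return np.abs(resid) <= n_mad * 1.4826 * mad


def _single_exp(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def _double_exp(t, a1, tau1, a2, tau2, c):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def fit_bleach_model(roi_mean_trace: np.ndarray) -> BleachModel:
    """Fit a photobleaching trend to an ROI mean fluorescence trace.

    Both a single and a double exponential (plus offset) are fitted by
    nonlinear least squares to the outlier-cleaned trace; the model with the
    better (lower) corrected Akaike criterion wins. If neither converges the
    trace is assumed bleach-free and a zero-amplitude constant model is
    returned with a warning.

    Outliers (motion/activity artifacts) are flagged against a preliminary
    single-exponential fit: samples whose residual is more than 3 scaled
    median absolute deviations from the residual median are excluded before
    the final fits. A moving-median criterion is the fallback when the
    preliminary fit fails.
    """
    trace = np.asarray(roi_mean_trace, dtype=float)
    if trace.size < 20:
        raise DegenerateInputError("need at least 20 samples to fit bleaching")
    t_all = np.arange(trace.size, dtype=float)
    try:
        p0 = [trace[0] - trace[-1], trace.size / 3.0, trace[-1]]
        prelim, _ = curve_fit(
            _single_exp, t_all, trace, p0=p0,
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        resid = trace - _single_exp(t_all, *prelim)
        med = np.median(resid)
        mad = np.median(np.abs(resid - med))
        keep = (np.ones(trace.size, dtype=bool) if mad == 0
                else np.abs(resid - med) <= 3.0 * 1.4826 * mad)
    except (RuntimeError, ValueError):
        keep = exclude_outliers(trace)
    t = np.arange(trace.size, dtype=float)[keep]
    y = trace[keep]
    n = y.size
    span = y.max() - y.min()

    candidates = []
    try:
        p0 = [y[0] - y[-1], n / 3.0, y[-1]]
        popt, _ = curve_fit(
            _single_exp, t, y, p0=p0,
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        rss = float(np.sum((y - _single_exp(t, *popt)) ** 2))
        candidates.append(BleachModel(
            "single", {"a": popt[0], "tau": popt[1], "c": popt[2]},
            _aicc(rss, n, 3)))
    except (RuntimeError, ValueError):
        pass
    try:
        p0 = [span / 2 or 1.0, n / 10.0, span / 2 or 1.0, n / 2.0, y[-1]]
        popt, _ = curve_fit(
            _double_exp, t, y, p0=p0,
            bounds=([-np.inf, 1e-6, -np.inf, 1e-6, -np.inf],
                    [np.inf, np.inf, np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        rss = float(np.sum((y - _double_exp(t, *popt)) ** 2))
        candidates.append(BleachModel(
            "double",
            {"a1": popt[0], "tau1": popt[1], "a2": popt[2], "tau2": popt[3],
             "c": popt[4]},
            _aicc(rss, n, 5)))
    except (RuntimeError, ValueError):
        pass

    if not candidates:
        warnings.warn("bleach fit did not converge; using constant model")
        rss = float(np.sum((y - y.mean()) ** 2))
        return BleachModel("constant", {"c": float(y.mean())}, _aicc(rss, n, 1))
    return min(candidates, key=lambda m: m.goodness_of_fit)


def correct_bleaching(movie: FluorescenceMovie, roi_mask: np.ndarray,
                      model: BleachModel) -> FluorescenceMovie:
    """Subtract the fitted bleaching trend from every pixel inside the ROI.

    Only the decaying component is removed; the fitted offset stays, so a
    zero-amplitude model is the identity. Pixels outside the mask are
    untouched.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != movie.data.shape[1:]:
        raise ShapeError("mask shape does not match movie frame shape")
    trend = model.trend(np.arange(movie.n_frames)).astype(np.float32)
    out = movie.data.copy()
    out[:, roi_mask] = out[:, roi_mask] - trend[:, None]
    return FluorescenceMovie(out, frame_rate=movie.frame_rate,
                             displacement=movie.displacement.copy())


# ---------------------------------------------------------------------------
# z-scoring and motion cleaning
# ---------------------------------------------------------------------------

def zscore_trace(trace: np.ndarray) -> np.ndarray:
    """Z-score a trace: subtract the mean of the whole signal and divide by
    its (population) standard deviation. Output is in ``Fz`` units."""
    trace = np.asarray(trace, dtype=float)
    sd = trace.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("cannot z-score a constant trace")
    return (trace - trace.mean()) / sd


def interpolate_motion_frames(trace: np.ndarray, displacement: np.ndarray,
                              threshold: float = 2.0) -> np.ndarray:
    """Replace frames with displacement above ``threshold`` pixels by linear
    interpolation between the nearest flanking valid frames. Leading and
    trailing invalid frames take the nearest valid value."""
    trace = np.asarray(trace, dtype=float)
    displacement = np.asarray(displacement, dtype=float)
    if trace.shape != displacement.shape:
        raise ShapeError("trace and displacement must have equal length")
    valid = displacement <= threshold
    if not valid.any():
        raise DegenerateInputError("every frame exceeds the motion threshold")
    if valid.all():
        return trace.copy()
    idx = np.arange(trace.size)
    out = trace.copy()
    out[~valid] = np.interp(idx[~valid], idx[valid], trace[valid])
    return out


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def _merge_sides(name: str) -> tuple[str, str | None]:
    for suffix in ("_left", "_right"):
        if name.endswith(suffix):
            return name[: -len(suffix)], suffix[1:]
    return name, None


def extract_roi_traces(movie: FluorescenceMovie, label_mask: np.ndarray,
                       label_names: dict[int, str],
                       side_averaging: bool = False) -> RegionTraces:
    """Average pixels per labelled region into one trace per region.

    ``label_mask`` is an integer image (0 = background); ``label_names`` maps
    label values to region names, using ``_left``/``_right`` suffixes for
    lateralised regions. With ``side_averaging`` the two sides of a region
    are averaged into a single trace (used where left/right signals are
    symmetric around the events of interest).
    """
    label_mask = np.asarray(label_mask)
    if label_mask.shape != movie.data.shape[1:]:
        raise ShapeError("label mask shape does not match movie frame shape")
    flat = movie.pixel_traces()
    flat_labels = label_mask.ravel()
    names, traces = [], []
    for value, name in label_names.items():
        sel = flat_labels == value
        if not sel.any():
            raise MissingRegionError(f"label {value} ({name}) covers no pixels")
        names.append(name)
        traces.append(flat[:, sel].mean(axis=1))
    traces = np.stack(traces)

    if side_averaging:
        merged: dict[str, list[int]] = {}
        for i, name in enumerate(names):
            base, _ = _merge_sides(name)
            merged.setdefault(base, []).append(i)
        names = list(merged)
        traces = np.stack([traces[rows].mean(axis=0) for rows in merged.values()])
    return RegionTraces(names, traces, frame_rate=movie.frame_rate)


def preprocess_movie(movie: FluorescenceMovie, label_mask: np.ndarray,
                     label_names: dict[int, str], side_averaging: bool = False,
                     motion_threshold: float = 2.0) -> tuple[FluorescenceMovie, RegionTraces]:
    """Run the full preprocessing chain.

    Bleach-corrects each labelled ROI (trend fitted on its own mean trace),
    z-scores every labelled pixel, extracts ROI traces, then interpolates
    motion-contaminated frames in the ROI traces. Returns the z-scored movie
    (``Fz`` per pixel; unlabelled pixels zeroed) and the cleaned traces.
    """
    label_mask = np.asarray(label_mask)
    corrected = movie
    for value in label_names:
        roi = label_mask == value
        model = fit_bleach_model(movie.data[:, roi].mean(axis=1))
        corrected = correct_bleaching(corrected, roi, model)

    flat = corrected.pixel_traces().astype(float)
    labelled = np.isin(label_mask.ravel(), list(label_names))
    z = np.zeros_like(flat)
    sub = flat[:, labelled]
    sd = sub.std(axis=0)
    sd[sd == 0] = 1.0
    z[:, labelled] = (sub - sub.mean(axis=0)) / sd
    zmovie = FluorescenceMovie(z.reshape(movie.shape), frame_rate=movie.frame_rate,
                               displacement=movie.displacement.copy())

    traces = extract_roi_traces(zmovie, label_mask, label_names,
                                side_averaging=side_averaging)
    cleaned = np.stack([
        interpolate_motion_frames(tr, movie.displacement, motion_threshold)
        for tr in traces.traces
    ])
    return zmovie, RegionTraces(traces.regions, cleaned,
                                frame_rate=movie.frame_rate)
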