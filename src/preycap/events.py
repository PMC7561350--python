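"""Detection and classification of behavioral and neural events.

Covers eye-angle extraction from binary eye blobs, convergence detection
(vergence crossing 30 degrees with both eyes rotating nasally), tail-flick
detection from side intensity traces, pretectal-transient detection from
z-scored traces, transient classification against the convergence train,
and event-triggered summaries of region activity.

Conventions: eye angles are nasal-rotation-positive so vergence is the sum
of the two eyes' angles. The recording is semi-automatic in spirit: an
explicit refractory gap between events (default 5 frames, ~1.4 s at 3.6 Hz)
replaces the manual curation a human scorer would apply.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateInputError,
    InvalidEpochError,
    NoValidEventError,
    ParameterError,
    ShapeError,
    UndefinedProbabilityError,
)
from .preprocess import RegionTraces

CONVERGENCE_THRESHOLD_DEG = 30.0
DEFAULT_REFRACTORY = 5  # frames (~1.4 s at 3.6 Hz)


@dataclass
class EyeTrace:
    """Per-frame eye angles in degrees, nasal rotation positive."""

    left_angle: np.ndarray
    right_angle: np.ndarray

    def __post_init__(self):
        self.left_angle = np.asarray(self.left_angle, dtype=float)
        self.right_angle = np.asarray(self.right_angle, dtype=float)
        if self.left_angle.shape != self.right_angle.shape:
            raise ShapeError("eye traces must have equal length")

    @property
    def vergence(self) -> np.ndarray:
        """Vergence angle = nasalward sum of the two eyes, degrees."""
        return self.left_angle + self.right_angle

    def __len__(self) -> int:
        return self.left_angle.size


@dataclass
class EventTrain:
    """Detected events of one kind within a recording.

    ``side`` entries are ``left``/``right`` (dominant/contralateral side),
    ``none``, or ``tie:left`` when a bilateral tie was broken
    deterministically. ``classification`` entries are ``with_behavior``,
    ``without_behavior`` or ``unclassified``.
    """

    kind: str
    peak_frames: np.ndarray
    amplitudes: np.ndarray
    n_frames: int
    sides: list[str] = field(default_factory=list)
    classifications: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.peak_frames = np.asarray(self.peak_frames, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if not self.sides:
            self.sides = ["none"] * self.peak_frames.size
        if not self.classifications:
            self.classifications = ["unclassified"] * self.peak_frames.size
        if np.any(self.peak_frames < 0) or np.any(self.peak_frames >= self.n_frames):
            raise ParameterError("event frames must lie within the recording")

    def __len__(self) -> int:
        return self.peak_frames.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "kind": self.kind,
            "peak_frame": self.peak_frames,
            "amplitude": self.amplitudes,
            "side": self.sides,
            "classification": self.classifications,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# eye angle from a binary blob
# ---------------------------------------------------------------------------

def eye_angle_from_mask(binary_eye_blob: np.ndarray) -> float:
    """Orientation of an eye blob's best-fit ellipse major axis, degrees.

    Computed from second central moments of the pixel coordinates; the
    returned angle is relative to the image row axis (the fish midline by
    convention), in (−90, 90], positive toward increasing column index.
    A rotationally symmetric blob has no defined major axis; the tie is
    broken by reporting 0.
    """
    blob = np.asarray(binary_eye_blob).astype(bool)
    rr, cc = np.nonzero(blob)
    if rr.size < 5:
        raise DegenerateInputError("eye blob must contain at least 5 pixels")
    r = rr - rr.mean()
    c = cc - cc.mean()
    mu_rr = np.mean(r * r)
    mu_cc = np.mean(c * c)
    mu_rc = np.mean(r * c)
    if np.isclose(mu_rr, mu_cc) and np.isclose(mu_rc, 0.0):
        return 0.0  # symmetric blob: tie-break
    theta = 0.5 * np.arctan2(2.0 * mu_rc, mu_rr - mu_cc)
    deg = np.degrees(theta)
    if deg <= -90.0:
        deg += 180.0
    elif deg > 90.0:
        deg -= 180.0
    return float(deg)


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def _enforce_refractory(frames: np.ndarray, amplitudes: np.ndarray,
                        refractory: int) -> np.ndarray:
    """Keep events separated by at least ``refractory`` frames (first wins)."""
    keep = []
    last = -np.inf
    for i in np.argsort(frames, kind="stable"):
        if frames[i] - last >= refractory:
            keep.append(i)
            last = frames[i]
    return np.sort(np.asarray(keep, dtype=int))


def detect_convergences(eyes: EyeTrace,
                        threshold: float = CONVERGENCE_THRESHOLD_DEG,
                        refractory: int = DEFAULT_REFRACTORY,
                        velocity_window: int = 3) -> EventTrain:
    """Detect eye-convergence (hunting-initiation) events.

    An event is an upward crossing of the vergence threshold (default 30
    degrees) at which both eyes have been rotating nasally on average over
    the preceding ``velocity_window`` frames. The event frame is the
    crossing frame; a refractory gap suppresses re-triggering.
    """
    v = eyes.vergence
    if not np.all(np.isfinite(v)):
        raise DegenerateInputError("eye traces must be finite")
    up = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold)) + 1
    frames, amps = [], []
    for t in up:
        lo = max(t - velocity_window, 0)
        if (np.mean(np.diff(eyes.left_angle[lo:t + 1])) > 0
                and np.mean(np.diff(eyes.right_angle[lo:t + 1])) > 0):
            frames.append(t)
            amps.append(v[t])
    frames = np.asarray(frames, dtype=int)
    amps = np.asarray(amps, dtype=float)
    keep = _enforce_refractory(frames, amps, refractory)
    return EventTrain("convergence", frames[keep], amps[keep], len(eyes))


def detect_tail_flicks(side_left: np.ndarray, side_right: np.ndarray,
                       baseline_window: int = 20, threshold_sd: float = 2.0,
                       refractory: int = DEFAULT_REFRACTORY) -> EventTrain:
    """Detect tail flicks from left/right tail-side intensity traces.

    Each trace is baseline-corrected by subtracting a centred rolling
    average (default 20 frames); an event starts wherever either corrected
    trace upcrosses its own mean + ``threshold_sd`` standard deviations.
    """
    side_left = np.asarray(side_left, dtype=float)
    side_right = np.asarray(side_right, dtype=float)
    if side_left.shape != side_right.shape:
        raise ShapeError("tail traces must have equal length")
    if side_left.size <= baseline_window:
        raise DegenerateInputError("trace shorter than the baseline window")

    frames, amps, sides = [], [], []
    excursions = {}
    for name, trace in (("left", side_left), ("right", side_right)):
        base = pd.Series(trace).rolling(
            baseline_window, center=True, min_periods=1).mean().to_numpy()
        corr = trace - base
        thr = corr.mean() + threshold_sd * corr.std()
        above = corr > thr
        onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        if above[0]:
            onsets = np.concatenate([[0], onsets])
        excursions[name] = (onsets, corr)
    for name, (onsets, corr) in excursions.items():
        for t in onsets:
            frames.append(t)
            amps.append(corr[t])
            sides.append(name)
    frames = np.asarray(frames, dtype=int)
    amps = np.asarray(amps, dtype=float)
    keep = _enforce_refractory(frames, amps, refractory)
    return EventTrain("tail_flick", frames[keep], amps[keep], side_left.size,
                      sides=[sides[i] for i in keep])


def detect_pretectal_transients(pretectal_left: np.ndarray,
                                pretectal_right: np.ndarray,
                                threshold_sd: float = 2.0,
                                refractory: int = DEFAULT_REFRACTORY
                                ) -> EventTrain:
    """Detect pretectal calcium transients from the z-scored left/right pair.

    Each trace is thresholded at ``threshold_sd`` standard deviations above
    its own mean; supra-threshold excursions of the element-wise maximum of
    the two traces are events. Each event's peak is the maximum within its
    excursion, and its side (the putative contralateral pretectum) is
    whichever trace is larger at the peak. An exact bilateral tie is broken
    to the left and flagged ``tie:left``.
    """
    left = np.asarray(pretectal_left, dtype=float)
    right = np.asarray(pretectal_right, dtype=float)
    if left.shape != right.shape:
        raise ShapeError("pretectal traces must have equal length")
    thr_l = left.mean() + threshold_sd * left.std()
    thr_r = right.mean() + threshold_sd * right.std()
    combined = np.maximum(left, right)
    above = (left > thr_l) | (right > thr_r)
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])

    frames, amps, sides = [], [], []
    for s, e in zip(starts, ends):
        peak = s + int(np.argmax(combined[s:e]))
        frames.append(peak)
        amps.append(combined[peak])
        if left[peak] > right[peak]:
            sides.append("left")
        elif right[peak] > left[peak]:
            sides.append("right")
        else:
            sides.append("tie:left")
    frames = np.asarray(frames, dtype=int)
    amps = np.asarray(amps, dtype=float)
    keep = _enforce_refractory(frames, amps, refractory)
    return EventTrain("pretectal_transient", frames[keep], amps[keep],
                      left.size, sides=[sides[i] for i in keep])


# ---------------------------------------------------------------------------
# classification and rates
# ---------------------------------------------------------------------------

def classify_transients(transients: EventTrain, convergences: EventTrain,
                        window: int = 5) -> EventTrain:
    """Label each pretectal transient by whether an eye convergence occurred
    within ``window`` frames (inclusive) of its peak: ``with_behavior``
    ('prey detected, capture initiated') vs ``without_behavior``."""
    labels = []
    conv = convergences.peak_frames
    for t in transients.peak_frames:
        hit = conv.size > 0 and np.any(np.abs(conv - t) <= window)
        labels.append("with_behavior" if hit else "without_behavior")
    return EventTrain(transients.kind, transients.peak_frames.copy(),
                      transients.amplitudes.copy(), transients.n_frames,
                      sides=list(transients.sides), classifications=labels)


def transition_probability(transients: EventTrain) -> float:
    """Fraction of pretectal transients followed by an eye convergence."""
    if len(transients) == 0:
        raise UndefinedProbabilityError("no transients to classify")
    labels = np.asarray(transients.classifications)
    return float(np.mean(labels == "with_behavior"))


def evoked_minus_spontaneous_rate(events: EventTrain,
                                  spontaneous_span: tuple[int, int],
                                  evoked_span: tuple[int, int],
                                  frame_rate: float = 3.6) -> float:
    """Evoked minus spontaneous event frequency, events per minute.

    Spans are half-open frame intervals ``[start, end)``; the spontaneous
    epoch is recorded before the prey is added.
    """
    rates = []
    for start, end in (spontaneous_span, evoked_span):
        if end <= start:
            raise InvalidEpochError("epoch must have positive length")
        n = np.count_nonzero((events.peak_frames >= start)
                             & (events.peak_frames < end))
        minutes = (end - start) / frame_rate / 60.0
        rates.append(n / minutes)
    return rates[1] - rates[0]


# ---------------------------------------------------------------------------
# event-triggered summaries
# ---------------------------------------------------------------------------

@dataclass
class EventTriggeredSummary:
    """Event-aligned activity summaries for a set of regions.

    ``mean_traces`` is regions x window (window spans ``-pre .. +post``
    inclusive); ``baseline`` / ``response`` hold the per-region means over
    the baseline and response windows with a permutation p-value for their
    difference; ``integrals`` is regions x events, the per-event summed
    activity over the integral window (used for forebrain contrasts);
    ``summed_map`` (if a movie was supplied) is the pixel-wise activity
    summed over the map window and averaged over events.
    """

    regions: list[str]
    window_offsets: np.ndarray
    mean_traces: np.ndarray
    baseline: np.ndarray
    response: np.ndarray
    p_values: np.ndarray
    integrals: np.ndarray
    n_events: int
    summed_map: np.ndarray | None = None


def event_triggered_summary(traces: RegionTraces, events: EventTrain,
                            pre: int = 5, post: int = 10,
                            baseline_window: tuple[int, int] = (-10, -5),
                            response_window: tuple[int, int] = (0, 5),
                            integral_window: tuple[int, int] = (-5, 5),
                            movie=None,
                            map_window: tuple[int, int] = (-5, 10),
                            n_perm: int = 2000, seed: int = 0
                            ) -> EventTriggeredSummary:
    """Average region activity around events and test baseline vs response.

    All windows are inclusive frame offsets relative to the event frame.
    Events whose widest window would leave the recording are dropped with a
    warning. The baseline-vs-response comparison per region is a two-sided
    difference-in-means permutation test on the per-event window means.
    """
    from .stats import permutation_test

    windows = [(-pre, post), baseline_window, response_window, integral_window]
    if movie is not None:
        windows.append(map_window)
    lo = min(w[0] for w in windows)
    hi = max(w[1] for w in windows)
    T = traces.n_frames
    valid = [t for t in events.peak_frames if t + lo >= 0 and t + hi < T]
    dropped = len(events) - len(valid)
    if dropped:
        warnings.warn(f"dropped {dropped} edge event(s)")
    if not valid:
        raise NoValidEventError("no event has a full window inside the recording")
    valid = np.asarray(valid)

    offsets = np.arange(-pre, post + 1)
    aligned = np.stack([traces.traces[:, t + offsets] for t in valid], axis=1)
    mean_traces = aligned.mean(axis=1)  # regions x window

    def _window_means(win):
        off = np.arange(win[0], win[1] + 1)
        return np.stack([traces.traces[:, t + off].mean(axis=1)
                         for t in valid], axis=1)  # regions x events

    base = _window_means(baseline_window)
    resp = _window_means(response_window)
    integ = np.stack([traces.traces[:, t + np.arange(integral_window[0],
                                                     integral_window[1] + 1)]
                      .sum(axis=1) for t in valid], axis=1)

    p_values = np.empty(len(traces.regions))
    for i in range(len(traces.regions)):
        if valid.size >= 2 and not np.allclose(base[i], resp[i]):
            p_values[i] = permutation_test(base[i], resp[i], n_perm=n_perm,
                                           seed=seed + i).p_value
        else:
            p_values[i] = 1.0

    summed_map = None
    if movie is not None:
        off = np.arange(map_window[0], map_window[1] + 1)
        summed_map = np.mean(
            [movie.data[t + off].sum(axis=0) for t in valid], axis=0)

    return EventTriggeredSummary(
        regions=list(traces.regions), window_offsets=offsets,
        mean_traces=mean_traces, baseline=base.mean(axis=1),
        response=resp.mean(axis=1), p_values=p_values, integrals=integ,
        n_events=int(valid.size), summed_map=summed_map)
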