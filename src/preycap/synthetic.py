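"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: a prey
item wandering in front of a stationary larva, pixels with polar receptive
fields convolved with GCaMP6f-like kinetics plus photobleaching and noise,
region traces drawn from a vector-autoregressive (VAR) process with known
directed coupling, and behavior sessions in which pretectal transients are
stochastically followed by eye-convergence events.

Conventions: angles are radians in (−π, π], 0 = straight ahead, positive =
the fish's left; radii are millimetres; frames are 0-based at a default
acquisition rate of 3.6 Hz.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CapacityError, InstabilityError, ParameterError
from .preprocess import FluorescenceMovie, RegionTraces

DEFAULT_FRAME_RATE = 3.6  # Hz
#: Radial coordinate scaling: basis-space units per millimetre. The analysis
#: basis uses a Gaussian radial width of 40 of these units over a 0–5 mm span.
UNITS_PER_MM = 40.0
#: VAR burn-in discarded before returning samples.
VAR_BURN_IN = 500


# ---------------------------------------------------------------------------
# prey trajectory
# ---------------------------------------------------------------------------

@dataclass
class PreyTrajectory:
    """Per-frame prey position in polar coordinates relative to the fish.

    ``angle`` is in (−π, π] (0 straight ahead, positive left), ``radius`` in
    millimetres. Frames where no prey is present are NaN in both fields.
    """

    frame_index: np.ndarray
    angle: np.ndarray
    radius: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.angle = np.asarray(self.angle, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if not (self.frame_index.size == self.angle.size == self.radius.size):
            raise ParameterError("trajectory fields must have equal length")

    def __len__(self) -> int:
        return self.frame_index.size

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "frame": self.frame_index,
            "angle_rad": self.angle,
            "radius_mm": self.radius,
        }).to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path, frame_rate=DEFAULT_FRAME_RATE) -> "PreyTrajectory":
        df = pd.read_csv(path)
        return cls(df["frame"].to_numpy(), df["angle_rad"].to_numpy(),
                   df["radius_mm"].to_numpy(), frame_rate=frame_rate)


def simulate_prey_trajectory(duration_frames: int,
                             frame_rate: float = DEFAULT_FRAME_RATE,
                             arena_radius: float = 5.0,
                             step_sd: float = 0.25,
                             seed: int = 0,
                             start: tuple[float, float] | None = None
                             ) -> PreyTrajectory:
    """Simulate a prey item as a reflecting Gaussian random walk.

    The walk lives in Cartesian coordinates centred on the fish and is
    reflected at the arena boundary (radius ``arena_radius`` mm), then
    converted to polar coordinates. A live paramecium's kinematics are not
    modelled; any trajectory with good angular coverage serves the encoding
    analysis, and :func:`angular_coverage` reports the coverage achieved.

    ``step_sd`` is the per-frame Cartesian step standard deviation in mm
    (0 yields a parked prey). Reproducible for a fixed ``seed``.
    """
    if duration_frames < 1:
        raise ParameterError("duration_frames must be >= 1")
    if arena_radius <= 0:
        raise ParameterError("arena_radius must be positive")
    if step_sd < 0:
        raise ParameterError("step_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if start is None:
        start = (arena_radius / 2.0, 0.0)
    pos = np.empty((duration_frames, 2))
    pos[0] = start
    steps = rng.normal(0.0, step_sd, size=(duration_frames - 1, 2))
    for t in range(1, duration_frames):
        p = pos[t - 1] + steps[t - 1]
        r = np.hypot(*p)
        if r > arena_radius:
            # fold the radius back inside, keeping the direction
            p = p * (2 * arena_radius - r) / r
        pos[t] = p
    x, y = pos[:, 0], pos[:, 1]
    angle = np.arctan2(y, x)  # +y is the fish's left
    radius = np.hypot(x, y)
    return PreyTrajectory(np.arange(duration_frames), angle, radius,
                          frame_rate=frame_rate)


def angular_coverage(trajectory: PreyTrajectory, n_bins: int = 19) -> np.ndarray:
    """Fraction of frames spent in each of ``n_bins`` angular bins
    (centres evenly spaced on the circle, matching the analysis basis)."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    ok = np.isfinite(trajectory.angle)
    counts, _ = np.histogram(trajectory.angle[ok], bins=edges)
    return counts / max(ok.sum(), 1)


# ---------------------------------------------------------------------------
# tuned-pixel movie
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthPixel:
    """Bookkeeping for one simulated pixel's true tuning."""

    pixel_id: int
    true_preferred_angle: float
    true_preferred_radius: float  # mm
    response_gain: float
    is_tuned: bool

    def __post_init__(self):
        if not self.is_tuned and self.response_gain != 0:
            raise ParameterError("untuned pixels must have zero gain")


def make_ground_truth_pixels(n_tuned: int, n_untuned: int, seed: int = 0,
                             gain: float = 1.0, r_range=(0.5, 4.5)
                             ) -> list[GroundTruthPixel]:
    """Draw a population of tuned pixels with angles uniform on the circle
    and radii uniform on ``r_range`` (mm), plus untuned (zero-gain) pixels."""
    rng = np.random.default_rng(seed)
    pixels = []
    for i in range(n_tuned):
        pixels.append(GroundTruthPixel(
            i, float(rng.uniform(-np.pi, np.pi)),
            float(rng.uniform(*r_range)), gain, True))
    for i in range(n_untuned):
        pixels.append(GroundTruthPixel(n_tuned + i, np.nan, np.nan, 0.0, False))
    return pixels


def ground_truth_to_json(pixels: list[GroundTruthPixel], path) -> None:
    with open(path, "w") as f:
        json.dump([asdict(p) for p in pixels], f, indent=1)


def tuning_drive(angle: np.ndarray, radius_mm: np.ndarray, pref_angle: float,
                 pref_radius_mm: float, kappa: float = 20.0,
                 sigma: float = 40.0, units_per_mm: float = UNITS_PER_MM
                 ) -> np.ndarray:
    """Instantaneous drive of a pixel with a polar receptive field.

    A von Mises bump in angle (concentration ``kappa``) times a Gaussian in
    radius (width ``sigma`` in basis-space units, default 40 units/mm),
    normalised to peak 1 at the preferred position. NaN positions (no prey)
    drive 0. Defaults mirror the analysis basis so the encoding model is
    well specified on these fixtures.
    """
    angle = np.asarray(angle, dtype=float)
    u = np.asarray(radius_mm, dtype=float) * units_per_mm
    u0 = pref_radius_mm * units_per_mm
    drive = np.exp(kappa * (np.cos(angle - pref_angle) - 1.0))
    drive *= np.exp(-((u - u0) ** 2) / (2.0 * sigma ** 2))
    return np.nan_to_num(drive)


def _calcium_kernel_filter(x: np.ndarray, tau_s: float, frame_rate: float
                           ) -> np.ndarray:
    """Causal exponential (GCaMP-like) filtering along axis 0, unit-gain."""
    from scipy.signal import lfilter

    a = np.exp(-1.0 / (tau_s * frame_rate))
    return lfilter([1.0 - a], [1.0, -a], x, axis=0)


def simulate_pixel_movie(trajectory: PreyTrajectory,
                         pixels: list[GroundTruthPixel],
                         calcium_tau: float = 1.0,
                         bleach: tuple[float, float] = (0.0, 100.0),
                         noise_sd: float = 0.1,
                         seed: int = 0,
                         kappa: float = 20.0,
                         sigma: float = 40.0,
                         grid_shape: tuple[int, int] | None = None
                         ) -> tuple[FluorescenceMovie, list[GroundTruthPixel]]:
    """Render a movie of pixels with known polar receptive fields.

    Each tuned pixel's drive is its receptive field evaluated at the prey's
    per-frame position, convolved with a causal exponential calcium kernel
    (``calcium_tau`` seconds, GCaMP6f-like at 1.0 s), plus a decaying
    exponential photobleaching trend ``bleach = (amplitude, tau_seconds)``
    shared by all pixels and i.i.d. Gaussian noise.

    Pixels are laid out row-major on a near-square grid (or ``grid_shape``);
    any padding cells become untuned noise pixels appended to the returned
    ground-truth list.
    """
    if not pixels:
        raise ParameterError("pixel list must be non-empty")
    if calcium_tau <= 0:
        raise ParameterError("calcium_tau must be positive")
    pixels = list(pixels)
    n = len(pixels)
    if grid_shape is None:
        w = int(np.ceil(np.sqrt(n)))
        h = int(np.ceil(n / w))
    else:
        h, w = grid_shape
        if h * w < n:
            raise ParameterError("grid_shape too small for pixel list")
    for extra in range(h * w - n):
        pixels.append(GroundTruthPixel(n + extra, np.nan, np.nan, 0.0, False))

    T = len(trajectory)
    rng = np.random.default_rng(seed)
    drive = np.zeros((T, h * w))
    for j, px in enumerate(pixels):
        if px.is_tuned and px.response_gain != 0:
            drive[:, j] = px.response_gain * tuning_drive(
                trajectory.angle, trajectory.radius,
                px.true_preferred_angle, px.true_preferred_radius,
                kappa=kappa, sigma=sigma)
    data = _calcium_kernel_filter(drive, calcium_tau, trajectory.frame_rate)
    amp, btau = bleach
    if amp != 0:
        t = np.arange(T) / trajectory.frame_rate
        data = data + amp * np.exp(-t / btau)[:, None]
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    movie = FluorescenceMovie(data.reshape(T, h, w).astype(np.float32),
                              frame_rate=trajectory.frame_rate)
    return movie, pixels


# ---------------------------------------------------------------------------
# coupled-region VAR process
# ---------------------------------------------------------------------------

@dataclass
class CouplingSpec:
    """Ground-truth vector-autoregressive coupling between regions.

    ``coefficients[i, j, k]`` is the weight of region ``j`` at lag ``k+1``
    onto region ``i``; this is the ground truth for the autoregressive
    coefficients recovered by the connectivity analysis.
    """

    n_regions: int
    order: int
    coefficients: np.ndarray
    noise_sd: np.ndarray | float = 1.0

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        expected = (self.n_regions, self.n_regions, self.order)
        if self.coefficients.shape != expected:
            raise ParameterError(
                f"coefficients must have shape {expected}")
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.n_regions,)).copy()
        if np.any(self.noise_sd <= 0):
            raise ParameterError("noise_sd must be positive")

    def companion_matrix(self) -> np.ndarray:
        r, q = self.n_regions, self.order
        top = self.coefficients.transpose(2, 0, 1).reshape(q, r, r)
        comp = np.zeros((r * q, r * q))
        for k in range(q):
            comp[:r, k * r:(k + 1) * r] = top[k]
        if q > 1:
            comp[r:, :-r] = np.eye(r * (q - 1))
        return comp

    @property
    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion_matrix())).max())

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0


def simulate_coupled_regions(spec: CouplingSpec, T: int, seed: int = 0,
                             burn_in: int = VAR_BURN_IN,
                             frame_rate: float = DEFAULT_FRAME_RATE
                             ) -> tuple[RegionTraces, CouplingSpec]:
    """Draw region traces from the specified stable VAR process.

    The first ``burn_in`` frames after a zero start are discarded so the
    returned samples come from (approximately) the stationary distribution.
    """
    if not spec.is_stable:
        raise InstabilityError(
            f"VAR spectral radius {spec.spectral_radius:.3f} >= 1")
    if T <= 10 * spec.order:
        raise ParameterError("T must exceed 10x the model order")
    rng = np.random.default_rng(seed)
    r, q = spec.n_regions, spec.order
    total = T + burn_in
    e = rng.normal(0.0, 1.0, size=(total, r)) * spec.noise_sd
    x = np.zeros((total, r))
    A = spec.coefficients  # (target, source, lag)
    for t in range(total):
        acc = e[t].copy()
        for k in range(1, min(q, t) + 1):
            acc += A[:, :, k - 1] @ x[t - k]
        x[t] = acc
    traces = RegionTraces([f"region_{i}" for i in range(r)], x[burn_in:].T,
                          frame_rate=frame_rate)
    return traces, spec


# ---------------------------------------------------------------------------
# behavior session
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSessionTruth:
    """Planted ground truth for a simulated behavior session."""

    transient_frames: np.ndarray
    paired: np.ndarray  # True where the transient is followed by a convergence
    sides: list[str]
    convergence_frames: np.ndarray


@dataclass
class BehaviorSession:
    """Simulated traces for the behavioral event-detection stage."""

    left_eye: np.ndarray       # degrees, nasal-positive
    right_eye: np.ndarray
    tail_left: np.ndarray      # side intensity traces, a.u.
    tail_right: np.ndarray
    pretectal_left: np.ndarray   # ~z-units
    pretectal_right: np.ndarray
    frame_rate: float
    truth: BehaviorSessionTruth


def _gauss_bump(T: int, center: int, amplitude: float, width: float) -> np.ndarray:
    t = np.arange(T)
    return amplitude * np.exp(-((t - center) ** 2) / (2.0 * width ** 2))


def simulate_behavior_session(n_transients: int, p_convergence: float,
                              T: int, seed: int = 0, min_spacing: int = 25,
                              frame_rate: float = DEFAULT_FRAME_RATE,
                              transient_amplitude: float = 5.0,
                              vergence_peak: float = 42.0
                              ) -> BehaviorSession:
    """Simulate pretectal transients stochastically followed by convergences.

    Gaussian-bump transients (amplitude ~5 z, width 2 frames) are planted in
    unit-variance pretectal noise on a random (dominant) side; each
    transient is independently accompanied, with probability
    ``p_convergence``, by an eye-vergence excursion crossing the 30 degree
    convergence threshold within +/-5 frames of the transient peak,
    together with a tail flick. The pretectal noise floor is exponentially
    filtered (calcium-like) so that suprathreshold excursions are
    overwhelmingly the planted transients.
    """
    if not 0.0 <= p_convergence <= 1.0:
        raise ParameterError("p_convergence must be in [0, 1]")
    margin = 15
    if n_transients * min_spacing > T - 2 * margin:
        raise CapacityError("transients at the minimum spacing exceed T")
    rng = np.random.default_rng(seed)

    def _smooth_noise():
        w = _calcium_kernel_filter(rng.normal(0, 1, T), 1.0, frame_rate)
        return w / w.std()

    # evenly slotted peaks with jitter, spacing >= min_spacing guaranteed
    slots = np.linspace(margin, T - margin, n_transients + 1)
    peaks = []
    for i in range(n_transients):
        lo, hi = slots[i], slots[i + 1] - min_spacing
        peaks.append(int(rng.uniform(lo, max(lo + 1, hi))))
    peaks = np.asarray(peaks)

    pretect_l = _smooth_noise()
    pretect_r = _smooth_noise()
    sides, paired, conv_frames = [], [], []
    for p in peaks:
        side = "left" if rng.random() < 0.5 else "right"
        sides.append(side)
        main = _gauss_bump(T, p, transient_amplitude, 2.0)
        minor = _gauss_bump(T, p, transient_amplitude * 0.3, 2.0)
        if side == "left":
            pretect_l += main
            pretect_r += minor
        else:
            pretect_r += main
            pretect_l += minor
        paired.append(rng.random() < p_convergence)
        if paired[-1]:
            offset = int(rng.integers(-4, 5))
            conv_frames.append(int(np.clip(p + offset, 3, T - 4)))
    paired = np.asarray(paired, dtype=bool)
    conv_frames = np.asarray(conv_frames, dtype=int)

    vergence = np.full(T, 10.0) + rng.normal(0, 0.5, T)
    tail_l = rng.normal(0, 1, T)
    tail_r = rng.normal(0, 1, T)
    for c in conv_frames:
        # fast nasal ramp to above threshold, slower release
        t = np.arange(T, dtype=float)
        rise = np.clip((t - (c - 3)) / 3.0, 0, 1)
        fall = np.clip(1 - (t - c) / 8.0, 0, 1)
        vergence += (vergence_peak - 10.0) * np.minimum(rise, fall)
        tail = tail_l if rng.random() < 0.5 else tail_r
        tail[c:c + 3] += 6.0
    left_eye = vergence / 2.0
    right_eye = vergence / 2.0

    truth = BehaviorSessionTruth(peaks, paired, sides, conv_frames)
    return BehaviorSession(left_eye, right_eye, tail_l, tail_r,
                           pretect_l, pretect_r, frame_rate, truth)
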