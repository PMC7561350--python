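"""Orchestration: configuration, sub-seeding, and the two end-to-end runs.

``run_encoding_analysis`` composes preprocessing and the pixel-wise
encoding model on a movie + prey trajectory; ``run_connectivity_analysis``
composes preprocessing, behavioral event detection and Granger-causality
on region traces. ``run_synthetic_demo`` generates a full synthetic
session and pushes it through both.

Frame indices are 0-based and epochs are half-open ``[start, end)``
(defaults: spontaneous ``[0, 1500)``, evoked ``[1500, 4000)``, matching a
7-minute baseline followed by an 11-minute prey epoch at 3.6 Hz). Angles
are stored in radians; the CLI renders degrees. Every stochastic stage
receives a sub-seed derived by stable hashing of the stage name with the
master seed, so adding a stage never reshuffles the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import encoding, events, granger, stats, synthetic
from .exceptions import ConfigError
from .preprocess import FluorescenceMovie, RegionTraces, preprocess_movie


def subseed(master_seed: int, stage: str) -> int:
    """Derive a stage sub-seed (< 2**31) by hashing the stage name."""
    digest = hashlib.sha256(f"{stage}:{master_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration for an end-to-end run. Parameter blocks for the
    individual stages are plain dicts forwarded as keyword arguments."""

    seed: int = 0
    spontaneous_span: tuple[int, int] = (0, 1500)
    evoked_span: tuple[int, int] = (1500, 4000)
    frame_rate: float = 3.6
    synthetic: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)
    encoding: dict = field(default_factory=dict)
    granger: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        s0, e0 = self.spontaneous_span
        s1, e1 = self.evoked_span
        if e0 <= s0 or e1 <= s1:
            raise ConfigError("epochs must have positive length")
        if max(s0, s1) < min(e0, e1):
            raise ConfigError("epochs must not overlap")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = json.load(f)
        raw["spontaneous_span"] = tuple(raw.get("spontaneous_span", (0, 1500)))
        raw["evoked_span"] = tuple(raw.get("evoked_span", (1500, 4000)))
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=1, default=str)


def _write_manifest(outdir: Path, config: RunConfig, extra: dict) -> None:
    import scipy

    manifest = {
        "config": asdict(config),
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
        **extra,
    }
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, default=str)


# ---------------------------------------------------------------------------
# encoding run
# ---------------------------------------------------------------------------

def run_encoding_analysis(config: RunConfig, outdir,
                          movie: FluorescenceMovie | None = None,
                          trajectory: synthetic.PreyTrajectory | None = None
                          ) -> pd.DataFrame:
    """Fit the pixel-wise encoding model and write per-pixel results.

    Inputs come from ``config.paths`` (``movie`` HDF5/TIFF, ``trajectory``
    CSV) unless passed in memory. Writes ``encoding_results.csv`` (pixel,
    r, p, significant, preferred_angle_rad), a preferred-angle map TIFF
    (radians, NaN where not significant) and a manifest; returns the table.
    """
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if movie is None:
        path = Path(config.paths["movie"])
        if path.suffix in (".h5", ".hdf5"):
            movie = FluorescenceMovie.from_hdf5(path)
        else:
            movie = FluorescenceMovie.from_tiff(path)
    if trajectory is None:
        trajectory = synthetic.PreyTrajectory.from_csv(
            config.paths["trajectory"])

    # pixel traces in Fz with bleaching removed (whole frame as one ROI)
    from .preprocess import correct_bleaching, fit_bleach_model

    mask = np.ones(movie.shape[1:], dtype=bool)

    model = fit_bleach_model(movie.pixel_traces().mean(axis=1))
    corrected = correct_bleaching(movie, mask, model)
    flat = corrected.pixel_traces().astype(float)
    sd = flat.std(axis=0)
    sd[sd == 0] = 1.0
    Y = (flat - flat.mean(axis=0)) / sd

    enc_cfg = dict(config.encoding)
    basis_kwargs = enc_cfg.pop("basis", {})
    delays = enc_cfg.pop("delays", encoding.DEFAULT_DELAYS)
    basis = encoding.build_spatial_basis(encoding.BasisConfig(**basis_kwargs))
    series = encoding.project_trajectory(trajectory, basis)
    design = encoding.build_design_matrix(series, delays=delays, basis=basis)
    result = encoding.nested_cv_fit(
        design, Y, basis=basis, seed=subseed(config.seed, "encoding"),
        **enc_cfg)

    table = pd.DataFrame({
        "pixel": np.arange(result.n_pixels),
        "r": result.cv_correlation,
        "p": result.p_values,
        "significant": result.significant,
        "preferred_angle_rad": result.preferred_angle,
    })
    table.to_csv(outdir / "encoding_results.csv", index=False,
                 float_format="%.9g")
    angle_map = result.preferred_angle.reshape(movie.shape[1:])
    tifffile.imwrite(outdir / "preferred_angle_map.tif",
                     angle_map.astype(np.float32))
    _write_manifest(outdir, config, {
        "stage": "encoding",
        "seed_used": subseed(config.seed, "encoding"),
        "n_features": design.n_features,
        "delays": list(design.delays),
        "note": ("delay window -5..+14 frames keeps the feature count at "
                 "n_basis x 20; the nominal window extends to +15"),
    })
    return table


# ---------------------------------------------------------------------------
# connectivity run
# ---------------------------------------------------------------------------

def run_connectivity_analysis(config: RunConfig, outdir,
                              traces: RegionTraces | None = None,
                              session: synthetic.BehaviorSession | None = None
                              ) -> dict:
    """GC matrices per condition plus behavioral event tables.

    Region traces come from ``config.paths['traces']`` (CSV) unless given.
    If a behavior session is supplied (or simulated upstream), convergences
    and pretectal transients are detected and classified and the transition
    probability reported. Writes per-condition GC CSVs, an events CSV and a
    manifest; returns the results as a dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if traces is None:
        traces = RegionTraces.from_csv(config.paths["traces"])

    q = config.granger.get("order", 5)
    results: dict = {}
    for condition, span in (("spontaneous", config.spontaneous_span),
                            ("evoked", config.evoked_span)):
        span = (span[0], min(span[1], traces.n_frames))
        if span[1] - span[0] <= 3 * q + 2:
            continue
        gcm = granger.connectivity_matrix(traces, q, condition=condition,
                                          epoch=span)
        gcm.to_csv(outdir / f"gc_{condition}.csv")
        results[condition] = gcm

    if session is not None:
        eyes = events.EyeTrace(session.left_eye, session.right_eye)
        conv = events.detect_convergences(eyes, **config.events)
        trans = events.detect_pretectal_transients(session.pretectal_left,
                                                   session.pretectal_right)
        trans = events.classify_transients(trans, conv)
        pd.concat([conv.to_frame(), trans.to_frame()]).to_csv(
            outdir / "events.csv", index=False, float_format="%.9g")
        results["convergences"] = conv
        results["transients"] = trans
        if len(trans):
            results["transition_probability"] = \
                events.transition_probability(trans)

    _write_manifest(outdir, config, {
        "stage": "connectivity", "order": q,
        "association_window_frames": 5,
    })
    return results


# ---------------------------------------------------------------------------
# synthetic demonstration
# ---------------------------------------------------------------------------

def run_synthetic_demo(outdir, seed: int = 0, n_regions: int = 4,
                       T: int = 2500) -> dict:
    """Generate a synthetic session and run both analyses at demo scale.

    Uses a small pixel grid and a reduced delay window so the demo runs in
    seconds; writes everything under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = RunConfig(seed=seed, spontaneous_span=(0, T // 2),
                       evoked_span=(T // 2, T),
                       encoding={"delays": list(range(0, 3)),
                                 "alphas": list(np.logspace(0, 3, 5)),
                                 "n_inner_reps": 3})

    traj = synthetic.simulate_prey_trajectory(
        T, seed=subseed(seed, "trajectory"))
    traj.to_csv(outdir / "trajectory.csv")
    pixels = synthetic.make_ground_truth_pixels(
        12, 4, seed=subseed(seed, "pixels"), gain=3.0)
    movie, pixels = synthetic.simulate_pixel_movie(
        traj, pixels, noise_sd=0.05, seed=subseed(seed, "movie"))
    movie.to_hdf5(outdir / "movie.h5")
    synthetic.ground_truth_to_json(pixels, outdir / "ground_truth.json")
    enc_table = run_encoding_analysis(config, outdir / "encoding",
                                      movie=movie, trajectory=traj)

    coeffs = np.zeros((n_regions, n_regions, 1))
    for i in range(n_regions):
        coeffs[i, i, 0] = 0.3
    coeffs[2, 0, 0] = 0.5  # region_0 -> region_2 planted link
    spec = synthetic.CouplingSpec(n_regions, 1, coeffs)
    traces, _ = synthetic.simulate_coupled_regions(
        spec, T, seed=subseed(seed, "regions"))
    traces.to_csv(outdir / "region_traces.csv")
    session = synthetic.simulate_behavior_session(
        20, 0.5, T, seed=subseed(seed, "behavior"))
    conn = run_connectivity_analysis(
        RunConfig(seed=seed, spontaneous_span=(0, T // 2),
                  evoked_span=(T // 2, T), granger={"order": 1}),
        outdir / "connectivity", traces=traces, session=session)
    return {"encoding": enc_table, "connectivity": conn,
            "ground_truth_pixels": pixels, "coupling": spec}
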