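"""Synthetic fixtures with the statistical structure the analyses assume.

Each generator emulates one measurement the pipeline consumes:

* EFTEM unfiltered/zero-loss pairs over a sagged nanochannel, with the
  attenuation I0/I = exp(-(t_ice(x)/lambda_ice + t_SiN/lambda_SiN)) and
  Poisson count noise;
* filling kymographs with a Washburn front x(t) = a*sqrt(t-b) + c and
  Gaussian camera noise;
* particle-number/resolution tables generated from the linear
  1/d^2 = (2/B) ln n + c0 relation;
* whole-frame motion trajectories with per-cluster drift directions and a
  step size decaying with exposure (fast early motion).

Generators are pure functions of their parameters and a seed; the random
stream is derived from (seed, generator name) so adding a generator never
perturbs another's output.  No contrast-transfer or multislice physics is
simulated: the fixtures encode only the attenuation, kinetic and
statistical structure the analyses rely on.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .capillary import Kymograph, MeniscusTrace
from .emstats import MotionTrajectorySet, ResLogTable
from .geometry import ChannelGeometry, thickness_profile
from .thickness import EftemImagePair, ScatteringCalibration

import pandas as pd

__all__ = [
    "SyntheticSpec",
    "make_eftem_pair",
    "make_kymograph",
    "make_washburn_trace",
    "make_reslog",
    "make_trajectories",
]


def _rng(seed: int, name: str) -> np.random.Generator:
    """Stream keyed by (seed, generator name)."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass
class SyntheticSpec:
    """Study conditions for the generators; defaults mirror the device and
    acquisition parameters the analyses were designed around."""

    seed: int = 0
    dose: float = 4000.0                       # mean counts/pixel, unfiltered
    noise_model: str = "poisson"               # none | poisson | gaussian
    gaussian_sigma: float = 0.0
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    calibration: ScatteringCalibration = field(default_factory=ScatteringCalibration)
    washburn_params: tuple[float, float, float] = (2000.0, 0.05, 10.0)  # a, b, c
    motion_clusters: list[tuple[float, float, int]] = field(
        default_factory=lambda: [(0.0, 5.1, 5), (120.0, 5.1, 5), (240.0, 5.1, 5)]
    )  # (direction deg, total path A, n_movies)
    reslog_params: tuple[float, float, int, float] = (178.0, 0.02, 8, 0.0)
    # (B in A^2, intercept in 1/A^2, n_points, noise sigma on 1/d^2)


def make_eftem_pair(
    spec: SyntheticSpec,
    shape: tuple[int, int] = (64, 129),
    pixel_size_A: float = 75.0,
    shift_px: tuple[int, int] = (0, 0),
) -> EftemImagePair:
    """Unfiltered/zero-loss pair over a vertical sagged nanochannel.

    The channel axis runs along rows, centered horizontally.  Outside the
    channel only the membrane attenuates; inside, the ice thickness follows
    the geometry profile.  ``shift_px`` rolls the zero-loss image to
    emulate a misaligned acquisition (``aligned`` is set accordingly).
    """
    rng = _rng(spec.seed, "eftem_pair")
    geom, cal = spec.geometry, spec.calibration
    nrow, ncol = shape
    px_nm = pixel_size_A / 10.0
    x_nm = (np.arange(ncol) - (ncol - 1) / 2.0) * px_nm
    half_w = geom.width_nm / 2.0
    t_ice = np.zeros(ncol)
    inside = np.abs(x_nm) <= half_w
    t_ice[inside] = thickness_profile(geom, x_nm[inside])
    attenuation = np.exp(-(t_ice / cal.lambda_ice_nm + cal.t_sin_total_nm / cal.lambda_sin_nm))
    unfiltered = np.full(shape, spec.dose, dtype=float)
    zeroloss = spec.dose * np.tile(attenuation, (nrow, 1))
    if spec.noise_model == "poisson":
        unfiltered = rng.poisson(unfiltered).astype(float)
        zeroloss = rng.poisson(zeroloss).astype(float)
    elif spec.noise_model == "gaussian":
        unfiltered = unfiltered + rng.normal(0, spec.gaussian_sigma, shape)
        zeroloss = zeroloss + rng.normal(0, spec.gaussian_sigma, shape)
        unfiltered = np.clip(unfiltered, 0, None)
        zeroloss = np.clip(zeroloss, 0, None)
    elif spec.noise_model != "none":
        raise ValueError(f"unknown noise model {spec.noise_model!r}")
    aligned = shift_px == (0, 0)
    if not aligned:
        zeroloss = np.roll(zeroloss, shift_px, axis=(0, 1))
    return EftemImagePair(
        unfiltered_I=unfiltered, zeroloss_I0=zeroloss,
        pixel_size_A=pixel_size_A, aligned=aligned,
    )


def make_washburn_trace(
    spec: SyntheticSpec,
    duration_s: float = 1.0,
    frame_rate_fps: float = 10.0,
    noise_um: float = 0.0,
) -> MeniscusTrace:
    """Ideal meniscus trace sampled from x(t) = a*sqrt(t-b) + c, with
    optional Gaussian position noise."""
    rng = _rng(spec.seed, "washburn_trace")
    a, b, c = spec.washburn_params
    t = np.arange(np.ceil(b * frame_rate_fps) / frame_rate_fps,
                  duration_s + 0.5 / frame_rate_fps, 1.0 / frame_rate_fps)
    if len(t) == 0:
        raise ValueError("duration too short: no samples past the time origin")
    x = a * np.sqrt(np.clip(t - b, 0, None)) + c
    if noise_um > 0:
        x = x + rng.normal(0, noise_um, len(t))
    return MeniscusTrace(t, x)


def make_kymograph(
    spec: SyntheticSpec,
    duration_s: float = 1.0,
    n_positions: int = 800,
    frame_rate_fps: float = 10.0,
    pixel_size_um: float = 1.6,
    filled_level: float = 40.0,
    unfilled_level: float = 200.0,
    noise_sigma: float = 0.0,
) -> Kymograph:
    """Kymograph of an advancing Washburn front (filled region dark).

    Pixels with center position below the model front x(t) take the filled
    intensity; Gaussian read noise is added when ``noise_sigma > 0``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = _rng(spec.seed, "kymograph")
    a, b, c = spec.washburn_params
    n_frames = int(round(duration_s * frame_rate_fps))
    if n_frames < 1:
        raise ValueError("zero-duration movie")
    t = np.arange(n_frames) / frame_rate_fps
    front = a * np.sqrt(np.clip(t - b, 0, None)) + c
    pos = np.arange(n_positions) * pixel_size_um
    img = np.where(pos[None, :] < front[:, None], filled_level, unfilled_level).astype(float)
    if noise_sigma > 0:
        img = img + rng.normal(0, noise_sigma, img.shape)
    return Kymograph(
        intensity=img, frame_rate_fps=frame_rate_fps,
        pixel_size_um=pixel_size_um, filled_is_dark=True,
    )


def make_reslog(spec: SyntheticSpec, n_min: int = 500, n_max: int = 40000) -> ResLogTable:
    """Table of (n, d) rows drawn from 1/d^2 = (2/B) ln n + intercept."""
    rng = _rng(spec.seed, "reslog")
    B, intercept, n_points, sigma = spec.reslog_params
    if B <= 0:
        raise ValueError("B must be > 0")
    n = np.unique(np.geomspace(n_min, n_max, n_points).round().astype(int))
    y = (2.0 / B) * np.log(n) + intercept
    if sigma > 0:
        y = y + rng.normal(0, sigma, len(n))
    if np.any(y <= 0):
        raise ValueError("parameters give non-physical (non-positive) 1/d^2")
    d = 1.0 / np.sqrt(y)
    return ResLogTable(n.astype(float), d)


def make_trajectories(
    spec: SyntheticSpec,
    n_frames: int = 40,
    exposure_per_frame: float = 1.0,
    angle_jitter_deg: float = 0.0,
    decay_rate: float = 0.1,
) -> MotionTrajectorySet:
    """Clustered unidirectional drift trajectories.

    Each cluster ``(angle_deg, total_path_A, n_movies)`` yields movies
    drifting along the cluster direction (plus per-movie angular jitter)
    with per-frame step sizes decaying exponentially with exposure
    (fast initial motion); steps are normalised so the net path length over
    all frames equals ``total_path_A``.  Cluster index doubles as the
    shot-position label; movies are round-robin assigned to chips.
    """
    if not spec.motion_clusters:
        raise ValueError("need at least one motion cluster")
    rng = _rng(spec.seed, "trajectories")
    steps = np.exp(-decay_rate * np.arange(n_frames))
    positions: dict[str, np.ndarray] = {}
    rows = []
    for ci, (angle_deg, total_path, n_movies) in enumerate(spec.motion_clusters):
        for mi in range(n_movies):
            ang = np.radians(angle_deg + (rng.normal(0, angle_jitter_deg) if angle_jitter_deg else 0.0))
            mags = steps / steps.sum() * total_path
            direction = np.array([np.cos(ang), np.sin(ang)])
            pos = np.concatenate(
                [np.zeros((1, 2)), np.cumsum(mags[:, None] * direction[None, :], axis=0)]
            )
            mid = f"c{ci}m{mi}"
            # n_frames + 1 points: start position plus one per frame, so the
            # point at index i corresponds to exposure i * exposure_per_frame
            positions[mid] = pos
            rows.append({"movie_id": mid, "chip": f"chip{mi % 3}", "shot_position": f"pos{ci}"})
    labels = pd.DataFrame(rows).set_index("movie_id")
    return MotionTrajectorySet(
        positions_A=positions, exposure_per_frame=exposure_per_frame, labels=labels
    )
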