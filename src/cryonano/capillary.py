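"""Capillary filling kinetics: kymographs, meniscus tracking, Washburn fits.

Spontaneous capillary imbibition into a channel follows Washburn kinetics:
the penetration distance grows with the square root of time,

    x(t) = a * sqrt(t - b) + c,

where ``a`` (µm/s^1/2) sets the filling rate, ``b`` (s) shifts the time
origin to the moment the liquid enters the field of view and ``c`` (µm)
shifts the position origin.  Squaring the shifted position linearises the
law: (x - c)^2 = a^2 (t - b) is affine in t with slope a^2.

Filling movies are reduced to kymographs (time x position intensity
images), the meniscus front is tracked per frame, and the model is fitted
by nonlinear least squares with case-resampling bootstrap uncertainties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "Kymograph",
    "MeniscusTrace",
    "WashburnFit",
    "build_kymograph",
    "track_meniscus",
    "fit_washburn",
    "bootstrap_washburn",
    "linearized_trace",
    "linearized_slope",
    "mean_filling_speed",
]


class EmptyTraceError(ValueError):
    """No meniscus positions could be extracted."""


class FitError(RuntimeError):
    """Washburn fit failed or is degenerate."""


@dataclass
class Kymograph:
    """Space-time intensity image: rows are frames, columns positions.

    Default acquisition matches a 10 fps optical movie at 1.6 µm/pixel.
    """

    intensity: np.ndarray
    frame_rate_fps: float = 10.0
    pixel_size_um: float = 1.6
    channel_axis_origin_um: float = 0.0
    filled_is_dark: bool = True

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("kymograph must be 2D (time x position)")
        if self.frame_rate_fps <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame_rate_fps and pixel_size_um must be > 0")


@dataclass
class MeniscusTrace:
    """Meniscus position (µm) versus time (s)."""

    times_s: np.ndarray
    positions_um: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.times_s.shape != self.positions_um.shape:
            raise ValueError("times and positions must have the same length")
        if len(self.times_s) and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class WashburnFit:
    """Parameters of x(t) = a*sqrt(t - b) + c with bootstrap uncertainties."""

    a: float
    b: float
    c: float
    a_sd: float = 0.0
    b_sd: float = 0.0
    c_sd: float = 0.0
    n_boot: int = 0
    residual_rms_um: float = 0.0
    n_excluded: int = 0
    seed: int | None = None

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.a * np.sqrt(np.clip(t - self.b, 0.0, None)) + self.c


def build_kymograph(
    frames: np.ndarray,
    stripe: tuple[int, int, int, int],
    frame_rate_fps: float = 10.0,
    pixel_size_um: float = 1.6,
    filled_is_dark: bool = True,
) -> Kymograph:
    """Average a stripe along the channel over all movie frames.

    ``frames`` has axes (frame, row, col); ``stripe = (r0, r1, c0, c1)``
    selects a section along the channel (columns) a few pixels wide
    (rows, conventionally 10).  Each frame contributes one kymograph row:
    the mean over the stripe width.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be 3D (frame, row, col)")
    r0, r1, c0, c1 = stripe
    _, nrow, ncol = frames.shape
    if not (0 <= r0 < r1 <= nrow and 0 <= c0 < c1 <= ncol):
        raise IndexError(f"stripe {stripe} outside frame shape {(nrow, ncol)}")
    kymo = frames[:, r0:r1, c0:c1].mean(axis=1)
    return Kymograph(
        intensity=kymo,
        frame_rate_fps=frame_rate_fps,
        pixel_size_um=pixel_size_um,
        filled_is_dark=filled_is_dark,
    )


def track_meniscus(kymo: Kymograph, method: str = "half_max_edge") -> MeniscusTrace:
    """Extract the meniscus position per frame.

    ``half_max_edge`` thresholds at the midpoint between the filled and
    unfilled median intensities and takes the extent of the filled region
    growing from the channel entrance (column 0).  Frames without a
    crossing are dropped with a warning; an empty result raises
    :class:`EmptyTraceError`.
    """
    if method != "half_max_edge":
        raise ValueError(f"unknown tracking method {method!r}")
    img = kymo.intensity
    lo, hi = np.percentile(img, [5, 95])
    if hi - lo <= np.finfo(float).eps * max(abs(hi), 1.0):
        raise EmptyTraceError("uniform kymograph: no filled/unfilled contrast")
    thr = 0.5 * (lo + hi)
    filled = (img < thr) if kymo.filled_is_dark else (img > thr)
    times, positions = [], []
    n_dropped = 0
    for i, row in enumerate(filled):
        if not row[0] or row.all():
            # front not yet in view, or channel fully filled: no crossing
            n_dropped += 1
            continue
        front_px = int(np.argmin(row))  # first unfilled pixel from the entrance
        times.append(i / kymo.frame_rate_fps)
        positions.append(kymo.channel_axis_origin_um + front_px * kymo.pixel_size_um)
    if n_dropped:
        logger.warning("track_meniscus: dropped %d frames without a front crossing", n_dropped)
    if not times:
        raise EmptyTraceError("no frames contained a meniscus crossing")
    return MeniscusTrace(np.array(times), np.array(positions))


def _washburn_model(t, a, b, c):
    return a * np.sqrt(np.clip(t - b, 0.0, None)) + c


def _profiled_rss(b: float, t: np.ndarray, x: np.ndarray):
    """Least-squares (a, c) and residual sum of squares for fixed b.

    Given b the model is linear in (a, c) through the regressor
    s = sqrt(max(t - b, 0)), so the nonlinear fit reduces to a 1D search
    over b.
    """
    s = np.sqrt(np.clip(t - b, 0.0, None))
    A = np.column_stack([s, np.ones_like(s)])
    coef, rss, *_ = np.linalg.lstsq(A, x, rcond=None)
    resid = x - A @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_washburn(trace: MeniscusTrace) -> WashburnFit:
    """Least-squares fit of x(t) = a*sqrt(t - b) + c.

    For fixed b the model is linear in (a, c), so b is profiled out: a
    coarse grid over plausible time origins followed by a bounded scalar
    refinement, then a joint curve_fit polish.  Points with t < b enter
    through the clipped radical (they contribute x = c) and are counted as
    excluded from the square-root branch.
    """
    t, x = trace.times_s, trace.positions_um
    if len(t) < 4:
        raise FitError(f"need >= 4 points for a 3-parameter fit, got {len(t)}")
    span = t[-1] - t[0]
    if span <= 0:
        raise FitError("zero time span")
    dx = x[-1] - x[0]
    if abs(dx) <= 1e-12 * max(abs(x[-1]), 1.0):
        raise FitError("degenerate trace: meniscus does not move")

    # profile b on a coarse grid, then refine in the bracketing interval
    b_lo, b_hi = t[0] - 2.0 * span, t[-2]
    grid = np.linspace(b_lo, b_hi, 256)
    rss_grid = np.array([_profiled_rss(b, t, x)[2] for b in grid])
    i_best = int(np.argmin(rss_grid))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda b: _profiled_rss(b, t, x)[2], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12 * max(abs(span), 1.0)},
    )
    b = float(res.x)
    a, c, _ = _profiled_rss(b, t, x)
    try:  # joint polish from the profiled optimum
        popt, _ = optimize.curve_fit(
            _washburn_model, t, x, p0=(a, b, c),
            bounds=([0.0, b_lo, -np.inf], [np.inf, t[-1], np.inf]),
            maxfev=10000,
        )
        a, b, c = (float(v) for v in popt)
    except (RuntimeError, ValueError):
        logger.debug("curve_fit polish failed; keeping profiled solution")
    if a <= 0:
        raise FitError(f"degenerate fit: a = {a:g} <= 0")
    n_excluded = int(np.count_nonzero(t < b))
    resid = x - _washburn_model(t, a, b, c)
    return WashburnFit(
        a=float(a), b=float(b), c=float(c),
        residual_rms_um=float(np.sqrt(np.mean(resid**2))),
        n_excluded=n_excluded,
    )


def bootstrap_washburn(
    trace: MeniscusTrace, n_boot: int = 100, seed: int | None = None
) -> WashburnFit:
    """Case-resampling bootstrap of the Washburn fit.

    Refits ``n_boot`` resamples of n-out-of-n (time, position) pairs with
    replacement; parameters are reported as the mean over refits with their
    standard deviations.  More than 20% failed refits raises
    :class:`FitError`.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    base = fit_washburn(trace)  # must succeed on the full trace
    rng = np.random.default_rng(seed)
    n = len(trace.times_s)
    params = []
    for _ in range(n_boot):
        idx = np.sort(rng.integers(0, n, size=n))
        # collapse duplicate times so MeniscusTrace stays strictly increasing
        tt = trace.times_s[idx] + np.arange(n) * 1e-12
        try:
            fit = fit_washburn(MeniscusTrace(tt, trace.positions_um[idx]))
            params.append((fit.a, fit.b, fit.c))
        except FitError:
            continue
    if len(params) < 0.8 * n_boot:
        raise FitError(
            f"bootstrap unstable: only {len(params)}/{n_boot} refits converged"
        )
    arr = np.array(params)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(3)
    return WashburnFit(
        a=float(mean[0]), b=float(mean[1]), c=float(mean[2]),
        a_sd=float(sd[0]), b_sd=float(sd[1]), c_sd=float(sd[2]),
        n_boot=len(params), residual_rms_um=base.residual_rms_um,
        n_excluded=base.n_excluded, seed=seed,
    )


def linearized_trace(trace: MeniscusTrace, fit: WashburnFit):
    """Return (t, (x - c)^2) pairs: affine in t with slope a^2 and
    intercept -a^2*b under the Washburn model."""
    y = (trace.positions_um - fit.c) ** 2
    return trace.times_s.copy(), y


def linearized_slope(trace: MeniscusTrace, fit: WashburnFit) -> tuple[float, float]:
    """Slope (µm²/s) and intercept of the linearised squared-position plot.

    Display convention quotes slopes in 1e6 µm²/s.
    """
    t, y = linearized_trace(trace, fit)
    res = stats.linregress(t, y)
    return float(res.slope), float(res.intercept)


def mean_filling_speed(trace: MeniscusTrace) -> float:
    """Average front speed (mm/s) over the trace: net displacement over
    elapsed time."""
    if len(trace.times_s) < 2:
        raise ValueError("need >= 2 points for a mean speed")
    dt = trace.times_s[-1] - trace.times_s[0]
    if dt <= 0:
        raise ValueError("zero elapsed time")
    speed = (trace.positions_um[-1] - trace.positions_um[0]) / dt / 1e3
    if speed < 0:
        logger.warning("mean_filling_speed: negative speed %.3g mm/s (receding front?)", speed)
    return float(speed)
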