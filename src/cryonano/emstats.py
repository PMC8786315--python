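"""Cryo-EM quality statistics: vitreous fraction, on-chip concentration,
B-factor from particle-number/resolution tables, beam-induced motion.

The B-factor follows the Rosenthal-Henderson relation: over a series of
reconstructions from n particles each reaching resolution d, the inverse
squared resolution is linear in ln(n),

    1/d^2 = (2/B) * ln(n) + const,

so B (A^2) is two over the fitted slope.  Beam-induced motion is summarised
as the root-mean-square deviation (RMSD) across whole-frame alignment
trajectories, accumulated over electron exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

__all__ = [
    "CountPair",
    "ConcentrationEstimate",
    "ResLogTable",
    "MotionTrajectorySet",
    "BFactorFit",
    "vitreous_fraction",
    "concentration_from_count",
    "bfactor_from_reslog",
    "rmsd_vs_exposure",
    "group_trajectories",
]

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23
#: Liters per nm^3 (1 nm^3 = 1e-24 L); the single place this conversion lives.
L_PER_NM3 = 1e-24


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return float(round(x, -int(np.floor(np.log10(abs(x)))) + sig - 1))


@dataclass(frozen=True)
class CountPair:
    """Kept/total image counts for a classification (e.g. vitreous vs icy)."""

    n_kept: int
    n_total: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be > 0")
        if not 0 <= self.n_kept <= self.n_total:
            raise ValueError("need 0 <= n_kept <= n_total")


@dataclass(frozen=True)
class VitreousFraction:
    percent: float            # full precision, 100 * n_kept / n_total
    percent_display: int      # rounded to integer percent
    ci_low_percent: float     # Wilson 95% interval
    ci_high_percent: float
    counts: CountPair


def vitreous_fraction(counts: CountPair) -> VitreousFraction:
    """Fraction of images classified as vitreous, with a Wilson 95% CI."""
    frac = counts.n_kept / counts.n_total
    lo, hi = proportion_confint(counts.n_kept, counts.n_total, alpha=0.05, method="wilson")
    return VitreousFraction(
        percent=100.0 * frac,
        percent_display=int(round(100.0 * frac)),
        ci_low_percent=100.0 * lo,
        ci_high_percent=100.0 * hi,
        counts=counts,
    )


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Particle concentration inside a counted volume.

    Full-precision values plus display values rounded to 3 significant
    figures; ``fold_increase`` compares the mass concentration with the
    concentration of the applied sample.
    """

    n_particles: int
    volume_nm3: float
    mw_kda: float
    c_initial_mg_ml: float
    molar_uM: float
    mass_mg_ml: float
    fold_increase: float

    @property
    def molar_uM_display(self) -> float:
        return _round_sig(self.molar_uM)

    @property
    def mass_mg_ml_display(self) -> float:
        return _round_sig(self.mass_mg_ml)

    @property
    def fold_increase_display(self) -> float:
        return _round_sig(self.fold_increase, 2)


def concentration_from_count(
    n: int, volume_nm3: float, mw_kda: float, c_initial_mg_ml: float
) -> ConcentrationEstimate:
    """Molar and mass concentration from a particle count in a known volume.

    molar = n / (N_A * V) with V in liters (1 nm^3 = 1e-24 L); mass
    concentration multiplies by the molecular weight; the fold increase
    divides by the applied sample concentration.
    """
    if volume_nm3 <= 0:
        raise ValueError("volume_nm3 must be > 0")
    if n < 0:
        raise ValueError("particle count must be >= 0")
    molar_M = n / (AVOGADRO * volume_nm3 * L_PER_NM3)
    molar_uM = molar_M * 1e6
    mass_mg_ml = molar_M * mw_kda * 1e3  # mol/L * g/mol = g/L = mg/mL; kDa -> g/mol is 1e3
    fold = mass_mg_ml / c_initial_mg_ml if c_initial_mg_ml > 0 else float("nan")
    return ConcentrationEstimate(
        n_particles=n, volume_nm3=volume_nm3, mw_kda=mw_kda,
        c_initial_mg_ml=c_initial_mg_ml,
        molar_uM=molar_uM, mass_mg_ml=mass_mg_ml, fold_increase=fold,
    )


@dataclass
class ResLogTable:
    """Rows of (particle count, resolution in A) from reconstruction series."""

    n_particles: np.ndarray
    resolution_A: np.ndarray

    def __post_init__(self) -> None:
        self.n_particles = np.asarray(self.n_particles, dtype=float)
        self.resolution_A = np.asarray(self.resolution_A, dtype=float)
        if self.n_particles.shape != self.resolution_A.shape:
            raise ValueError("n_particles and resolution_A must match in length")
        if np.any(self.n_particles < 1) or np.any(self.resolution_A <= 0):
            raise ValueError("need n >= 1 and resolution > 0")

    @classmethod
    def from_csv(cls, path) -> "ResLogTable":
        df = pd.read_csv(path)
        return cls(df["n_particles"].to_numpy(), df["resolution_A"].to_numpy())


@dataclass(frozen=True)
class BFactorFit:
    bfactor_A2: float         # NaN when flagged
    slope: float              # d(1/d^2)/d(ln n)
    intercept: float
    r_squared: float
    ok: bool
    n_rows: int


def bfactor_from_reslog(
    table: ResLogTable | list[ResLogTable],
) -> BFactorFit:
    """B-factor from the slope of 1/d^2 versus ln(n): B = 2/slope.

    Multiple tables (independent reconstruction runs) are averaged
    row-wise before fitting.  A non-positive slope yields a flagged result
    with B = NaN rather than an error.
    """
    if isinstance(table, (list, tuple)):
        if len({len(t.n_particles) for t in table}) != 1:
            raise ValueError("tables to average must have equal length")
        n = np.mean([t.n_particles for t in table], axis=0)
        d = np.mean([t.resolution_A for t in table], axis=0)
        table = ResLogTable(n, d)
    if len(table.n_particles) < 3:
        raise ValueError("need >= 3 rows to fit a ResLog line")
    if len(np.unique(table.n_particles)) < 2:
        raise ValueError("need distinct particle counts")
    x = np.log(table.n_particles)
    y = 1.0 / table.resolution_A**2
    res = stats.linregress(x, y)
    ok = res.slope > 0
    if not ok:
        logger.warning("ResLog slope %.3g <= 0: B-factor undefined", res.slope)
    return BFactorFit(
        bfactor_A2=float(2.0 / res.slope) if ok else float("nan"),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        ok=bool(ok),
        n_rows=len(x),
    )


@dataclass
class MotionTrajectorySet:
    """Whole-frame alignment trajectories from dose-fractionated movies.

    ``positions_A[movie_id]`` is an (n_frames, 2) array of cumulative frame
    positions in A; all movies share ``exposure_per_frame`` (e-/A^2) and
    carry chip / shot-position labels for grouping.
    """

    positions_A: dict[str, np.ndarray]
    exposure_per_frame: float
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)  # index: movie_id

    def __post_init__(self) -> None:
        if self.exposure_per_frame <= 0:
            raise ValueError("exposure_per_frame must be > 0")
        lengths = {len(v) for v in self.positions_A.values()}
        if len(lengths) > 1:
            n_min = min(lengths)
            logger.warning("truncating trajectories to the common %d frames", n_min)
            self.positions_A = {k: np.asarray(v)[:n_min] for k, v in self.positions_A.items()}
        self.positions_A = {k: np.asarray(v, dtype=float) for k, v in self.positions_A.items()}

    @classmethod
    def from_csv(cls, path, exposure_per_frame: float) -> "MotionTrajectorySet":
        """Columns: movie_id, frame, dx_A, dy_A[, chip, shot_position]."""
        df = pd.read_csv(path)
        pos = {
            str(mid): g.sort_values("frame")[["dx_A", "dy_A"]].to_numpy()
            for mid, g in df.groupby("movie_id")
        }
        label_cols = [c for c in ("chip", "shot_position") if c in df.columns]
        labels = (
            df.groupby("movie_id")[label_cols].first() if label_cols else pd.DataFrame()
        )
        labels.index = labels.index.map(str)
        return cls(positions_A=pos, exposure_per_frame=exposure_per_frame, labels=labels)


def rmsd_vs_exposure(
    trajs: MotionTrajectorySet,
    exposure_range: tuple[float, float] = (0.0, 40.0),
) -> tuple[np.ndarray, np.ndarray, float]:
    """Accumulated motion as RMSD over trajectories versus exposure.

    Each movie's displacement is measured from its position at the start of
    the exposure range; the RMSD across movies is evaluated at every frame
    in the range.  Returns ``(exposures, rmsd_A, rmsd_at_range_end)``.
    """
    if not trajs.positions_A:
        raise ValueError("empty trajectory set")
    e0, e1 = exposure_range
    if e1 <= e0:
        raise ValueError("exposure range must be increasing")
    per = trajs.exposure_per_frame
    n_frames = min(len(v) for v in trajs.positions_A.values())
    total = n_frames * per
    if e0 >= total:
        raise ValueError(f"range start {e0} beyond total exposure {total}")
    i0 = int(np.floor(e0 / per))
    i1 = min(int(np.ceil(e1 / per)), n_frames - 1)
    disp_sq = []
    for pos in trajs.positions_A.values():
        d = pos[i0:i1 + 1] - pos[i0]
        disp_sq.append(np.sum(d**2, axis=1))
    disp_sq = np.array(disp_sq)  # (movies, frames in range)
    rmsd = np.sqrt(disp_sq.mean(axis=0))
    exposures = (np.arange(i0, i1 + 1) - i0) * per + e0
    return exposures, rmsd, float(rmsd[-1])


@dataclass(frozen=True)
class TrajectoryGroupStats:
    group: str
    mean_angle_deg: float
    circular_dispersion: float  # 1 - R, in [0, 1]
    n_movies: int


def group_trajectories(
    trajs: MotionTrajectorySet, by: str = "shot_position"
) -> list[TrajectoryGroupStats]:
    """Circular mean direction and dispersion of net displacements per group.

    The net displacement of each movie defines an angle; groups (by chip or
    beam-image-shift position) are summarised by the circular mean angle and
    the circular dispersion 1 - R (0 for perfectly aligned trajectories,
    and 0 by convention for single-movie groups).
    """
    if by not in ("chip", "shot_position"):
        raise ValueError(f"unknown grouping {by!r}")
    if trajs.labels.empty or by not in trajs.labels.columns:
        raise ValueError(f"trajectory set carries no {by!r} labels")
    out = []
    for group, idx in trajs.labels.groupby(by).groups.items():
        angles = []
        for mid in idx:
            pos = trajs.positions_A[str(mid)]
            net = pos[-1] - pos[0]
            angles.append(np.arctan2(net[1], net[0]))
        angles = np.array(angles)
        z = np.exp(1j * angles).mean()
        mean_angle = float(np.degrees(np.angle(z)))
        dispersion = 0.0 if len(angles) == 1 else float(1.0 - np.abs(z))
        out.append(TrajectoryGroupStats(str(group), mean_angle, dispersion, len(angles)))
    return sorted(out, key=lambda g: g.group)
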