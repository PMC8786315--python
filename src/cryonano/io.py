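"""Readers, writers, run configuration and the pipeline driver.

Images move through MRC (float32, pixel size in the header) and TIFF;
tabular data through headered CSV (comma separator, '.' decimal).  A run
configuration (YAML or JSON) is schema-validated with unknown keys
rejected, and ``run_pipeline`` executes the requested stages in dependency
order, logging seed, versions and every clamp/drop counter.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import mrcfile
import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .capillary import MeniscusTrace, bootstrap_washburn, mean_filling_speed
from .geometry import (
    ChannelGeometry,
    MicrochannelGeometry,
    microchannel_volume,
    nanochannel_volume,
    total_filling_volume,
)
from .thickness import ScatteringCalibration
from .vitrify import (
    CoolantProps,
    MaterialProps,
    film_heat_transfer_coeff,
    fd_cooling_profile,
    lumped_cooling_time,
    SILICON_NITRIDE,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_image",
    "write_mrc",
    "write_tiff",
    "read_trace_csv",
    "write_trace_csv",
    "RunConfig",
    "load_config",
    "run_pipeline",
]


class FormatError(ValueError):
    """File is not a valid image of the expected format."""


def read_image(path, format: str | None = None):
    """Read an MRC or TIFF image (stack).

    Returns ``(array, pixel_size)``: arrays are (row, col) or (frame, row,
    col); pixel size (A for MRC, None for TIFF without metadata) comes from
    the header when present.  The format is inferred from magic bytes when
    not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        with open(path, "rb") as fh:
            head = fh.read(4)
        if head[:2] in (b"II", b"MM"):
            format = "tiff"
        else:
            format = "mrc"
    if format == "tiff":
        try:
            data = tifffile.imread(path)
        except Exception as exc:
            raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
        return np.asarray(data), None
    if format == "mrc":
        try:
            with mrcfile.open(path, permissive=False) as mrc:
                data = np.asarray(mrc.data)
                px = float(mrc.voxel_size.x) if mrc.voxel_size.x else None
        except Exception as exc:
            raise FormatError(f"{path}: not a valid MRC file ({exc})") from exc
        return data, px
    raise ValueError(f"unknown format {format!r}")


def write_mrc(path, array, pixel_size_A: float | None = None) -> None:
    """Write a float32 (mode 2) MRC file with the pixel size in the header."""
    with mrcfile.new(str(path), overwrite=True) as mrc:
        mrc.set_data(np.asarray(array, dtype=np.float32))
        if pixel_size_A:
            mrc.voxel_size = pixel_size_A


def write_tiff(path, array) -> None:
    tifffile.imwrite(str(path), np.asarray(array))


def read_trace_csv(path) -> MeniscusTrace:
    df = pd.read_csv(path)
    return MeniscusTrace(df["time_s"].to_numpy(), df["position_um"].to_numpy())


def write_trace_csv(path, trace: MeniscusTrace) -> None:
    pd.DataFrame({"time_s": trace.times_s, "position_um": trace.positions_um}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Run configuration


class GeometryBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    width_nm: float = 750.0
    height_nm: float = 100.0
    length_um: float = 50.0
    n_channels: int = 5
    profile: str = "sagged_parabolic"

    def build(self) -> ChannelGeometry:
        return ChannelGeometry(
            width_nm=self.width_nm, max_height_nm=self.height_nm,
            length_um=self.length_um, n_channels=self.n_channels,
            profile=self.profile,
        )


class MicrochannelBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    length_um: float = 1000.0
    width_um: float = 4.0
    height_um: float = 0.4

    def build(self) -> MicrochannelGeometry:
        return MicrochannelGeometry(self.length_um, self.width_um, self.height_um)


class CalibrationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lambda_ice_nm: float = 320.0
    lambda_sin_nm: float = 163.0
    t_sin_total_nm: float = 19.0
    sin_logratio_ref: float = 0.89

    def build(self) -> ScatteringCalibration:
        return ScatteringCalibration(
            lambda_ice_nm=self.lambda_ice_nm, lambda_sin_nm=self.lambda_sin_nm,
            t_sin_total_nm=self.t_sin_total_nm, sin_logratio_ref=self.sin_logratio_ref,
        )


class MaterialBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    density: float
    cp: float
    k: float

    def build(self) -> MaterialProps:
        return MaterialProps(self.name, self.density, self.cp, self.k)


class CoolantBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    density: float = 650.0
    viscosity: float = 1.2e-3
    k: float = 0.25
    cp: float = 2300.0
    T_inf_K: float = 90.0
    velocity: float = 1.5
    plate_length: float = 2e-3

    def build(self) -> CoolantProps:
        return CoolantProps(**self.model_dump())


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    stages: list[str] = Field(default_factory=lambda: ["volume"])
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    entry_microchannel: MicrochannelBlock = Field(default_factory=MicrochannelBlock)
    exit_microchannel: MicrochannelBlock = Field(default_factory=MicrochannelBlock)
    calibration: CalibrationBlock = Field(default_factory=CalibrationBlock)
    coolant: CoolantBlock = Field(default_factory=CoolantBlock)
    membrane_thickness_m: float = 20e-9
    seed: int = 0
    trace_csv: str | None = None
    unfiltered_path: str | None = None
    zeroloss_path: str | None = None
    output_dir: str = "cryonano_out"


def load_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(data)


KNOWN_STAGES = ("volume", "cooling", "filling", "thickness")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write a JSON report bundle.

    Stages: ``volume`` (channel volumetrics), ``cooling`` (film coefficient
    + lumped membrane cooling + finite-difference profile), ``filling``
    (Washburn fit of a meniscus trace CSV), ``thickness`` (thickness maps
    from an image pair on disk).  Any stage error aborts with the stage
    named; missing inputs are caught before computation starts.
    """
    for stage in config.stages:
        if stage not in KNOWN_STAGES:
            raise ValueError(f"unknown stage {stage!r}; known: {KNOWN_STAGES}")
    # pre-flight: check all referenced inputs exist before running anything
    if "filling" in config.stages:
        if not config.trace_csv or not Path(config.trace_csv).exists():
            raise FileNotFoundError(f"filling stage needs trace_csv, got {config.trace_csv}")
    if "thickness" in config.stages:
        for key in ("unfiltered_path", "zeroloss_path"):
            p = getattr(config, key)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"thickness stage needs {key}, got {p}")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    for stage in config.stages:
        logger.info("running stage %s", stage)
        try:
            if stage == "volume":
                nano = config.geometry.build()
                entry = config.entry_microchannel.build()
                exit_ = config.exit_microchannel.build()
                report["stages"]["volume"] = {
                    "nanochannel_fL": nanochannel_volume(nano),
                    "per_channel_fL": nanochannel_volume(nano, per_channel=True),
                    "entry_pL": microchannel_volume(entry),
                    "exit_pL": microchannel_volume(exit_),
                    "total_pL": total_filling_volume(entry, exit_, nano),
                    "total_unrounded_pL": total_filling_volume(
                        entry, exit_, nano, rounding="none"
                    ),
                }
            elif stage == "cooling":
                coolant = config.coolant.build()
                h = film_heat_transfer_coeff(coolant)
                t_lumped = lumped_cooling_time(
                    config.membrane_thickness_m, SILICON_NITRIDE, h,
                    T_inf_K=coolant.T_inf_K,
                )
                fd = fd_cooling_profile(h=h, coolant=coolant)
                pd.DataFrame({
                    "time_s": fd.times_s,
                    "T_membrane_K": fd.temperatures_K[:, fd.extras["probe_idx"]],
                    "T_base_K": fd.temperatures_K[:, 0],
                }).to_csv(outdir / "cooling.csv", index=False)
                report["stages"]["cooling"] = {
                    "h_W_m2K": h,
                    "biot_membrane": h * config.membrane_thickness_m / SILICON_NITRIDE.k,
                    "lumped_time_below_Tg_s": t_lumped,
                    "fd_time_below_Tg_s": fd.time_below_Tg_s,
                }
            elif stage == "filling":
                trace = read_trace_csv(config.trace_csv)
                fit = bootstrap_washburn(trace, seed=config.seed)
                report["stages"]["filling"] = {
                    "a_um_per_sqrt_s": fit.a, "b_s": fit.b, "c_um": fit.c,
                    "a_sd": fit.a_sd, "b_sd": fit.b_sd, "c_sd": fit.c_sd,
                    "n_boot": fit.n_boot,
                    "mean_speed_mm_s": mean_filling_speed(trace),
                }
            elif stage == "thickness":
                from .thickness import (
                    EftemImagePair, align_pair, ice_thickness_map, wet_map,
                )
                unf, px = read_image(config.unfiltered_path)
                zl, _ = read_image(config.zeroloss_path)
                pair = EftemImagePair(unf, zl, pixel_size_A=px or 1.0)
                pair = align_pair(pair)
                cal = config.calibration.build()
                tmap = ice_thickness_map(wet_map(pair, cal), cal)
                write_mrc(outdir / "wet_nm.mrc", tmap.wet_nm, tmap.pixel_size_A)
                write_mrc(outdir / "it_nm.mrc", tmap.it_nm, tmap.pixel_size_A)
                report["stages"]["thickness"] = {
                    "n_clamped_wet": tmap.n_clamped_wet,
                    "n_clamped_it": tmap.n_clamped_it,
                    "n_invalid": tmap.n_invalid,
                    "max_it_nm": float(np.max(tmap.it_nm)),
                }
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
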