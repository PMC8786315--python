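"""Nanochannel and microchannel geometry: thickness profiles and filling volumes.

The sample support encloses liquid in parallel nanochannels whose top
membrane sags smoothly onto the flat bottom membrane, touching at the
channel centerline.  The liquid layer therefore has zero thickness at the
center and reaches the nominal channel height ``H`` at the side walls.
With the lateral offset ``x`` measured from the centerline and the channel
width ``w``, the sagged-parabolic thickness profile is

    t(x) = H * (2 x / w)**2,    |x| <= w / 2.

Volumes follow from integrating the profile along the channel: a
sagged-parabolic channel of length ``L`` holds ``L * w * H / 3`` (one third
of the bounding box), a rectangular channel the full box.  Supply and exit
microchannels are treated as plain boxes.

Unit conventions are fixed: transverse dimensions in nm, channel lengths in
µm, nanochannel volumes in fL, microchannel volumes in pL.  Public names
carry their units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "ChannelGeometry",
    "MicrochannelGeometry",
    "thickness_profile",
    "nanochannel_volume",
    "microchannel_volume",
    "total_filling_volume",
]

#: nm^3 per femtoliter (1 fL = 1 µm^3 = 1e9 nm^3)
NM3_PER_FL = 1e9
#: µm^3 per picoliter (1 pL = 1e-15 m^3 = 1e3 µm^3)
UM3_PER_PL = 1e3

Profile = Literal["sagged_parabolic", "rectangular"]


class OutOfChannelError(ValueError):
    """Lateral offset lies outside the channel walls."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Observation nanochannel: sagged membrane over a flat base.

    Parameters
    ----------
    width_nm : float
        Channel width w (wall to wall), nm.  Typical devices range
        650–1000 nm between chips; the default is 750 nm.
    max_height_nm : float
        Maximum liquid thickness H at the channel wall, nm.
    length_um : float
        Channel length L, µm.
    n_channels : int
        Number of parallel nanochannels on the observation membrane.
    profile : {"sagged_parabolic", "rectangular"}
        Cross-sectional thickness model.
    """

    width_nm: float = 750.0
    max_height_nm: float = 100.0
    length_um: float = 50.0
    n_channels: int = 5
    profile: Profile = "sagged_parabolic"

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError(f"width_nm must be > 0, got {self.width_nm}")
        if self.max_height_nm <= 0:
            raise ValueError(f"max_height_nm must be > 0, got {self.max_height_nm}")
        if self.length_um <= 0:
            raise ValueError(f"length_um must be > 0, got {self.length_um}")
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.profile not in ("sagged_parabolic", "rectangular"):
            raise ValueError(f"unknown profile {self.profile!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelGeometry":
        return cls(
            width_nm=d["width_nm"],
            max_height_nm=d.get("height_nm", d.get("max_height_nm")),
            length_um=d["length_um"],
            n_channels=d.get("n_channels", 1),
            profile=d.get("profile", "sagged_parabolic"),
        )

    def to_dict(self) -> dict:
        return {
            "width_nm": self.width_nm,
            "height_nm": self.max_height_nm,
            "length_um": self.length_um,
            "n_channels": self.n_channels,
            "profile": self.profile,
        }


@dataclass(frozen=True)
class MicrochannelGeometry:
    """Supply/exit microchannel modelled as a rectangular box (all µm)."""

    length_um: float
    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        for name in ("length_um", "width_um", "height_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


def thickness_profile(geom: ChannelGeometry, x_nm):
    """Liquid thickness (nm) at lateral offset ``x_nm`` from the centerline.

    Accepts scalars or arrays.  Raises :class:`OutOfChannelError` if any
    offset lies outside ``[-w/2, w/2]``.
    """
    x = np.asarray(x_nm, dtype=float)
    half_w = geom.width_nm / 2.0
    if np.any(np.abs(x) > half_w):
        raise OutOfChannelError(
            f"offset outside channel: |x| > {half_w:g} nm (w = {geom.width_nm:g} nm)"
        )
    if geom.profile == "rectangular":
        t = np.full_like(x, geom.max_height_nm)
    else:
        t = geom.max_height_nm * (2.0 * x / geom.width_nm) ** 2
    return t.item() if np.isscalar(x_nm) else t


def nanochannel_volume(geom: ChannelGeometry, *, per_channel: bool = False) -> float:
    """Liquid volume of the nanochannels in femtoliters.

    Per channel this is ``L * integral of t(x) dx`` over the width, which is
    ``L*w*H/3`` for the sagged-parabolic profile and ``L*w*H`` for the
    rectangular one; the aggregate multiplies by ``n_channels``.
    """
    if geom.profile == "sagged_parabolic":
        area_nm2 = geom.width_nm * geom.max_height_nm / 3.0
    else:
        area_nm2 = geom.width_nm * geom.max_height_nm
    vol_nm3 = area_nm2 * geom.length_um * 1e3  # µm -> nm
    vol_fl = vol_nm3 / NM3_PER_FL
    return vol_fl if per_channel else vol_fl * geom.n_channels


def microchannel_volume(
    geom: MicrochannelGeometry, rounding: Literal["none", "nearest_pL"] = "none"
) -> float:
    """Box volume of a microchannel in picoliters, optionally rounded.

    ``rounding="nearest_pL"`` reproduces the convention of quoting supply
    and exit channel volumes to the nearest picoliter before summing.
    """
    vol_pl = geom.length_um * geom.width_um * geom.height_um / UM3_PER_PL
    if rounding == "nearest_pL":
        return float(round(vol_pl))
    if rounding != "none":
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return vol_pl


def total_filling_volume(
    entry: MicrochannelGeometry,
    exit: MicrochannelGeometry,
    nano: ChannelGeometry,
    rounding: Literal["none", "nearest_pL"] = "nearest_pL",
) -> float:
    """Total liquid volume (pL) drawn in when entry + exit microchannels and
    all nanochannels fill.

    With ``rounding="nearest_pL"`` each microchannel term is rounded to the
    nearest picoliter before summing, matching the convention under which a
    1.6 pL supply channel is quoted as ~2 pL and the total as ~4 pL.
    """
    v_entry = microchannel_volume(entry, rounding)
    v_exit = microchannel_volume(exit, rounding)
    v_nano_pl = nanochannel_volume(nano) / 1e3  # fL -> pL
    return v_entry + v_exit + v_nano_pl
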