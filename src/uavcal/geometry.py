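"""Viewing geometry: view zenith angle, ground sample distance, ROI scaling.

A nadir-pointing, gimbal-stabilized camera over flat terrain is assumed.
A ground target horizontally offset x meters from the nadir point is seen
at view zenith angle (VZA) alpha = arctan(x / H) for flying altitude H; a
target at the horizontal image edge sits at alpha = fov_h / 2 at every
altitude.  The horizontal ground sample distance is the footprint width
divided by the pixel count, GSD = 2 H tan(fov_h / 2) / image_width, so ROIs
drawn at one altitude are rescaled by the altitude ratio to cover the same
ground area at another.

The altitude-sensitivity summary STD/STDR uses the population standard
deviation of plot reflectance over all flown altitudes, normalized by the
reflectance at a reference (near-nadir, highest) altitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sensor import CameraProfile


@dataclass(frozen=True)
class ViewGeometry:
    """Flying altitude H (m), horizontal target offset x (m) and the camera."""

    altitude: float
    ground_offset: float
    camera: CameraProfile

    def __post_init__(self) -> None:
        if self.altitude <= 0:
            raise ValueError(f"altitude must be > 0, got {self.altitude}")
        if self.ground_offset < 0:
            raise ValueError("ground offset must be >= 0")


def view_zenith_angle(geom: ViewGeometry) -> float:
    """VZA in degrees: arctan(x / H), in [0, 90)."""
    return math.degrees(math.atan2(geom.ground_offset, geom.altitude))


def edge_offset(altitude: float, camera: CameraProfile) -> float:
    """Ground offset of the horizontal image edge: H * tan(fov_h / 2)."""
    return altitude * math.tan(math.radians(camera.fov_h / 2.0))


def vza_profile(
    ground_offset: float, altitudes, camera: CameraProfile
) -> np.ndarray:
    """VZA (degrees) of a fixed ground target over a list of altitudes."""
    alts = np.asarray(list(altitudes), dtype=float)
    if alts.size == 0:
        raise ValueError("empty altitude list")
    if np.any(alts <= 0):
        raise ValueError("altitudes must be > 0")
    return np.degrees(np.arctan2(ground_offset, alts))


def ground_sample_distance(altitude: float, camera: CameraProfile) -> float:
    """Horizontal GSD in m/pixel; strictly linear in altitude."""
    if altitude <= 0:
        raise ValueError(f"altitude must be > 0, got {altitude}")
    footprint = 2.0 * altitude * math.tan(math.radians(camera.fov_h / 2.0))
    return footprint / camera.image_width


def _round_half_away(v: float) -> int:
    return int(math.floor(v + 0.5)) if v >= 0 else -int(math.floor(-v + 0.5))


def scale_roi(
    roi: tuple[int, int, int, int], h_ref: float, h_new: float
) -> tuple[int, int, int, int]:
    """Rescale a half-open pixel ROI so it covers the same ground area.

    Each pixel dimension is scaled by h_ref / h_new (GSD grows with
    altitude), rounded to the nearest integer (ties away from zero) with a
    1 px floor; the ROI center is preserved.
    """
    r0, c0, r1, c1 = roi
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"degenerate ROI {roi}")
    if h_ref <= 0 or h_new <= 0:
        raise ValueError("altitudes must be > 0")
    scale = h_ref / h_new
    out = []
    for lo, hi in ((r0, r1), (c0, c1)):
        size = max(1, _round_half_away((hi - lo) * scale))
        center = (lo + hi) / 2.0
        new_lo = _round_half_away(center - size / 2.0)
        out.append((new_lo, new_lo + size))
    (nr0, nr1), (nc0, nc1) = out
    return nr0, nc0, nr1, nc1


def stdr_sensitivity(
    reflectance_by_altitude: dict[float, np.ndarray],
    reference_altitude: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-band (STD, STDR) of plot reflectance across altitudes.

    STD is the population standard deviation over altitudes; STDR divides
    it by the reflectance at the reference (near-nadir) altitude.
    """
    if len(reflectance_by_altitude) < 2:
        raise ValueError("need reflectance at >= 2 altitudes")
    if reference_altitude not in reflectance_by_altitude:
        raise ValueError(f"reference altitude {reference_altitude} not present")
    series = np.vstack([
        np.atleast_1d(np.asarray(v, dtype=float))
        for _, v in sorted(reflectance_by_altitude.items())
    ])  # (n_altitudes, n_bands)
    std = series.std(axis=0, ddof=0)
    ref = np.atleast_1d(np.asarray(
        reflectance_by_altitude[reference_altitude], dtype=float
    ))
    if np.any(ref == 0.0):
        raise ValueError("reference reflectance contains zeros; STDR undefined")
    return std, std / ref
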