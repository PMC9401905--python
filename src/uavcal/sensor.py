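"""Camera model and band-equivalent reflectance convolution.

The reference sensor is a 12-lens multispectral camera (Mini-MCA12 class)
with band centers from 490 to 950 nm, 1280 x 1024 px images and a
horizontal/vertical field of view of 38.26deg / 30.97deg.  Field-spectrometer
reflectance R(lambda) is converted to camera-equivalent band reflectance by
weighting with the band's spectral response S_j(lambda):

    R_j = int_s^e R(lambda) S_j(lambda) dlambda / int_s^e S_j(lambda) dlambda

evaluated on the union of the spectrum and response sample grids with a
quadrature that is exact for piecewise-linear inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("uavcal")

#: Center wavelengths (nm) of the reference 12-band camera, ascending.
DEFAULT_BAND_CENTERS: tuple[float, ...] = (
    490.0, 520.0, 550.0, 570.0, 670.0, 680.0,
    700.0, 720.0, 800.0, 850.0, 900.0, 950.0,
)

#: Default synthetic response width used when no measured response exists.
DEFAULT_RESPONSE_FWHM_NM = 10.0


class CoverageError(ValueError):
    """Spectrum does not cover the support of a band response."""


class DegenerateResponseError(ValueError):
    """Band response integrates to zero over its support."""


def gaussian_response(
    center: float,
    fwhm: float = DEFAULT_RESPONSE_FWHM_NM,
    n_sigma: float = 4.0,
    step: float = 0.5,
) -> np.ndarray:
    """Synthesize a Gaussian spectral response sampled every ``step`` nm.

    Used as a stand-in when the sensor's measured response functions are
    unavailable; the true Mini-MCA responses are not public.  Returns an
    (n, 2) array of (wavelength_nm, weight).
    """
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    half = n_sigma * sigma
    wl = np.arange(center - half, center + half + step / 2, step)
    w = np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    return np.column_stack([wl, w])


@dataclass(frozen=True)
class Band:
    """One camera band: 1-based index, center wavelength and optional response.

    ``response`` is an (n, 2) array of (wavelength_nm, weight >= 0) samples;
    the response is linearly interpolated between samples and zero outside
    its support [s, e].
    """

    index: int
    center: float
    response: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"band index must be 1-based, got {self.index}")
        if self.response is not None:
            r = np.asarray(self.response, dtype=float)
            if r.ndim != 2 or r.shape[1] != 2 or r.shape[0] < 2:
                raise ValueError("response must be an (n>=2, 2) array")
            if np.any(np.diff(r[:, 0]) <= 0):
                raise ValueError("response wavelengths must be strictly increasing")
            if np.any(r[:, 1] < 0):
                raise ValueError("response weights must be non-negative")
            object.__setattr__(self, "response", r)

    @property
    def support(self) -> tuple[float, float]:
        if self.response is None:
            raise ValueError(f"band {self.index} has no response")
        return float(self.response[0, 0]), float(self.response[-1, 0])

    def with_synthetic_response(
        self, fwhm: float = DEFAULT_RESPONSE_FWHM_NM
    ) -> "Band":
        """Return a copy carrying a synthetic Gaussian response."""
        logger.info(
            "band %d (%.0f nm): synthesizing Gaussian response (FWHM %.1f nm); "
            "this is a synthetic stand-in, not a measured response",
            self.index, self.center, fwhm,
        )
        return Band(self.index, self.center, gaussian_response(self.center, fwhm))


@dataclass(frozen=True)
class BandSet:
    """Ordered camera bands with strictly increasing center wavelengths."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        centers = [b.center for b in self.bands]
        if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
            raise ValueError("band centers must be strictly increasing")
        idx = [b.index for b in self.bands]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("band indices must be 1..n in order")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bands])

    def band_at(self, center: float) -> Band:
        for b in self.bands:
            if b.center == center:
                return b
        raise KeyError(f"no band centered at {center} nm")

    def with_responses(self, fwhm: float = DEFAULT_RESPONSE_FWHM_NM) -> "BandSet":
        """Fill any missing responses with synthetic Gaussians."""
        return BandSet(tuple(
            b if b.response is not None else b.with_synthetic_response(fwhm)
            for b in self.bands
        ))

    @classmethod
    def reference(cls, with_responses: bool = False) -> "BandSet":
        """The 12-band reference camera profile (490-950 nm)."""
        bs = cls(tuple(
            Band(i + 1, c) for i, c in enumerate(DEFAULT_BAND_CENTERS)
        ))
        return bs.with_responses() if with_responses else bs


@dataclass(frozen=True)
class CameraProfile:
    """Sensor geometry: band set, image dimensions and field of view."""

    band_set: BandSet
    image_width: int = 1280
    image_height: int = 1024
    fov_h: float = 38.26
    fov_v: float = 30.97

    def __post_init__(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        for f in (self.fov_h, self.fov_v):
            if not 0.0 < f < 180.0:
                raise ValueError(f"FOV must be in (0, 180) degrees, got {f}")

    @classmethod
    def reference(cls, with_responses: bool = False) -> "CameraProfile":
        return cls(band_set=BandSet.reference(with_responses=with_responses))

    @property
    def n_bands(self) -> int:
        return len(self.band_set)


@dataclass(frozen=True)
class HyperspectralSpectrum:
    """A wavelength-reflectance table, e.g. a field-spectrometer reading.

    Reflectance is a fraction; values slightly above 1 are tolerated
    (specular glint) up to 1.5.
    """

    samples: np.ndarray  # (n, 2): wavelength_nm, reflectance

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 2 or s.shape[0] < 2:
            raise ValueError("spectrum must be an (n>=2, 2) array")
        if np.any(np.diff(s[:, 0]) <= 0):
            raise ValueError("spectrum wavelengths must be strictly increasing")
        if np.any(s[:, 1] < 0) or np.any(s[:, 1] > 1.5):
            raise ValueError("reflectance must lie in [0, 1.5]")
        object.__setattr__(self, "samples", s)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def values(self) -> np.ndarray:
        return self.samples[:, 1]

    @classmethod
    def from_arrays(cls, wavelengths, values) -> "HyperspectralSpectrum":
        return cls(np.column_stack([wavelengths, values]))

    @classmethod
    def constant(cls, value: float, lo: float = 350.0, hi: float = 1100.0
                 ) -> "HyperspectralSpectrum":
        return cls.from_arrays([lo, hi], [value, value])


def band_equivalent_reflectance(
    spectrum: HyperspectralSpectrum, band: Band
) -> float:
    """Response-weighted mean reflectance for one band.

    Both curves are treated as piecewise linear on the union of their
    wavelength grids (the response is zero outside its support).  On each
    union segment the product R*S is quadratic, so the numerator is
    integrated with the segment-exact rule
    h/6 * (r0*(2*w0 + w1) + r1*(w0 + 2*w1)) and the denominator with the
    trapezoid rule (exact for the linear S) — the quadrature is therefore
    exact for piecewise-linear inputs.
    """
    if band.response is None:
        raise ValueError(f"band {band.index} has no spectral response")
    s, e = band.support
    wl_sp = spectrum.wavelengths
    if wl_sp[0] > s or wl_sp[-1] < e:
        raise CoverageError(
            f"spectrum [{wl_sp[0]:g}, {wl_sp[-1]:g}] nm does not cover band "
            f"{band.index} support [{s:g}, {e:g}] nm"
        )
    grid = np.union1d(wl_sp, band.response[:, 0])
    grid = grid[(grid >= s) & (grid <= e)]
    r = np.interp(grid, wl_sp, spectrum.values)
    w = np.interp(grid, band.response[:, 0], band.response[:, 1])
    denom = np.trapezoid(w, grid)
    if denom <= 0.0:
        raise DegenerateResponseError(
            f"band {band.index} response integrates to zero"
        )
    h = np.diff(grid)
    r0, r1 = r[:-1], r[1:]
    w0, w1 = w[:-1], w[1:]
    num = float(np.sum(h / 6.0 * (r0 * (2 * w0 + w1) + r1 * (w0 + 2 * w1))))
    return num / denom


def convolve_all_bands(
    spectrum: HyperspectralSpectrum, camera: CameraProfile
) -> np.ndarray:
    """Camera-equivalent reflectance for every band, ordered by band index.

    Raises a single ValueError naming every band that lacks a response.
    """
    missing = [b.index for b in camera.band_set if b.response is None]
    if missing:
        raise ValueError(f"bands without spectral response: {missing}")
    return np.array([
        band_equivalent_reflectance(spectrum, b) for b in camera.band_set
    ])
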