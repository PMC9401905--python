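"""Vegetation indices from calibrated band reflectance.

Nine indices commonly used for rice growth monitoring and yield prediction
are implemented over a configurable band assignment.  Division by zero
yields NaN (counted in diagnostics), never an exception, so whole-image
index maps always complete.

Formulas (N = NIR, R = red, G = green, B = blue, RE = 720 nm red edge,
R700/R670/R550 = reflectance at those centers):

    RVI        = N / R
    NDVI       = (N - R) / (N + R)
    NDRE       = (N - RE) / (N + RE)
    VARI       = (G - R) / (G + R - B)
    EVI2       = 2.5 (N - R) / (N + 2.4 R + 1)
    CI_rededge = N / RE - 1
    CI_green   = N / G - 1
    MCARI      = [(R700 - R670) - 0.2 (R700 - R550)] * (R700 / R670)
    WDRVI      = (a N - R) / (a N + R),  default a = 0.1
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Wavelengths the reference camera allows for the red and NIR slots.
ALLOWED_RED = (670.0, 680.0)
ALLOWED_NIR = (800.0, 850.0, 900.0, 950.0)

INDEX_NAMES = (
    "RVI", "NDVI", "NDRE", "VARI", "EVI2",
    "CI_rededge", "CI_green", "MCARI", "WDRVI",
)

DEFAULT_WDRVI_ALPHA = 0.1


@dataclass(frozen=True)
class BandAssignment:
    """Maps semantic band roles to center wavelengths of the camera."""

    blue: float = 490.0
    green: float = 550.0
    red: float = 670.0
    rededge700: float = 700.0
    rededge720: float = 720.0
    nir: float = 800.0

    def __post_init__(self) -> None:
        if self.red not in ALLOWED_RED:
            raise ValueError(f"red must be one of {ALLOWED_RED}, got {self.red}")
        if self.nir not in ALLOWED_NIR:
            raise ValueError(f"nir must be one of {ALLOWED_NIR}, got {self.nir}")

    def validate_against(self, centers) -> None:
        centers = set(float(c) for c in centers)
        for role in ("blue", "green", "red", "rededge700", "rededge720", "nir"):
            c = getattr(self, role)
            if c not in centers:
                raise ValueError(f"{role} -> {c} nm is not a camera band")


def _bands(reflectance: dict[float, np.ndarray], *centers: float):
    out = []
    for c in centers:
        if c not in reflectance:
            raise KeyError(f"missing band {c} nm in reflectance input")
        out.append(np.asarray(reflectance[c], dtype=float))
    return out


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0.0, np.nan, num / np.where(den == 0.0, 1.0, den))
    return out


def compute_index(
    name: str,
    reflectance: dict[float, np.ndarray],
    assignment: BandAssignment | None = None,
    wdrvi_alpha: float = DEFAULT_WDRVI_ALPHA,
) -> np.ndarray:
    """Evaluate one index on reflectance keyed by band center (nm).

    Accepts scalars, vectors or image planes; broadcasting applies.
    """
    a = assignment or BandAssignment()
    if name == "RVI":
        n, r = _bands(reflectance, a.nir, a.red)
        return _safe_div(n, r)
    if name == "NDVI":
        n, r = _bands(reflectance, a.nir, a.red)
        return _safe_div(n - r, n + r)
    if name == "NDRE":
        n, re = _bands(reflectance, a.nir, a.rededge720)
        return _safe_div(n - re, n + re)
    if name == "VARI":
        g, r, b = _bands(reflectance, a.green, a.red, a.blue)
        return _safe_div(g - r, g + r - b)
    if name == "EVI2":
        n, r = _bands(reflectance, a.nir, a.red)
        return _safe_div(2.5 * (n - r), n + 2.4 * r + 1.0)
    if name == "CI_rededge":
        n, re = _bands(reflectance, a.nir, a.rededge720)
        return _safe_div(n, re) - 1.0
    if name == "CI_green":
        n, g = _bands(reflectance, a.nir, a.green)
        return _safe_div(n, g) - 1.0
    if name == "MCARI":
        # MCARI is defined on the 700/670/550 nm triplet regardless of the
        # red slot used by the broadband indices
        r700, r670, r550 = _bands(reflectance, a.rededge700, 670.0, 550.0)
        return ((r700 - r670) - 0.2 * (r700 - r550)) * _safe_div(r700, r670)
    if name == "WDRVI":
        n, r = _bands(reflectance, a.nir, a.red)
        return _safe_div(wdrvi_alpha * n - r, wdrvi_alpha * n + r)
    raise ValueError(f"unknown index {name!r}; known: {INDEX_NAMES}")


def compute_all(
    reflectance: dict[float, np.ndarray],
    assignment: BandAssignment | None = None,
    wdrvi_alpha: float = DEFAULT_WDRVI_ALPHA,
) -> dict[str, np.ndarray]:
    """All nine indices; NaN counts are available via count_nonfinite."""
    return {
        name: compute_index(name, reflectance, assignment, wdrvi_alpha)
        for name in INDEX_NAMES
    }


def count_nonfinite(values: np.ndarray) -> int:
    return int(np.sum(~np.isfinite(np.asarray(values, dtype=float))))


def reflectance_by_center(stack: np.ndarray, centers) -> dict[float, np.ndarray]:
    """Key a (bands, ...) stack by band-center wavelength."""
    stack = np.asarray(stack, dtype=float)
    centers = [float(c) for c in centers]
    if stack.shape[0] != len(centers):
        raise ValueError(
            f"stack has {stack.shape[0]} bands but {len(centers)} centers given"
        )
    return {c: stack[i] for i, c in enumerate(centers)}
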