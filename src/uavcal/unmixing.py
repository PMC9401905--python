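"""Fully constrained least-squares linear spectral unmixing (FCLS-LSM).

A mixed pixel's reflectance R is modeled as an abundance-weighted sum of
endmember spectra, R = sum_i A_i R_i + e, with the abundances constrained
to the simplex (0 <= A_i <= 1, sum A_i = 1).  The solver augments the
endmember matrix with a sum-to-one row scaled by a large weight and solves
the non-negative least-squares problem, which enforces both constraints to
tight tolerance without a QP dependency.

Background enhancement/attenuation factors summarize how much of a pixel
the four background endmembers (water and soil, lit and shaded) occupy:
the NIR attenuation factor is their total abundance, and the visible
enhancement factor is light_water + light_soil + shaded_soil - shaded_water.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

logger = logging.getLogger("uavcal")

#: Canonical endmember labels of a flooded-paddy scene, in order.
CANONICAL_LABELS = (
    "light_leaf", "shaded_leaf",
    "light_water", "shaded_water",
    "light_soil", "shaded_soil",
)
#: The subset regarded as background (non-canopy).
BACKGROUND_LABELS = ("light_water", "shaded_water", "light_soil", "shaded_soil")

#: Weight multiplier for the sum-to-one row in the augmented NNLS system.
SUM_TO_ONE_WEIGHT = 1e3
#: Constraint satisfaction tolerance guaranteed by the solver.
CONSTRAINT_TOL = 1e-8


@dataclass(frozen=True)
class EndmemberSet:
    """Labeled endmember spectra: (n_endmembers, n_bands) reflectance matrix."""

    labels: tuple[str, ...]
    spectra: np.ndarray
    background: tuple[str, ...] = BACKGROUND_LABELS

    def __post_init__(self) -> None:
        spectra = np.asarray(self.spectra, dtype=float)
        if spectra.ndim != 2 or spectra.shape[0] < 2:
            raise ValueError("need an (n>=2, bands) spectra matrix")
        if len(self.labels) != spectra.shape[0]:
            raise ValueError("labels/spectra length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("endmember labels must be unique")
        if not np.all(np.isfinite(spectra)) or np.any(spectra < 0):
            raise ValueError("endmember spectra must be finite and non-negative")
        if np.any(np.all(spectra == 0.0, axis=1)):
            raise ValueError("all-zero endmember spectrum")
        unknown = set(self.background) - set(self.labels)
        if unknown:
            raise ValueError(f"background labels not in set: {sorted(unknown)}")
        object.__setattr__(self, "spectra", spectra)
        cond = np.linalg.cond(spectra.T)
        if cond > 1e8:
            logger.warning(
                "endmember matrix is ill-conditioned (cond=%.3g); "
                "abundances may be unstable", cond,
            )

    @property
    def n_endmembers(self) -> int:
        return len(self.labels)

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no endmember labeled {label!r}") from None


@dataclass(frozen=True)
class AbundanceVector:
    """Simplex-constrained abundances plus the per-band RMS residual."""

    labels: tuple[str, ...]
    values: np.ndarray
    residual_norm: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < -CONSTRAINT_TOL) or np.any(v > 1 + CONSTRAINT_TOL):
            raise ValueError("abundances must lie in [0, 1] within tolerance")
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"abundances sum to {v.sum():.8f}, expected 1")
        object.__setattr__(self, "values", v)

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.labels.index(label)])

    def as_dict(self) -> dict[str, float]:
        return {lab: float(v) for lab, v in zip(self.labels, self.values)}


def fcls_unmix(pixel: np.ndarray, endmembers: EndmemberSet) -> AbundanceVector:
    """Solve min ||R - E^T A||_2 subject to A on the simplex for one pixel."""
    r = np.asarray(pixel, dtype=float).ravel()
    if r.size != endmembers.n_bands:
        raise ValueError(
            f"pixel has {r.size} bands, endmembers have {endmembers.n_bands}"
        )
    E = endmembers.spectra.T  # (bands, n)
    delta = SUM_TO_ONE_WEIGHT * float(np.max(np.linalg.norm(E, axis=0)))
    A_aug = np.vstack([E, delta * np.ones(endmembers.n_endmembers)])
    b_aug = np.append(r, delta)
    sol, _ = nnls(A_aug, b_aug)
    total = sol.sum()
    if total > 0:
        sol = sol / total  # remove the O(1/delta) sum defect exactly
    resid = E @ sol - r
    return AbundanceVector(
        endmembers.labels, sol, float(np.sqrt(np.mean(resid ** 2)))
    )


def unmix_image(
    reflectance: np.ndarray, endmembers: EndmemberSet
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel FCLS on a (bands, rows, cols) stack.

    Returns (abundance planes (n_endmembers, rows, cols), residual plane).
    """
    stack = np.asarray(reflectance, dtype=float)
    if stack.ndim != 3 or stack.shape[0] != endmembers.n_bands:
        raise ValueError(
            f"expected ({endmembers.n_bands}, rows, cols) stack, got {stack.shape}"
        )
    _, h, w = stack.shape
    planes = np.empty((endmembers.n_endmembers, h, w))
    residual = np.empty((h, w))
    flat = stack.reshape(stack.shape[0], -1)
    for k in range(flat.shape[1]):
        ab = fcls_unmix(flat[:, k], endmembers)
        planes[:, k // w, k % w] = ab.values
        residual[k // w, k % w] = ab.residual_norm
    return planes, residual


def background_factors(abundance: AbundanceVector) -> tuple[float, float]:
    """(NIR attenuation, visible enhancement) from the canonical six labels.

    attenuation = A_lw + A_sw + A_ls + A_ss            in [0, 1]
    enhancement = A_lw + A_ls + A_ss - A_sw            in [-1, 1]
    """
    missing = set(CANONICAL_LABELS) - set(abundance.labels)
    if missing:
        raise KeyError(f"missing canonical endmember labels: {sorted(missing)}")
    lw = abundance["light_water"]
    sw = abundance["shaded_water"]
    ls = abundance["light_soil"]
    ss = abundance["shaded_soil"]
    return lw + sw + ls + ss, lw + ls + ss - sw
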