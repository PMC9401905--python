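"""Synthetic multi-altitude scene generator with known ground truth.

Emulates a paddy-field UAV campaign at desk scale: a six-endmember
spectral library (lit/shaded leaf, water, soil), plot abundances that
respond to view zenith angle, eight grayscale calibration panels spanning
3-80% reflectance, per-band reflectance -> DN sensor transfer functions
(inverses of the affine, piecewise and power calibration models), and
linear VI-trait tables with additive Gaussian noise.  Every bundle stores
its ground truth so calibration, unmixing and regression code can be
tested closed-loop; all randomness flows from one explicit seed per call.

The altitude response follows the observed mechanism: a plot off nadir is
seen at VZA alpha = arctan(x/H); more background enters the footprint as
alpha grows, modeled as background fraction f = clip(f0 + g*tan(alpha),
0, 1).  Because leaf NIR reflectance exceeds every background's, plot-mean
NIR reflectance falls as background abundance rises while visible
reflectance rises — the trend the enhancement/attenuation factors track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationPanel, PEL_THRESHOLD
from .geometry import ground_sample_distance
from .sensor import BandSet, CameraProfile, DEFAULT_BAND_CENTERS
from .unmixing import CANONICAL_LABELS, EndmemberSet

#: Nominal reflectances of the eight grayscale panels (fractions).
DEFAULT_PANEL_REFLECTANCES = (0.03, 0.06, 0.12, 0.24, 0.36, 0.48, 0.56, 0.80)

#: Desk-scale camera: reference band set and FOV, reduced pixel count.
def scaled_camera(width: int = 160, height: int = 128) -> CameraProfile:
    return CameraProfile(
        band_set=BandSet.reference(), image_width=width, image_height=height,
    )


# ---------------------------------------------------------------------------
# endmember library

_LIGHT_TEMPLATES = {
    # 490   520   550   570   670   680   700   720   800   850   900   950
    "light_leaf": (0.040, 0.060, 0.100, 0.090, 0.050, 0.052, 0.120, 0.300,
                   0.500, 0.520, 0.530, 0.500),
    "light_water": (0.060, 0.055, 0.050, 0.048, 0.040, 0.038, 0.035, 0.030,
                    0.020, 0.016, 0.013, 0.010),
    "light_soil": (0.100, 0.120, 0.140, 0.150, 0.180, 0.190, 0.200, 0.210,
                   0.240, 0.260, 0.270, 0.280),
}

_NIR_SLICE = slice(8, 12)   # 800-950 nm
_RED_IDX = 4                # 670 nm


def make_endmembers(
    seed: int,
    shading_factor: float = 0.35,
    jitter: float = 0.08,
    shade_jitter: float = 0.1,
) -> EndmemberSet:
    """Six paddy endmembers with seed-controlled multiplicative jitter.

    Construction guarantees: leaf NIR reflectance above every background's
    NIR reflectance; leaf red reflectance below lit soil's; shaded spectra
    are the lit spectra scaled by a per-band factor around
    ``shading_factor`` (spread ``shade_jitter``) — the per-band spread
    keeps the endmember matrix full rank, since exactly proportional
    lit/shaded pairs make abundances non-identifiable.  With
    ``shading_factor=1`` the shaded spectra equal the lit ones exactly.
    """
    if not 0.0 < shading_factor <= 1.0:
        raise ValueError("shading factor must be in (0, 1]")
    rng = np.random.default_rng(seed)
    spectra = {}
    for label, template in _LIGHT_TEMPLATES.items():
        t = np.asarray(template)
        spectra[label] = t * rng.uniform(1 - jitter, 1 + jitter, size=t.size)
    for label in ("light_leaf", "light_water", "light_soil"):
        shaded = "shaded_" + label.split("_")[1]
        if shading_factor == 1.0:
            factors = np.ones(12)
        else:
            factors = np.clip(
                shading_factor
                * rng.uniform(1 - shade_jitter, 1 + shade_jitter, 12),
                1e-6, 1.0,
            )
        spectra[shaded] = spectra[label] * factors
    mat = np.vstack([spectra[lab] for lab in CANONICAL_LABELS])
    ems = EndmemberSet(CANONICAL_LABELS, mat)
    _check_endmember_constraints(ems)
    return ems


def _check_endmember_constraints(ems: EndmemberSet) -> None:
    leaf = ems.spectra[ems.index_of("light_leaf")]
    for lab in ("light_water", "shaded_water", "light_soil", "shaded_soil"):
        bg = ems.spectra[ems.index_of(lab)]
        if not np.all(leaf[_NIR_SLICE] > bg[_NIR_SLICE]):
            raise AssertionError(f"leaf NIR not above {lab} NIR")
    soil = ems.spectra[ems.index_of("light_soil")]
    if not leaf[_RED_IDX] < soil[_RED_IDX]:
        raise AssertionError("leaf red not below lit-soil red")


# ---------------------------------------------------------------------------
# sensor transfer (reflectance -> DN), inverses of the calibration models

@dataclass(frozen=True)
class SensorTransfer:
    """Per-band forward map reflectance -> DN.

    ``kind`` selects the inverse calibration model: ``affine`` inverts
    y = a*x + b; ``piecewise`` inverts the proportional-below-tau /
    affine-above form (a4, a5, b5, tau); ``power`` inverts the two-group
    model (power in visible bands 1-7, affine in bands 8-12).  Parameters
    are stored in the calibration direction (DN -> reflectance), so the
    forward map is their exact inverse; noise is additive Gaussian in DN,
    truncated at zero, applied by the scene renderer.
    """

    kind: str
    params: dict[str, np.ndarray]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("affine", "piecewise", "power"):
            raise ValueError(f"unknown transfer kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.kind == "piecewise":
            a4, a5, b5 = (self.params[k] for k in ("a4", "a5", "b5"))
            tau = self.params.get("tau", PEL_THRESHOLD)
            floor = self.params.get("floor", 0.06)
            # branch consistency: on the proportional segment (up to the
            # sensor-floor reflectance) the affine segment's prediction
            # must stay <= tau, and DN must increase across the boundary
            if np.any(a5 * (floor / a4) + b5 > tau + 1e-12):
                raise ValueError(
                    "inconsistent piecewise transfer: affine prediction "
                    "exceeds tau on the proportional segment"
                )
            if np.any((floor - b5) / a5 < floor / a4):
                raise ValueError(
                    "piecewise transfer is not monotone at the floor"
                )

    @property
    def n_bands(self) -> int:
        return len(next(iter(self.params.values())))

    def forward(self, reflectance: np.ndarray) -> np.ndarray:
        """Noiseless DN for a (bands, ...) reflectance array."""
        y = np.asarray(reflectance, dtype=float)
        shape = (self.n_bands,) + (1,) * (y.ndim - 1)
        if self.kind == "affine":
            a = self.params["a"].reshape(shape)
            b = self.params["b"].reshape(shape)
            return (y - b) / a
        if self.kind == "piecewise":
            a4 = self.params["a4"].reshape(shape)
            a5 = self.params["a5"].reshape(shape)
            b5 = self.params["b5"].reshape(shape)
            floor = self.params.get("floor", 0.06)
            return np.where(y <= floor, y / a4, (y - b5) / a5)
        # power: bands 1-7 invert y = a*x^b; bands 8-12 invert y = a*x + b
        a = self.params["a"].reshape(shape)
        b = self.params["b"].reshape(shape)
        low = np.zeros(shape, dtype=bool)
        low[:7] = True
        with np.errstate(invalid="ignore"):
            x_pow = np.power(np.maximum(y, 0.0) / a, 1.0 / b)
        return np.where(low, x_pow, (y - b) / a)

    @classmethod
    def affine(cls, n_bands: int = 12, noise_sd: float = 0.0,
               seed: int | None = None) -> "SensorTransfer":
        """Affine truth with small per-band slope jitter around 9e-4."""
        rng = np.random.default_rng(seed)
        a = 9e-4 * rng.uniform(0.9, 1.1, n_bands)
        b = rng.uniform(-0.03, -0.01, n_bands)
        return cls("affine", {"a": a, "b": b}, noise_sd)

    @classmethod
    def piecewise(cls, n_bands: int = 12, noise_sd: float = 0.0,
                  seed: int | None = None, tau: float = PEL_THRESHOLD,
                  floor: float = 0.06) -> "SensorTransfer":
        """Piecewise truth emulating a sensor floor.

        Reflectance up to ``floor`` (default 0.06, so the two darkest
        panels sit on it) maps proportionally through y = a4*x; brighter
        targets map through the affine segment, whose parameters are
        chosen so its prediction stays below tau on the whole
        proportional segment — the self-consistency the piecewise
        calibration's branch rule requires.
        """
        rng = np.random.default_rng(seed)
        a4 = 5e-4 * rng.uniform(0.95, 1.05, n_bands)
        a5 = 9e-4 * rng.uniform(0.95, 1.05, n_bands)
        b5 = tau - a5 * (floor / a4) - rng.uniform(0.0, 0.01, n_bands)
        return cls("piecewise",
                   {"a4": a4, "a5": a5, "b5": b5, "tau": tau, "floor": floor},
                   noise_sd)

    @classmethod
    def power(cls, n_bands: int = 12, noise_sd: float = 0.0,
              a: float = 0.001, b: float = 1.2) -> "SensorTransfer":
        """Two-group truth: y = a*x^b in bands 1-7, affine in bands 8-12."""
        av = np.full(n_bands, a)
        bv = np.full(n_bands, b)
        av[7:] = 9e-4
        bv[7:] = -0.02
        return cls("power", {"a": av, "b": bv}, noise_sd)


# ---------------------------------------------------------------------------
# scene specification and rendering

@dataclass(frozen=True)
class SceneSpec:
    """Study conditions for a multi-altitude synthetic campaign.

    Defaults mirror the reference field setup: the fourteen flight
    altitudes of the multi-altitude experiment (60-250 m), 1 m2 plots,
    the eight-panel grayscale ladder, and a background fraction that grows
    with tan(VZA) from its nadir value f0 at rate g.
    """

    altitudes: tuple[float, ...] = (
        60, 70, 80, 90, 100, 110, 120, 130, 150, 170, 190, 210, 230, 250,
    )
    n_plots: int = 4
    plot_size_m: float = 1.0
    plot_offsets_m: tuple[float, ...] | None = None  # ground offsets from nadir
    panel_reflectances: tuple[float, ...] = DEFAULT_PANEL_REFLECTANCES
    f0: float = 0.15          # background fraction at nadir
    g: float = 0.6            # background gain vs tan(VZA)
    leaf_light_ratio: float = 0.7
    background_weights: tuple[float, float, float, float] = (0.3, 0.2, 0.3, 0.2)
    water_margin_frac: float = 0.1  # open-water strip at the image bottom
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.altitudes) or not self.altitudes:
            raise ValueError("altitudes must be positive and non-empty")
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError("f0 must be in [0, 1]")
        if abs(sum(self.background_weights) - 1.0) > 1e-9:
            raise ValueError("background weights must sum to 1")
        if any(not 0 < p < 1 for p in self.panel_reflectances):
            raise ValueError("panel reflectances must be in (0, 1)")

    def offsets(self) -> np.ndarray:
        if self.plot_offsets_m is not None:
            return np.asarray(self.plot_offsets_m, dtype=float)
        # spread plots from near-nadir toward (not onto) the edge at 60 m
        h_min = min(self.altitudes)
        x_max = 0.8 * h_min * math.tan(math.radians(38.26 / 2.0))
        return np.linspace(2.0, x_max, self.n_plots)


@dataclass
class SceneBundle:
    """One altitude's rendered products plus ground truth."""

    altitude: float
    gsd: float
    dn_image: np.ndarray            # (bands, h, w) float DN
    true_reflectance: np.ndarray    # (bands, h, w); panel ROIs hold nominals
    true_abundance: np.ndarray      # (n_endmembers, h, w); undefined on panels
    panel_mask: np.ndarray          # (h, w) bool, True on panel pixels
    panels: list[CalibrationPanel]
    plot_rois: dict[str, tuple[int, int, int, int]]
    plot_vza: dict[str, float]
    plot_abundance: dict[str, np.ndarray]

    def plot_mean_reflectance(self, plot_id: str) -> np.ndarray:
        r0, c0, r1, c1 = self.plot_rois[plot_id]
        return self.true_reflectance[:, r0:r1, c0:c1].mean(axis=(1, 2))


def make_scene(
    spec: SceneSpec,
    transfer: SensorTransfer,
    endmembers: EndmemberSet | None = None,
    camera: CameraProfile | None = None,
) -> dict[float, SceneBundle]:
    """Render the campaign: one bundle per altitude, seed-reproducible."""
    camera = camera or scaled_camera()
    ems = endmembers if endmembers is not None else make_endmembers(spec.seed)
    if ems.n_bands != len(camera.band_set):
        raise ValueError("endmember band count does not match camera")
    rng = np.random.default_rng(spec.seed)
    offsets = spec.offsets()
    h, w = camera.image_height, camera.image_width
    n_bands = len(camera.band_set)

    # outside the plots the paddy is a fixed background mix; a strip of
    # open water along the bottom edge provides the scene's darkest pixels
    ambient = _abundance(spec, background_fraction=min(1.0, spec.f0 + 0.2))
    water = np.array([0.0, 0.0, 0.5, 0.5, 0.0, 0.0])

    bundles: dict[float, SceneBundle] = {}
    for alt in spec.altitudes:
        gsd = ground_sample_distance(alt, camera)
        plot_px = max(1, round(spec.plot_size_m / gsd))
        if plot_px > min(h, w) // 2:
            raise ValueError(
                f"plot ({plot_px}px) larger than half the footprint at {alt} m"
            )
        abundance = np.tile(ambient[:, None, None], (1, h, w)).astype(float)
        n_water_rows = int(round(spec.water_margin_frac * h))
        if n_water_rows:
            abundance[:, h - n_water_rows:, :] = water[:, None, None]
        plot_rois, plot_vza, plot_ab = {}, {}, {}
        for k, x in enumerate(offsets):
            vza = math.degrees(math.atan2(x, alt))
            f = float(np.clip(spec.f0 + spec.g * math.tan(math.radians(vza)),
                              0.0, 1.0))
            a_vec = _abundance(spec, background_fraction=f)
            col_c = w // 2 + int(round(x / gsd))
            row_c = h // 2
            r0 = row_c - plot_px // 2
            c0 = min(col_c - plot_px // 2, w - plot_px)
            roi = (r0, c0, r0 + plot_px, c0 + plot_px)
            if r0 < 0 or c0 < 0:
                raise ValueError(f"plot {k} falls outside the image at {alt} m")
            abundance[:, roi[0]:roi[2], roi[1]:roi[3]] = a_vec[:, None, None]
            pid = f"plot{k}"
            plot_rois[pid], plot_vza[pid], plot_ab[pid] = roi, vza, a_vec
        reflectance = np.einsum("eb,ehw->bhw",
                                ems.spectra, abundance, optimize=True)
        dn = transfer.forward(reflectance)
        if transfer.noise_sd > 0:
            dn = dn + rng.normal(0.0, transfer.noise_sd, dn.shape)
        dn = np.maximum(dn, 0.0)
        panels, panel_mask = _render_panels(
            spec, transfer, dn, reflectance, n_bands
        )
        bundles[alt] = SceneBundle(
            altitude=alt, gsd=gsd, dn_image=dn,
            true_reflectance=reflectance, true_abundance=abundance,
            panel_mask=panel_mask, panels=panels, plot_rois=plot_rois,
            plot_vza=plot_vza, plot_abundance=plot_ab,
        )
    return bundles


def _abundance(spec: SceneSpec, background_fraction: float) -> np.ndarray:
    """Six-endmember abundance vector for a given background fraction."""
    f = background_fraction
    leaf = 1.0 - f
    bw = np.asarray(spec.background_weights)
    return np.concatenate([
        [leaf * spec.leaf_light_ratio, leaf * (1 - spec.leaf_light_ratio)],
        f * bw,
    ])


def _render_panels(
    spec: SceneSpec,
    transfer: SensorTransfer,
    dn: np.ndarray,
    reflectance: np.ndarray,
    n_bands: int,
) -> tuple[list[CalibrationPanel], np.ndarray]:
    """Paint the grayscale panels noiseless at fixed pixel positions.

    Panels overwrite both the DN stack and the reflectance truth; the
    returned mask flags their pixels (abundance truth is undefined there).
    """
    panels = []
    mask = np.zeros(dn.shape[1:], dtype=bool)
    size, gap, row0 = 6, 2, 2
    for k, refl in enumerate(spec.panel_reflectances):
        c0 = 2 + k * (size + gap)
        roi = (row0, c0, row0 + size, c0 + size)
        panel_dn = transfer.forward(np.full((n_bands, 1, 1), refl))
        dn[:, roi[0]:roi[2], roi[1]:roi[3]] = panel_dn
        reflectance[:, roi[0]:roi[2], roi[1]:roi[3]] = refl
        mask[roi[0]:roi[2], roi[1]:roi[3]] = True
        panels.append(CalibrationPanel(f"panel_{refl:.2f}", roi, refl))
    return panels, mask


def make_trait_dataset(
    n: int,
    slope: float = 0.336,
    intercept: float = 1.0176,
    noise_sd: float = 0.3,
    seed: int = 0,
    vi_range: tuple[float, float] = (0.0, 6.0),
    vi_name: str = "CI_green",
    trait_name: str = "LAI",
) -> pd.DataFrame:
    """Plot table with trait = slope*vi + intercept + N(0, noise_sd).

    The defaults reproduce the LAI ~ CI_green conditions of the reference
    campaign's best-performing calibration.  VI values are uniform over
    ``vi_range``; the true (noiseless) trait is included for closed-loop
    tests.
    """
    if n < 3:
        raise ValueError("need n >= 3 plots")
    rng = np.random.default_rng(seed)
    vi = rng.uniform(*vi_range, n)
    truth = slope * vi + intercept
    trait = truth + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({
        "plot_id": [f"plot{i:03d}" for i in range(n)],
        vi_name: vi,
        trait_name: trait,
        trait_name + "_true": truth,
    })
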