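"""Empirical-line radiometric calibration: EL, SEL and PEL.

Reference panels of known reflectance are imaged alongside the scene, their
mean digital numbers (DN) extracted, and a per-band DN -> reflectance map
fitted:

* EL  — a single least-squares line  y = a1*x + b1  over all panels.
* SEL — the twelve bands are split into a low-reflectance visible group
  (bands 1-7, 490-700 nm) fitted with a power law  y = a2*x**b2  and a
  high-reflectance red-edge/NIR group (bands 8-12, 720-950 nm) fitted
  linearly  y = a3*x + b3.
* PEL — piecewise: a through-origin line  y = a4*x  for reflectance at or
  below a threshold tau (default 0.03) fitted on the darkest panels, and
  the EL line  y = a5*x + b5  above it.  At application time the linear
  prediction y_lin = a5*x + b5 selects the branch (the true y being
  unknown); continuity at tau is not enforced.

Negative or >1 reflectance is preserved (not clamped) and counted in the
returned diagnostics — EL characteristically produces negative values in
dark visible bands, which is the failure mode PEL removes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import mrpe, rmse

logger = logging.getLogger("uavcal")

#: PEL branch threshold (reflectance fraction).
PEL_THRESHOLD = 0.03
#: Panels with nominal reflectance at or below this feed the PEL low segment.
PEL_LOW_PANEL_MAX = 0.06
#: SEL band grouping for the reference camera (1-based band indices).
SEL_LOW_BAND_INDICES = tuple(range(1, 8))    # 490-700 nm, power fit
SEL_HIGH_BAND_INDICES = tuple(range(8, 13))  # 720-950 nm, linear fit

METHODS = ("EL", "SEL", "PEL")


@dataclass(frozen=True)
class CalibrationPanel:
    """A grayscale reference panel: ROI rectangle + nominal reflectance.

    The ROI is 0-based, half-open: rows [row0, row1), cols [col0, col1).
    ``nominal_reflectance`` is either a scalar (gray panel, same in every
    band) or a per-band vector of fractions in (0, 1).
    """

    label: str
    roi: tuple[int, int, int, int]
    nominal_reflectance: float | np.ndarray

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.roi
        if r1 <= r0 or c1 <= c0 or r0 < 0 or c0 < 0:
            raise ValueError(f"panel {self.label!r}: empty or invalid ROI {self.roi}")
        refl = np.atleast_1d(np.asarray(self.nominal_reflectance, dtype=float))
        if np.any(refl <= 0) or np.any(refl >= 1):
            raise ValueError(
                f"panel {self.label!r}: nominal reflectance must be in (0, 1)"
            )

    def reflectance_for_band(self, band_idx0: int) -> float:
        refl = np.atleast_1d(np.asarray(self.nominal_reflectance, dtype=float))
        return float(refl[0] if refl.size == 1 else refl[band_idx0])


def extract_panel_dn(image_band: np.ndarray, panel: CalibrationPanel,
                     trimmed: float = 0.0) -> float:
    """Mean DN over the panel ROI (optionally a symmetric trimmed mean).

    ``trimmed`` is the fraction cut from each tail (0 = plain mean).
    """
    r0, c0, r1, c1 = panel.roi
    h, w = image_band.shape
    if r1 > h or c1 > w:
        raise ValueError(
            f"panel {panel.label!r} ROI {panel.roi} exceeds image {h}x{w}"
        )
    pix = np.asarray(image_band[r0:r1, c0:c1], dtype=float).ravel()
    if trimmed > 0.0:
        k = int(len(pix) * trimmed)
        if k > 0:
            pix = np.sort(pix)[k:len(pix) - k]
    return float(pix.mean())


# ---------------------------------------------------------------------------
# per-band fit records

@dataclass(frozen=True)
class ELRecord:
    a1: float
    b1: float

    def apply(self, dn: np.ndarray) -> np.ndarray:
        return self.a1 * dn + self.b1


@dataclass(frozen=True)
class SELRecord:
    """Either a power-law (low group) or linear (high group) record."""
    kind: str  # "power" | "linear"
    a: float
    b: float

    def apply(self, dn: np.ndarray) -> np.ndarray:
        dn = np.asarray(dn, dtype=float)
        if self.kind == "power":
            if np.any(dn < 0):
                raise ValueError("power-law calibration is undefined for DN < 0")
            return self.a * np.power(dn, self.b)
        return self.a * dn + self.b


@dataclass(frozen=True)
class PELRecord:
    a4: float
    a5: float
    b5: float
    tau: float = PEL_THRESHOLD

    def apply(self, dn: np.ndarray) -> np.ndarray:
        dn = np.asarray(dn, dtype=float)
        y_lin = self.a5 * dn + self.b5
        return np.where(y_lin <= self.tau, self.a4 * dn, y_lin)


@dataclass
class CalibrationFit:
    """Per-band DN -> reflectance coefficients for one method.

    ``records`` maps 1-based band index to the per-band record;
    ``panel_rmse`` holds the residual RMSE on the fitting panels.
    """

    method: str
    records: dict[int, ELRecord | SELRecord | PELRecord]
    panel_rmse: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected {METHODS}")

    @property
    def n_bands(self) -> int:
        return len(self.records)

    def to_dict(self) -> dict:
        out = {"method": self.method, "bands": {}}
        for i, rec in sorted(self.records.items()):
            d = {k: getattr(rec, k) for k in rec.__dataclass_fields__}
            d["rmse_panels"] = self.panel_rmse.get(i)
            out["bands"][str(i)] = d
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationFit":
        method = d["method"]
        records: dict[int, ELRecord | SELRecord | PELRecord] = {}
        panel_rmse: dict[int, float] = {}
        for k, v in d["bands"].items():
            i = int(k)
            v = dict(v)
            r = v.pop("rmse_panels", None)
            if r is not None:
                panel_rmse[i] = r
            if method == "EL":
                records[i] = ELRecord(**v)
            elif method == "SEL":
                records[i] = SELRecord(**v)
            else:
                records[i] = PELRecord(**v)
        return cls(method, records, panel_rmse)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form least-squares slope/intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.ptp(x) == 0.0:
        raise ValueError("need >= 2 panels with distinct DN for a line fit")
    xm, ym = x.mean(), y.mean()
    slope = float(((x - xm) @ (y - ym)) / ((x - xm) @ (x - xm)))
    return slope, float(ym - slope * xm)


def _residual_rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def fit_el(panel_dns: np.ndarray, reflectances: np.ndarray) -> CalibrationFit:
    """EL: one least-squares line per band over all panels.

    ``panel_dns`` is (n_panels, n_bands); ``reflectances`` either
    (n_panels,) for gray panels or (n_panels, n_bands).
    """
    dns, refl = _as_panel_matrices(panel_dns, reflectances)
    records, diags = {}, {}
    for j in range(dns.shape[1]):
        a1, b1 = _ols_line(dns[:, j], refl[:, j])
        rec = ELRecord(a1, b1)
        records[j + 1] = rec
        diags[j + 1] = _residual_rmse(rec.apply(dns[:, j]), refl[:, j])
    return CalibrationFit("EL", records, diags)


def fit_sel(
    panel_dns: np.ndarray,
    reflectances: np.ndarray,
    low_band_indices: tuple[int, ...] = SEL_LOW_BAND_INDICES,
) -> CalibrationFit:
    """SEL: power fit for the low (visible) group, linear for the rest.

    The power law is fitted in log-log space (closed form); all panel DN
    and reflectances in the low group must be positive.
    """
    dns, refl = _as_panel_matrices(panel_dns, reflectances)
    records, diags = {}, {}
    for j in range(dns.shape[1]):
        x, y = dns[:, j], refl[:, j]
        if (j + 1) in low_band_indices:
            if np.any(x <= 0) or np.any(y <= 0):
                raise ValueError(
                    f"band {j + 1}: power fit requires positive DN and reflectance"
                )
            slope, intercept = _ols_line(np.log(x), np.log(y))
            rec = SELRecord("power", float(np.exp(intercept)), slope)
        else:
            a3, b3 = _ols_line(x, y)
            rec = SELRecord("linear", a3, b3)
        records[j + 1] = rec
        diags[j + 1] = _residual_rmse(rec.apply(x), y)
    return CalibrationFit("SEL", records, diags)


def fit_pel(
    panel_dns: np.ndarray,
    reflectances: np.ndarray,
    tau: float = PEL_THRESHOLD,
    low_panel_max: float = PEL_LOW_PANEL_MAX,
) -> CalibrationFit:
    """PEL: linear fit on the bright panels + through-origin on the dark.

    The through-origin slope a4 is the least-squares solution
    sum(x*y)/sum(x*x) over panels whose nominal reflectance is at most
    ``low_panel_max`` (default 0.06: the 3% and 6% panels); the linear
    segment (a5, b5) is fitted on the remaining, brighter panels — dark
    panels sitting on a sensor floor would otherwise bias it (it falls
    back to all panels when fewer than two bright ones exist).  With no
    dark panel available PEL degrades to EL with a warning.
    """
    dns, refl = _as_panel_matrices(panel_dns, reflectances)
    records, diags = {}, {}
    for j in range(dns.shape[1]):
        x, y = dns[:, j], refl[:, j]
        low = y <= low_panel_max
        high = ~low
        if high.sum() >= 2:
            a5, b5 = _ols_line(x[high], y[high])
        else:
            a5, b5 = _ols_line(x, y)
        if not np.any(low):
            logger.warning(
                "PEL band %d: no panel with reflectance <= %.3g; "
                "falling back to the EL line for the low segment", j + 1,
                low_panel_max,
            )
            # proportional approximation of the EL line through the darkest panel
            k = int(np.argmin(y))
            a4 = (a5 * x[k] + b5) / x[k] if x[k] != 0 else a5
        else:
            xl, yl = x[low], y[low]
            a4 = float((xl @ yl) / (xl @ xl))
        rec = PELRecord(a4, a5, b5, tau)
        records[j + 1] = rec
        diags[j + 1] = _residual_rmse(rec.apply(x), y)
    return CalibrationFit("PEL", records, diags)


def fit_method(method: str, panel_dns, reflectances, **kw) -> CalibrationFit:
    if method == "EL":
        return fit_el(panel_dns, reflectances)
    if method == "SEL":
        return fit_sel(panel_dns, reflectances, **kw)
    if method == "PEL":
        return fit_pel(panel_dns, reflectances, **kw)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def _as_panel_matrices(panel_dns, reflectances) -> tuple[np.ndarray, np.ndarray]:
    dns = np.atleast_2d(np.asarray(panel_dns, dtype=float))
    refl = np.asarray(reflectances, dtype=float)
    if refl.ndim == 1:
        refl = np.repeat(refl[:, None], dns.shape[1], axis=1)
    if refl.shape != dns.shape:
        raise ValueError(
            f"panel DN shape {dns.shape} != reflectance shape {refl.shape}"
        )
    if dns.shape[0] < 2:
        raise ValueError("need at least 2 panels")
    return dns, refl


@dataclass
class ApplyDiagnostics:
    """Out-of-range pixel counts recorded while applying a calibration."""
    n_negative: int = 0
    n_above_one: int = 0
    per_band_negative: dict[int, int] = field(default_factory=dict)


def apply_calibration(
    dn_image: np.ndarray,
    fit: CalibrationFit,
    clamp: tuple[float, float] | None = None,
) -> tuple[np.ndarray, ApplyDiagnostics]:
    """Convert a (bands, rows, cols) DN stack to reflectance.

    Values outside [0, 1] are preserved by default and counted in the
    diagnostics; pass ``clamp=(0.0, 1.0)`` to clip instead.
    """
    dn_image = np.asarray(dn_image, dtype=float)
    if dn_image.ndim == 2:
        dn_image = dn_image[None]
    if dn_image.shape[0] != fit.n_bands:
        raise ValueError(
            f"image has {dn_image.shape[0]} bands but fit has {fit.n_bands}"
        )
    out = np.empty_like(dn_image)
    diag = ApplyDiagnostics()
    for j in range(dn_image.shape[0]):
        plane = fit.records[j + 1].apply(dn_image[j])
        neg = int(np.sum(plane < 0))
        diag.n_negative += neg
        diag.n_above_one += int(np.sum(plane > 1))
        diag.per_band_negative[j + 1] = neg
        out[j] = plane
    if clamp is not None:
        np.clip(out, clamp[0], clamp[1], out=out)
    return out, diag


def evaluate_calibration(
    estimated: np.ndarray, reference: np.ndarray
) -> dict[int, dict[str, float]]:
    """Per-band MRPE (%) and RMSE of estimated vs reference reflectance.

    Inputs are (n_samples, n_bands); the reference plays the role of the
    camera-equivalent spectrometer reflectance.
    """
    est = np.atleast_2d(np.asarray(estimated, dtype=float))
    ref = np.atleast_2d(np.asarray(reference, dtype=float))
    if est.shape != ref.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {ref.shape}")
    table = {}
    for j in range(est.shape[1]):
        table[j + 1] = {
            "MRPE": mrpe(ref[:, j], est[:, j]),
            "RMSE": rmse(ref[:, j], est[:, j]),
        }
    return table
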