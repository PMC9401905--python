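"""VI -> trait linear models and canopy chlorophyll content.

Rice growth parameters (leaf area index LAI, above-ground biomass AGB in
g/m2, canopy chlorophyll content CCC = LAI_green * SPAD_upper, and yield
in g/m2) are related to vegetation indices through ordinary least-squares
lines, reported with in-sample R^2, RMSE and RRMSE (% of the observed
mean).  A read-only catalog ships the published coefficient sets for the
reference field campaigns — keyed by experiment, calibration method or
flying altitude, trait and VI — so fitted models can be compared against
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import mrpe, rmse, rrmse

__all__ = [
    "TraitModel", "ccc", "fit_trait_model", "predict_trait",
    "reference_models", "mrpe", "rmse", "rrmse",
]


def ccc(lai_green: float, spad_upper: float):
    """Canopy chlorophyll content: LAI_green * SPAD_upper (both >= 0)."""
    lai = np.asarray(lai_green, dtype=float)
    spad = np.asarray(spad_upper, dtype=float)
    if np.any(lai < 0) or np.any(spad < 0):
        raise ValueError("LAI_green and SPAD_upper must be non-negative")
    out = lai * spad
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TraitModel:
    """A fitted or cataloged line trait = slope * vi + intercept."""

    trait: str
    vi: str
    slope: float
    intercept: float
    r2: float | None = None
    rmse: float | None = None
    rrmse: float | None = None  # percent
    provenance: str = "fitted"  # "fitted" | "published"

    def __post_init__(self) -> None:
        if self.r2 is not None and not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError(f"R^2 out of [0, 1]: {self.r2}")
        for name in ("rmse", "rrmse"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    def predict(self, vi_value):
        return predict_trait(self, vi_value)


def predict_trait(model: TraitModel, vi_value):
    vi = np.asarray(vi_value, dtype=float)
    out = model.slope * vi + model.intercept
    return float(out) if out.ndim == 0 else out


def fit_trait_model(
    vi: np.ndarray, trait: np.ndarray, trait_name: str = "trait",
    vi_name: str = "vi",
) -> TraitModel:
    """OLS line trait = slope*vi + intercept with in-sample R^2/RMSE/RRMSE."""
    x = np.asarray(vi, dtype=float)
    y = np.asarray(trait, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vi and trait must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError(f"need >= 3 samples, got {len(x)}")
    if np.ptp(x) == 0.0:
        raise ValueError("vi is constant; line fit undefined")
    xm, ym = x.mean(), y.mean()
    slope = float(((x - xm) @ (y - ym)) / ((x - xm) @ (x - xm)))
    intercept = float(ym - slope * xm)
    pred = slope * x + intercept
    sst = float(((y - ym) ** 2).sum())
    sse = float(((y - pred) ** 2).sum())
    r2 = 1.0 if sst == 0.0 else max(0.0, 1.0 - sse / sst)
    return TraitModel(
        trait=trait_name, vi=vi_name, slope=slope, intercept=intercept,
        r2=r2, rmse=rmse(y, pred),
        rrmse=rrmse(y, pred) if ym != 0 else None,
        provenance="fitted",
    )


# ---------------------------------------------------------------------------
# Published reference models (read-only catalog).
#
# Growth-parameter models (CI_green based, 100 m unless an altitude is
# given) and single-stage yield models.  Columns: experiment, key (RCM,
# altitude in m, or stage@altitude), trait, vi, slope, intercept, r2,
# rmse, rrmse_pct.

_CATALOG_ROWS = [
    # experiment, key, trait, vi, slope, intercept, r2, rmse, rrmse%
    # --- growth models by calibration method (100 m) ---
    ("Test1", "EL",  "LAI", "CI_green", 0.2138, 2.1213, 0.6159, 1.1894, 24.43),
    ("Test1", "SEL", "LAI", "CI_green", 0.3392, 1.2471, 0.7714, 0.9175, 18.84),
    ("Test1", "PEL", "LAI", "CI_green", 0.3360, 1.0176, 0.8364, 0.7772, 15.96),
    ("Test1", "EL",  "AGB", "CI_green", 31.8780, 58.2600, 0.6283, 258.5627, 47.60),
    ("Test1", "SEL", "AGB", "CI_green", 38.2660, 46.7340, 0.5478, 267.8949, 49.32),
    ("Test1", "PEL", "AGB", "CI_green", 39.6540, 3.7036, 0.6534, 255.5819, 47.05),
    ("Test1", "EL",  "CCC", "CI_green", 8.7479, 96.1880, 0.5419, 56.6725, 27.16),
    ("Test1", "SEL", "CCC", "CI_green", 14.7750, 50.8720, 0.7689, 40.2487, 19.29),
    ("Test1", "PEL", "CCC", "CI_green", 14.3360, 44.2940, 0.8001, 37.4370, 17.94),
    ("Test2", "EL",  "LAI", "CI_green", 0.2944, 0.6926, 0.8350, 0.8195, 18.38),
    ("Test2", "SEL", "LAI", "CI_green", 0.3210, 0.6811, 0.8026, 0.8755, 19.63),
    ("Test2", "PEL", "LAI", "CI_green", 0.3390, 0.4682, 0.8533, 0.7820, 17.53),
    ("Test2", "EL",  "AGB", "CI_green", 42.1860, 30.6610, 0.4654, 271.4445, 48.08),
    ("Test2", "SEL", "AGB", "CI_green", 45.0950, 31.0940, 0.4403, 277.7335, 49.20),
    ("Test2", "PEL", "AGB", "CI_green", 47.5830, 4.9777, 0.4690, 270.5139, 47.92),
    ("Test2", "EL",  "CCC", "CI_green", 11.9540, 28.8210, 0.8588, 30.9864, 17.05),
    ("Test2", "SEL", "CCC", "CI_green", 13.2190, 26.1690, 0.8492, 31.5024, 17.33),
    ("Test2", "PEL", "CCC", "CI_green", 13.9210, 17.8800, 0.8975, 27.5072, 15.13),
    # --- growth models by flying altitude (PEL) ---
    ("Test1", "100", "LAI", "CI_green", 0.3360, 1.0176, 0.8364, 0.7762, 15.94),
    ("Test1", "150", "LAI", "CI_green", 0.3539, 0.9984, 0.8546, 0.7318, 15.03),
    ("Test1", "200", "LAI", "CI_green", 0.3421, 0.9721, 0.8317, 0.7874, 16.17),
    ("Test1", "250", "LAI", "CI_green", 0.3554, 0.8772, 0.8411, 0.7649, 15.71),
    ("Test1", "100", "AGB", "CI_green", 39.6540, 3.7036, 0.6534, 162.6172, 36.55),
    ("Test1", "150", "AGB", "CI_green", 43.5090, -4.7125, 0.6363, 165.2271, 36.81),
    ("Test1", "200", "AGB", "CI_green", 38.6880, 6.2879, 0.6133, 171.7673, 38.60),
    ("Test1", "250", "AGB", "CI_green", 40.1870, 1.6108, 0.6130, 171.8381, 38.62),
    ("Test1", "100", "CCC", "CI_green", 14.3360, 44.2940, 0.8001, 37.4370, 17.94),
    ("Test1", "150", "CCC", "CI_green", 14.6560, 48.3090, 0.8103, 35.0322, 17.07),
    ("Test1", "200", "CCC", "CI_green", 15.0250, 37.4670, 0.8430, 33.1784, 15.90),
    ("Test1", "250", "CCC", "CI_green", 15.5450, 34.0210, 0.8455, 32.9088, 15.77),
    ("Test2", "50",  "LAI", "CI_green", 0.2788, 0.8889, 0.7761, 1.1150, 25.00),
    ("Test2", "100", "LAI", "CI_green", 0.3390, 0.4682, 0.8533, 0.7820, 17.53),
    ("Test2", "50",  "AGB", "CI_green", 39.5530, 55.1480, 0.4301, 280.2471, 49.64),
    ("Test2", "100", "AGB", "CI_green", 47.5830, 4.9777, 0.4690, 270.5139, 47.92),
    ("Test2", "50",  "CCC", "CI_green", 11.4960, 34.5720, 0.8228, 33.9458, 18.67),
    ("Test2", "100", "CCC", "CI_green", 13.9210, 17.8800, 0.8975, 27.5072, 15.13),
    # --- single-stage yield models (PEL) ---
    ("Test2", "booting@50",  "yield", "EVI2", 3186.2660, -2002.0312, 0.3859, 124.7462, 15.4756),
    ("Test2", "booting@100", "yield", "EVI2", 5475.6664, -3455.1211, 0.5177, 110.5548, 13.7151),
    ("Test2", "heading@50",  "yield", "WDRVI", 1337.1689, -120.3483, 0.3165, 131.6050, 16.3265),
    ("Test2", "heading@100", "yield", "WDRVI", 2867.1955, -1007.9788, 0.5170, 110.6357, 13.7251),
]

_CATALOG = pd.DataFrame(
    _CATALOG_ROWS,
    columns=["experiment", "key", "trait", "vi",
             "slope", "intercept", "r2", "rmse", "rrmse_pct"],
)


def reference_catalog() -> pd.DataFrame:
    """The full published-model catalog as a copy (read-only semantics)."""
    return _CATALOG.copy()


def reference_models(
    experiment: str | None = None,
    key: str | None = None,
    trait: str | None = None,
) -> list[TraitModel]:
    """Look up published models; filters combine with AND."""
    df = _CATALOG
    if experiment is not None:
        df = df[df.experiment == experiment]
    if key is not None:
        df = df[df.key == key]
    if trait is not None:
        df = df[df.trait == trait]
    return [
        TraitModel(
            trait=r.trait, vi=r.vi, slope=r.slope, intercept=r.intercept,
            r2=r.r2, rmse=r.rmse, rrmse=r.rrmse_pct, provenance="published",
        )
        for r in df.itertuples()
    ]


def reference_model(experiment: str, key: str, trait: str) -> TraitModel:
    """Exactly one published model, or KeyError."""
    models = reference_models(experiment, key, trait)
    if len(models) != 1:
        raise KeyError(
            f"catalog lookup ({experiment}, {key}, {trait}) "
            f"matched {len(models)} models"
        )
    return models[0]
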