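"""Accuracy metrics shared by calibration and trait modeling.

MRPE  = mean(|(est - obs)/obs|) * 100          (percent)
RMSE  = sqrt(mean((est - obs)^2))              (units of obs)
RRMSE = RMSE / mean(obs) * 100                 (percent)
"""

from __future__ import annotations

import numpy as np


def mrpe(observed, estimated) -> float:
    """Mean relative percent error; every observed value must be non-zero."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(estimated, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    zero = np.flatnonzero(y == 0.0)
    if zero.size:
        raise ValueError(
            f"MRPE undefined: observed is zero at indices {zero.tolist()[:10]}"
        )
    return float(np.mean(np.abs((yhat - y) / y)) * 100.0)


def rmse(observed, estimated) -> float:
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(estimated, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def rrmse(observed, estimated) -> float:
    """RMSE relative to the observed mean, as a percent."""
    y = np.asarray(observed, dtype=float)
    ybar = float(np.mean(y))
    if ybar == 0.0:
        raise ValueError("RRMSE undefined: observed mean is zero")
    return rmse(observed, estimated) / ybar * 100.0
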