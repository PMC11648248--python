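"""Regression fit metrics: R2, RMSE, relative RMSE (percent) and MAE."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MetricReport:
    """Fit metrics of one observed-vs-predicted comparison.

    ``r2`` may be negative for models worse than the mean; ``rrmse`` is RMSE
    as a percentage of the observed mean and is NaN when that mean is zero.
    """

    r2: float
    rmse: float
    rrmse: float
    mae: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "rmse": self.rmse, "rrmse": self.rrmse,
                "mae": self.mae, "n": self.n}


def compute_metrics(observed, predicted) -> MetricReport:
    """R2 = 1 - SSE/SST, RMSE = sqrt(mean squared error), rRMSE = 100*RMSE/mean."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    resid = y - yhat
    sse = float((resid**2).sum())
    ybar = float(y.mean())
    sst = float(((y - ybar) ** 2).sum())
    r2 = float("nan") if sst == 0 else 1.0 - sse / sst
    rmse = float(np.sqrt(sse / n))
    rrmse = float("nan") if ybar == 0 else 100.0 * rmse / ybar
    mae = float(np.abs(resid).mean())
    return MetricReport(r2=r2, rmse=rmse, rrmse=rrmse, mae=mae, n=n)
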