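"""Plot-level map validation: RMSE, Bias, R², relative forms and binned bias.

Conventions, with y the reference (field) values and y_hat the predictions:

    RMSE  = sqrt( sum_i (y_i - y_hat_i)^2 / n )
    Bias  = sum_i (y_i - y_hat_i) / n              (reference minus prediction)
    R²    = 1 - sum_i (y_i - y_hat_i)^2 / sum_i (y_i - ybar)^2

Relative forms divide by the reference mean, x100 (RMSE%, Bias%). Because
the reference-minus-prediction convention prints overestimation of small
values as a *negative* bias while binned-bias tables in this field usually
show it positive, the binned report also carries the prediction-minus-
reference sign alongside, clearly labelled — neither convention is silently
chosen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Default AGB bin edges (t/ha): [0,125), [125,250), [250,375), [375,500), [500,inf)
DEFAULT_AGB_EDGES = (0.0, 125.0, 250.0, 375.0, 500.0)


@dataclass
class MetricsReport:
    """Accuracy metrics for one variable on one validation set."""

    variable: str
    units: str
    n: int
    mean_ref: float
    rmse: float
    bias: float  # reference minus prediction
    r2: float
    rmse_pct: float | None  # % of the reference mean; None when mean is 0
    bias_pct: float | None
    binned: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "variable": self.variable, "units": self.units, "n": self.n,
                "mean_ref": self.mean_ref, "rmse": self.rmse, "bias": self.bias,
                "r2": self.r2, "rmse_pct": self.rmse_pct, "bias_pct": self.bias_pct,
            }]
        )


def _as_pairs(y, y_hat):
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise ValueError("y and y_hat must be 1-D arrays of equal length")
    return y, y_hat


def compute_metrics(y, y_hat, variable: str = "", units: str = "") -> MetricsReport:
    """RMSE, Bias, R² and their relative forms for one validation variable."""
    y, y_hat = _as_pairs(y, y_hat)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 validation pairs")
    resid = y - y_hat
    rmse = math.sqrt(float(resid @ resid) / n)
    bias = float(resid.mean())
    ybar = float(y.mean())
    ss_tot = float(((y - ybar) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
    rel = (lambda v: 100.0 * v / ybar) if ybar != 0 else (lambda v: None)
    return MetricsReport(
        variable=variable, units=units, n=n, mean_ref=ybar,
        rmse=rmse, bias=bias, r2=r2,
        rmse_pct=rel(rmse), bias_pct=rel(bias),
    )


def binned_bias(y, y_hat, edges=DEFAULT_AGB_EDGES) -> pd.DataFrame:
    """Bias per reference-value bin.

    Bins are half-open intervals [e_j, e_{j+1}) over the strictly increasing
    ``edges``, the last bin open-ended — matching integer bin labels like
    "0-124", "125-249", ..., "500->". Each row reports n, the bin's
    reference mean, bias in both sign conventions and the corresponding
    Bias% relative to the bin's reference mean; empty bins carry n=0 and NaN
    metrics.
    """
    y, y_hat = _as_pairs(y, y_hat)
    edges = tuple(float(e) for e in edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    rows = []
    bounds = list(zip(edges, edges[1:])) + [(edges[-1], math.inf)]
    for lo, hi in bounds:
        label = f"{lo:g}-{hi - 1:g}" if math.isfinite(hi) else f"{lo:g}->"
        sel = (y >= lo) & (y < hi)
        n = int(sel.sum())
        if n == 0:
            rows.append({
                "bin": label, "n": 0, "mean_ref": float("nan"),
                "bias_ref_minus_pred": float("nan"), "bias_pred_minus_ref": float("nan"),
                "bias_pct_ref_minus_pred": float("nan"), "bias_pct_pred_minus_ref": float("nan"),
            })
            continue
        ybar = float(y[sel].mean())
        b = float((y[sel] - y_hat[sel]).mean())
        pct = 100.0 * b / ybar if ybar != 0 else float("nan")
        rows.append({
            "bin": label, "n": n, "mean_ref": ybar,
            "bias_ref_minus_pred": b, "bias_pred_minus_ref": -b,
            "bias_pct_ref_minus_pred": pct, "bias_pct_pred_minus_ref": -pct,
        })
    return pd.DataFrame(rows)


def validate_predictions(
    reference: pd.DataFrame,
    predictions: pd.DataFrame,
    variables=(("vol", "m3/ha"), ("agb", "t/ha"), ("dcp", "%")),
    agb_bins=DEFAULT_AGB_EDGES,
) -> dict[str, MetricsReport]:
    """Join reference and prediction tables on plot_id and score each variable.

    ``predictions`` must carry columns ``{var}_pred``; the AGB report also
    carries the binned-bias table.
    """
    merged = reference.merge(predictions, on="plot_id", how="inner", suffixes=("", "_p"))
    if merged.empty:
        raise ValueError("no common plot_id between reference and predictions")
    reports = {}
    for var, units in variables:
        rep = compute_metrics(merged[var], merged[f"{var}_pred"], variable=var, units=units)
        if var == "agb":
            rep.binned = binned_bias(merged[var], merged[f"{var}_pred"], edges=agb_bins)
        reports[var] = rep
    return reports
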