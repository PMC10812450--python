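"""Shared fit metrics and the polynomial-vs-network comparison report."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .ann import MLPModel, DataSplit, predict_mlp
from .rsm import RSMModel, build_design_matrix

__all__ = ["r_squared", "rmse", "build_report"]


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - SSE/SST (SST mean-centered).

    Returns NaN with a warning for a zero-variance y.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        warnings.warn("zero-variance observations; R^2 undefined", stacklevel=2)
        return float("nan")
    sse = float(((y - yhat) ** 2).sum())
    return 1.0 - sse / sst


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean square error sqrt(SSE / n)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size < 1:
        raise ValueError("need at least 1 observation")
    return float(np.sqrt(((y - yhat) ** 2).mean()))


def build_report(
    rsm_models: dict[str, RSMModel],
    networks: list[tuple[str, MLPModel]],
    coded: np.ndarray,
    features: np.ndarray,
    targets: pd.DataFrame,
    split: DataSplit | None = None,
) -> pd.DataFrame:
    """Per-response R²/RMSE rows for the polynomial model and each
    retained network.

    Rows are response-major: the polynomial row first (metrics on the full
    dataset), then networks in retained rank order.  Network rows carry
    pooled metrics and, when a *split* is given, test-partition metrics in
    separate columns — the partition each number uses is explicit in the
    column name.  ``residual_sd`` summarizes residual spread (pooled).

    *targets* columns must equal the rsm_models keys and the network
    output order.
    """
    responses = list(targets.columns)
    if set(rsm_models) != set(responses):
        raise ValueError("rsm_models and targets name different responses")
    for _name, net in networks:
        if net.architecture.n_outputs != len(responses):
            raise ValueError("network output count != number of responses")
    Y = targets.to_numpy(dtype=float)
    rows = []
    for j, resp in enumerate(responses):
        y = Y[:, j]
        ok = np.isfinite(y)
        m = rsm_models[resp]
        yhat = build_design_matrix(np.asarray(coded)[ok], m.terms) @ m.beta
        resid = y[ok] - yhat
        rows.append({
            "response": resp, "model": "RSM", "rank": 0,
            "r2_pooled": r_squared(y[ok], yhat),
            "rmse_pooled": rmse(y[ok], yhat),
            "r2_test": np.nan, "rmse_test": np.nan,
            "residual_sd": float(np.std(resid, ddof=1)),
        })
        for rank, (name, net) in enumerate(networks, start=1):
            pred = predict_mlp(net, features)[:, j]
            resid = y[ok] - pred[ok]
            row = {
                "response": resp, "model": name, "rank": rank,
                "r2_pooled": r_squared(y[ok], pred[ok]),
                "rmse_pooled": rmse(y[ok], pred[ok]),
                "r2_test": np.nan, "rmse_test": np.nan,
                "residual_sd": float(np.std(resid, ddof=1)),
            }
            if split is not None:
                te = [i for i in split.test if ok[i]]
                if len(te) >= 2:
                    row["r2_test"] = r_squared(y[te], pred[te])
                    row["rmse_test"] = rmse(y[te], pred[te])
            rows.append(row)
    return pd.DataFrame(rows)
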