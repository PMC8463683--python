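"""Predictor standardization and collinearity diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["standardize_predictors", "vif"]


def standardize_predictors(
    table: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score the given columns; returns the table and a scaling record.

    The scaling record maps each column to its (mean, sd) so coefficients can
    be mapped back to the raw scale.  Interactions should be built from the
    standardized main effects, not standardized themselves.
    """
    out = table.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        mu, sd = float(x.mean()), float(x.std(ddof=0))
        if sd == 0:
            raise ValueError(f"cannot standardize zero-variance column {col!r}")
        out[col] = (x - mu) / sd
        scaling[col] = (mu, sd)
    return out, scaling


def vif(design: np.ndarray | pd.DataFrame, names: list[str] | None = None) -> pd.Series:
    """Variance inflation factor per design column.

    ``VIF_k = 1 / (1 - R^2_k)`` where R^2_k comes from regressing column k on
    the remaining columns (with an intercept).  Constant columns are treated
    as the model intercept and excluded from scoring.  Rank-deficient designs
    raise, naming the dependent columns.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns) if names is None else names
        x = design.to_numpy(dtype=float)
    else:
        x = np.asarray(design, dtype=float)
        if names is None:
            names = [f"x{i}" for i in range(x.shape[1])]
    n, p = x.shape
    keep = [j for j in range(p) if np.ptp(x[:, j]) > 0]
    xc = x[:, keep] - x[:, keep].mean(axis=0)
    rank = np.linalg.matrix_rank(xc)
    if rank < len(keep):
        _, r = np.linalg.qr(xc)
        dep = [names[keep[j]] for j in range(len(keep)) if abs(r[j, j]) < 1e-8 * max(1, abs(r[0, 0]))]
        raise ValueError(f"design is rank deficient; dependent columns: {dep}")
    out = {}
    for jj, j in enumerate(keep):
        yj = xc[:, jj]
        others = np.delete(xc, jj, axis=1)
        if others.shape[1] == 0:
            out[names[j]] = 1.0
            continue
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        r2 = 1.0 - resid @ resid / (yj @ yj)
        out[names[j]] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
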