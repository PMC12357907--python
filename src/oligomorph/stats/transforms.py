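"""Transform-to-normality selection.

Candidate families: Yeo-Johnson, Box-Cox (positive data only), rank-based
inverse-normal (ordernorm), sqrt(x + a), asinh(x) and identity.  Each is fit
to the sample, scored by the Shapiro-Wilk W of the transformed values, and
the maximizer wins; ties go to the simplest family so an already-normal
sample is left alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps
from scipy.interpolate import interp1d

# tie-break order: simpler transforms first
_COMPLEXITY = ["identity", "sqrt_shift", "asinh", "box-cox", "yeo-johnson", "ordernorm"]


@dataclass
class TransformResult:
    transform: str
    params: dict
    values: np.ndarray  # transformed sample
    shapiro_before: float
    shapiro_after: float
    degenerate: bool = False

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return _inverse_transform(self.transform, self.params, np.asarray(y, dtype=float))


def _blom_scores(x: np.ndarray) -> np.ndarray:
    n = len(x)
    ranks = sps.rankdata(x, method="average")
    return sps.norm.ppf((ranks - 0.375) / (n + 0.25))


def _fit_one(name: str, x: np.ndarray) -> tuple[np.ndarray, dict] | None:
    if name == "identity":
        return x.copy(), {}
    if name == "asinh":
        return np.arcsinh(x), {}
    if name == "sqrt_shift":
        a = 0.0 if x.min() > 0 else 1.0 - x.min()
        return np.sqrt(x + a), {"a": float(a)}
    if name == "box-cox":
        if x.min() <= 0 or np.allclose(x, x[0]):
            return None
        y, lmbda = sps.boxcox(x)
        return y, {"lmbda": float(lmbda)}
    if name == "yeo-johnson":
        if np.allclose(x, x[0]):
            return None
        y, lmbda = sps.yeojohnson(x)
        return y, {"lmbda": float(lmbda)}
    if name == "ordernorm":
        y = _blom_scores(x)
        order = np.argsort(x)
        return y, {"train_x": x[order].tolist(), "train_y": y[order].tolist()}
    raise ValueError(name)


def _inverse_transform(name: str, params: dict, y: np.ndarray) -> np.ndarray:
    if name == "identity":
        return y
    if name == "asinh":
        return np.sinh(y)
    if name == "sqrt_shift":
        return y**2 - params["a"]
    if name == "box-cox":
        return sps.inv_boxcox(y, params["lmbda"])
    if name == "yeo-johnson":
        return _inv_yeojohnson(y, params["lmbda"])
    if name == "ordernorm":
        tx = np.array(params["train_x"])
        ty = np.array(params["train_y"])
        ty_u, idx = np.unique(ty, return_index=True)
        f = interp1d(ty_u, tx[idx], bounds_error=False,
                     fill_value=(tx.min(), tx.max()))
        return f(y)
    raise ValueError(name)


def _inv_yeojohnson(y: np.ndarray, lmbda: float) -> np.ndarray:
    x = np.empty_like(y, dtype=float)
    pos = y >= 0
    if abs(lmbda) < 1e-12:
        x[pos] = np.expm1(y[pos])
    else:
        x[pos] = np.power(y[pos] * lmbda + 1, 1 / lmbda) - 1
    if abs(lmbda - 2) < 1e-12:
        x[~pos] = -np.expm1(-y[~pos])
    else:
        x[~pos] = 1 - np.power(-(2 - lmbda) * y[~pos] + 1, 1 / (2 - lmbda))
    return x


def _shapiro_w(x: np.ndarray) -> float:
    if len(x) < 3 or np.allclose(x, x[0]):
        return -np.inf
    return float(sps.shapiro(x).statistic)


def select_transform(values) -> TransformResult:
    """Fit every candidate family and return the best-normalizing one."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 4:
        raise ValueError("need at least 4 finite values")
    w_before = _shapiro_w(x)
    if np.allclose(x, x[0]):
        return TransformResult("identity", {}, x.copy(), w_before, w_before, degenerate=True)

    best: tuple[float, int, str, np.ndarray, dict] | None = None
    for rank, name in enumerate(_COMPLEXITY):
        fit = _fit_one(name, x)
        if fit is None:
            continue
        y, params = fit
        w = _shapiro_w(y)
        # maximize W; ties (within 1e-10) to the simpler family
        key = (round(w, 10), -rank)
        if best is None or key > (round(best[0], 10), -best[1]):
            best = (w, rank, name, y, params)
    assert best is not None
    w, _, name, y, params = best
    return TransformResult(name, params, y, w_before, w)


def apply_transform(result: TransformResult, x) -> np.ndarray:
    """Apply a fitted transform to new values (ordernorm: by interpolation)."""
    x = np.asarray(x, dtype=float)
    name, params = result.transform, result.params
    if name == "ordernorm":
        tx = np.array(params["train_x"])
        ty = np.array(params["train_y"])
        tx_u, idx = np.unique(tx, return_index=True)
        f = interp1d(tx_u, ty[idx], bounds_error=False,
                     fill_value=(ty.min(), ty.max()))
        return f(x)
    if name == "box-cox":
        return sps.boxcox(x, lmbda=params["lmbda"])
    if name == "yeo-johnson":
        return sps.yeojohnson(x, lmbda=params["lmbda"])
    y, _ = _fit_one(name, x) if name in ("identity", "asinh") else (np.sqrt(x + params["a"]), None)
    return y
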