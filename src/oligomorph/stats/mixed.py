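"""Mixed-effects ANOVA: group fixed effect, donor-line random intercept.

The model is y = b0 + b1 * [group == SCZ] + u_line + e with
u ~ N(0, var_line), e ~ N(0, var_resid), fitted by restricted maximum
likelihood.  The variance ratio is profiled out, so the one-dimensional REML
criterion is optimized directly; the block-diagonal structure of the
marginal covariance (one block per line) gives closed-form inverses.

The group F test uses the between-within denominator df (#lines - 2) by
default; ``df_method='residual'`` switches to n - #lines - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar


@dataclass
class MixedAnovaResult:
    estimate: float  # fixed group difference (second group minus first)
    se: float
    F: float
    df_num: int
    df_den: float
    p_value: float
    var_line: float
    var_resid: float
    n_lines: int
    n_obs: int
    singular: bool = False
    groups: tuple[str, str] = ("Ctrl", "SCZ")


def _reml_pieces(lam: float, y: np.ndarray, X: np.ndarray, starts: np.ndarray):
    """Sufficient statistics under V = I + lam * block-ones, per line block."""
    p = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    logdet_v = 0.0
    XtViX = XtX.astype(float).copy()
    XtViy = Xty.astype(float).copy()
    ytViy = yty
    for i in range(len(starts) - 1):
        sl = slice(starts[i], starts[i + 1])
        ni = starts[i + 1] - starts[i]
        w = lam / (1.0 + lam * ni)
        sx = X[sl].sum(axis=0)
        sy = float(y[sl].sum())
        XtViX -= w * np.outer(sx, sx)
        XtViy -= w * sx * sy
        ytViy -= w * sy * sy
        logdet_v += np.log1p(lam * ni)
    beta = np.linalg.solve(XtViX, XtViy)
    rss = max(ytViy - float(beta @ XtViy), 1e-300)
    n = len(y)
    sigma2 = rss / (n - p)
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    neg2reml = (n - p) * np.log(sigma2) + logdet_v + logdet_xvx
    return neg2reml, beta, sigma2, XtViX


def fit_mixed_anova(table: pd.DataFrame, metric: str,
                    value_col: str = "value",
                    df_method: str = "between_within") -> MixedAnovaResult:
    """Fit the random-intercept model by REML and test the group effect.

    Missing values are dropped listwise.  A boundary fit (zero line variance)
    is returned with ``singular=True`` rather than raising.
    """
    sub = table[table["metric"] == metric].dropna(subset=[value_col])
    groups = sorted(sub["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    lines_per_group = sub.groupby("group")["line"].nunique()
    if (lines_per_group < 2).any():
        raise ValueError("need >= 2 lines per group")

    sub = sub.sort_values(["line", "fov"], kind="stable")
    y = sub[value_col].to_numpy(dtype=float)
    g = (sub["group"] == groups[1]).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(y), g])
    line_codes, line_idx = np.unique(sub["line"].to_numpy(), return_inverse=True)
    order = np.argsort(line_idx, kind="stable")
    y, X, line_idx = y[order], X[order], line_idx[order]
    counts = np.bincount(line_idx)
    starts = np.concatenate([[0], np.cumsum(counts)])
    n_lines = len(line_codes)
    n = len(y)

    def objective(log_lam: float) -> float:
        return _reml_pieces(np.exp(log_lam), y, X, starts)[0]

    res = minimize_scalar(objective, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    lam_hat = float(np.exp(res.x))
    # compare against the boundary lambda = 0 (no line variance)
    neg2_b, *_ = _reml_pieces(1e-12, y, X, starts)
    singular = False
    if neg2_b <= res.fun + 1e-9 or lam_hat < 1e-8:
        lam_hat = 0.0
        singular = True
        _, beta, sigma2, XtViX = _reml_pieces(1e-12, y, X, starts)
    else:
        _, beta, sigma2, XtViX = _reml_pieces(lam_hat, y, X, starts)

    cov_beta = sigma2 * np.linalg.inv(XtViX)
    est = float(beta[1])
    se = float(np.sqrt(cov_beta[1, 1]))
    F = (est / se) ** 2 if se > 0 else np.inf
    if df_method == "between_within":
        df_den = float(n_lines - 2)
    elif df_method == "residual":
        df_den = float(n - n_lines - 1)
    else:
        raise ValueError(f"unknown df_method {df_method!r}")
    p = float(sps.f.sf(F, 1, df_den)) if np.isfinite(F) else 0.0
    return MixedAnovaResult(
        estimate=est, se=se, F=float(F), df_num=1, df_den=df_den, p_value=p,
        var_line=float(lam_hat * sigma2), var_resid=float(sigma2),
        n_lines=n_lines, n_obs=n, singular=singular,
        groups=(groups[0], groups[1]),
    )
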