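"""Distributional diagnostics: normality, variance and covariance homogeneity,
extreme-outlier flags."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

IQR_FACTOR = 3.0  # "extreme" outlier rule: beyond Q1 - 3 IQR / Q3 + 3 IQR


def extreme_outliers(values: np.ndarray) -> np.ndarray:
    """Boolean flags for values beyond the 3xIQR fences."""
    x = np.asarray(values, dtype=float)
    q1, q3 = np.nanpercentile(x, [25, 75])
    iqr = q3 - q1
    return (x < q1 - IQR_FACTOR * iqr) | (x > q3 + IQR_FACTOR * iqr)


def box_m(groups: list[np.ndarray]) -> dict:
    """Box's M test for homogeneity of covariance matrices.

    ``groups`` is a list of (n_i, p) observation matrices.  Returns the M
    statistic, its chi-square approximation, df and p-value.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    p = groups[0].shape[1]
    ns = np.array([g.shape[0] for g in groups])
    if np.any(ns <= p):
        raise ValueError("each group needs more observations than variables")
    covs = [np.cov(g, rowvar=False) for g in groups]
    dfs = ns - 1
    pooled = sum(df * c for df, c in zip(dfs, covs)) / dfs.sum()

    def _logdet(a):
        sign, ld = np.linalg.slogdet(np.atleast_2d(a))
        if sign <= 0:
            raise np.linalg.LinAlgError("non-positive-definite covariance")
        return ld

    M = dfs.sum() * _logdet(pooled) - sum(df * _logdet(c) for df, c in zip(dfs, covs))
    c1 = (2 * p**2 + 3 * p - 1) / (6 * (p + 1) * (k - 1)) * (
        np.sum(1.0 / dfs) - 1.0 / dfs.sum()
    )
    chi2 = M * (1 - c1)
    df = p * (p + 1) * (k - 1) / 2
    return {"M": float(M), "chi2": float(chi2), "df": float(df),
            "p": float(sps.chi2.sf(chi2, df))}


def diagnostics(table: pd.DataFrame) -> dict:
    """Per-metric Shapiro-Wilk and Levene checks plus outlier flags.

    Expects the tidy columns group/line/fov/metric/value.  When at least two
    metrics are present, Box's M compares the per-group covariance of the
    (line, fov)-aligned metric matrix.
    """
    groups = sorted(table["group"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    report: dict = {"metrics": {}, "box_m": None}
    for metric, sub in table.groupby("metric"):
        sub = sub.dropna(subset=["value"])
        if len(sub) < 3:
            log.warning("diagnostics: metric %r has < 3 values; skipped", metric)
            continue
        vals = sub["value"].to_numpy()
        per_group = [sub.loc[sub["group"] == g, "value"].to_numpy() for g in groups]
        if all(np.ptp(g) == 0 for g in per_group if len(g)):
            lev_stat, lev_p = 0.0, 1.0  # no spread anywhere: trivially homogeneous
        else:
            try:
                with np.errstate(invalid="ignore", divide="ignore"):
                    lev = sps.levene(*per_group, center="median")
                lev_stat, lev_p = float(lev.statistic), float(lev.pvalue)
            except ValueError:
                lev_stat, lev_p = float("nan"), float("nan")
        flags = extreme_outliers(vals)
        report["metrics"][metric] = {
            "shapiro_p": float(sps.shapiro(vals).pvalue) if len(vals) >= 3 else float("nan"),
            "levene_stat": lev_stat,
            "levene_p": lev_p,
            "n_extreme_outliers": int(flags.sum()),
            "outlier_index": sub.index[flags].tolist(),
        }

    metrics = sorted(table["metric"].unique())
    if len(metrics) >= 2:
        wide = table.pivot_table(index=["group", "line", "fov"], columns="metric",
                                 values="value").dropna()
        try:
            mats = [wide.loc[g].to_numpy() for g in groups]
            report["box_m"] = box_m(mats)
        except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
            log.warning("diagnostics: Box's M unavailable (%s)", exc)
    return report
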