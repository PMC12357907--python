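"""Line-level t-test and Cohen's d on group averages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class EffectSizeResult:
    t: float
    df: float
    p: float
    cohen_d: float
    mean_diff: float  # second group minus first (SCZ - Ctrl)
    line_means: dict


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD standardized mean difference, b minus a."""
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    diff = b.mean() - a.mean()
    if pooled == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / pooled)


def group_ttest_cohend(table: pd.DataFrame, metric: str,
                       value_col: str = "value") -> EffectSizeResult:
    """Collapse fields of view to line means, then t-test + Cohen's d.

    The sign convention is second group minus first (alphabetical order, so
    SCZ - Ctrl for the canonical labels).
    """
    sub = table[table["metric"] == metric].dropna(subset=[value_col])
    groups = sorted(sub["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    means = sub.groupby(["group", "line"])[value_col].mean()
    a = means.loc[groups[0]].to_numpy()
    b = means.loc[groups[1]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 lines per group")
    diff = float(b.mean() - a.mean())
    if a.var(ddof=1) + b.var(ddof=1) == 0:
        t, p = (0.0, 1.0) if diff == 0 else (float(np.sign(diff) * np.inf), 0.0)
    else:
        t_res = sps.ttest_ind(b, a, equal_var=True)
        t, p = float(t_res.statistic), float(t_res.pvalue)
    return EffectSizeResult(
        t=t, df=float(len(a) + len(b) - 2), p=p, cohen_d=cohens_d(a, b),
        mean_diff=diff,
        line_means={groups[0]: a.tolist(), groups[1]: b.tolist()},
    )
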