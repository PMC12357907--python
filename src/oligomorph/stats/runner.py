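"""Per-metric statistical analysis of a tidy measurement table."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from oligomorph.stats.diagnostics import diagnostics
from oligomorph.stats.effects import group_ttest_cohend
from oligomorph.stats.mixed import fit_mixed_anova
from oligomorph.stats.transforms import select_transform

log = logging.getLogger(__name__)


def analyze_table(table: pd.DataFrame, alpha: float = 0.05,
                  df_method: str = "between_within",
                  transform: bool = True) -> dict:
    """Run the full chain per metric and return a JSON-serializable report.

    For each metric: choose the best normalizing transform, fit the
    mixed-effects ANOVA on the transformed values, and add the line-mean
    t-test with Cohen's d.  Table-wide diagnostics are attached once.
    """
    table = table.copy()
    report: dict = {"alpha": alpha, "metrics": {}}
    try:
        report["diagnostics"] = diagnostics(table)
    except ValueError as exc:
        log.warning("diagnostics skipped: %s", exc)
        report["diagnostics"] = None

    for metric in sorted(table["metric"].unique()):
        sub = table[table["metric"] == metric].dropna(subset=["value"])
        entry: dict = {"n_obs": int(len(sub))}
        if len(sub) < 4:
            entry["error"] = "too few observations"
            report["metrics"][metric] = entry
            continue
        work = sub.copy()
        if transform:
            tr = select_transform(work["value"].to_numpy())
            work["value"] = tr.values
            entry["transform"] = {
                "family": tr.transform,
                "params": {k: v for k, v in tr.params.items()
                           if k not in ("train_x", "train_y")},
                "shapiro_w_before": tr.shapiro_before,
                "shapiro_w_after": tr.shapiro_after,
            }
        try:
            mm = fit_mixed_anova(work, metric, df_method=df_method)
            entry["mixed_anova"] = {
                "estimate": mm.estimate, "se": mm.se, "F": mm.F,
                "df_num": mm.df_num, "df_den": mm.df_den, "p": mm.p_value,
                "var_line": mm.var_line, "var_resid": mm.var_resid,
                "singular": mm.singular, "significant": mm.p_value < alpha,
            }
        except (ValueError, np.linalg.LinAlgError) as exc:
            entry["mixed_anova"] = {"error": str(exc)}
        try:
            es = group_ttest_cohend(work, metric)
            entry["line_mean_ttest"] = {
                "t": es.t, "df": es.df, "p": es.p, "cohen_d": es.cohen_d,
                "mean_diff": es.mean_diff,
            }
        except ValueError as exc:
            entry["line_mean_ttest"] = {"error": str(exc)}
        report["metrics"][metric] = entry
    return report
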