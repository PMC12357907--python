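"""Hierarchical cohort measurement tables: fields of view nested in donor lines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("Ctrl", "SCZ")

DEFAULT_METRICS = ("avg_branch_length", "avg_junction_number")


@dataclass
class CohortDesign:
    """Two-group nested design: lines within groups, fields of view within lines.

    ``group_effect`` is the additive shift applied to the second group (SCZ);
    a scalar applies to all metrics, a dict maps metric name to shift.
    ``n_fov_per_line`` may be an int or an inclusive (lo, hi) range sampled
    per line, mirroring unbalanced field-of-view counts.
    """

    n_lines_per_group: int = 7
    n_fov_per_line: int | tuple[int, int] = 10
    group_effect: float | dict[str, float] = 0.0
    line_sd: float = 0.1
    fov_sd: float = 0.15
    grand_mean: float = 0.5
    metrics: tuple[str, ...] = DEFAULT_METRICS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines_per_group < 1:
            raise ValueError("n_lines_per_group must be >= 1")
        if self.line_sd < 0 or self.fov_sd < 0:
            raise ValueError("SDs must be >= 0")
        fov = self.n_fov_per_line
        if isinstance(fov, int):
            if fov < 1:
                raise ValueError("n_fov_per_line must be >= 1")
        else:
            if len(fov) != 2 or fov[0] < 1 or fov[1] < fov[0]:
                raise ValueError("n_fov_per_line range must be (lo, hi) with 1 <= lo <= hi")

    def effect_for(self, metric: str) -> float:
        if isinstance(self.group_effect, dict):
            return float(self.group_effect.get(metric, 0.0))
        return float(self.group_effect)


def simulate_measurements(design: CohortDesign) -> pd.DataFrame:
    """Draw a tidy measurement table from the nested random-effects model.

    value = grand_mean + group_effect * [group == SCZ] + line intercept + fov noise,
    with line intercepts ~ N(0, line_sd^2) and fov noise ~ N(0, fov_sd^2),
    independently per metric.  Columns: group, line, fov, metric, value.
    """
    rng = np.random.default_rng([design.seed, 0xC0457])
    rows = []
    for g_idx, group in enumerate(GROUPS):
        for li in range(design.n_lines_per_group):
            line_id = f"{group}_{li + 1:02d}"
            fov = design.n_fov_per_line
            n_fov = fov if isinstance(fov, int) else int(rng.integers(fov[0], fov[1] + 1))
            for metric in design.metrics:
                line_eff = rng.normal(0.0, design.line_sd)
                shift = design.effect_for(metric) if g_idx == 1 else 0.0
                vals = design.grand_mean + shift + line_eff + rng.normal(
                    0.0, design.fov_sd, size=n_fov
                )
                for fi, v in enumerate(vals):
                    rows.append((group, line_id, fi + 1, metric, float(v)))
    return pd.DataFrame(rows, columns=["group", "line", "fov", "metric", "value"])
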