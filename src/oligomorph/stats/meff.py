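"""Effective number of independent tests from the correlation eigenspectrum."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class MeffResult:
    m: int  # tests entering the correlation matrix
    eigenvalues: np.ndarray  # descending
    meff: int
    adjusted_alpha: float
    dropped_constant: int = 0


def effective_tests_simplem(statistic_matrix, variance_fraction: float = 0.995,
                            alpha: float = 0.05) -> MeffResult:
    """Eigen-decompose the tests' correlation matrix and count the principal
    components needed to reach ``variance_fraction`` of the total variance.

    ``statistic_matrix`` is samples x tests.  Constant columns carry no test
    and are removed with a warning before computing correlations.
    """
    X = np.asarray(statistic_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a samples x tests matrix")
    if X.shape[0] < 3:
        raise ValueError("need >= 3 samples")
    sd = X.std(axis=0)
    const = sd == 0
    dropped = int(const.sum())
    if dropped:
        log.warning("effective_tests_simplem: dropping %d constant column(s)", dropped)
        X = X[:, ~const]
    m = X.shape[1]
    if m < 2:
        raise ValueError("need >= 2 non-constant tests")
    corr = np.corrcoef(X, rowvar=False)
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.clip(eig, 0.0, None)
    cum = np.cumsum(eig)
    meff = int(np.searchsorted(cum, variance_fraction * cum[-1] - 1e-12) + 1)
    meff = max(1, min(meff, m))
    return MeffResult(m=m, eigenvalues=eig, meff=meff,
                      adjusted_alpha=alpha / meff, dropped_constant=dropped)
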