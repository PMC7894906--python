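"""Z-score abnormality baselines.

Two classical statistics kept for comparison with the adaptive methods:
one using only the individual's history (Student-t reference), and one
substituting a universal pooled within-subject standard deviation
(standard-normal reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import ObservationTable
from .errors import DataError, NumericalError

__all__ = ["ZScoreResult", "zscore_individual", "zscore_sharpe", "pooled_within_subject_variance"]


@dataclass(frozen=True)
class ZScoreResult:
    z: float
    df: int | None
    p_two_sided: float
    method: str


def _denominator_factor(n: int, conventional_factor: bool) -> float:
    # literal printed form uses 1/(n+1); the conventional prediction-interval
    # factor 1/n is available behind a flag for cross-checks
    return float(np.sqrt(1.0 + (1.0 / n if conventional_factor else 1.0 / (n + 1))))


def zscore_individual(
    history: Sequence[float], new_value: float, conventional_factor: bool = False
) -> ZScoreResult:
    """Z-score of a new value against the subject's own history.

    ``z = (y_{n+1} - ybar_n) / (s_n * sqrt(1 + 1/(n+1)))`` with a
    two-sided p-value from the Student t distribution with ``n - 1``
    degrees of freedom.
    """
    y = np.asarray(history, dtype=float)
    n = y.size
    if n < 2:
        raise DataError(f"insufficient history: need n >= 2, got {n}")
    s = float(y.std(ddof=1))
    if s == 0.0:
        raise NumericalError("degenerate history: zero variance")
    z = (float(new_value) - float(y.mean())) / (s * _denominator_factor(n, conventional_factor))
    p = float(2.0 * stats.t.sf(abs(z), n - 1))
    return ZScoreResult(z=float(z), df=n - 1, p_two_sided=p, method="individual")


def pooled_within_subject_variance(table: ObservationTable) -> float:
    """Unbiased pooled WSV: sum of within-subject SS over sum of (n_i - 1)."""
    n, s1, s2 = table.suffstats()
    usable = n >= 2
    if not np.any(usable):
        raise DataError("cannot estimate universal WSV: no subject with >= 2 observations")
    ss = s2[usable] - s1[usable] ** 2 / n[usable]
    df = (n[usable] - 1).sum()
    v = float(ss.sum() / df)
    if v <= 0.0:
        raise NumericalError("degenerate data: pooled within-subject variance is zero")
    return v


def zscore_sharpe(
    table: ObservationTable,
    subject_id: str,
    new_value: float,
    conventional_factor: bool = False,
) -> ZScoreResult:
    """Population-informed Z-score with a universal within-subject SD.

    Same numerator as :func:`zscore_individual` but the subject's sample SD
    is replaced by the pooled within-subject SD estimated across all
    subjects, and the reference distribution is standard normal.
    """
    hist = table.values_for(subject_id)
    if hist.size < 1:
        raise DataError(f"insufficient history for subject {subject_id!r}")
    sigma_uni = float(np.sqrt(pooled_within_subject_variance(table)))
    n = hist.size
    z = (float(new_value) - float(hist.mean())) / (sigma_uni * _denominator_factor(n, conventional_factor))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ZScoreResult(z=float(z), df=None, p_two_sided=p, method="sharpe")
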