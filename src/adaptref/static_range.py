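"""Population-based (static) tolerance-interval reference ranges.

A ``(100p, 100(1-alpha))%`` two-sided normal tolerance interval is
``ybar +/- k * s`` with the tolerance factor ``k`` computed by the
Wald-Wolfowitz/Howe approximation; as n grows, ``k`` approaches the
``(1+p)/2`` standard-normal quantile.  Also hosts the Harris-Boyd
between-group variance-ratio check used to decide stratification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import ObservationTable, ReferenceBand
from .errors import DataError, NumericalError

__all__ = [
    "ToleranceInterval",
    "tolerance_factor",
    "tolerance_interval",
    "static_band_for_subject",
    "static_score",
    "stratification_ratio",
    "HARRIS_BOYD_THRESHOLD",
]

#: Stratify when the larger/smaller ratio of group BSVs exceeds this.
HARRIS_BOYD_THRESHOLD = 1.5


@dataclass(frozen=True)
class ToleranceInterval:
    lower: float
    upper: float
    p: float
    confidence: float
    n: int

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise NumericalError("degenerate tolerance interval")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def tolerance_factor(n: int, p: float = 0.95, confidence: float = 0.95) -> float:
    """Two-sided normal tolerance factor (Howe approximation).

    ``k = z_{(1+p)/2} * sqrt(df * (1 + 1/n) / chi2_{1-confidence, df})``
    with ``df = n - 1``.  Isolated so an exact method can be swapped in.
    """
    if n < 2:
        raise DataError("insufficient data: tolerance factor needs n >= 2")
    if not (0 < p < 1 and 0 < confidence < 1):
        raise DataError("p and confidence must lie in (0, 1)")
    df = n - 1
    z = stats.norm.ppf((1.0 + p) / 2.0)
    chi2 = stats.chi2.ppf(1.0 - confidence, df)
    return float(z * np.sqrt(df * (1.0 + 1.0 / n) / chi2))


def tolerance_interval(
    sample: Sequence[float], p: float = 0.95, confidence: float = 0.95
) -> ToleranceInterval:
    """Normal two-sided tolerance interval ``ybar +/- k s`` for a sample."""
    y = np.asarray(sample, dtype=float)
    if y.size < 3:
        raise DataError(f"insufficient data: need n >= 3, got {y.size}")
    if not np.all(np.isfinite(y)):
        raise DataError("invalid value: sample contains non-finite entries")
    s = float(y.std(ddof=1))
    if s == 0.0:
        raise NumericalError("degenerate sample: zero variance")
    m = float(y.mean())
    k = tolerance_factor(y.size, p, confidence)
    return ToleranceInterval(m - k * s, m + k * s, p, confidence, int(y.size))


def _control_pool(
    table: ObservationTable, subject_id: str, per_subject_means: bool
) -> np.ndarray:
    pos = table.position(subject_id)
    mask = table.subject_pos != pos
    if per_subject_means:
        others = table.without_subject(subject_id)
        return others.subject_means()
    return table.value[mask]


def static_band_for_subject(
    table: ObservationTable,
    subject_id: str,
    p: float = 0.95,
    confidence: float = 0.95,
    per_subject_means: bool = False,
) -> ReferenceBand:
    """Leave-one-subject-out static band for every index of a subject.

    The tolerance interval is fitted on the pooled observations of all
    other subjects (or on their per-subject means if requested) and
    replicated, unchanged, across the subject's observation indices.
    """
    if table.n_subjects < 2:
        raise DataError("need at least 2 subjects for a leave-one-out static band")
    pool = _control_pool(table, subject_id, per_subject_means)
    ti = tolerance_interval(pool, p, confidence)
    band = ReferenceBand(alpha_level=1.0 - p)
    for j, v in enumerate(table.values_for(subject_id), start=1):
        band.append(subject_id, j, ti.lower, ti.upper, v, "static")
    return band


def static_score(
    table: ObservationTable, subject_id: str, observed: float, per_subject_means: bool = False
) -> float:
    """Two-sided normal tail probability under the control-cohort fit.

    The abnormality score used for ROC evaluation of the static method:
    small values indicate atypical observations.
    """
    pool = _control_pool(table, subject_id, per_subject_means)
    if pool.size < 3:
        raise DataError("insufficient data: control pool smaller than 3")
    s = float(pool.std(ddof=1))
    if s == 0.0:
        raise NumericalError("degenerate sample: zero variance in control pool")
    z = abs(observed - float(pool.mean())) / s
    return float(2.0 * stats.norm.sf(z))


def stratification_ratio(
    table: ObservationTable, group_labels: Mapping[str, str] | None = None
) -> float:
    """Harris-Boyd ratio of between-subject variances across two groups.

    Computes the variance of subject means within each group and returns
    larger/smaller; the caller stratifies when the ratio exceeds
    :data:`HARRIS_BOYD_THRESHOLD`.
    """
    labels = group_labels if group_labels is not None else table.groups
    if labels is None:
        raise DataError("no group labels supplied")
    means = table.subject_means()
    by_group: dict[str, list[float]] = {}
    for sid, m in zip(table.subject_ids, means):
        try:
            g = labels[sid]
        except KeyError:
            raise DataError(f"missing group label for subject {sid!r}") from None
        by_group.setdefault(str(g), []).append(float(m))
    if len(by_group) != 2:
        raise DataError(f"need exactly two groups, got {sorted(by_group)}")
    bsvs = []
    for g, ms in by_group.items():
        if len(ms) < 2:
            raise DataError(f"insufficient group data: group {g!r} has < 2 subjects")
        bsvs.append(float(np.var(ms, ddof=1)))
    lo, hi = sorted(bsvs)
    if lo == 0.0:
        raise NumericalError("degenerate group: zero between-subject variance")
    return hi / lo
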