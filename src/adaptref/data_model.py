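"""Core data structures and the synthetic-data generator.

The universal input is a long-format table of longitudinal biomarker
records ``(subject, index, value)`` where ``index`` is the 1-based
observation order within a subject.  All models in this package are
exchangeable within subject, so timestamps are reduced to rank order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, NumericalError

__all__ = [
    "Hyperparameters",
    "ObservationTable",
    "PopulationParameters",
    "ReferenceBand",
    "BandEntry",
    "Sigma2Spec",
    "validate_table",
    "simulate_population",
]


@dataclass(frozen=True)
class Hyperparameters:
    """Prior constants of the hierarchical normal model.

    ``nu`` is the prior standard deviation of the grand mean, ``alpha1`` /
    ``beta1`` the inverse-gamma shape/scale for the within-subject
    variances, ``alpha2`` / ``beta2`` the same for the between-subject
    variance, and ``alpha_level`` the two-sided miscoverage of reference
    bands.
    """

    nu: float = 1e3
    alpha1: float = 0.01
    beta1: float = 0.01
    alpha2: float = 0.01
    beta2: float = 0.01
    alpha_level: float = 0.05

    def __post_init__(self) -> None:
        for name in ("nu", "alpha1", "beta1", "alpha2", "beta2"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise DataError(f"hyperparameter {name} must be positive, got {v!r}")
        if not 0.0 < self.alpha_level < 1.0:
            raise DataError(f"alpha_level must be in (0, 1), got {self.alpha_level!r}")


@dataclass(frozen=True)
class PopulationParameters:
    """Generating parameters: grand mean, BSV and per-subject WSV.

    ``mu_i_by_subject`` carries the realised subject means when the
    parameters come from the synthetic generator; the simulation study's
    case-alteration rule needs them.
    """

    mu: float
    tau2: float
    sigma2_by_subject: Mapping[str, float]
    mu_i_by_subject: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.tau2 > 0:
            raise DataError(f"tau2 must be positive, got {self.tau2!r}")
        for sid, s2 in self.sigma2_by_subject.items():
            if not s2 > 0:
                raise DataError(f"sigma2 for subject {sid!r} must be positive, got {s2!r}")

    def sigma2_array(self, subject_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.sigma2_by_subject[s] for s in subject_ids], dtype=float)


class ObservationTable:
    """Validated long-format table of longitudinal observations.

    Stores parallel arrays (one element per record) plus per-subject
    sufficient statistics ``(n_i, sum y, sum y^2)`` that every model in the
    package consumes.  Subjects keep their order of first appearance.
    """

    __slots__ = ("subject_ids", "_pos", "subject_pos", "index", "value", "groups")

    def __init__(
        self,
        subject_ids: Sequence[str],
        subject_pos: np.ndarray,
        index: np.ndarray,
        value: np.ndarray,
        groups: Mapping[str, str] | None = None,
    ) -> None:
        self.subject_ids: list[str] = list(subject_ids)
        self._pos = {s: k for k, s in enumerate(self.subject_ids)}
        self.subject_pos = np.asarray(subject_pos, dtype=np.intp)
        self.index = np.asarray(index, dtype=np.intp)
        self.value = np.asarray(value, dtype=float)
        self.groups = dict(groups) if groups is not None else None

    # -- basic introspection -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_records(self) -> int:
        return self.value.size

    def __len__(self) -> int:
        return self.n_records

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self._pos

    def position(self, subject_id: str) -> int:
        try:
            return self._pos[subject_id]
        except KeyError:
            raise DataError(f"unknown subject {subject_id!r}") from None

    def n_obs(self, subject_id: str) -> int:
        return int(np.count_nonzero(self.subject_pos == self.position(subject_id)))

    def values_for(self, subject_id: str) -> np.ndarray:
        """Values of one subject, ordered by observation index."""
        mask = self.subject_pos == self.position(subject_id)
        order = np.argsort(self.index[mask], kind="stable")
        return self.value[mask][order]

    def counts(self) -> np.ndarray:
        return np.bincount(self.subject_pos, minlength=self.n_subjects).astype(np.intp)

    def suffstats(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-subject ``(n_i, sum_j y_ij, sum_j y_ij^2)`` in subject order."""
        n = self.counts()
        s1 = np.bincount(self.subject_pos, weights=self.value, minlength=self.n_subjects)
        s2 = np.bincount(self.subject_pos, weights=self.value**2, minlength=self.n_subjects)
        return n, s1, s2

    def subject_means(self) -> np.ndarray:
        n, s1, _ = self.suffstats()
        return s1 / np.maximum(n, 1)

    # -- derived tables ------------------------------------------------------

    def records(self) -> list[tuple[str, int, float]]:
        return [
            (self.subject_ids[p], int(j), float(v))
            for p, j, v in zip(self.subject_pos, self.index, self.value)
        ]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject": [self.subject_ids[p] for p in self.subject_pos],
                "index": self.index,
                "value": self.value,
            }
        )
        if self.groups is not None:
            df["group"] = [self.groups[s] for s in df["subject"]]
        return df

    def without_subject(self, subject_id: str) -> "ObservationTable":
        pos = self.position(subject_id)
        keep = self.subject_pos != pos
        return validate_table(
            [
                (self.subject_ids[p], int(j), float(v))
                for p, j, v in zip(self.subject_pos[keep], self.index[keep], self.value[keep])
            ],
            groups=self.groups,
        )

    def with_prefix(self, subject_id: str, n_keep: int) -> "ObservationTable":
        """Copy keeping only ``subject_id``'s first ``n_keep`` observations."""
        pos = self.position(subject_id)
        keep = (self.subject_pos != pos) | (self.index <= n_keep)
        return validate_table(
            [
                (self.subject_ids[p], int(j), float(v))
                for p, j, v in zip(self.subject_pos[keep], self.index[keep], self.value[keep])
            ],
            groups=self.groups,
        )

    def drop_final_observations(self) -> tuple["ObservationTable", np.ndarray]:
        """Remove each subject's last observation.

        Returns the reduced table and the removed values (subject order).
        Subjects with a single observation keep it (they would otherwise
        vanish) and contribute ``nan`` in the returned array.
        """
        n = self.counts()
        finals = np.full(self.n_subjects, np.nan)
        is_final = self.index == n[self.subject_pos]
        droppable = is_final & (n[self.subject_pos] > 1)
        for p, v in zip(self.subject_pos[is_final], self.value[is_final]):
            finals[p] = v
        keep = ~droppable
        reduced = ObservationTable(
            self.subject_ids,
            self.subject_pos[keep],
            self.index[keep],
            self.value[keep],
            groups=self.groups,
        )
        return reduced, finals

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ObservationTable):
            return NotImplemented
        return (
            self.subject_ids == other.subject_ids
            and np.array_equal(self.subject_pos, other.subject_pos)
            and np.array_equal(self.index, other.index)
            and np.array_equal(self.value, other.value)
        )


def validate_table(
    raw_records: Iterable[tuple],
    groups: Mapping[str, str] | None = None,
) -> ObservationTable:
    """Build a canonical :class:`ObservationTable` from raw records.

    Records are ``(subject, index_or_timestamp, value)`` triples.  Within
    each subject the observations are re-indexed 1..n_i by sort order of
    the supplied index, so arbitrary (strictly ordered) timestamps are
    accepted.

    Raises
    ------
    DataError
        "no data" for empty input, "duplicate observation" for repeated
        ``(subject, index)`` pairs, "invalid value" for non-numeric or
        non-finite values.
    """
    records = list(raw_records)
    if not records:
        raise DataError("no data")

    subject_ids: list[str] = []
    pos_of: dict[str, int] = {}
    per_subject: dict[int, list[tuple[float, float]]] = {}
    for rec in records:
        try:
            sid, idx, val = rec
        except (TypeError, ValueError) as exc:
            raise DataError(f"malformed record {rec!r}") from exc
        sid = str(sid)
        try:
            idx = float(idx)
            val = float(val)
        except (TypeError, ValueError) as exc:
            raise DataError(f"invalid value in record {rec!r}") from exc
        if not math.isfinite(idx):
            raise DataError(f"invalid value: non-finite index in record {rec!r}")
        if not math.isfinite(val):
            raise DataError(f"invalid value: non-finite value in record {rec!r}")
        if sid not in pos_of:
            pos_of[sid] = len(subject_ids)
            subject_ids.append(sid)
        per_subject.setdefault(pos_of[sid], []).append((idx, val))

    subject_pos: list[int] = []
    index: list[int] = []
    value: list[float] = []
    for p in range(len(subject_ids)):
        obs = per_subject[p]
        seen = {i for i, _ in obs}
        if len(seen) != len(obs):
            raise DataError(f"duplicate observation for subject {subject_ids[p]!r}")
        obs.sort(key=lambda t: t[0])
        for j, (_, v) in enumerate(obs, start=1):
            subject_pos.append(p)
            index.append(j)
            value.append(v)

    if groups is not None:
        missing = [s for s in subject_ids if s not in groups]
        if missing:
            raise DataError(f"missing group label for subjects {missing!r}")
        groups = {s: groups[s] for s in subject_ids}

    return ObservationTable(
        subject_ids,
        np.array(subject_pos, dtype=np.intp),
        np.array(index, dtype=np.intp),
        np.array(value, dtype=float),
        groups=groups,
    )


@dataclass(frozen=True)
class BandEntry:
    subject_id: str
    index: int
    lower: float
    upper: float
    observed: float
    atypical: bool
    method: str


@dataclass
class ReferenceBand:
    """Per-observation reference limits with atypical flags."""

    entries: list[BandEntry] = field(default_factory=list)
    alpha_level: float = 0.05

    def append(
        self, subject_id: str, index: int, lower: float, upper: float, observed: float, method: str
    ) -> None:
        if not lower < upper:
            raise NumericalError(f"degenerate band: lower {lower!r} !< upper {upper!r}")
        atypical = bool(observed < lower or observed > upper)
        self.entries.append(BandEntry(subject_id, int(index), float(lower), float(upper), float(observed), atypical, method))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [e.subject_id for e in self.entries],
                "index": [e.index for e in self.entries],
                "value": [e.observed for e in self.entries],
                "lower": [e.lower for e in self.entries],
                "upper": [e.upper for e in self.entries],
                "atypical": [e.atypical for e in self.entries],
                "method": [e.method for e in self.entries],
            }
        )

    def flag_rate(self) -> float:
        if not self.entries:
            return float("nan")
        return sum(e.atypical for e in self.entries) / len(self.entries)


@dataclass(frozen=True)
class Sigma2Spec:
    """How within-subject variances are generated.

    Either a fixed common variance, or heterogeneous variances drawn from
    an inverse-gamma distribution whose mean and variance are moment-matched
    to ``(r2 * tau2, r1 * tau2**2)`` — the generating distribution is an
    implementation choice consistent with the model's inverse-gamma prior.
    """

    fixed_value: float | None = None
    r1: float | None = None
    r2: float | None = None

    @classmethod
    def fixed(cls, value: float) -> "Sigma2Spec":
        if not value > 0:
            raise DataError(f"invalid variance spec: fixed sigma2 {value!r} must be > 0")
        return cls(fixed_value=float(value))

    @classmethod
    def from_ratios(cls, r1: float, r2: float) -> "Sigma2Spec":
        if r1 < 0 or not r2 > 0:
            raise DataError(f"invalid variance spec: need r1 >= 0 and r2 > 0, got {(r1, r2)!r}")
        return cls(r1=float(r1), r2=float(r2))

    def draw(self, n: int, tau2: float, rng: np.random.Generator) -> np.ndarray:
        if self.fixed_value is not None:
            return np.full(n, self.fixed_value)
        mean = self.r2 * tau2
        var = self.r1 * tau2**2
        if var == 0.0:
            return np.full(n, mean)
        # inverse gamma with matched first two moments: shape a = 2 + mean^2/var
        a = 2.0 + mean**2 / var
        b = mean * (a - 1.0)
        draws = b / rng.standard_gamma(a, size=n)
        return draws


def simulate_population(
    I: int,
    n_per_subject: int | Sequence[int],
    mu: float,
    tau2: float,
    sigma2_spec: Sigma2Spec | float,
    seed: int | np.random.Generator,
) -> tuple[ObservationTable, PopulationParameters]:
    """Simulate a hierarchical-normal population.

    Subject means are drawn i.i.d. from ``N(mu, tau2)`` and observations
    from ``N(mu_i, sigma_i^2)`` with within-subject variances given by
    ``sigma2_spec``.  Fully reproducible under a fixed seed.
    """
    if I < 1:
        raise DataError("need at least one subject")
    if not tau2 > 0:
        raise DataError(f"invalid variance spec: tau2 {tau2!r} must be > 0")
    if isinstance(sigma2_spec, (int, float)):
        sigma2_spec = Sigma2Spec.fixed(float(sigma2_spec))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_arr = (
        np.full(I, int(n_per_subject), dtype=np.intp)
        if np.isscalar(n_per_subject)
        else np.asarray(n_per_subject, dtype=np.intp)
    )
    if n_arr.size != I or np.any(n_arr < 1):
        raise DataError("n_per_subject must be a positive scalar or length-I sequence")

    mu_i = mu + math.sqrt(tau2) * rng.standard_normal(I)
    sigma2_i = sigma2_spec.draw(I, tau2, rng)
    total = int(n_arr.sum())
    subject_pos = np.repeat(np.arange(I, dtype=np.intp), n_arr)
    index = np.concatenate([np.arange(1, n + 1, dtype=np.intp) for n in n_arr])
    value = mu_i[subject_pos] + np.sqrt(sigma2_i)[subject_pos] * rng.standard_normal(total)

    subject_ids = [f"S{k + 1}" for k in range(I)]
    table = ObservationTable(subject_ids, subject_pos, index, value)
    params = PopulationParameters(
        mu=float(mu),
        tau2=float(tau2),
        sigma2_by_subject={sid: float(s2) for sid, s2 in zip(subject_ids, sigma2_i)},
        mu_i_by_subject={sid: float(m) for sid, m in zip(subject_ids, mu_i)},
    )
    return table, params
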