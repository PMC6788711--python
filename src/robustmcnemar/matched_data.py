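"""Ingest unit-level data, coarsen covariates, and build exact-match partitions.

A *unit* is one observational sample: a binary treatment indicator
(1 = treated / post-policy), a binary outcome, and a set of covariates.
Exact matching on the (coarsened) covariate signature groups units into
*partitions*; within a partition every treated unit is an admissible match
for every control unit.  Partitions that lack one of the two arms provide no
common support and are dropped (and counted) rather than matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, NoCommonSupportError, ValidationError

__all__ = [
    "Unit",
    "CoarseningScheme",
    "OutcomeTally",
    "Partition",
    "MatchedSet",
    "read_units",
    "coarsen",
    "build_partitions",
    "tally_partition",
]


@dataclass(frozen=True)
class Unit:
    """One observational sample.

    Parameters
    ----------
    unit_id : str
        Opaque identifier, unique within a dataset.
    treatment : int
        Binary treatment indicator; 1 means treated (post-policy era).
    outcome : int
        Binary outcome.
    covariates : tuple of (name, value)
        Ordered covariate mapping; values may be categorical labels or
        numbers before coarsening, labels only afterwards.
    """

    unit_id: str
    treatment: int
    outcome: int
    covariates: tuple[tuple[str, object], ...]

    def __post_init__(self) -> None:
        if self.treatment not in (0, 1):
            raise ValidationError(
                f"unit {self.unit_id!r}: treatment must be 0 or 1, got {self.treatment!r}"
            )
        if self.outcome not in (0, 1):
            raise ValidationError(
                f"unit {self.unit_id!r}: outcome must be 0 or 1, got {self.outcome!r}"
            )

    @property
    def covariate_dict(self) -> dict[str, object]:
        return dict(self.covariates)


@dataclass(frozen=True)
class NumericBins:
    """Ordered bins mapping a numeric covariate to category labels.

    Intervals are left-closed / right-open, ``[b_i, b_{i+1})``; when
    ``open_ended`` is true the last bin is ``[b_last, +inf)``.  Values outside
    every bin are rejected rather than clipped.
    """

    boundaries: tuple[float, ...]
    labels: tuple[str, ...]
    open_ended: bool = True

    def __post_init__(self) -> None:
        if any(b >= a for b, a in zip(self.boundaries, self.boundaries[1:])):
            raise ConfigurationError("bin boundaries must be strictly increasing")
        n_bins = len(self.boundaries) if self.open_ended else len(self.boundaries) - 1
        if len(self.labels) != n_bins:
            raise ConfigurationError(
                f"expected {n_bins} labels for {len(self.boundaries)} boundaries "
                f"(open_ended={self.open_ended}), got {len(self.labels)}"
            )

    def apply(self, value: float) -> str:
        v = float(value)
        if v < self.boundaries[0]:
            raise ValidationError(f"value {value!r} below first bin boundary")
        for i in range(len(self.boundaries) - 1):
            if self.boundaries[i] <= v < self.boundaries[i + 1]:
                return self.labels[i]
        if self.open_ended:
            return self.labels[-1]
        raise ValidationError(f"value {value!r} above last bin boundary")


CATEGORICAL = "categorical"


@dataclass(frozen=True)
class CoarseningScheme:
    """Per-covariate coarsening rules: pass-through categorical or numeric bins."""

    rules: tuple[tuple[str, object], ...]  # name -> CATEGORICAL or NumericBins

    @classmethod
    def from_dict(cls, mapping: Mapping[str, object]) -> "CoarseningScheme":
        """Build a scheme from a plain mapping (e.g. parsed YAML).

        Each value is either the string ``"categorical"`` or a mapping with
        keys ``boundaries``, ``labels`` and optional ``open_ended``.
        """
        rules = []
        for name, rule in mapping.items():
            if rule == CATEGORICAL:
                rules.append((name, CATEGORICAL))
            elif isinstance(rule, Mapping):
                rules.append(
                    (
                        name,
                        NumericBins(
                            boundaries=tuple(float(b) for b in rule["boundaries"]),
                            labels=tuple(str(l) for l in rule["labels"]),
                            open_ended=bool(rule.get("open_ended", True)),
                        ),
                    )
                )
            else:
                raise ConfigurationError(
                    f"covariate {name!r}: rule must be 'categorical' or a bins mapping"
                )
        return cls(rules=tuple(rules))

    @classmethod
    def all_categorical(cls, names: Iterable[str]) -> "CoarseningScheme":
        return cls(rules=tuple((n, CATEGORICAL) for n in names))

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.rules)

    def apply(self, name: str, value: object, unit_id: str = "?") -> str:
        rule = dict(self.rules).get(name)
        if rule is None:
            raise ConfigurationError(f"no coarsening rule for covariate {name!r}")
        if rule == CATEGORICAL:
            return str(value)
        try:
            return rule.apply(value)  # type: ignore[union-attr]
        except ValidationError as exc:
            raise ValidationError(f"covariate {name!r}, unit {unit_id!r}: {exc}") from None


@dataclass(frozen=True)
class OutcomeTally:
    """Per-arm outcome counts for one partition.

    ``n_t_pos``/``n_t_neg`` count treated units with outcome 1/0;
    ``n_c_pos``/``n_c_neg`` count controls likewise.
    """

    n_t_pos: int
    n_t_neg: int
    n_c_pos: int
    n_c_neg: int

    def __post_init__(self) -> None:
        for name in ("n_t_pos", "n_t_neg", "n_c_pos", "n_c_neg"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def n_treated(self) -> int:
        return self.n_t_pos + self.n_t_neg

    @property
    def n_control(self) -> int:
        return self.n_c_pos + self.n_c_neg

    @property
    def max_pairs(self) -> int:
        """Largest number of one-to-one pairs this partition can host."""
        return min(self.n_treated, self.n_control)


@dataclass(frozen=True)
class Partition:
    """An exact-match cell: all members share one coarsened covariate signature."""

    key: tuple[str, ...]
    treated_ids: tuple[str, ...]
    control_ids: tuple[str, ...]
    tally: OutcomeTally


@dataclass(frozen=True)
class MatchedSet:
    """The set of good matches M, partitioned by exact covariate signature.

    Only two-armed partitions are retained; ``n_dropped_units`` and
    ``n_dropped_partitions`` record the common-support losses.
    """

    partitions: tuple[Partition, ...]
    covariate_names: tuple[str, ...] = ()
    n_dropped_units: int = 0
    n_dropped_partitions: int = 0

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    @property
    def n_units(self) -> int:
        return sum(p.tally.n_treated + p.tally.n_control for p in self.partitions)

    @classmethod
    def from_tallies(cls, tallies: Sequence[OutcomeTally]) -> "MatchedSet":
        """Build a matched set directly from per-partition tallies (no unit ids)."""
        parts = tuple(
            Partition(key=(f"p{i:04d}",), treated_ids=(), control_ids=(), tally=t)
            for i, t in enumerate(tallies)
        )
        return cls(partitions=parts, covariate_names=("stratum",))


def read_units(
    source,
    id_col: str = "id",
    treatment_col: str = "treatment",
    outcome_col: str = "outcome",
    covariate_cols: Sequence[str] | None = None,
) -> list[Unit]:
    """Read a delimited unit table into validated :class:`Unit` records.

    ``source`` is anything :func:`pandas.read_csv` accepts.  Columns not named
    as id/treatment/outcome are taken as covariates unless ``covariate_cols``
    restricts them.  Treatment and outcome must parse as integer 0/1; rows
    violating that are reported by unit id in a single :class:`ValidationError`.
    """
    df = pd.read_csv(source)
    for col in (id_col, treatment_col, outcome_col):
        if col not in df.columns:
            raise ConfigurationError(f"required column {col!r} not found in input")
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c not in (id_col, treatment_col, outcome_col)]
    else:
        missing = [c for c in covariate_cols if c not in df.columns]
        if missing:
            raise ConfigurationError(f"covariate columns not found: {missing}")

    units: list[Unit] = []
    bad_rows: list[str] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        rec = row._asdict()
        uid = str(rec[id_col])
        if uid in seen:
            raise ValidationError(f"duplicate unit id {uid!r}")
        seen.add(uid)
        try:
            t = _as_binary(rec[treatment_col])
            y = _as_binary(rec[outcome_col])
        except ValueError as exc:
            bad_rows.append(f"{uid}: {exc}")
            continue
        covs = []
        for c in covariate_cols:
            v = rec[c]
            if pd.isna(v):
                bad_rows.append(f"{uid}: missing covariate {c!r}")
                break
            covs.append((c, v))
        else:
            units.append(Unit(unit_id=uid, treatment=t, outcome=y, covariates=tuple(covs)))
    if bad_rows:
        raise ValidationError(
            "invalid rows: " + "; ".join(bad_rows[:10])
            + (f" (+{len(bad_rows) - 10} more)" if len(bad_rows) > 10 else "")
        )
    return units


def _as_binary(value) -> int:
    if pd.isna(value):
        raise ValueError("missing value")
    f = float(value)
    i = int(f)
    if i != f or i not in (0, 1):
        raise ValueError(f"must be 0 or 1, got {value!r}")
    return i


def coarsen(units: Iterable[Unit], scheme: CoarseningScheme) -> list[Unit]:
    """Map every covariate value to its category label under ``scheme``.

    Original units are untouched; a numeric value outside all bins raises
    :class:`ValidationError` naming the covariate and unit.
    """
    out: list[Unit] = []
    scheme_names = set(scheme.covariate_names)
    for u in units:
        missing = [n for n, _ in u.covariates if n not in scheme_names]
        if missing:
            raise ConfigurationError(
                f"unit {u.unit_id!r} has covariates with no coarsening rule: {missing}"
            )
        covs = tuple(
            (name, scheme.apply(name, value, unit_id=u.unit_id)) for name, value in u.covariates
        )
        out.append(Unit(u.unit_id, u.treatment, u.outcome, covs))
    return out


def tally_partition(
    treated_outcomes: Sequence[int], control_outcomes: Sequence[int]
) -> OutcomeTally:
    """Count the four per-arm outcome cells for one partition's members."""
    if len(treated_outcomes) == 0 and len(control_outcomes) == 0:
        raise ValidationError("cannot tally an empty partition")
    t_pos = sum(1 for y in treated_outcomes if y == 1)
    c_pos = sum(1 for y in control_outcomes if y == 1)
    return OutcomeTally(
        n_t_pos=t_pos,
        n_t_neg=len(treated_outcomes) - t_pos,
        n_c_pos=c_pos,
        n_c_neg=len(control_outcomes) - c_pos,
    )


def build_partitions(units: Sequence[Unit]) -> MatchedSet:
    """Group coarsened units by exact covariate-signature equality.

    Partitions lacking either arm are excluded from the matched set and
    counted as common-support drops.  Partition order is fixed by sorting
    signatures, so downstream reports are reproducible.
    """
    if not units:
        raise ValidationError("no units to partition")
    cov_names = tuple(name for name, _ in units[0].covariates)
    groups: dict[tuple[str, ...], list[Unit]] = {}
    for u in units:
        names = tuple(name for name, _ in u.covariates)
        if names != cov_names:
            raise ConfigurationError(
                f"unit {u.unit_id!r} has covariate names {names}, expected {cov_names}"
            )
        key = tuple(str(v) for _, v in u.covariates)
        groups.setdefault(key, []).append(u)

    partitions: list[Partition] = []
    dropped_units = 0
    dropped_partitions = 0
    for key in sorted(groups):
        members = groups[key]
        treated = [u for u in members if u.treatment == 1]
        control = [u for u in members if u.treatment == 0]
        if not treated or not control:
            dropped_units += len(members)
            dropped_partitions += 1
            continue
        partitions.append(
            Partition(
                key=key,
                treated_ids=tuple(u.unit_id for u in treated),
                control_ids=tuple(u.unit_id for u in control),
                tally=tally_partition(
                    [u.outcome for u in treated], [u.outcome for u in control]
                ),
            )
        )
    if not partitions:
        raise NoCommonSupportError(
            "no common support: every covariate signature is single-armed"
        )
    return MatchedSet(
        partitions=tuple(partitions),
        covariate_names=cov_names,
        n_dropped_units=dropped_units,
        n_dropped_partitions=dropped_partitions,
    )
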