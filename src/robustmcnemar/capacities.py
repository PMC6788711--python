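"""Discordant-pair capacities per partition and in aggregate.

Within an exact-match partition any treated unit may pair with any control
unit, so the largest attainable count of each discordant pair type is a
simple minimum of per-arm outcome counts:

* ``B`` pairs a treated unit with outcome 0 to a control with outcome 1,
  so ``B_p = min(n_t_neg, n_c_pos)``;
* ``C`` pairs a treated unit with outcome 1 to a control with outcome 0,
  so ``C_p = min(n_t_pos, n_c_neg)``.

Filling the leftover units into the concordant types ``A`` (both 1) and
``D`` (both 0) exhausts the partition: B + C + A + D = min(N_t, N_c), the
maximum number of one-to-one pairs the partition can host.  Aggregates are
sums over partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ValidationError
from .matched_data import MatchedSet, OutcomeTally

__all__ = [
    "PartitionCapacities",
    "CapacitySet",
    "discordant_capacities",
    "concordant_fill",
    "aggregate_capacities",
]


def discordant_capacities(tally: OutcomeTally) -> tuple[int, int]:
    """Maximum attainable (B, C) discordant counts for one partition."""
    b = min(tally.n_t_neg, tally.n_c_pos)
    c = min(tally.n_t_pos, tally.n_c_neg)
    return b, c


def concordant_fill(tally: OutcomeTally, b: int, c: int) -> tuple[int, int]:
    """Concordant fills (A, D) after assigning the discordant capacities.

    ``b`` and ``c`` must be the capacities of ``tally``; with those removed,
    A = min(n_t_pos - c, n_c_pos - b) and D = min(n_t_neg - b, n_c_neg - c),
    and the four counts sum to min(N_t, N_c).
    """
    b_cap, c_cap = discordant_capacities(tally)
    if (b, c) != (b_cap, c_cap):
        raise ValidationError(
            f"concordant_fill requires the capacity split ({b_cap}, {c_cap}), got ({b}, {c})"
        )
    a = min(tally.n_t_pos - c, tally.n_c_pos - b)
    d = min(tally.n_t_neg - b, tally.n_c_neg - c)
    return a, d


@dataclass(frozen=True)
class PartitionCapacities:
    """Capacity quadruple for one partition; sums to the partition's max pairs."""

    key: tuple[str, ...]
    b: int
    c: int
    a: int
    d: int
    max_pairs: int

    @classmethod
    def from_tally(cls, tally: OutcomeTally, key: tuple[str, ...] = ()) -> "PartitionCapacities":
        b, c = discordant_capacities(tally)
        a, d = concordant_fill(tally, b, c)
        return cls(key=key, b=b, c=c, a=a, d=d, max_pairs=tally.max_pairs)


@dataclass(frozen=True)
class CapacitySet:
    """Per-partition capacities and their aggregates.

    ``b_max`` and ``c_max`` bound the total counts of the two discordant pair
    types over all admissible assignments; ``m_max = b_max + c_max`` is the
    largest feasible total discordant count, at which the test statistic's
    maximum and minimum coincide.
    """

    per_partition: tuple[PartitionCapacities, ...]
    b_max: int
    c_max: int
    a_max: int
    d_max: int
    max_pairs: int

    def __post_init__(self) -> None:
        if self.per_partition:
            if self.b_max != sum(p.b for p in self.per_partition):
                raise ValidationError("b_max does not equal the per-partition sum")
            if self.c_max != sum(p.c for p in self.per_partition):
                raise ValidationError("c_max does not equal the per-partition sum")

    @property
    def m_max(self) -> int:
        return self.b_max + self.c_max

    @classmethod
    def from_aggregates(cls, b_max: int, c_max: int) -> "CapacitySet":
        """Capacity set known only at the aggregate level (no partition detail)."""
        if b_max < 0 or c_max < 0:
            raise ValidationError("capacities must be nonnegative")
        return cls(
            per_partition=(),
            b_max=int(b_max),
            c_max=int(c_max),
            a_max=0,
            d_max=0,
            max_pairs=b_max + c_max,
        )


def aggregate_capacities(matched_set: MatchedSet) -> CapacitySet:
    """Compute per-partition capacity quadruples and sum them over M."""
    if matched_set.n_partitions == 0:
        raise ValidationError("matched set has no partitions")
    per = tuple(
        PartitionCapacities.from_tally(p.tally, key=p.key) for p in matched_set.partitions
    )
    return CapacitySet(
        per_partition=per,
        b_max=sum(p.b for p in per),
        c_max=sum(p.c for p in per),
        a_max=sum(p.a for p in per),
        d_max=sum(p.d for p in per),
        max_pairs=sum(p.max_pairs for p in per),
    )
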