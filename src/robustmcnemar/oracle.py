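"""Brute-force ground truth for small matched instances.

Enumerates all admissible pair assignments with a fixed total discordant
count m and returns the exact extrema of the statistic.  Two modes:

* ``"splits"`` (default): enumerate per-partition discordant split counts
  (b_p <= B_p, c_p <= C_p, sum = m).  Units of equal (arm, outcome) within a
  partition are exchangeable, so this is equivalent to enumerating raw
  unit-level assignments while being factorially smaller.
* ``"units"``: enumerate raw injective treated-to-control assignments for a
  single partition of at most 4x4 units — a direct double-check of the
  exchangeability argument.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .capacities import aggregate_capacities
from .exceptions import InfeasibleError, OracleSizeError, ValidationError
from .extrema import DiscordantSplit, lambda_stat
from .matched_data import MatchedSet

__all__ = ["Assignment", "enumerate_extrema", "oracle_profile"]

_DEFAULT_GUARD = 12
_UNITS_GUARD = 4


@dataclass(frozen=True)
class Assignment:
    """A witness assignment: per-partition (b, c) splits and induced totals."""

    splits: tuple[tuple[int, int], ...]

    @property
    def b(self) -> int:
        return sum(s[0] for s in self.splits)

    @property
    def c(self) -> int:
        return sum(s[1] for s in self.splits)


def _check_guard(matched_set: MatchedSet, guard: int) -> None:
    n_t = sum(p.tally.n_treated for p in matched_set.partitions)
    n_c = sum(p.tally.n_control for p in matched_set.partitions)
    if n_t > guard or n_c > guard:
        raise OracleSizeError(
            f"instance has {n_t} treated and {n_c} controls; oracle guard is {guard} per arm"
        )


def _unit_level_extrema(matched_set: MatchedSet, m: int):
    """Enumerate raw injective pairings for a single small partition."""
    if matched_set.n_partitions != 1:
        raise OracleSizeError("units mode handles a single partition only")
    tally = matched_set.partitions[0].tally
    if tally.n_treated > _UNITS_GUARD or tally.n_control > _UNITS_GUARD:
        raise OracleSizeError(f"units mode guard is {_UNITS_GUARD} per arm")
    yt = [1] * tally.n_t_pos + [0] * tally.n_t_neg
    yc = [1] * tally.n_c_pos + [0] * tally.n_c_neg
    best: dict[str, tuple[float, Assignment]] = {}
    for k in range(0, min(len(yt), len(yc)) + 1):
        for t_idx in itertools.combinations(range(len(yt)), k):
            for c_idx in itertools.permutations(range(len(yc)), k):
                b = sum(1 for ti, ci in zip(t_idx, c_idx) if yt[ti] == 0 and yc[ci] == 1)
                c = sum(1 for ti, ci in zip(t_idx, c_idx) if yt[ti] == 1 and yc[ci] == 0)
                if b + c != m:
                    continue
                lam = lambda_stat(DiscordantSplit(b=b, c=c)).value
                wit = Assignment(splits=((b, c),))
                if "min" not in best or lam < best["min"][0]:
                    best["min"] = (lam, wit)
                if "max" not in best or lam > best["max"][0]:
                    best["max"] = (lam, wit)
    return best


def enumerate_extrema(
    matched_set: MatchedSet, m: int, *, guard: int = _DEFAULT_GUARD, mode: str = "splits"
) -> tuple[float, float, dict[str, Assignment]]:
    """Exact (Lambda_min, Lambda_max) over all assignments with B + C = m.

    Returns the extrema and witness assignments for audit.  Raises
    :class:`InfeasibleError` when no assignment attains the requested m and
    :class:`OracleSizeError` above the size guard.
    """
    if m < 1:
        raise InfeasibleError(f"m must be >= 1, got {m}")
    _check_guard(matched_set, guard)
    if mode == "units":
        best = _unit_level_extrema(matched_set, m)
        if not best:
            raise InfeasibleError(f"no admissible assignment attains m={m}")
        return best["min"][0], best["max"][0], {k: v[1] for k, v in best.items()}
    if mode != "splits":
        raise ValidationError(f"mode must be 'splits' or 'units', got {mode!r}")

    caps = aggregate_capacities(matched_set)
    per_ranges = [
        [(b, c) for b in range(p.b + 1) for c in range(p.c + 1)] for p in caps.per_partition
    ]
    best: dict[str, tuple[float, Assignment]] = {}
    for combo in itertools.product(*per_ranges):
        b = sum(s[0] for s in combo)
        c = sum(s[1] for s in combo)
        if b + c != m:
            continue
        lam = lambda_stat(DiscordantSplit(b=b, c=c)).value
        wit = Assignment(splits=tuple(combo))
        if "min" not in best or lam < best["min"][0]:
            best["min"] = (lam, wit)
        if "max" not in best or lam > best["max"][0]:
            best["max"] = (lam, wit)
    if not best:
        raise InfeasibleError(f"no admissible assignment attains m={m}")
    return best["min"][0], best["max"][0], {k: v[1] for k, v in best.items()}


def oracle_profile(matched_set: MatchedSet, *, guard: int = _DEFAULT_GUARD) -> pd.DataFrame:
    """Exhaustive (m, Lambda_min, Lambda_max) table for every feasible m.

    A single pass over all per-partition split combinations accumulates the
    extrema for every m at once; results are identical to calling
    :func:`enumerate_extrema` per m.
    """
    _check_guard(matched_set, guard)
    caps = aggregate_capacities(matched_set)
    per_ranges = [
        [(b, c) for b in range(p.b + 1) for c in range(p.c + 1)] for p in caps.per_partition
    ]
    lo: dict[int, float] = {}
    hi: dict[int, float] = {}
    for combo in itertools.product(*per_ranges):
        b = sum(s[0] for s in combo)
        c = sum(s[1] for s in combo)
        m = b + c
        if m == 0:
            continue
        lam = lambda_stat(DiscordantSplit(b=b, c=c)).value
        if m not in lo or lam < lo[m]:
            lo[m] = lam
        if m not in hi or lam > hi[m]:
            hi[m] = lam
    rows = [
        {"m": m, "lambda_min": lo[m], "lambda_max": hi[m]} for m in sorted(lo)
    ]
    return pd.DataFrame(rows)
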