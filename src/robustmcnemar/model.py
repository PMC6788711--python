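"""Model/results interface for the robust matched-pairs McNemar test.

:class:`RobustMcNemar` is constructed from a matched set (or directly from
aggregate discordant capacities) and ``fit()`` evaluates the test at the
robustness condition m = B_max + C_max, where the maximum and minimum of the
statistic over all admissible pair assignments coincide.  The returned
:class:`RobustMcNemarResults` carries the statistic, p-values, the
robustness classification, and the uncertainty sweep over smaller m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import extrema
from .capacities import CapacitySet, aggregate_capacities
from .exceptions import InfeasibleError, NoDiscordantPairsError, ValidationError
from .extrema import (
    ABSOLUTE_ROBUST,
    DiscordantSplit,
    LambdaValue,
    lambda_stat,
    optimal_discordant_split,
    p_value,
    robust_decision,
)
from .matched_data import (
    CoarseningScheme,
    MatchedSet,
    OutcomeTally,
    build_partitions,
    coarsen,
    read_units,
)

__all__ = ["RobustMcNemar", "RobustMcNemarResults", "UncertaintyProfile", "allocate_split"]

# Default sweep resolution: coarse enough that a profile table stays readable.
_MAX_DEFAULT_GRID_ROWS = 200


def default_increment(m_max: int) -> int:
    """Smallest increment that keeps the default sweep at or under 200 rows."""
    return max(1, int(np.ceil(m_max / _MAX_DEFAULT_GRID_ROWS)))


def allocate_split(capacities: CapacitySet, split: DiscordantSplit) -> list[tuple[tuple[str, ...], int, int]]:
    """Audit-trail allocation of an aggregate (B, C) split to partitions.

    Fills B from partitions in stored (lexicographic-key) order up to each
    partition's capacity, then C likewise.  The allocation cannot change the
    statistic — only the totals enter Lambda — but lets a reviewer verify
    feasibility partition by partition.
    """
    if not capacities.per_partition:
        raise ValidationError("per-partition allocation needs partition-level capacities")
    if split.b > capacities.b_max or split.c > capacities.c_max:
        raise InfeasibleError(
            f"split ({split.b}, {split.c}) exceeds capacities "
            f"({capacities.b_max}, {capacities.c_max})"
        )
    rows = []
    b_left, c_left = split.b, split.c
    for part in capacities.per_partition:
        b_here = min(b_left, part.b)
        c_here = min(c_left, part.c)
        b_left -= b_here
        c_left -= c_here
        rows.append((part.key, b_here, c_here))
    return rows


@dataclass(frozen=True)
class UncertaintyProfile:
    """Lambda_min/Lambda_max envelope and p-value band over a grid of m.

    ``frame`` has one row per total discordant count m with the optimal
    splits, both envelope statistics, and the corresponding p-value band
    (``p_low`` from Lambda_max, ``p_high`` from Lambda_min).  The grid always
    contains m_max = B_max + C_max, where the band collapses to a point.
    """

    frame: pd.DataFrame
    increment: int | None
    m_max: int
    sidedness: str

    def to_dataframe(self) -> pd.DataFrame:
        return self.frame.copy()

    def __len__(self) -> int:
        return len(self.frame)


class RobustMcNemar:
    """Matching-algorithm-independent McNemar test for matched binary outcomes.

    Parameters
    ----------
    matched_set : MatchedSet, optional
        Exact-match partitions of the good-match set.  Either this or
        ``capacities`` must be given.
    capacities : CapacitySet, optional
        Pre-computed (possibly aggregate-only) discordant capacities.
    alpha : float
        Significance level for the robustness classification.
    sidedness : str
        ``"one_sided_upper"`` (default; directional alternative of a
        positive effect) or ``"two_sided"``.
    """

    def __init__(
        self,
        matched_set: MatchedSet | None = None,
        *,
        capacities: CapacitySet | None = None,
        alpha: float = 0.05,
        sidedness: str = extrema.ONE_SIDED,
    ) -> None:
        if (matched_set is None) == (capacities is None):
            raise ValidationError("provide exactly one of matched_set or capacities")
        if not 0.0 < alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0, 1), got {alpha!r}")
        self.matched_set = matched_set
        self.capacities = capacities if capacities is not None else aggregate_capacities(matched_set)
        self.alpha = float(alpha)
        self.sidedness = sidedness

    # ------------------------------------------------------------------ #
    # constructors
    # ------------------------------------------------------------------ #
    @classmethod
    def from_capacities(
        cls, b_max: int, c_max: int, *, alpha: float = 0.05, sidedness: str = extrema.ONE_SIDED
    ) -> "RobustMcNemar":
        """Build the model from aggregate capacities alone (no unit data)."""
        return cls(capacities=CapacitySet.from_aggregates(b_max, c_max), alpha=alpha, sidedness=sidedness)

    @classmethod
    def from_tallies(
        cls, tallies: Sequence[OutcomeTally], *, alpha: float = 0.05, sidedness: str = extrema.ONE_SIDED
    ) -> "RobustMcNemar":
        return cls(MatchedSet.from_tallies(tallies), alpha=alpha, sidedness=sidedness)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        *,
        id_col: str = "id",
        treatment_col: str = "treatment",
        outcome_col: str = "outcome",
        covariate_cols: Sequence[str] | None = None,
        scheme: CoarseningScheme | None = None,
        alpha: float = 0.05,
        sidedness: str = extrema.ONE_SIDED,
    ) -> "RobustMcNemar":
        """Build the model from a unit-level table.

        Covariates are coarsened under ``scheme`` (pass-through categorical
        when omitted), then units are grouped into exact-match partitions.
        """
        import io

        buf = io.StringIO()
        data.to_csv(buf, index=False)
        buf.seek(0)
        units = read_units(
            buf,
            id_col=id_col,
            treatment_col=treatment_col,
            outcome_col=outcome_col,
            covariate_cols=covariate_cols,
        )
        if scheme is None:
            scheme = CoarseningScheme.all_categorical(name for name, _ in units[0].covariates)
        units = coarsen(units, scheme)
        return cls(build_partitions(units), alpha=alpha, sidedness=sidedness)

    # ------------------------------------------------------------------ #
    # fitting
    # ------------------------------------------------------------------ #
    def fit(self) -> "RobustMcNemarResults":
        """Evaluate the test at the robustness condition m = B_max + C_max."""
        caps = self.capacities
        if caps.m_max < 1:
            raise NoDiscordantPairsError(
                "B_max + C_max = 0: no discordant pair is attainable, the test is undefined"
            )
        split = DiscordantSplit(b=caps.b_max, c=caps.c_max)
        lam = lambda_stat(split)
        p_one = p_value(lam, extrema.ONE_SIDED)
        p_two = p_value(lam, extrema.TWO_SIDED)
        return RobustMcNemarResults(model=self, lambda_robust=lam, p_one_sided=p_one, p_two_sided=p_two)

    def extrema_at(self, m: int) -> tuple[LambdaValue, LambdaValue]:
        """(Lambda_min, Lambda_max) at a fixed total discordant count m."""
        lo = lambda_stat(optimal_discordant_split(m, self.capacities, "min"))
        hi = lambda_stat(optimal_discordant_split(m, self.capacities, "max"))
        return lo, hi

    def uncertainty_sweep(
        self, increment: int | None = None, m_grid: Sequence[int] | None = None
    ) -> UncertaintyProfile:
        """Sweep the envelope (Lambda_min, Lambda_max) over a grid of m.

        Either ``increment`` steps m from 1 by I, or ``m_grid`` gives the
        values explicitly; m_max is always appended so the profile ends at
        the robustness condition.
        """
        caps = self.capacities
        if caps.m_max < 1:
            raise NoDiscordantPairsError("B_max + C_max = 0: nothing to sweep")
        if m_grid is not None:
            grid = [int(m) for m in m_grid]
            if not grid:
                raise ValidationError("explicit m grid is empty")
            inc = None
        else:
            inc = int(increment) if increment is not None else default_increment(caps.m_max)
            if inc < 1:
                raise ValidationError(f"increment must be >= 1, got {inc}")
            grid = list(range(1, caps.m_max + 1, inc))
        if caps.m_max not in grid:
            grid.append(caps.m_max)
        for m in grid:
            if not 1 <= m <= caps.m_max:
                raise InfeasibleError(f"grid value m={m} outside [1, {caps.m_max}]")

        rows = []
        for m in grid:
            lo, hi = self.extrema_at(m)
            rows.append(
                {
                    "m": m,
                    "lambda_min": lo.value,
                    "lambda_max": hi.value,
                    "b_at_min": lo.split.b,
                    "c_at_min": lo.split.c,
                    "b_at_max": hi.split.b,
                    "c_at_max": hi.split.c,
                    "p_low": p_value(hi, self.sidedness),
                    "p_high": p_value(lo, self.sidedness),
                }
            )
        frame = pd.DataFrame(rows)
        return UncertaintyProfile(frame=frame, increment=inc, m_max=caps.m_max, sidedness=self.sidedness)


@dataclass(frozen=True)
class RobustMcNemarResults:
    """Results of the robust McNemar test at the robustness condition."""

    model: RobustMcNemar
    lambda_robust: LambdaValue
    p_one_sided: float
    p_two_sided: float

    @property
    def m_robust(self) -> int:
        return self.model.capacities.m_max

    @property
    def alpha(self) -> float:
        return self.model.alpha

    @property
    def p_value(self) -> float:
        """p-value under the model's configured sidedness."""
        return self.p_one_sided if self.model.sidedness == extrema.ONE_SIDED else self.p_two_sided

    @property
    def classification(self) -> str:
        # At m = B_max + C_max the two envelope statistics coincide, so the
        # extreme p-values are equal by construction.
        return robust_decision(self.p_value, self.p_value, self.alpha)

    def decision_at(self, m: int) -> str:
        """Robustness classification at an arbitrary feasible m."""
        lo, hi = self.model.extrema_at(m)
        return robust_decision(
            p_value(lo, self.model.sidedness), p_value(hi, self.model.sidedness), self.alpha
        )

    def uncertainty_profile(
        self, increment: int | None = None, m_grid: Sequence[int] | None = None
    ) -> UncertaintyProfile:
        return self.model.uncertainty_sweep(increment=increment, m_grid=m_grid)

    def summary(self) -> str:
        """Plain-text summary table in the style of a regression results view."""
        caps = self.model.capacities
        lines = [
            "Robust McNemar Test (matching-algorithm-independent)",
            "=" * 56,
            f"{'Partitions':<34}{caps.per_partition and len(caps.per_partition) or 'n/a (aggregate)':>22}",
            f"{'Max one-to-one pairs':<34}{caps.max_pairs:>22}",
            f"{'B_max (treated 0 / control 1)':<34}{caps.b_max:>22}",
            f"{'C_max (treated 1 / control 0)':<34}{caps.c_max:>22}",
            f"{'m at robustness condition':<34}{self.m_robust:>22}",
            "-" * 56,
            f"{'Lambda_robust':<34}{self.lambda_robust.value:>22.2f}",
            f"{'p-value (one-sided upper)':<34}{self.p_one_sided:>22.4g}",
            f"{'p-value (two-sided)':<34}{self.p_two_sided:>22.4g}",
            f"{'alpha':<34}{self.alpha:>22.3g}",
            f"{'classification':<34}{self.classification:>22}",
            "=" * 56,
        ]
        return "\n".join(lines)

    def plot_profile(self, increment: int | None = None, ax=None):
        """Plot the Lambda envelope against m (requires matplotlib)."""
        import matplotlib.pyplot as plt

        prof = self.uncertainty_profile(increment=increment).frame
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(prof["m"], prof["lambda_max"], label=r"$\Lambda_{max}$", color="tab:red")
        ax.plot(prof["m"], prof["lambda_min"], label=r"$\Lambda_{min}$", color="tab:blue")
        ax.axvline(self.m_robust, ls=":", color="grey", label="robustness condition")
        ax.set_xlabel("total discordant pairs m")
        ax.set_ylabel(r"test statistic $\Lambda$")
        ax.legend()
        return ax
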