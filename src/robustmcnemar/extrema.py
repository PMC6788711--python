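"""The continuity-corrected McNemar statistic and its closed-form extrema.

For discordant counts B (treated 0 / control 1) and C (treated 1 / control 0)
the statistic is

    Lambda(B, C) = (B - C - 1) / sqrt(B + C),

approximately standard normal under the null of homogeneous marginal
proportions.  Lambda is strictly increasing in B and non-increasing in C, so
with the total discordant count fixed at m the extrema over all admissible
pair assignments have a closed form driven only by the aggregate capacities
B_max and C_max:

* maximum: B* = min(m, B_max), C* = m - B*;
* minimum: C* = min(m, C_max), B* = m - C*.

At m = B_max + C_max both branches force (B_max, C_max) and the extrema
coincide — the robustness condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .capacities import CapacitySet
from .exceptions import InfeasibleError, NoDiscordantPairsError, ValidationError

__all__ = [
    "DiscordantSplit",
    "LambdaValue",
    "lambda_stat",
    "optimal_discordant_split",
    "p_value",
    "robust_decision",
    "ABSOLUTE_ROBUST",
    "ALPHA_ROBUST_REJECT",
    "ALPHA_ROBUST_FAIL",
    "NOT_ROBUST",
]

ABSOLUTE_ROBUST = "absolute-robust"
ALPHA_ROBUST_REJECT = "alpha-robust (reject)"
ALPHA_ROBUST_FAIL = "alpha-robust (fail to reject)"
NOT_ROBUST = "not robust"

ONE_SIDED = "one_sided_upper"
TWO_SIDED = "two_sided"


@dataclass(frozen=True)
class DiscordantSplit:
    """A (B, C) split of the total discordant-pair count m = B + C."""

    b: int
    c: int

    def __post_init__(self) -> None:
        if self.b < 0 or self.c < 0:
            raise ValidationError(f"discordant counts must be nonnegative, got ({self.b}, {self.c})")

    @property
    def m(self) -> int:
        return self.b + self.c


@dataclass(frozen=True)
class LambdaValue:
    """A test-statistic value together with the split it came from."""

    value: float
    split: DiscordantSplit

    def rounded(self, ndigits: int = 2) -> float:
        return round(self.value, ndigits)


def lambda_stat(split: DiscordantSplit) -> LambdaValue:
    """Evaluate Lambda = (B - C - 1)/sqrt(B + C); requires at least one discordant pair."""
    if split.m == 0:
        raise NoDiscordantPairsError(
            "the statistic is undefined without at least one discordant pair (B + C >= 1)"
        )
    value = (split.b - split.c - 1) / math.sqrt(split.m)
    return LambdaValue(value=value, split=split)


def optimal_discordant_split(m: int, capacities: CapacitySet, sense: str) -> DiscordantSplit:
    """Closed-form optimal (B, C) at fixed total discordant count m.

    ``sense`` is ``"max"`` (pack B first) or ``"min"`` (pack C first).
    Raises :class:`InfeasibleError` when m is outside [1, B_max + C_max].
    """
    m = int(m)
    m_max = capacities.m_max
    if not 1 <= m <= m_max:
        raise InfeasibleError(f"m={m} outside the feasible range [1, {m_max}]")
    if sense == "max":
        b = min(m, capacities.b_max)
        return DiscordantSplit(b=b, c=m - b)
    if sense == "min":
        c = min(m, capacities.c_max)
        return DiscordantSplit(b=m - c, c=c)
    raise ValueError(f"sense must be 'min' or 'max', got {sense!r}")


def p_value(lam: LambdaValue | float, sidedness: str = ONE_SIDED) -> float:
    """Standard-normal p-value of a statistic value.

    ``one_sided_upper`` is the upper-tail probability (the directional
    alternative of a positive effect); ``two_sided`` doubles the tail of
    the absolute value, capped at 1.
    """
    v = lam.value if isinstance(lam, LambdaValue) else float(lam)
    if not math.isfinite(v):
        raise ValidationError(f"statistic must be finite, got {v!r}")
    if sidedness == ONE_SIDED:
        return float(norm.sf(v))
    if sidedness == TWO_SIDED:
        return float(min(1.0, 2.0 * norm.sf(abs(v))))
    raise ValueError(f"sidedness must be {ONE_SIDED!r} or {TWO_SIDED!r}, got {sidedness!r}")


def robust_decision(p_from_lambda_min: float, p_from_lambda_max: float, alpha: float) -> str:
    """Classify the test's robustness from the two extreme p-values.

    When both extreme p-values land on the same side of ``alpha`` the
    conclusion cannot depend on which admissible pairing was chosen
    (alpha-robust); equal p-values mean the assignment ambiguity has
    vanished entirely (absolute-robust); a straddle means the test is
    not robust at this m.
    """
    for name, p in (("p_from_lambda_min", p_from_lambda_min), ("p_from_lambda_max", p_from_lambda_max)):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {p!r}")
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha!r}")
    if p_from_lambda_min == p_from_lambda_max:
        return ABSOLUTE_ROBUST
    if max(p_from_lambda_min, p_from_lambda_max) <= alpha:
        return ALPHA_ROBUST_REJECT
    if min(p_from_lambda_min, p_from_lambda_max) > alpha:
        return ALPHA_ROBUST_FAIL
    return NOT_ROBUST
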