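"""Seeded generators for matched-cohort unit tables with known ground truth.

Two generators:

* :func:`generate_units` plants an exact partition structure — a chosen
  number of two-armed covariate signatures (plus optional single-armed
  ones that must be dropped for lack of common support) with per-arm
  Bernoulli outcomes — and records the implied per-partition tallies and
  discordant capacities as ground truth, computed by arithmetic independent
  of the main code path.
* :func:`generate_hrrp_like` emulates the covariate scheme of a readmission
  policy study: nine categorical covariates with realistic marginals, a
  post-policy treatment indicator, and a per-arm non-index-readmission
  outcome.  It reproduces the scheme and approximate marginals only, not any
  real dataset's partition counts.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .capacities import CapacitySet, PartitionCapacities
from .exceptions import ConfigurationError
from .matched_data import OutcomeTally

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_units",
    "planted_capacities",
    "generate_hrrp_like",
    "HRRP_MARGINALS",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration for the partition-structure generator.

    ``treated_size``/``control_size`` are either a fixed per-partition arm
    size or an inclusive ``(lo, hi)`` range sampled per partition.
    ``p_treated``/``p_control`` are per-arm probabilities of outcome 1,
    scalar or one value per partition.  ``n_single_armed`` signatures are
    planted with one arm only; they exercise the common-support drop.
    """

    n_partitions: int
    treated_size: int | tuple[int, int] = (2, 6)
    control_size: int | tuple[int, int] = (2, 6)
    p_treated: float | Sequence[float] = 0.5
    p_control: float | Sequence[float] = 0.5
    n_single_armed: int = 0
    seed: int = 0
    covariate_alphabets: tuple[int, int] = (26, 60)

    def __post_init__(self) -> None:
        if self.n_partitions < 1:
            raise ConfigurationError("n_partitions must be >= 1")
        if self.n_single_armed < 0:
            raise ConfigurationError("n_single_armed must be >= 0")
        needed = self.n_partitions + self.n_single_armed
        capacity = self.covariate_alphabets[0] * self.covariate_alphabets[1]
        if needed > capacity:
            raise ConfigurationError(
                f"{needed} signatures requested but the covariate alphabet "
                f"only admits {capacity}"
            )
        for name in ("p_treated", "p_control"):
            probs = getattr(self, name)
            probs = [probs] if np.isscalar(probs) else list(probs)
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ConfigurationError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: per-partition tallies and capacities."""

    keys: tuple[tuple[str, str], ...]
    tallies: tuple[OutcomeTally, ...]
    quadruples: tuple[tuple[int, int, int, int], ...]  # (B, C, A, D) per partition
    n_single_armed_units: int
    n_treated_total: int

    def to_dict(self) -> dict:
        return {
            "partitions": [
                {
                    "key": list(k),
                    "tally": [t.n_t_pos, t.n_t_neg, t.n_c_pos, t.n_c_neg],
                    "capacities": list(q),
                }
                for k, t, q in zip(self.keys, self.tallies, self.quadruples)
            ],
            "n_single_armed_units": self.n_single_armed_units,
            "n_treated_total": self.n_treated_total,
        }


def _signature(i: int, alphabets: tuple[int, int]) -> tuple[str, str]:
    letters = (string.ascii_uppercase * 3)[: alphabets[0]]
    return letters[i % alphabets[0]], f"g{i // alphabets[0]:02d}"


def _draw_size(spec: int | tuple[int, int], rng: np.random.Generator) -> int:
    if np.isscalar(spec):
        return int(spec)
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def _prob_for(probs: float | Sequence[float], i: int) -> float:
    if np.isscalar(probs):
        return float(probs)
    return float(list(probs)[i % len(list(probs))])


def _planted_quadruple(treated: Sequence[int], control: Sequence[int]) -> tuple[int, int, int, int]:
    """Discordant/concordant capacities by explicit pairing simulation.

    Walks treated and control unit pools and forms pairs one at a time in
    priority order (both discordant types first, then the concordant fills),
    decrementing the pools.  Deliberately avoids the min() closed form used
    by the main code path, so agreement between the two is informative.
    """
    t_pos = sum(1 for y in treated if y == 1)
    t_neg = len(treated) - t_pos
    c_pos = sum(1 for y in control if y == 1)
    c_neg = len(control) - c_pos
    b = c = a = d = 0
    while t_neg > 0 and c_pos > 0:
        b += 1
        t_neg -= 1
        c_pos -= 1
    while t_pos > 0 and c_neg > 0:
        c += 1
        t_pos -= 1
        c_neg -= 1
    while t_pos > 0 and c_pos > 0:
        a += 1
        t_pos -= 1
        c_pos -= 1
    while t_neg > 0 and c_neg > 0:
        d += 1
        t_neg -= 1
        c_neg -= 1
    return b, c, a, d


def generate_units(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a unit table realizing the configured partition structure.

    Returns the table (columns ``id, treatment, outcome, region, grade``)
    and the ground-truth record.  Fixed seed gives byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    keys: list[tuple[str, str]] = []
    tallies: list[OutcomeTally] = []
    quads: list[tuple[int, int, int, int]] = []
    uid = 0

    def emit(sig: tuple[str, str], treatment: int, outcome: int) -> None:
        nonlocal uid
        uid += 1
        rows.append(
            {
                "id": f"u{uid:06d}",
                "treatment": treatment,
                "outcome": outcome,
                "region": sig[0],
                "grade": sig[1],
            }
        )

    for i in range(config.n_partitions):
        sig = _signature(i, config.covariate_alphabets)
        n_t = max(1, _draw_size(config.treated_size, rng))
        n_c = max(1, _draw_size(config.control_size, rng))
        yt = (rng.random(n_t) < _prob_for(config.p_treated, i)).astype(int).tolist()
        yc = (rng.random(n_c) < _prob_for(config.p_control, i)).astype(int).tolist()
        for y in yt:
            emit(sig, 1, y)
        for y in yc:
            emit(sig, 0, y)
        keys.append(sig)
        t_pos = sum(yt)
        c_pos = sum(yc)
        tallies.append(
            OutcomeTally(
                n_t_pos=t_pos, n_t_neg=n_t - t_pos, n_c_pos=c_pos, n_c_neg=n_c - c_pos
            )
        )
        quads.append(_planted_quadruple(yt, yc))

    n_single_units = 0
    for j in range(config.n_single_armed):
        sig = _signature(config.n_partitions + j, config.covariate_alphabets)
        arm = int(rng.integers(0, 2))  # 1 = treated-only signature
        size_spec = config.treated_size if arm == 1 else config.control_size
        n = max(1, _draw_size(size_spec, rng))
        p = _prob_for(config.p_treated if arm == 1 else config.p_control, j)
        for y in (rng.random(n) < p).astype(int).tolist():
            emit(sig, arm, y)
        n_single_units += n

    df = pd.DataFrame(rows, columns=["id", "treatment", "outcome", "region", "grade"])
    truth = GroundTruth(
        keys=tuple(keys),
        tallies=tuple(tallies),
        quadruples=tuple(quads),
        n_single_armed_units=n_single_units,
        n_treated_total=int((df["treatment"] == 1).sum()),
    )
    return df, truth


def planted_capacities(truth: GroundTruth) -> CapacitySet:
    """Capacity set from the generator's own bookkeeping (dual code path)."""
    order = sorted(range(len(truth.keys)), key=lambda i: truth.keys[i])
    per = tuple(
        PartitionCapacities(
            key=truth.keys[i],
            b=truth.quadruples[i][0],
            c=truth.quadruples[i][1],
            a=truth.quadruples[i][2],
            d=truth.quadruples[i][3],
            max_pairs=min(truth.tallies[i].n_treated, truth.tallies[i].n_control),
        )
        for i in order
    )
    return CapacitySet(
        per_partition=per,
        b_max=sum(p.b for p in per),
        c_max=sum(p.c for p in per),
        a_max=sum(p.a for p in per),
        d_max=sum(p.d for p in per),
        max_pairs=sum(p.max_pairs for p in per),
    )


# Categorical marginals of a readmitted-patient cohort (shares of the
# whole cohort) used by the policy-study-like fixture.
HRRP_MARGINALS: dict[str, dict[str, float]] = {
    "age": {
        "0-20": 0.0070,
        "21-30": 0.0118,
        "31-40": 0.0241,
        "41-50": 0.0700,
        "51-65": 0.2321,
        "65 and above": 0.6549,
    },
    "gender": {"Female": 0.4980, "Male": 0.5020},
    "income": {
        "Quartile 1": 0.2477,
        "Quartile 2": 0.2499,
        "Quartile 3": 0.2479,
        "Quartile 4": 0.2545,
    },
    "diagnosis": {"CHF": 0.5540, "AMI": 0.1320, "Pneumonia": 0.3140},
    "comorbidity": {
        "Low (0-2)": 0.3909,
        "Medium (3-6)": 0.5665,
        "Medium High (7-10)": 0.0375,
        "High (10 and above)": 0.0051,
    },
    "teaching": {"Teaching": 0.1130, "Non-teaching": 0.8870},
    "ownership": {"Non-profit": 0.6470, "Investor": 0.1980, "Public": 0.1550},
    "hospital_size": {"Small": 0.0550, "Medium": 0.6760, "Large": 0.2690},
    "location": {"Rural": 0.0268, "Metro": 0.9732},
}

# Post-policy share of the cohort and per-arm non-index readmission rates.
# The arm rates are modelling choices consistent with an overall non-index
# share near 0.256 at these arm weights.
HRRP_TREATED_FRACTION = 37200 / 90553
HRRP_OUTCOME_RATE = {0: 0.24, 1: 0.28}


def generate_hrrp_like(seed: int, scale: int = 10_000) -> pd.DataFrame:
    """Unit table emulating a readmission-policy cohort's covariate scheme.

    Nine categorical covariates are drawn independently with the marginals
    in :data:`HRRP_MARGINALS`; treatment is the post-policy indicator and
    the outcome is a per-arm Bernoulli non-index-readmission flag.
    """
    if scale < 100:
        raise ConfigurationError("scale must be >= 100")
    rng = np.random.default_rng(seed)
    data: dict[str, object] = {"id": [f"h{i:06d}" for i in range(1, scale + 1)]}
    treatment = (rng.random(scale) < HRRP_TREATED_FRACTION).astype(int)
    rates = np.where(treatment == 1, HRRP_OUTCOME_RATE[1], HRRP_OUTCOME_RATE[0])
    data["treatment"] = treatment
    data["outcome"] = (rng.random(scale) < rates).astype(int)
    for name, marg in HRRP_MARGINALS.items():
        labels = list(marg)
        probs = np.asarray(list(marg.values()))
        data[name] = rng.choice(labels, size=scale, p=probs / probs.sum())
    cols = ["id", "treatment", "outcome", *HRRP_MARGINALS]
    return pd.DataFrame(data)[cols]
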