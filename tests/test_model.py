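"""Model/results interface: fitting, the sweep, audit allocation, reporting."""

import time

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from robustmcnemar import (
    ABSOLUTE_ROBUST,
    DiscordantSplit,
    InfeasibleError,
    NoDiscordantPairsError,
    OutcomeTally,
    RobustMcNemar,
    ValidationError,
    allocate_split,
)
from robustmcnemar.model import default_increment
from robustmcnemar.synthetic import SyntheticConfig, generate_units

from conftest import random_matched_set


class TestConstruction:
    def test_requires_exactly_one_source(self):
        with pytest.raises(ValidationError):
            RobustMcNemar()

    def test_zero_capacities_cannot_fit(self):
        model = RobustMcNemar.from_capacities(0, 0)
        with pytest.raises(NoDiscordantPairsError):
            model.fit()

    def test_bad_alpha(self):
        with pytest.raises(ValidationError):
            RobustMcNemar.from_capacities(1, 1, alpha=1.5)

    def test_from_dataframe_end_to_end(self):
        df, truth = generate_units(SyntheticConfig(n_partitions=20, seed=9))
        model = RobustMcNemar.from_dataframe(df)
        from robustmcnemar.synthetic import planted_capacities

        planted = planted_capacities(truth)
        assert model.capacities.b_max == planted.b_max
        assert model.capacities.c_max == planted.c_max
        res = model.fit()
        assert res.classification == ABSOLUTE_ROBUST


class TestFitResults:
    def test_robustness_condition(self):
        res = RobustMcNemar.from_capacities(12082, 9448).fit()
        assert res.m_robust == 21530
        assert res.lambda_robust.rounded() == 17.94
        assert res.classification == ABSOLUTE_ROBUST
        lo, hi = res.model.extrema_at(res.m_robust)
        assert lo.value == hi.value == res.lambda_robust.value

    def test_summary_mentions_key_quantities(self):
        text = RobustMcNemar.from_capacities(12082, 9448).fit().summary()
        assert "17.94" in text and "21530" in text and "absolute-robust" in text

    def test_decision_at_intermediate_m_straddles(self):
        res = RobustMcNemar.from_capacities(12082, 9448).fit()
        assert res.decision_at(19000) == "not robust"
        assert res.decision_at(21000) == "alpha-robust (reject)"


class TestSweep:
    def test_default_grid_bounded_and_contains_m_max(self):
        model = RobustMcNemar.from_capacities(12082, 9448)
        prof = model.uncertainty_sweep()
        assert len(prof) <= 201
        assert prof.frame["m"].iloc[-1] == 21530
        last = prof.frame.iloc[-1]
        assert last["lambda_min"] == last["lambda_max"]

    def test_default_increment_scaling(self):
        assert default_increment(150) == 1
        assert default_increment(21530) == 108

    def test_envelope_order_everywhere(self, rng):
        ms = random_matched_set(rng, max_partitions=3, max_arm=6)
        model = RobustMcNemar(ms)
        if model.capacities.m_max == 0:
            return
        prof = model.uncertainty_sweep(increment=1).frame
        assert (prof["lambda_min"] <= prof["lambda_max"] + 1e-12).all()

    def test_infeasible_grid_value_identified(self):
        model = RobustMcNemar.from_capacities(5, 5)
        with pytest.raises(InfeasibleError, match="m=99"):
            model.uncertainty_sweep(m_grid=[2, 99])

    def test_bad_increment(self):
        model = RobustMcNemar.from_capacities(5, 5)
        with pytest.raises(ValidationError):
            model.uncertainty_sweep(increment=0)

    def test_p_band_is_ordered(self):
        prof = RobustMcNemar.from_capacities(50, 30).uncertainty_sweep(increment=1).frame
        assert (prof["p_low"] <= prof["p_high"] + 1e-12).all()


class TestAllocateSplit:
    def test_allocation_sums_and_respects_partition_capacities(self, rng):
        for _ in range(20):
            ms = random_matched_set(rng)
            model = RobustMcNemar(ms)
            caps = model.capacities
            if caps.m_max == 0:
                continue
            m = int(rng.integers(1, caps.m_max + 1))
            from robustmcnemar import optimal_discordant_split

            split = optimal_discordant_split(m, caps, "max")
            rows = allocate_split(caps, split)
            assert sum(b for _, b, _ in rows) == split.b
            assert sum(c for _, _, c in rows) == split.c
            for (key, b, c), part in zip(rows, caps.per_partition):
                assert key == part.key and b <= part.b and c <= part.c

    def test_overfull_split_rejected(self):
        ms = random_matched_set(np.random.default_rng(1))
        caps = RobustMcNemar(ms).capacities
        with pytest.raises((InfeasibleError, ValidationError)):
            allocate_split(caps, DiscordantSplit(b=caps.b_max + 1, c=0))


class TestScalingSmoke:
    def test_runtime_rank_correlates_with_problem_size(self):
        """Work should grow with (partitions x arm size), i.e. near-linear scaling."""
        sizes = [20, 200, 2000, 20000]
        timings = []
        for n_p in sizes:
            tallies = [OutcomeTally(2, 3, 3, 2)] * n_p
            from robustmcnemar import MatchedSet, aggregate_capacities

            ms = MatchedSet.from_tallies(tallies)
            best = np.inf
            for _ in range(3):
                t0 = time.perf_counter()
                aggregate_capacities(ms)
                best = min(best, time.perf_counter() - t0)
            timings.append(best)
        rho, _ = spearmanr(sizes, timings)
        assert rho > 0.7


class TestPlot:
    def test_plot_profile_returns_axis(self):
        import matplotlib

        matplotlib.use("Agg")
        res = RobustMcNemar.from_capacities(40, 25).fit()
        ax = res.plot_profile(increment=1)
        assert ax.get_xlabel() == "total discordant pairs m"
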