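"""Unit ingest, coarsening, and exact-match partition construction."""

import io

import numpy as np
import pytest

from robustmcnemar import (
    CoarseningScheme,
    ConfigurationError,
    NoCommonSupportError,
    Unit,
    ValidationError,
    build_partitions,
    coarsen,
    read_units,
    tally_partition,
)
from robustmcnemar.synthetic import SyntheticConfig, generate_units

AGE_BANDS = {
    "age": {
        "boundaries": [0, 21, 31, 41, 51, 66],
        "labels": ["0-20", "21-30", "31-40", "41-50", "51-65", "65 and above"],
        "open_ended": True,
    },
    "gender": "categorical",
}


def _csv(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")


class TestReadUnits:
    def test_basic_parse(self):
        units = read_units(
            _csv("id,treatment,outcome,gender\na,0,1,F\nb,0,0,F\nc,1,1,M\nd,1,0,M")
        )
        assert len(units) == 4
        assert sum(u.treatment for u in units) == 2
        assert units[0].covariate_dict == {"gender": "F"}

    def test_non_binary_outcome_names_offending_row(self):
        with pytest.raises(ValidationError, match="c"):
            read_units(_csv("id,treatment,outcome\na,0,1\nb,1,0\nc,1,2"))

    def test_missing_column_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="outcome"):
            read_units(_csv("id,treatment\na,0"))

    def test_duplicate_id_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            read_units(_csv("id,treatment,outcome\na,0,1\na,1,0"))

    def test_missing_covariate_rejected_not_imputed(self):
        with pytest.raises(ValidationError, match="missing covariate"):
            read_units(_csv("id,treatment,outcome,x\na,0,1,\nb,1,0,1"))

    def test_generator_roundtrip_keeps_treated_count(self):
        df, truth = generate_units(SyntheticConfig(n_partitions=40, seed=3))
        units = read_units(io.StringIO(df.to_csv(index=False)))
        assert len(units) == len(df)
        assert sum(u.treatment for u in units) == truth.n_treated_total


class TestCoarsen:
    def test_age_binning_and_passthrough(self):
        scheme = CoarseningScheme.from_dict(AGE_BANDS)
        units = [Unit("a", 1, 1, (("age", 67), ("gender", "Male")))]
        out = coarsen(units, scheme)
        assert out[0].covariate_dict == {"age": "65 and above", "gender": "Male"}
        assert units[0].covariate_dict["age"] == 67  # original untouched

    @pytest.mark.parametrize(
        "age,label",
        [(0, "0-20"), (20, "0-20"), (21, "21-30"), (50, "41-50"), (51, "51-65"), (66, "65 and above")],
    )
    def test_half_open_bin_edges(self, age, label):
        scheme = CoarseningScheme.from_dict(AGE_BANDS)
        assert scheme.apply("age", age) == label

    def test_out_of_range_value_names_covariate_and_unit(self):
        scheme = CoarseningScheme.from_dict(AGE_BANDS)
        units = [Unit("u9", 0, 0, (("age", -1), ("gender", "F")))]
        with pytest.raises(ValidationError, match="age.*u9"):
            coarsen(units, scheme)

    def test_non_monotone_boundaries_rejected(self):
        with pytest.raises(ConfigurationError):
            CoarseningScheme.from_dict(
                {"x": {"boundaries": [0, 10, 5], "labels": ["a", "b", "c"]}}
            )


class TestTally:
    def test_counts(self):
        t = tally_partition([1, 1, 0], [0, 1])
        assert (t.n_t_pos, t.n_t_neg, t.n_c_pos, t.n_c_neg) == (2, 1, 1, 1)
        assert t.n_treated == 3 and t.n_control == 2

    def test_all_positive_boundary(self):
        t = tally_partition([1, 1], [1])
        assert t.n_t_neg == 0 and t.n_c_neg == 0

    def test_empty_partition_rejected(self):
        with pytest.raises(ValidationError):
            tally_partition([], [])


class TestBuildPartitions:
    def _unit(self, uid, t, y, sig):
        return Unit(uid, t, y, (("s", sig),))

    def test_single_signature_group(self):
        units = [self._unit(f"u{i}", t, y, "A") for i, (t, y) in enumerate([(1, 1), (1, 0), (0, 1), (0, 0), (0, 0)])]
        ms = build_partitions(units)
        assert ms.n_partitions == 1
        assert ms.partitions[0].tally.n_treated == 2
        assert ms.partitions[0].tally.n_control == 3

    def test_no_common_support(self):
        units = [self._unit("a", 1, 1, "A"), self._unit("b", 0, 0, "B")]
        with pytest.raises(NoCommonSupportError):
            build_partitions(units)

    def test_empty_input(self):
        with pytest.raises(ValidationError):
            build_partitions([])

    def test_planted_signature_structure(self):
        df, _ = generate_units(SyntheticConfig(n_partitions=12, n_single_armed=3, seed=11))
        units = read_units(io.StringIO(df.to_csv(index=False)))
        ms = build_partitions(units)
        assert ms.n_partitions == 12
        assert ms.n_dropped_partitions == 3

    def test_unit_conservation_and_exactness(self, rng):
        df, _ = generate_units(SyntheticConfig(n_partitions=25, n_single_armed=5, seed=7))
        units = read_units(io.StringIO(df.to_csv(index=False)))
        ms = build_partitions(units)
        assert ms.n_units + ms.n_dropped_units == len(units)
        by_id = {u.unit_id: u for u in units}
        for part in ms.partitions:
            for uid in part.treated_ids + part.control_ids:
                sig = tuple(str(v) for _, v in by_id[uid].covariates)
                assert sig == part.key

    def test_rebuild_reproduces_keys_and_tallies(self):
        df, _ = generate_units(SyntheticConfig(n_partitions=15, seed=5))
        units = read_units(io.StringIO(df.to_csv(index=False)))
        ms1 = build_partitions(units)
        # rebuilding from the retained units must reproduce keys and tallies
        kept = [u for u in units if any(u.unit_id in p.treated_ids + p.control_ids for p in ms1.partitions)]
        ms2 = build_partitions(kept)
        assert [p.key for p in ms1.partitions] == [p.key for p in ms2.partitions]
        assert [p.tally for p in ms1.partitions] == [p.tally for p in ms2.partitions]
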