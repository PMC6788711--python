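import numpy as np
import pytest

from robustmcnemar import MatchedSet, OutcomeTally


def random_tally(rng: np.random.Generator, max_arm: int = 8) -> OutcomeTally:
    n_t = int(rng.integers(0, max_arm + 1))
    n_c = int(rng.integers(0, max_arm + 1))
    t_pos = int(rng.integers(0, n_t + 1))
    c_pos = int(rng.integers(0, n_c + 1))
    return OutcomeTally(n_t_pos=t_pos, n_t_neg=n_t - t_pos, n_c_pos=c_pos, n_c_neg=n_c - c_pos)


def random_matched_set(
    rng: np.random.Generator, max_partitions: int = 3, max_arm: int = 6
) -> MatchedSet:
    """A small random matched set with every partition two-armed and non-trivial."""
    n_p = int(rng.integers(1, max_partitions + 1))
    tallies = []
    for _ in range(n_p):
        n_t = int(rng.integers(1, max_arm + 1))
        n_c = int(rng.integers(1, max_arm + 1))
        t_pos = int(rng.integers(0, n_t + 1))
        c_pos = int(rng.integers(0, n_c + 1))
        tallies.append(
            OutcomeTally(n_t_pos=t_pos, n_t_neg=n_t - t_pos, n_c_pos=c_pos, n_c_neg=n_c - c_pos)
        )
    return MatchedSet.from_tallies(tallies)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231)
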