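import itertools
from math import comb

import pytest


def ora_bruteforce(N: int, K: int, n: int, k: int, direction: str = "over") -> float:
    """Independent ORA oracle: enumerate all C(N, n) equally likely draws of a
    test set from an N-gene universe whose first K genes form the category,
    and count draws with the required overlap."""
    universe = range(N)
    category = set(range(K))
    total = comb(N, n)
    if direction == "over":
        good = sum(1 for draw in itertools.combinations(universe, n) if len(category & set(draw)) >= k)
    elif direction == "under":
        good = sum(1 for draw in itertools.combinations(universe, n) if len(category & set(draw)) <= k)
    else:
        raise ValueError(direction)
    return good / total


@pytest.fixture
def small_gmt(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "setA\tfirst set\tA\tB\tC\n"
        "setB\tsecond set\tB\tC\tD\n"
    )
    return path
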