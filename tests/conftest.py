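import random

import pytest

from multibwt import StringCollection


@pytest.fixture
def gtc_gt() -> StringCollection:
    """{GTC, GT}: the running two-string example."""
    return StringCollection(["GTC", "GT"])


@pytest.fixture
def example1() -> StringCollection:
    """{AACGAC, TCAC}: suffix vs internal occurrences of AC."""
    return StringCollection(["AACGAC", "TCAC"])


@pytest.fixture
def toy5() -> StringCollection:
    """The five-string toy collection used for the variant comparison."""
    return StringCollection(["ATATG", "TGA", "ACG", "ATCA", "GGA"])


@pytest.fixture
def eight_strings() -> StringCollection:
    """Eight 4-mers whose mdolBWT has 28 runs and colexBWT 18."""
    return StringCollection(
        ["AAAA", "AGCA", "GCAA", "GTCA", "CAAA", "CGCA", "TCAA", "TTCA"]
    )


def random_collection(
    rng: random.Random,
    max_k: int = 8,
    max_len: int = 20,
    alphabet: str = "ACGT",
    total_cap: int | None = None,
) -> StringCollection:
    """A small random collection, with occasional shared suffixes and
    duplicates to exercise tie-breaking paths."""
    k = rng.randint(1, max_k)
    strings = [
        "".join(rng.choice(alphabet) for _ in range(rng.randint(1, max_len)))
        for _ in range(k)
    ]
    if k >= 2 and rng.random() < 0.4:
        suffix = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 3)))
        strings = [s + suffix if rng.random() < 0.6 else s for s in strings]
    if k >= 2 and rng.random() < 0.15:
        strings[rng.randrange(k)] = strings[0]
    if total_cap is not None:
        while sum(len(s) for s in strings) > total_cap and len(strings) > 1:
            strings.pop()
    return StringCollection(strings)
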