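"""Interesting intervals, run bounds, variability, and pairwise distances."""

import random
from fractions import Fraction
from itertools import combinations, permutations

import pytest

from multibwt import (
    SEPARATOR_VARIANTS,
    StringCollection,
    colex_bwt,
    compare_all,
    edit_distance,
    hamming,
    interesting_intervals,
    interval_max_runs,
    opt_bwt,
    transform,
    variability,
)
from multibwt.oracles import (
    brute_interesting_suffixes,
    brute_interval_max_runs,
)

from conftest import random_collection

EX2_MDOL = "AAAAAAAAACACACACACACAC$$GTGTGT$$AC$$GT$$"
EX2_COLEX = "AAAAAAAAAAAACCCCAACCAC$$GGTTGT$$AC$$GT$$"


# ----------------------------------------------------------------------
# interesting intervals
# ----------------------------------------------------------------------

def test_toy_collection_has_four_intervals(toy5):
    ivs = interesting_intervals(toy5)
    by_suffix = {iv.suffix: iv for iv in ivs}
    assert set(by_suffix) == {b"", b"A", b"G", b"GA"}
    # empty suffix: all five strings, ranks [1, 5]
    assert (by_suffix[b""].begin, by_suffix[b""].end) == (1, 5)
    # suffix A: TGA, ATCA, GGA preceded by G, C, G
    assert by_suffix[b"A"].parikh == {b"G": 2, b"C": 1}
    # suffix G: ATATG, ACG preceded by T, C
    assert by_suffix[b"G"].parikh == {b"T": 1, b"C": 1}
    # suffix GA: TGA, GGA preceded by T, G
    assert by_suffix[b"GA"].parikh == {b"T": 1, b"G": 1}


def test_left_maximality_filters_shared_suffixes():
    # AAA is preceded by A vs C; AA and A are shared but both preceded by A,
    # and both strings end in A, so no other interval exists
    m = StringCollection(["AAAA", "CAAA"])
    ivs = interesting_intervals(m)
    assert [iv.suffix for iv in ivs] == [b"AAA"]


def test_identical_strings_have_no_interval():
    assert interesting_intervals(StringCollection(["GT", "GT"])) == []


def test_whole_string_suffix_uses_separator_as_preceding_char():
    ivs = interesting_intervals(StringCollection(["GT", "AGT"]))
    assert [iv.suffix for iv in ivs] == [b"GT"]
    assert ivs[0].parikh == {b"$": 1, b"A": 1}


@pytest.mark.parametrize("seed", range(40))
def test_intervals_match_brute_force_and_are_disjoint(seed):
    rng = random.Random(6000 + seed)
    m = random_collection(rng, max_k=7, max_len=8, alphabet="ACG")
    ivs = interesting_intervals(m)
    assert {iv.suffix for iv in ivs} == set(brute_interesting_suffixes(m))
    for a, b in zip(ivs, ivs[1:]):
        assert a.end < b.begin  # Lemma-style disjointness
    for iv in ivs:
        assert sum(iv.parikh.values()) == iv.width >= 2


@pytest.mark.parametrize("seed", range(10))
def test_interval_coordinates_invariant_under_permutation(seed):
    rng = random.Random(7000 + seed)
    m = random_collection(rng, max_k=4, max_len=6)
    ref = [(iv.suffix, iv.begin, iv.end) for iv in interesting_intervals(m)]
    for perm in permutations(range(m.k)):
        shuffled = m.reordered(perm)
        got = [
            (iv.suffix, iv.begin, iv.end)
            for iv in interesting_intervals(shuffled)
        ]
        assert got == ref


# ----------------------------------------------------------------------
# Parikh run bounds and variability
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts, expected",
    [({"A": 3, "C": 1}, 3), ({"A": 2, "C": 2}, 4), ({"A": 5}, 1)],
)
def test_interval_max_runs_examples(counts, expected):
    assert interval_max_runs(counts) == expected
    assert brute_interval_max_runs(counts) == expected


@pytest.mark.parametrize("seed", range(25))
def test_interval_max_runs_matches_enumeration(seed):
    rng = random.Random(8000 + seed)
    m = random_collection(rng, max_k=6, max_len=6, alphabet="AC")
    for iv in interesting_intervals(m):
        if iv.width <= 8:
            assert interval_max_runs(iv.parikh) == brute_interval_max_runs(
                iv.parikh
            )


def test_interval_max_runs_rejects_empty():
    with pytest.raises(ValueError):
        interval_max_runs({})


def test_variability_undefined_without_intervals():
    v = variability(StringCollection(["GT", "GT"]))
    assert v.value == 0 and not v.defined


def test_variability_of_single_balanced_interval():
    # only interval: suffix G preceded by A, A, C, C -> bound 4, width 4
    m = StringCollection(["AG", "AG", "CG", "CG"])
    ivs = interesting_intervals(m)
    assert len(ivs) == 1 and ivs[0].parikh == {b"A": 2, b"C": 2}
    v = variability(m)
    assert v.value == 1 and v.defined


def test_variability_of_toy_collection(toy5):
    ivs = interesting_intervals(toy5)
    expected = Fraction(
        sum(iv.var_bound for iv in ivs), sum(iv.width for iv in ivs)
    )
    v = variability(toy5)
    assert v.value == expected and v.defined
    assert 0 <= v.value <= 1


# ----------------------------------------------------------------------
# distances
# ----------------------------------------------------------------------

def test_hamming_of_example2_variants():
    direct = sum(a != b for a, b in zip(EX2_MDOL, EX2_COLEX))
    assert hamming(EX2_MDOL, EX2_COLEX) == direct
    assert hamming(EX2_MDOL, EX2_MDOL) == 0
    assert hamming(EX2_MDOL, EX2_COLEX, normalized=True) == Fraction(
        direct, len(EX2_MDOL)
    )


def test_hamming_requires_equal_lengths():
    with pytest.raises(ValueError, match="edit_distance"):
        hamming("AB", "ABC")


def _levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def test_edit_distance_examples():
    assert edit_distance("", "AB") == 2
    assert edit_distance("CGACATAACC", "CGACATAACC") == 0
    dp = _levenshtein("CGACATAACC", "CC$GCAAATAC$")
    assert edit_distance("CGACATAACC", "CC$GCAAATAC$") == dp


def test_edit_distance_cap():
    with pytest.raises(ValueError, match="cap"):
        edit_distance("A" * 20, "C" * 20, cap=10)


@pytest.mark.parametrize("seed", range(20))
def test_mismatches_confined_to_interesting_intervals(seed):
    rng = random.Random(9000 + seed)
    m = random_collection(rng, max_k=7, max_len=10)
    ivs = interesting_intervals(m)
    inside = set()
    for iv in ivs:
        inside.update(range(iv.begin - 1, iv.end))
    texts = {v: transform(m, v).text for v in SEPARATOR_VARIANTS}
    total_width = sum(iv.width for iv in ivs)
    for a, b in combinations(SEPARATOR_VARIANTS, 2):
        mismatches = [
            i for i, (x, y) in enumerate(zip(texts[a], texts[b])) if x != y
        ]
        assert set(mismatches) <= inside
        assert len(mismatches) <= total_width


def test_dollar_positions_and_proper_suffix_pairs():
    # GT is a proper suffix of AGT: dollar positions may (and here do) differ
    with_pair = StringCollection(["GT", "AGT"])
    positions = {
        transform(with_pair, v).separator_positions
        for v in SEPARATOR_VARIANTS
    }
    assert len(positions) > 1
    # no proper-suffix pair: all variants agree on dollar positions
    without = StringCollection(["GTC", "AGT"])
    positions = {
        transform(without, v).separator_positions for v in SEPARATOR_VARIANTS
    }
    assert len(positions) == 1


@pytest.mark.parametrize("seed", range(15))
def test_colex_within_two_runs_per_interval_of_optimum(seed):
    rng = random.Random(10_000 + seed)
    m = random_collection(rng, max_k=7, max_len=8)
    c_m = len(interesting_intervals(m))
    assert colex_bwt(m).runs <= opt_bwt(m).runs + 2 * c_m


# ----------------------------------------------------------------------
# full report
# ----------------------------------------------------------------------

def test_compare_all_on_toy_collection(toy5):
    report = compare_all(toy5)
    assert (
        report.runs["colexbwt"].run_count - report.runs["optbwt"].run_count
        == 2
    )
    assert report.c_m == 4
    assert 0 <= report.interval_ratio_transform <= 1
    assert 0 <= report.variability <= 1
    for dist in report.pairwise_hamming.values():
        assert 0 <= dist <= 1
    data = report.to_dict()
    assert data["number of sequences"] == 5
    assert set(data["runs"]) == {
        "ebwt", "dolebwt", "mdolbwt", "colexbwt", "optbwt", "concbwt"
    }


def test_compare_all_identical_strings():
    report = compare_all(StringCollection(["GT", "GT"]))
    assert all(d == 0 for d in report.pairwise_hamming.values())
    assert report.c_m == 0 and not report.variability_defined


def test_compare_all_subsample_is_seeded():
    m = StringCollection(
        ["ACGTA", "ACGTT", "TTGCA", "GGCAT", "ACCAT", "TGGAT"]
    )
    r1 = compare_all(m, subsample=3, seed=11)
    r2 = compare_all(m, subsample=3, seed=11)
    assert r1.edit_vs_ebwt == r2.edit_vs_ebwt
    assert r1.edit_subsample_size == 3
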