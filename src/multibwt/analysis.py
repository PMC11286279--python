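"""Comparison machinery for the BWT variants of one collection.

The central object is the *interesting interval*: for a suffix U shared
by at least two members whose preceding characters differ (a left-maximal
shared suffix), the rotations beginning ``U$`` occupy a consecutive rank
range [b, e] of the sorted rotation list, identical across all
separator-based variants.  Every position at which two separator-based
transforms of the same collection differ lies inside such an interval,
distinct intervals are disjoint, and the Hamming distance between any two
separator-based transforms is bounded by the summed interval widths.

Per interval, the maximum run count over all arrangements of its
character multiset {n_1, ..., n_sigma} is ``e - b + 1`` when
``n_a - 1 <= N_a`` (with n_a the largest multiplicity and N_a the rest),
and ``2 * N_a + 1`` otherwise.  The *variability* of a collection is the
ratio of the summed per-interval maxima to the summed interval widths —
a measure of how much the run count can differ between variants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import NamedTuple, Optional, Union

import edlib

from .core import SEPARATOR, StringCollection, RunsSummary, count_runs
from .transforms import (
    SEPARATOR_VARIANTS,
    Transform,
    _multidollar_array,
    _suffix_array,
    colex_bwt,
    conc_bwt,
    dol_ebwt,
    ebwt,
    mdol_bwt,
    opt_bwt,
)

__all__ = [
    "InterestingInterval",
    "VariabilityResult",
    "ComparisonReport",
    "interesting_intervals",
    "interval_max_runs",
    "variability",
    "hamming",
    "edit_distance",
    "compare_all",
]

EDIT_DISTANCE_CAP = 10**5


@dataclass(frozen=True)
class InterestingInterval:
    """A maximal shared-suffix interval [b, e] (1-based, inclusive).

    ``suffix`` is the shared suffix U (possibly empty); ``parikh`` maps
    each character occurring in the interval — the separator class is the
    single key ``b"$"`` — to its multiplicity; ``members`` lists
    (string index, preceding character) pairs in input order.
    """

    suffix: bytes
    begin: int
    end: int
    parikh: dict[bytes, int]
    members: tuple[tuple[int, bytes], ...] = field(repr=False, default=())

    @property
    def width(self) -> int:
        return self.end - self.begin + 1

    @property
    def max_char_count(self) -> int:
        """n_a: the largest character multiplicity in the interval."""
        return max(self.parikh.values())

    @property
    def rest_count(self) -> int:
        """N_a: interval width minus the dominant multiplicity."""
        return self.width - self.max_char_count

    @property
    def var_bound(self) -> int:
        """Maximum run count over all arrangements of the interval."""
        return interval_max_runs(self.parikh)


class VariabilityResult(NamedTuple):
    value: Fraction
    defined: bool


def _interval_details(m: StringCollection) -> list[InterestingInterval]:
    """Enumerate interesting intervals on the multidollar rotation matrix.

    Rows are the N_M + k rotations of T1 $1 ... Tk $k; the row of the
    rotation starting at suffix U of Ti (U possibly empty: the rotation
    starting at $i belongs to the empty suffix of Ti) carries the
    character preceding U in Ti, with the separator standing in when
    U = Ti.  Rows are grouped by U; groups of size >= 2 with >= 2
    distinct characters are the interesting intervals.  Coordinates are
    computed in input order but are invariant under permuting the
    collection.
    """
    arr = _multidollar_array(m)
    k = m.k
    n = arr.size
    sa = _suffix_array(arr)
    rank = [0] * n
    for r, p in enumerate(sa):
        rank[p] = r

    # Map each position to (owner string, suffix bytes).
    groups: dict[bytes, list[tuple[int, int, bytes]]] = {}
    pos = 0
    for i, t in enumerate(m.strings):
        seg_start = pos
        for off in range(len(t) + 1):  # off == len(t): the $i rotation
            p = seg_start + off
            suffix = t[off:]
            if off == 0:
                prev = SEPARATOR  # rotation Ti $i ... is preceded by a dollar
            else:
                prev = t[off - 1: off]
            groups.setdefault(suffix, []).append((rank[p], i, prev))
        pos += len(t) + 1

    out: list[InterestingInterval] = []
    for suffix, rows in groups.items():
        if len(rows) < 2:
            continue
        chars = {prev for _, _, prev in rows}
        if len(chars) < 2:
            continue
        ranks = sorted(r for r, _, _ in rows)
        b, e = ranks[0] + 1, ranks[-1] + 1
        assert e - b + 1 == len(rows), "shared-suffix rows must be consecutive"
        members = tuple(
            (i, prev) for _, i, prev in sorted(rows, key=lambda x: x[0])
        )
        parikh = dict(Counter(prev for _, _, prev in rows))
        out.append(InterestingInterval(suffix, b, e, parikh, members))
    out.sort(key=lambda iv: iv.begin)
    for a, b_ in zip(out, out[1:]):  # disjointness holds by construction
        assert a.end < b_.begin, "interesting intervals must be disjoint"
    return out


def interesting_intervals(m: StringCollection) -> list[InterestingInterval]:
    """All interesting intervals of the collection, sorted by begin."""
    return _interval_details(m)


def interval_max_runs(parikh: Union[dict, Counter]) -> int:
    """Maximum run count over all arrangements of a character multiset.

    With n_a the dominant multiplicity and N_a the sum of the others, the
    maximum is the full width when n_a - 1 <= N_a (the dominant character
    can be fully interleaved) and 2 * N_a + 1 otherwise.
    """
    counts = [c for c in parikh.values() if c > 0]
    if not counts or any(c < 0 for c in parikh.values()):
        raise ValueError("parikh vector must contain positive counts")
    width = sum(counts)
    na = max(counts)
    rest = width - na
    return width if na - 1 <= rest else 2 * rest + 1


def variability(m: StringCollection) -> VariabilityResult:
    """Summed per-interval run maxima over summed interval widths.

    Undefined (flag False, value 0) when the collection has no
    interesting interval.
    """
    ivs = _interval_details(m)
    if not ivs:
        return VariabilityResult(Fraction(0), False)
    num = sum(iv.var_bound for iv in ivs)
    den = sum(iv.width for iv in ivs)
    return VariabilityResult(Fraction(num, den), True)


def _text(x: Union[Transform, bytes, str]) -> bytes:
    if isinstance(x, Transform):
        return x.text
    if isinstance(x, str):
        return x.encode("ascii")
    return bytes(x)


def hamming(
    l1: Union[Transform, bytes, str],
    l2: Union[Transform, bytes, str],
    normalized: bool = False,
) -> Union[int, Fraction]:
    """Positional mismatch count of two equal-length texts."""
    a, b = _text(l1), _text(l2)
    if len(a) != len(b):
        raise ValueError(
            "Hamming distance requires equal lengths "
            f"({len(a)} vs {len(b)}); use edit_distance for unequal texts"
        )
    d = sum(x != y for x, y in zip(a, b))
    return Fraction(d, len(a)) if normalized else d


def edit_distance(
    l1: Union[Transform, bytes, str],
    l2: Union[Transform, bytes, str],
    cap: int = EDIT_DISTANCE_CAP,
) -> int:
    """Unit-cost Levenshtein distance (library-backed alignment)."""
    a, b = _text(l1), _text(l2)
    if len(a) > cap or len(b) > cap:
        raise ValueError(
            f"inputs exceed the edit-distance cap ({cap}); "
            "subsample the collection first"
        )
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(
        a.decode("latin-1"), b.decode("latin-1"), task="distance"
    )["editDistance"]


@dataclass(frozen=True)
class ComparisonReport:
    """Dataset statistics and pairwise transform distances.

    ``interval_ratio_transform`` divides the summed interval widths by
    the separator-based transform length N_M + k (sharing a denominator
    with the normalized Hamming distances); ``interval_ratio_raw`` by the
    raw dataset length N_M.  ``avg_hamming`` averages the normalized
    Hamming distances over all pairs of separator-based variants
    excluding optBWT, which serves as the baseline.
    """

    k: int
    total_length: int
    avg_length: Fraction
    c_m: int
    interval_ratio_transform: Fraction
    interval_ratio_raw: Fraction
    variability: Fraction
    variability_defined: bool
    runs: dict[str, RunsSummary]
    pairwise_hamming: dict[tuple[str, str], Fraction]
    avg_hamming: Fraction
    edit_vs_ebwt: dict[str, int]
    edit_subsample_size: int
    max_nr: Fraction
    min_nr: Fraction
    nr_optimal: Fraction

    def to_dict(self) -> dict:
        return {
            "number of sequences": self.k,
            "average length": float(self.avg_length),
            "ratio of positions in interesting intervals": float(
                self.interval_ratio_transform
            ),
            "ratio of positions in interesting intervals (raw length)": float(
                self.interval_ratio_raw
            ),
            "number of interesting intervals": self.c_m,
            "variability": float(self.variability),
            "variability defined": self.variability_defined,
            "average normalized Hamming distance": float(self.avg_hamming),
            "max n/r": float(self.max_nr),
            "min n/r": float(self.min_nr),
            "n/r optimal": float(self.nr_optimal),
            "runs": {v: s.run_count for v, s in self.runs.items()},
            "pairwise normalized Hamming": {
                f"{a}-{b}": float(d) for (a, b), d in self.pairwise_hamming.items()
            },
            "edit distance vs eBWT": dict(self.edit_vs_ebwt),
            "edit subsample size": self.edit_subsample_size,
        }


def compare_all(
    m: StringCollection,
    subsample: Optional[int] = None,
    seed: Optional[int] = None,
) -> ComparisonReport:
    """Build all six transforms of ``m`` and compare them.

    ``subsample`` caps the number of whole sequences used for the edit
    distances against the eBWT (a seeded uniform sample of members, never
    of substrings); Hamming distances and run statistics always use the
    full collection.
    """
    import numpy as np

    transforms = {
        "ebwt": ebwt(m),
        "dolebwt": dol_ebwt(m),
        "mdolbwt": mdol_bwt(m),
        "colexbwt": colex_bwt(m),
        "optbwt": opt_bwt(m),
        "concbwt": conc_bwt(m),
    }
    runs = {v: t.runs_summary() for v, t in transforms.items()}

    ivs = _interval_details(m)
    total_width = sum(iv.width for iv in ivs)
    sep_len = m.total_length + m.k
    var = variability(m)

    pairwise: dict[tuple[str, str], Fraction] = {}
    for i, a in enumerate(SEPARATOR_VARIANTS):
        for b in SEPARATOR_VARIANTS[i + 1:]:
            pairwise[(a, b)] = hamming(
                transforms[a], transforms[b], normalized=True
            )
    non_opt_pairs = [
        d for (a, b), d in pairwise.items() if "optbwt" not in (a, b)
    ]
    avg_hamming = (
        sum(non_opt_pairs, Fraction(0)) / len(non_opt_pairs)
        if non_opt_pairs
        else Fraction(0)
    )

    if subsample is not None and subsample < m.k:
        rng = np.random.default_rng(seed)
        chosen = sorted(rng.choice(m.k, size=subsample, replace=False))
        sub = StringCollection([m.strings[i] for i in chosen])
    else:
        sub = m
    sub_ebwt = ebwt(sub)
    edit_vs = {
        "dolebwt": edit_distance(sub_ebwt, dol_ebwt(sub)),
        "mdolbwt": edit_distance(sub_ebwt, mdol_bwt(sub)),
        "colexbwt": edit_distance(sub_ebwt, colex_bwt(sub)),
        "optbwt": edit_distance(sub_ebwt, opt_bwt(sub)),
        "concbwt": edit_distance(sub_ebwt, conc_bwt(sub)),
    }

    non_opt_nr = [
        runs[v].avg_runlength for v in VARIANT_ORDER_NON_OPT
    ]
    return ComparisonReport(
        k=m.k,
        total_length=m.total_length,
        avg_length=Fraction(m.total_length, m.k),
        c_m=len(ivs),
        interval_ratio_transform=Fraction(total_width, sep_len),
        interval_ratio_raw=Fraction(total_width, m.total_length),
        variability=var.value,
        variability_defined=var.defined,
        runs=runs,
        pairwise_hamming=pairwise,
        avg_hamming=avg_hamming,
        edit_vs_ebwt=edit_vs,
        edit_subsample_size=sub.k,
        max_nr=max(non_opt_nr),
        min_nr=min(non_opt_nr),
        nr_optimal=runs["optbwt"].avg_runlength,
    )


VARIANT_ORDER_NON_OPT = ("ebwt", "dolebwt", "mdolbwt", "colexbwt", "concbwt")
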