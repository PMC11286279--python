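"""Brute-force reference implementations and a seeded collection generator.

Every fast construction path in :mod:`multibwt.transforms` and
:mod:`multibwt.analysis` has an independent ground truth here: explicit
rotation lists sorted with the builtin comparison sort, exhaustive
enumeration of input permutations, and exhaustive enumeration of interval
arrangements.  The generator produces deterministic synthetic collections
so that the test suite needs no external data.

All caps are parameters, not constants, so callers may raise them.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterator, Optional

import numpy as np

from .core import (
    SEPARATOR,
    StringCollection,
    count_runs,
    primitive_root,
)
from .transforms import OrderPermutation, mdol_bwt

__all__ = [
    "GeneratorSpec",
    "generate",
    "naive_omega_sort",
    "naive_ebwt",
    "naive_mdol_bwt",
    "naive_conc_bwt",
    "brute_min_runs_order",
    "brute_interval_max_runs",
    "brute_interesting_suffixes",
]


# ----------------------------------------------------------------------
# naive transforms (explicit rotation lists, comparison sort)
# ----------------------------------------------------------------------

def naive_omega_sort(
    m: StringCollection, cap: int = 500
) -> list[tuple[bytes, int, int]]:
    """All conjugates of all members in omega-order, by materialized powers.

    Each conjugate's infinite power is expanded to twice the maximum
    member length and compared directly; equal powers (equal roots) are
    ordered by exponent, then stably by (member index, offset).  Returns
    (conjugate, member index, offset) triples.
    """
    if m.total_length > cap:
        raise ValueError(f"collection exceeds the oracle cap ({cap})")
    horizon = 2 * max(len(t) for t in m.strings)
    entries = []
    for i, t in enumerate(m.strings):
        exp = len(t) // len(primitive_root(t).root)
        reps = horizon // len(t) + 1
        for off in range(len(t)):
            conj = t[off:] + t[:off]
            entries.append(((conj * reps)[:horizon], exp, i, off, conj))
    entries.sort(key=lambda e: e[:4])
    return [(conj, i, off) for _, _, i, off, conj in entries]


def naive_ebwt(m: StringCollection, cap: int = 500) -> bytes:
    """eBWT text from the naive omega-sort."""
    return bytes(conj[-1] for conj, _, _ in naive_omega_sort(m, cap))


def _rotations_of(seq: tuple[int, ...]) -> list[tuple[int, ...]]:
    return [seq[i:] + seq[:i] for i in range(len(seq))]


def naive_mdol_bwt(
    m: StringCollection,
    order: Optional[OrderPermutation] = None,
    cap: int = 500,
) -> bytes:
    """mdolBWT text by explicit rotation sort of T1 $1 ... Tk $k.

    The concatenation is modelled as a tuple of ints with dollar i
    encoded as i (1..k) below every alphabet byte (b + k + 1); the full
    rotation list is sorted by tuple comparison.
    """
    if m.total_length > cap:
        raise ValueError(f"collection exceeds the oracle cap ({cap})")
    if order is not None:
        m = m.reordered(order.indices)
    k = m.k
    seq: list[int] = []
    for i, t in enumerate(m.strings):
        seq.extend(b + k + 1 for b in t)
        seq.append(i + 1)
    rots = sorted(_rotations_of(tuple(seq)))
    return bytes(
        SEPARATOR[0] if r[-1] <= k else r[-1] - k - 1 for r in rots
    )


def naive_conc_bwt(
    m: StringCollection,
    order: Optional[OrderPermutation] = None,
    normalized: bool = True,
    cap: int = 500,
) -> bytes:
    """concBWT text by explicit rotation sort of T1 $ ... Tk $ #."""
    if m.total_length > cap:
        raise ValueError(f"collection exceeds the oracle cap ({cap})")
    if order is not None:
        m = m.reordered(order.indices)
    seq: list[int] = []
    for t in m.strings:
        seq.extend(b + 2 for b in t)
        seq.append(1)
    seq.append(0)
    rots = sorted(_rotations_of(tuple(seq)))
    last = [r[-1] for r in rots]
    if normalized:
        assert last[0] == 1
        last = last[1:]
        last = [1 if v == 0 else v for v in last]
        return bytes(SEPARATOR[0] if v == 1 else v - 2 for v in last)
    out = []
    for v in last:
        out.append(0x23 if v == 0 else (SEPARATOR[0] if v == 1 else v - 2))
    return bytes(out)


# ----------------------------------------------------------------------
# exhaustive optimizers
# ----------------------------------------------------------------------

def brute_min_runs_order(
    m: StringCollection, max_k: int = 7
) -> tuple[OrderPermutation, int]:
    """Exhaustive minimum of runs(mdolBWT) over all k! input orders."""
    if m.k > max_k:
        raise ValueError(f"k={m.k} exceeds the exhaustive cap ({max_k})")
    best_perm: Optional[tuple[int, ...]] = None
    best_runs = None
    for perm in permutations(range(m.k)):
        r = count_runs(mdol_bwt(m, OrderPermutation(perm)).text).run_count
        if best_runs is None or r < best_runs:
            best_runs = r
            best_perm = perm
    return OrderPermutation(best_perm), best_runs


def _multiset_permutations(counts: dict) -> Iterator[tuple]:
    symbols = sorted(counts)
    remaining = dict(counts)
    total = sum(counts.values())

    def rec(prefix: list) -> Iterator[tuple]:
        if len(prefix) == total:
            yield tuple(prefix)
            return
        for s in symbols:
            if remaining[s] > 0:
                remaining[s] -= 1
                prefix.append(s)
                yield from rec(prefix)
                prefix.pop()
                remaining[s] += 1

    yield from rec([])


def brute_interval_max_runs(parikh: dict, cap: int = 10) -> int:
    """Maximum run count over all distinct arrangements of a multiset."""
    counts = {s: c for s, c in parikh.items() if c > 0}
    if not counts:
        raise ValueError("parikh vector must contain positive counts")
    width = sum(counts.values())
    if width > cap:
        raise ValueError(f"width {width} exceeds the enumeration cap ({cap})")
    return max(
        count_runs(bytes(ord("a") + i for i in _relabel(arr))).run_count
        for arr in _multiset_permutations(counts)
    )


def _relabel(arrangement: tuple) -> list[int]:
    labels: dict = {}
    out = []
    for s in arrangement:
        out.append(labels.setdefault(s, len(labels)))
    return out


def brute_interesting_suffixes(
    m: StringCollection,
) -> dict[bytes, list[tuple[int, bytes]]]:
    """Left-maximal shared suffixes by direct enumeration.

    Maps each suffix U shared by >= 2 members with >= 2 distinct
    preceding characters (the separator when U is a whole member) to its
    (member index, preceding character) pairs.
    """
    shared: dict[bytes, list[tuple[int, bytes]]] = {}
    for i, t in enumerate(m.strings):
        for off in range(len(t) + 1):
            u = t[off:]
            prev = SEPARATOR if off == 0 else t[off - 1: off]
            shared.setdefault(u, []).append((i, prev))
    return {
        u: rows
        for u, rows in shared.items()
        if len(rows) >= 2 and len({p for _, p in rows}) >= 2
    }


# ----------------------------------------------------------------------
# synthetic collections
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for a deterministic synthetic collection.

    Modes
    -----
    ``iid``
        Independent uniform characters.
    ``mutated-copies``
        One random ancestor per collection; each member is a copy with
        per-site substitutions at ``substitution_rate`` and, optionally,
        single-character insertions/deletions at ``indel_rate``.  Small
        rates over short strings yield many shared suffixes, the regime
        where the BWT variants differ most.
    ``shared-suffix``
        Random strings with explicit suffix blocks appended
        (``suffix_blocks`` = (suffix, how many members receive it)),
        forcing interesting intervals at known suffixes.

    The same spec and seed always produce the same collection.
    """

    k: int
    length_range: tuple[int, int]
    alphabet: bytes = b"ACGT"
    mode: str = "mutated-copies"
    substitution_rate: float = 0.02
    indel_rate: float = 0.0
    suffix_blocks: tuple[tuple[bytes, int], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid length range")
        if self.mode not in ("iid", "mutated-copies", "shared-suffix"):
            raise ValueError(f"unknown generator mode {self.mode!r}")
        if len(self.alphabet) < 1:
            raise ValueError("alphabet must be non-empty")


def generate(spec: GeneratorSpec) -> StringCollection:
    """Materialize the collection described by ``spec`` deterministically."""
    rng = np.random.default_rng(spec.seed)
    sigma = len(spec.alphabet)
    lo, hi = spec.length_range

    def rand_string(length: int) -> bytearray:
        return bytearray(
            spec.alphabet[i] for i in rng.integers(0, sigma, size=length)
        )

    strings: list[bytes] = []
    if spec.mode == "iid":
        for _ in range(spec.k):
            strings.append(bytes(rand_string(int(rng.integers(lo, hi + 1)))))
    elif spec.mode == "mutated-copies":
        ancestor = rand_string(int(rng.integers(lo, hi + 1)))
        for _ in range(spec.k):
            copy = bytearray(ancestor)
            for pos in range(len(copy)):
                if rng.random() < spec.substitution_rate:
                    copy[pos] = spec.alphabet[int(rng.integers(0, sigma))]
            if spec.indel_rate > 0:
                out = bytearray()
                for b in copy:
                    roll = rng.random()
                    if roll < spec.indel_rate / 2:
                        continue  # deletion
                    out.append(b)
                    if roll > 1 - spec.indel_rate / 2:
                        out.append(spec.alphabet[int(rng.integers(0, sigma))])
                copy = out or bytearray([spec.alphabet[0]])
            strings.append(bytes(copy))
    else:  # shared-suffix
        assignments: list[Optional[bytes]] = [None] * spec.k
        slot = 0
        for suffix, count in spec.suffix_blocks:
            for _ in range(count):
                if slot >= spec.k:
                    raise ValueError("suffix blocks exceed the collection size")
                assignments[slot] = bytes(suffix)
                slot += 1
        for suffix in assignments:
            body = rand_string(int(rng.integers(lo, hi + 1)))
            strings.append(bytes(body) + (suffix or b""))
    return StringCollection(strings)
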