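"""Construction of the six BWT variants for string collections.

The variants and their defining input orders:

=========  ==================================================================
eBWT       last characters of all conjugates of all members, in omega-order;
           no sentinels, length N_M, input-order independent.
dolEBWT    eBWT of {Ti$}; equals mdolBWT of the lexicographically sorted
           collection.
mdolBWT    BWT of T1 $1 T2 $2 ... Tk $k with distinct ranked dollars
           ($1 < $2 < ... < $k < alphabet); depends on the input order.
colexBWT   mdolBWT under the colexicographic (reverse-lexicographic) order.
optBWT     mdolBWT under an input order minimizing the number of runs.
concBWT    BWT of T1 $ T2 $ ... Tk $ # with identical dollars and a final
           terminator # < $; normalized by stripping the leading separator
           and renaming # to $.
=========  ==================================================================

All separator-based outputs render every sentinel as the single glyph
``$``; distinct dollar ranks exist only internally (dollar i is ranked i
among sentinels), never as materialized symbols of an enlarged alphabet.

The sorting engine is a prefix-doubling suffix array over the
sentinel-augmented concatenation.  Because the multidollar concatenation
carries pairwise-distinct sentinels (and the concatenated string a unique
terminator), no suffix is a proper prefix of another, so the suffix order
coincides with the rotation order and the last rotation column can be
read off directly.  A naive comparison-sort oracle lives in
:mod:`multibwt.oracles`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cmp_to_key
from typing import Optional, Sequence
import warnings

import numpy as np

from .core import (
    SEPARATOR,
    StringCollection,
    count_runs,
    primitive_root,
)

__all__ = [
    "Transform",
    "OrderPermutation",
    "VARIANTS",
    "SEPARATOR_VARIANTS",
    "ebwt",
    "dol_ebwt",
    "mdol_bwt",
    "colex_order",
    "colex_bwt",
    "opt_order",
    "opt_bwt",
    "conc_bwt",
    "transform",
]

VARIANTS = ("ebwt", "dolebwt", "mdolbwt", "colexbwt", "optbwt", "concbwt")
#: Variants whose output contains separator glyphs (everything but ebwt).
SEPARATOR_VARIANTS = ("dolebwt", "mdolbwt", "colexbwt", "optbwt", "concbwt")


@dataclass(frozen=True)
class OrderPermutation:
    """An input order for a collection: a 0-based bijection on range(k).

    ``indices[j]`` is the original position of the member listed at
    position ``j``.  External permutation files use 1-based indices; the
    Python surface is 0-based.
    """

    indices: tuple[int, ...]
    kind: str = "input"

    def __post_init__(self):
        if sorted(self.indices) != list(range(len(self.indices))):
            raise ValueError("indices do not form a permutation")

    @classmethod
    def identity(cls, k: int, kind: str = "input") -> "OrderPermutation":
        return cls(tuple(range(k)), kind)


@dataclass(frozen=True)
class Transform:
    """A variant-tagged BWT output.

    ``text`` is a byte-string over the collection's alphabet plus the
    separator glyph ``$``.  ``separator_positions`` are 1-based.
    ``order_used`` (0-based permutation) is absent for the
    order-independent variants ebwt and dolEBWT.  ``conjugate_ranks``
    (ebwt only) holds the 1-based omega-ranks of the k input conjugates,
    i.e. the indices that make the eBWT reversible.
    """

    variant: str
    text: bytes
    separator_positions: tuple[int, ...] = ()
    order_used: Optional[tuple[int, ...]] = None
    conjugate_ranks: Optional[tuple[int, ...]] = None

    def __post_init__(self):
        assert self.variant in VARIANTS
        sep = tuple(
            i + 1 for i, c in enumerate(self.text) if c == SEPARATOR[0]
        )
        assert sep == self.separator_positions

    @property
    def length(self) -> int:
        return len(self.text)

    @property
    def runs(self) -> int:
        return count_runs(self.text).run_count

    def runs_summary(self):
        return count_runs(self.text)


# ----------------------------------------------------------------------
# sorting machinery
# ----------------------------------------------------------------------

def _suffix_array(arr: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence by prefix doubling (O(n log^2 n))."""
    n = int(arr.size)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = np.unique(arr, return_inverse=True)[1].astype(np.int64)
    step = 1
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - step] = rank[step:]
        order = np.lexsort((second, rank))
        r1, r2 = rank[order], second[order]
        changed = np.ones(n, dtype=bool)
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.cumsum(changed) - 1
        rank = np.empty(n, dtype=np.int64)
        rank[order] = new_rank
        if new_rank[-1] == n - 1:
            return order
        step *= 2


def _multidollar_array(m: StringCollection) -> np.ndarray:
    """Encode T1 $1 ... Tk $k as ints: dollar i -> i (1..k), byte b -> b+k+1."""
    k = m.k
    parts = []
    for i, t in enumerate(m.strings):
        parts.append(np.frombuffer(t, dtype=np.uint8).astype(np.int64) + k + 1)
        parts.append(np.array([i + 1], dtype=np.int64))
    return np.concatenate(parts)


def _render(values: np.ndarray, n_sentinels: int) -> bytes:
    """Render an int-encoded column: values <= n_sentinels become ``$``."""
    out = np.where(
        values <= n_sentinels, np.int64(SEPARATOR[0]), values - n_sentinels - 1
    )
    return out.astype(np.uint8).tobytes()


def _separator_positions(text: bytes) -> tuple[int, ...]:
    return tuple(i + 1 for i, c in enumerate(text) if c == SEPARATOR[0])


# ----------------------------------------------------------------------
# eBWT and dolEBWT (conjugate sorting in omega-order)
# ----------------------------------------------------------------------

# Internal unicode encoding for conjugate sorting: sentinel -> chr(1),
# byte b -> chr(b + 2).  Order-preserving, and string comparison stays in C.
_SENTINEL_CH = chr(1)


def _encode_str(t: bytes) -> str:
    return "".join(chr(b + 2) for b in t)


def _omega_sorted_conjugates(
    strings: Sequence[str],
) -> list[tuple[str, int, int]]:
    """All conjugates of all strings sorted in omega-order.

    Returns (conjugate, string_index, offset) triples.  Each conjugate is
    keyed by its power expanded to 2 * max length (enough to decide the
    infinite comparison, since |s| + |t| <= 2 * max length), with ties —
    equal infinite powers, i.e. equal roots — broken by exponent, then
    stably by (string index, offset).  Tied conjugates of equal strings
    contribute identical characters, so the output text is unaffected by
    the stable tie-break; it only fixes the provenance bookkeeping.
    """
    horizon = 2 * max(len(s) for s in strings)
    entries = []
    for i, s in enumerate(strings):
        exp = len(s) // len(primitive_root(s.encode("latin-1")).root)
        reps = horizon // len(s) + 1
        for off in range(len(s)):
            conj = s[off:] + s[:off]
            key = (conj * reps)[:horizon]
            entries.append((key, exp, i, off, conj))
    entries.sort(key=lambda e: e[:4])
    return [(conj, i, off) for (_, _, i, off, conj) in entries]


def ebwt(m: StringCollection) -> Transform:
    """Extended BWT: last characters of all conjugates in omega-order.

    Input-order independent and sentinel-free (length N_M).  The
    ``conjugate_ranks`` attribute records, for each input string, the
    1-based omega-rank of its offset-0 rotation; supplying those ranks to
    :func:`multibwt.inversion.invert_ebwt` makes the transform uniquely
    reversible.
    """
    enc = [_encode_str(t) for t in m.strings]
    ordered = _omega_sorted_conjugates(enc)
    text = bytes(ord(conj[-1]) - 2 for conj, _, _ in ordered)
    ranks = [0] * m.k
    for pos, (_, i, off) in enumerate(ordered):
        if off == 0 and ranks[i] == 0:
            ranks[i] = pos + 1
    return Transform("ebwt", text, conjugate_ranks=tuple(ranks))


def dol_ebwt(m: StringCollection) -> Transform:
    """Dollar-eBWT: the eBWT of {Ti$}, one separator appended per member.

    Appending ``$`` makes every member primitive, and on the augmented
    strings the omega-order coincides with the lexicographic order, so
    this equals the mdolBWT of the lexicographically sorted collection.
    The construction here nevertheless goes through the conjugate sorter,
    keeping the two routes independent.
    """
    enc = [_encode_str(t) + _SENTINEL_CH for t in m.strings]
    ordered = _omega_sorted_conjugates(enc)
    text = bytes(
        SEPARATOR[0] if conj[-1] == _SENTINEL_CH else ord(conj[-1]) - 2
        for conj, _, _ in ordered
    )
    return Transform("dolebwt", text, _separator_positions(text))


# ----------------------------------------------------------------------
# multidollar family
# ----------------------------------------------------------------------

def _resolve_order(
    m: StringCollection, order: Optional[OrderPermutation]
) -> OrderPermutation:
    if order is None:
        return OrderPermutation.identity(m.k)
    if len(order.indices) != m.k:
        raise ValueError("order permutation size does not match the collection")
    return order


def mdol_bwt(
    m: StringCollection, order: Optional[OrderPermutation] = None
) -> Transform:
    """Multidollar BWT: BWT(T1 $1 T2 $2 ... Tk $k) in the given order.

    Equivalently, the rotations of the Ti$ are sorted lexicographically
    with ties on the dollar broken by the member's position in the order.
    All dollars render as the single glyph ``$`` in the output.
    """
    order = _resolve_order(m, order)
    listed = m.reordered(order.indices)
    arr = _multidollar_array(listed)
    sa = _suffix_array(arr)
    col = arr[(sa - 1) % arr.size]
    text = _render(col, listed.k)
    return Transform(
        "mdolbwt", text, _separator_positions(text), order_used=order.indices
    )


def colex_order(m: StringCollection) -> OrderPermutation:
    """Colexicographic order: stable sort by reversed-string comparison."""
    idx = sorted(range(m.k), key=lambda i: m.strings[i][::-1])
    return OrderPermutation(tuple(idx), "colex")


def colex_bwt(m: StringCollection) -> Transform:
    """mdolBWT under the colexicographic order of the members."""
    t = mdol_bwt(m, colex_order(m))
    return Transform(
        "colexbwt", t.text, t.separator_positions, order_used=t.order_used
    )


def conc_bwt(
    m: StringCollection,
    order: Optional[OrderPermutation] = None,
    normalized: bool = True,
) -> Transform:
    """Concatenated BWT: BWT(T1 $ T2 $ ... Tk $ #) with # < $ < alphabet.

    The rotation starting with the terminator is the smallest and places
    one separator at the front of the raw transform.  When ``normalized``
    (the default), that leading separator is removed and the terminator
    glyph is renamed to ``$``, giving length N_M + k comparable with the
    other separator-based variants; the raw form has length N_M + k + 1
    and contains a literal ``#``.
    """
    order = _resolve_order(m, order)
    listed = m.reordered(order.indices)
    parts = []
    for t in listed.strings:
        parts.append(np.frombuffer(t, dtype=np.uint8).astype(np.int64) + 2)
        parts.append(np.array([1], dtype=np.int64))  # $
    parts.append(np.array([0], dtype=np.int64))  # terminator #
    arr = np.concatenate(parts)
    sa = _suffix_array(arr)
    col = arr[(sa - 1) % arr.size]
    if normalized:
        assert col[0] == 1, "smallest rotation must contribute a separator"
        col = col[1:]
        col[col == 0] = 1  # rename # to $
        text = _render(col, 1)
        return Transform(
            "concbwt", text, _separator_positions(text), order_used=order.indices
        )
    chars = []
    for v in col:
        if v == 0:
            chars.append(0x23)  # literal '#'
        elif v == 1:
            chars.append(SEPARATOR[0])
        else:
            chars.append(int(v) - 2)
    raw = bytes(chars)
    # Raw form is returned as plain bytes-bearing Transform; its '#' is a
    # literal glyph, and length is N_M + k + 1.
    return Transform("concbwt", raw, _separator_positions(raw), order_used=order.indices)


# ----------------------------------------------------------------------
# run-minimizing order (optBWT)
# ----------------------------------------------------------------------

def opt_order(m: StringCollection) -> OrderPermutation:
    """An input order whose mdolBWT attains the minimum run count.

    Within the interval of every left-maximal shared suffix U, the BWT
    characters are the characters preceding U in the member strings, and
    their order is the chosen order of those members; everywhere else the
    transform does not depend on the order.  Any order that keeps each
    interval's members grouped by character yields one run per distinct
    character there; the remaining freedom — which character group comes
    first and which last — is used to merge the interval's border runs
    with the fixed context outside.  Choices at different intervals are
    independent, because a pair of members is ordered relative to each
    other exactly at the interval of their longest common suffix; runs of
    consecutive intervals are coupled only through their shared borders,
    which a small dynamic program over each chain of adjacent intervals
    resolves optimally.
    """
    from .analysis import _interval_details  # deferred: analysis imports us

    k = m.k
    if k == 1:
        return OrderPermutation.identity(1, "opt")

    details = _interval_details(m)
    if not details:
        return OrderPermutation(colex_order(m).indices, "opt")

    context = colex_bwt(m).text  # chars outside intervals are order-invariant
    n = len(context)

    # Chains of positionally adjacent intervals.
    chains: list[list] = []
    for d in details:  # details sorted by begin
        if chains and chains[-1][-1].end + 1 == d.begin:
            chains[-1].append(d)
        else:
            chains.append([d])

    arrangements: dict[bytes, dict[bytes, int]] = {}
    for chain in chains:
        left = context[chain[0].begin - 2: chain[0].begin - 1] or None
        right = context[chain[-1].end: chain[-1].end + 1] or None
        _arrange_chain(chain, left, right, arrangements)

    def cmp(i: int, j: int) -> int:
        ri, rj = m.strings[i][::-1], m.strings[j][::-1]
        if ri == rj:
            return i - j  # stable on duplicates
        p = 0
        limit = min(len(ri), len(rj))
        while p < limit and ri[p] == rj[p]:
            p += 1
        ci = SEPARATOR if p == len(ri) else ri[p: p + 1]
        cj = SEPARATOR if p == len(rj) else rj[p: p + 1]
        suffix = m.strings[i][len(m.strings[i]) - p:]
        ranks = arrangements.get(suffix)
        if ranks is not None:
            return ranks[ci] - ranks[cj]
        return -1 if ri < rj else 1  # defensive; differing pairs sit in intervals

    idx = sorted(range(k), key=cmp_to_key(cmp))
    return OrderPermutation(tuple(idx), "opt")


def _arrange_chain(chain, left, right, arrangements) -> None:
    """Choose first/last character groups along one chain of adjacent intervals.

    DP state: the last character of the previous interval.  Every ordered
    pair (first, last) of distinct interval characters is feasible; a
    match with the preceding character saves one run, as does a match of
    the final interval's last character with the right context.
    """
    states: dict[Optional[bytes], tuple[int, tuple]] = {left: (0, ())}
    for d in chain:
        chars = sorted(d.parikh.keys())
        new: dict[Optional[bytes], tuple[int, tuple]] = {}
        for prev, (cost, path) in states.items():
            for first in chars:
                base = cost + len(chars) - (first == prev)
                for last in chars:
                    if last == first:
                        continue
                    cand = (base, path + ((first, last),))
                    if last not in new or cand[0] < new[last][0]:
                        new[last] = cand
        states = new
    best_last, (best_cost, best_path) = min(
        states.items(), key=lambda kv: kv[1][0] - (kv[0] == right)
    )
    for d, (first, last) in zip(chain, best_path):
        chars = sorted(d.parikh.keys())
        middle = [c for c in chars if c not in (first, last)]
        arrangements[d.suffix] = {
            c: r for r, c in enumerate([first, *middle, last])
        }


def opt_bwt(m: StringCollection) -> Transform:
    """mdolBWT under the run-minimizing input order."""
    t = mdol_bwt(m, opt_order(m))
    return Transform(
        "optbwt", t.text, t.separator_positions, order_used=t.order_used
    )


# ----------------------------------------------------------------------
# dispatch
# ----------------------------------------------------------------------

def transform(
    m: StringCollection,
    variant: str,
    order: Optional[OrderPermutation] = None,
    normalized: bool = True,
) -> Transform:
    """Build the named variant; ``order`` applies to mdolbwt/concbwt only."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if order is not None and variant not in ("mdolbwt", "concbwt"):
        warnings.warn(
            f"{variant} does not take an input order; ignoring it", stacklevel=2
        )
        order = None
    if variant == "ebwt":
        return ebwt(m)
    if variant == "dolebwt":
        return dol_ebwt(m)
    if variant == "mdolbwt":
        return mdol_bwt(m, order)
    if variant == "colexbwt":
        return colex_bwt(m)
    if variant == "optbwt":
        return opt_bwt(m)
    return conc_bwt(m, order, normalized)
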