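"""String algebra underlying the BWT variants for string collections.

This module provides the primitives that every transform builds on:
primitive roots and exponents, conjugates (rotations), runs, and the
omega-order comparator that defines the extended BWT (eBWT).

Strings are treated as opaque byte sequences throughout; no case folding
happens here (that is an I/O option).  Two byte values are reserved as
sentinel glyphs and may not occur in input strings: ``$`` (0x24), used as
the end-of-string separator, and ``#`` (0x23), the terminator of the
concatenated BWT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import groupby
from typing import Iterable, Sequence

__all__ = [
    "SEPARATOR",
    "TERMINATOR",
    "StringCollection",
    "RootDecomposition",
    "RunsSummary",
    "primitive_root",
    "count_runs",
    "omega_compare",
    "conjugates",
]

#: End-of-string separator glyph (rendered ``$``); smaller than every
#: alphabet symbol.
SEPARATOR: bytes = b"$"

#: Terminator glyph of the concatenated BWT (rendered ``#``); smaller
#: than the separator.
TERMINATOR: bytes = b"#"


def _as_bytes(s: bytes | str) -> bytes:
    if isinstance(s, str):
        return s.encode("ascii")
    return bytes(s)


@dataclass(frozen=True)
class StringCollection:
    """An ordered multiset of non-empty byte-strings M = [T1, ..., Tk].

    The input order of the members is significant: several transforms
    (mdolBWT, concBWT) depend on it.  Members may not contain the
    reserved sentinel glyphs ``$`` and ``#``.

    Parameters
    ----------
    strings:
        The members, in input order.  ``str`` items are encoded as ASCII.
    """

    strings: tuple[bytes, ...]

    def __init__(self, strings: Iterable[bytes | str]):
        members = tuple(_as_bytes(s) for s in strings)
        if len(members) == 0:
            raise ValueError("a string collection must contain at least one string")
        for idx, t in enumerate(members):
            if len(t) == 0:
                raise ValueError(f"empty string at position {idx + 1}")
            if SEPARATOR[0] in t or TERMINATOR[0] in t:
                raise ValueError(
                    f"string at position {idx + 1} contains a reserved "
                    f"sentinel glyph ('$' or '#')"
                )
        object.__setattr__(self, "strings", members)

    @property
    def k(self) -> int:
        """Number of member strings."""
        return len(self.strings)

    @property
    def total_length(self) -> int:
        """N_M, the summed length of all members."""
        return sum(len(t) for t in self.strings)

    @property
    def alphabet(self) -> tuple[int, ...]:
        """Sorted distinct byte values occurring in the collection."""
        seen: set[int] = set()
        for t in self.strings:
            seen.update(t)
        return tuple(sorted(seen))

    @property
    def sigma(self) -> int:
        """Alphabet size."""
        return len(self.alphabet)

    def reordered(self, permutation: Sequence[int]) -> "StringCollection":
        """Return the collection listed in the given order.

        ``permutation`` is a 0-based bijection on ``range(k)``; entry ``j``
        names the member placed at position ``j`` of the new listing.
        """
        if sorted(permutation) != list(range(self.k)):
            raise ValueError("not a permutation of the collection's indices")
        return StringCollection([self.strings[i] for i in permutation])

    def __iter__(self):
        return iter(self.strings)

    def __len__(self) -> int:
        return self.k


@dataclass(frozen=True)
class RootDecomposition:
    """The unique writing of a string as root^exponent with a primitive root."""

    root: bytes
    exponent: int

    def rebuild(self) -> bytes:
        return self.root * self.exponent


@dataclass(frozen=True)
class RunsSummary:
    """Run statistics of a string: length n, run count r, and n/r."""

    length: int
    run_count: int
    avg_runlength: Fraction = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "avg_runlength", Fraction(self.length, self.run_count)
        )


def primitive_root(t: bytes | str) -> RootDecomposition:
    """Decompose ``t`` uniquely as U^m with U primitive.

    The smallest period dividing ``len(t)`` is found by direct divisor
    check; a string is primitive iff that period is its full length.
    """
    t = _as_bytes(t)
    n = len(t)
    if n == 0:
        raise ValueError("the empty string has no root decomposition")
    for p in range(1, n + 1):
        if n % p == 0 and t[:p] * (n // p) == t:
            return RootDecomposition(t[:p], n // p)
    raise AssertionError("unreachable")  # pragma: no cover


def count_runs(t: bytes | str) -> RunsSummary:
    """Count maximal equal-symbol blocks, e.g. runs(CAAGGGA) = 4."""
    t = _as_bytes(t)
    if len(t) == 0:
        raise ValueError("runs of the empty string are undefined")
    r = sum(1 for _ in groupby(t))
    return RunsSummary(len(t), r)


def omega_compare(s: bytes | str, t: bytes | str) -> int:
    """Compare two non-empty strings in omega-order.

    ``s`` precedes ``t`` when the infinite powers satisfy
    ``s^omega <lex t^omega``, or when both strings share the same
    primitive root and ``s`` has the smaller exponent.  Returns -1, 0, or
    1.  The infinite comparison is truncated at ``len(s) + len(t)``
    symbols, which suffices by Fine and Wilf's periodicity theorem: if the
    powers agree that far, the roots are equal.

    Unlike the lexicographic order, a proper prefix need not come first:
    GT <lex GTC but GTC precedes GT in omega-order.
    """
    s = _as_bytes(s)
    t = _as_bytes(t)
    if len(s) == 0 or len(t) == 0:
        raise ValueError("omega-order is defined on non-empty strings only")
    horizon = len(s) + len(t)
    ps = (s * (horizon // len(s) + 1))[:horizon]
    pt = (t * (horizon // len(t) + 1))[:horizon]
    if ps < pt:
        return -1
    if ps > pt:
        return 1
    # Same infinite power => same primitive root; smaller exponent first.
    es = len(s) // len(primitive_root(s).root)
    et = len(t) // len(primitive_root(t).root)
    return (es > et) - (es < et)


def conjugates(t: bytes | str) -> list[tuple[bytes, int]]:
    """All rotations of ``t`` with their starting offsets.

    Duplicates are retained: a string of length n has n distinct
    conjugates iff it is primitive.
    """
    t = _as_bytes(t)
    if len(t) == 0:
        raise ValueError("the empty string has no conjugates")
    return [(t[i:] + t[:i], i) for i in range(len(t))]
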