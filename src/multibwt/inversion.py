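"""Inversion of the BWT variants via the LF mapping.

Separator-based texts (mdolBWT, colexBWT, optBWT, dolEBWT) are inverted
by walking the LF mapping backwards from each of the first k rows — the
rows of the k dollar-initial rotations — collecting characters until a
separator is met.  Those walks only ever step through ordinary alphabet
characters, for which the LF mapping is unambiguous regardless of how the
dollar ranks were assigned, so one procedure serves all multidollar-style
variants.

The eBWT has no sentinels; its LF permutation decomposes into cycles,
one per primitive conjugacy class (with multiplicities), so inversion
recovers the multiset of classes.  Supplying the conjugate ranks recorded
at construction anchors each class to the exact input rotation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .core import SEPARATOR, TERMINATOR, StringCollection

__all__ = ["InversionResult", "invert_separator_bwt", "invert_ebwt"]


@dataclass(frozen=True)
class InversionResult:
    """Recovered strings plus how faithfully they mirror the input.

    ``mode`` is ``"exact-multiset"`` when the recovered strings equal the
    input members, or ``"conjugacy-classes"`` when only rotation classes
    are determined (eBWT without ranks).  ``order_recovered`` is True
    when the listing order is the transform's internal concatenation
    order; the user's original labels are not encoded by any variant.
    """

    strings: tuple[bytes, ...]
    mode: str
    order_recovered: bool

    def collection(self) -> StringCollection:
        return StringCollection(self.strings)


def _as_bytes(text: Union[bytes, str]) -> bytes:
    return text.encode("ascii") if isinstance(text, str) else bytes(text)


def _lf_table(text: bytes) -> list[int]:
    """LF[i] = C[text[i]] + rank of text[i] within text[:i+1], 0-based."""
    counts = Counter(text)
    c_arr: dict[int, int] = {}
    acc = 0
    for sym in sorted(counts):
        c_arr[sym] = acc
        acc += counts[sym]
    seen: Counter = Counter()
    lf = []
    for ch in text:
        lf.append(c_arr[ch] + seen[ch])
        seen[ch] += 1
    return lf


def invert_separator_bwt(
    text: Union[bytes, str], variant: Optional[str] = None
) -> InversionResult:
    """Recover the collection from a separator-based transform text.

    Works identically for mdolBWT, colexBWT, optBWT and dolEBWT texts —
    they differ only in dollar tie-breaking, which the backward walks
    never need to resolve.  Pass ``variant="concbwt"`` for a normalized
    concBWT text (the implicit terminator is re-inserted); a raw concBWT
    containing a literal ``#`` is detected and inverted directly.
    """
    text = _as_bytes(text)
    if SEPARATOR[0] not in text:
        raise ValueError("not a separator-based transform: no separator found")
    if TERMINATOR[0] in text:
        return _invert_conc_raw(text)
    if variant == "concbwt":
        return _invert_conc_normalized(text)

    k = text.count(SEPARATOR[0])
    lf = _lf_table(text)
    n = len(text)
    strings: list[bytes] = []
    used = 0
    for row in range(k):
        out = bytearray()
        r = row
        steps = 0
        while text[r] != SEPARATOR[0]:
            out.append(text[r])
            r = lf[r]
            steps += 1
            if steps > n:
                raise ValueError("invalid transform: LF walk does not terminate")
        if not out:
            raise ValueError("invalid transform: empty string recovered")
        strings.append(bytes(out[::-1]))
        used += len(out)
    if used + k != n:
        raise ValueError("invalid transform: LF cycles do not cover the text")
    return InversionResult(tuple(strings), "exact-multiset", True)


def _invert_single_bwt(text: bytes) -> bytes:
    """Textbook inversion of a single-string BWT anchored at its smallest row.

    Returns the rotation whose row is 0; raises if the LF permutation is
    not a single cycle.
    """
    lf = _lf_table(text)
    n = len(text)
    out = bytearray()
    r = 0
    for _ in range(n):
        out.append(text[r])
        r = lf[r]
    if r != 0:
        raise ValueError("invalid transform: LF is not a single cycle")
    return bytes(out[::-1])


def _split_conc(s: bytes) -> tuple[bytes, ...]:
    """Split T1 $ ... Tk $ # back into members."""
    assert s.endswith(TERMINATOR)
    body = s[:-1]
    if not body.endswith(SEPARATOR):
        raise ValueError("invalid concBWT: concatenation does not end with $")
    parts = body[:-1].split(SEPARATOR)
    if any(len(p) == 0 for p in parts):
        raise ValueError("invalid concBWT: empty member recovered")
    return tuple(parts)


def _invert_conc_raw(text: bytes) -> InversionResult:
    if text.count(TERMINATOR[0]) != 1:
        raise ValueError("raw concBWT must contain exactly one terminator")
    rotation = _invert_single_bwt(text)  # row 0 starts with '#'
    s = rotation[1:] + rotation[:1]  # put the terminator last
    return InversionResult(_split_conc(s), "exact-multiset", True)


def _invert_conc_normalized(text: bytes) -> InversionResult:
    """Undo the concBWT normalization, then invert the raw text.

    Normalization stripped a leading separator and renamed the terminator
    to ``$``; the terminator's position is recovered by trying each
    separator occurrence and keeping the candidate whose inversion
    re-transforms to the candidate text.
    """
    from .transforms import conc_bwt  # deferred: avoid import cycle at load

    for p, ch in enumerate(text):
        if ch != SEPARATOR[0]:
            continue
        raw = SEPARATOR + text[:p] + TERMINATOR + text[p + 1:]
        try:
            rotation = _invert_single_bwt(raw)
            s = rotation[1:] + rotation[:1]
            members = _split_conc(s)
            m = StringCollection(members)
        except ValueError:
            continue
        if conc_bwt(m, normalized=False).text == raw:
            return InversionResult(members, "exact-multiset", True)
    raise ValueError("invalid transform: no consistent terminator position")


def invert_ebwt(
    text: Union[bytes, str],
    ranks: Optional[Iterable[int]] = None,
) -> InversionResult:
    """Invert an eBWT text into conjugacy classes, or exactly with ranks.

    Without ranks, the LF cycles yield the multiset of primitive
    conjugacy classes with multiplicities (a member U^m contributes m
    copies of U's class); classes are reported as their lexicographically
    least rotation, sorted, since the eBWT encodes no input order.  With
    ``ranks`` — the 1-based omega-ranks of the input conjugates, as
    recorded in :attr:`Transform.conjugate_ranks` — each input string is
    recovered exactly (up to the folding of non-primitive members, whose
    exponent the rank set cannot encode).
    """
    text = _as_bytes(text)
    if len(text) == 0:
        raise ValueError("cannot invert an empty eBWT")
    if SEPARATOR[0] in text or TERMINATOR[0] in text:
        raise ValueError("eBWT text may not contain sentinel glyphs")
    lf = _lf_table(text)
    n = len(text)

    if ranks is not None:
        strings = []
        for rank in ranks:
            if not 1 <= rank <= n:
                raise ValueError(f"conjugate rank {rank} out of range 1..{n}")
            start = rank - 1
            out = bytearray([text[start]])
            r = lf[start]
            while r != start:
                out.append(text[r])
                r = lf[r]
            strings.append(bytes(out[::-1]))
        return InversionResult(tuple(strings), "exact-multiset", True)

    visited = [False] * n
    classes: list[bytes] = []
    for start in range(n):
        if visited[start]:
            continue
        out = bytearray()
        r = start
        while not visited[r]:
            visited[r] = True
            out.append(text[r])
            r = lf[r]
        word = bytes(out[::-1])
        rotations = [word[i:] + word[:i] for i in range(len(word))]
        classes.append(min(rotations))
    return InversionResult(tuple(sorted(classes)), "conjugacy-classes", False)
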