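"""Readers and writers for collections, transforms, and reports.

Supported input formats: FASTA and FASTQ (via Biopython, gzip accepted),
and plain one-sequence-per-line text.  Records are ingested in file
order — the order is significant for the order-dependent transforms —
and may then be reordered by a named policy.  Records containing the
reserved sentinel glyphs ``$`` or ``#`` are rejected with the record
name rather than silently escaped.
"""

from __future__ import annotations

import gzip
import io as _io
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio import SeqIO

from .core import StringCollection
from .transforms import OrderPermutation, Transform, colex_order, opt_order

__all__ = [
    "read_collection",
    "read_permutation",
    "write_permutation",
    "write_transform",
    "write_fasta",
    "write_report",
    "resolve_order",
]

log = logging.getLogger("multibwt")

_FASTA_EXT = {".fa", ".fasta", ".fna", ".ffn"}
_FASTQ_EXT = {".fq", ".fastq"}


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _detect_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    ext = suffixes[-1] if suffixes else ""
    if ext in _FASTA_EXT:
        return "fasta"
    if ext in _FASTQ_EXT:
        return "fastq"
    if ext in {".txt", ".lines", ""}:
        return "lines"
    with _open_text(path) as fh:
        head = fh.read(1)
    if head == ">":
        return "fasta"
    if head == "@":
        return "fastq"
    return "lines"


def read_collection(
    path: Union[str, Path],
    format: str = "auto",
    case_policy: str = "preserve",
    names_out: Optional[list] = None,
) -> StringCollection:
    """Read an ordered collection from FASTA, FASTQ, or plain-line text.

    FASTQ quality lines are discarded.  ``case_policy="upper"`` folds
    sequences to upper case (transforms themselves never fold).  When a
    list is passed as ``names_out`` it receives the record names.
    """
    path = Path(path)
    fmt = _detect_format(path) if format == "auto" else format
    records: list[tuple[str, str]] = []
    if fmt in ("fasta", "fastq"):
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, fmt):
                records.append((rec.id, str(rec.seq)))
    elif fmt == "lines":
        with _open_text(path) as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if line:
                    records.append((f"line{i + 1}", line))
    else:
        raise ValueError(f"unknown input format {format!r}")
    if not records:
        raise ValueError(f"no sequences found in {path}")
    strings = []
    for name, seq in records:
        if not seq:
            raise ValueError(f"empty record {name!r} in {path}")
        if "$" in seq or "#" in seq:
            raise ValueError(
                f"record {name!r} contains a reserved sentinel glyph ('$' or '#')"
            )
        strings.append(seq.upper() if case_policy == "upper" else seq)
    if names_out is not None:
        names_out.extend(name for name, _ in records)
    m = StringCollection(strings)
    log.info(
        "read %d sequences, total length %d, alphabet size %d from %s",
        m.k, m.total_length, m.sigma, path,
    )
    return m


def resolve_order(
    m: StringCollection,
    policy: str,
    permutation_file: Optional[Union[str, Path]] = None,
) -> Optional[OrderPermutation]:
    """Turn an order policy name into a permutation (None = file order)."""
    if policy in ("file-order", "input"):
        return None
    if policy == "lex":
        idx = sorted(range(m.k), key=lambda i: m.strings[i])
        return OrderPermutation(tuple(idx), "lex")
    if policy == "colex":
        return colex_order(m)
    if policy == "opt":
        return opt_order(m)
    if policy == "permutation-file":
        if permutation_file is None:
            raise ValueError("permutation-file policy requires a file path")
        return read_permutation(permutation_file)
    raise ValueError(f"unknown order policy {policy!r}")


def read_permutation(path: Union[str, Path]) -> OrderPermutation:
    """Read a permutation file: one 1-based index per line."""
    with _open_text(path) as fh:
        idx = [int(line) - 1 for line in fh if line.strip()]
    return OrderPermutation(tuple(idx), "input")


def write_permutation(order: OrderPermutation, path: Union[str, Path]) -> None:
    Path(path).write_text("".join(f"{i + 1}\n" for i in order.indices))


def write_transform(
    t: Transform, path: Union[str, Path], format: str = "text"
) -> None:
    """Serialize a transform: one-line text, or run-length-encoded TSV."""
    path = Path(path)
    if format == "text":
        path.write_bytes(t.text + b"\n")
    elif format == "rle-tsv":
        rows = []
        prev, run = None, 0
        for ch in t.text:
            if ch == prev:
                run += 1
            else:
                if prev is not None:
                    rows.append((prev, run))
                prev, run = ch, 1
        rows.append((prev, run))
        with open(path, "w") as fh:
            for ch, run in rows:
                fh.write(f"{chr(ch)}\t{run}\n")
    else:
        raise ValueError(f"unknown transform format {format!r}")


def write_ranks(ranks: Sequence[int], path: Union[str, Path]) -> None:
    """Sidecar for eBWT reversibility: one 1-based conjugate rank per line."""
    Path(path).write_text("".join(f"{r}\n" for r in ranks))


def read_ranks(path: Union[str, Path]) -> tuple[int, ...]:
    with _open_text(path) as fh:
        return tuple(int(line) for line in fh if line.strip())


def write_fasta(
    strings: Sequence[Union[bytes, str]],
    path: Union[str, Path],
    names: Optional[Sequence[str]] = None,
) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(strings):
            if isinstance(s, bytes):
                s = s.decode("latin-1")
            name = names[i] if names else f"seq{i + 1}"
            fh.write(f">{name}\n{s}\n")


def write_lines(strings: Sequence[Union[bytes, str]], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for s in strings:
            if isinstance(s, bytes):
                s = s.decode("latin-1")
            fh.write(s + "\n")


def write_report(report, path: Union[str, Path], format: str = "json") -> None:
    """Write a comparison report as JSON or two-column TSV."""
    data = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(data, indent=2, default=str) + "\n")
    elif format == "tsv":
        buf = _io.StringIO()
        for key, value in data.items():
            if isinstance(value, dict):
                for sub, v in value.items():
                    buf.write(f"{key}\t{sub}\t{v}\n")
            else:
                buf.write(f"{key}\t{value}\n")
        path.write_text(buf.getvalue())
    else:
        raise ValueError(f"unknown report format {format!r}")
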