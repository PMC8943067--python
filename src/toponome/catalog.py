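"""Ranked combinatorial-molecular-phenotype (CMP) frequency tables.

A CMP is the binary presence/absence pattern of all markers at one pixel,
written as a bitstring whose *leftmost* character is marker 0 (the numbering
convention of serial immunostaining instruments, which label the first marker
imaged as marker #0).  A CMP table ranks the distinct CMPs of an image, a
cell, or a marker-restricted subset by pixel count, with rank 0 the most
abundant.
"""

from __future__ import annotations

import csv
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "CMPTable",
    "encode_cmp",
    "decode_cmp",
    "compile_cmp_table",
    "top_n",
    "marker_specific_table",
    "read_cmp_table",
    "write_cmp_table",
]


def encode_cmp(markers: Iterable[int], n_markers: int) -> str:
    """Encode a set of marker indices as a CMP bitstring.

    The leftmost character is marker 0.  The empty set encodes to the
    all-zero string, which is valid as an encoding but is never tabulated
    (an all-zero pixel is background, not a phenotype).

    >>> encode_cmp({8}, 12)
    '000000001000'
    """
    bits = ["0"] * n_markers
    for m in markers:
        if not 0 <= m < n_markers:
            raise ValueError(f"marker index {m} out of range for panel of {n_markers}")
        bits[m] = "1"
    return "".join(bits)


def decode_cmp(bitstring: str) -> frozenset[int]:
    """Decode a CMP bitstring into the set of marker indices present."""
    if set(bitstring) - {"0", "1"}:
        raise ValueError(f"invalid CMP bitstring {bitstring!r}")
    return frozenset(i for i, c in enumerate(bitstring) if c == "1")


@dataclass(frozen=True)
class CMPTable:
    """Frequency-ranked CMP list for one source (image, cell, or subset).

    ``df`` has columns ``rank`` (0 = most abundant), ``cmp`` (bitstring) and
    ``count`` (pixel count); marker-specific tables carry an extra
    ``original_rank`` column preserving the rank each CMP held in the parent
    table, so marker-restricted rankings are visibly non-consecutive.
    """

    df: pd.DataFrame
    n_markers: int
    source_id: str | None = None

    def __post_init__(self) -> None:
        counts = self.df["count"].to_numpy()
        if len(counts) and (counts <= 0).any():
            raise ValueError("CMP frequencies must be strictly positive")
        if len(counts) > 1 and (counts[:-1] < counts[1:]).any():
            raise ValueError("CMP frequencies must be non-increasing with rank")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cmps(self) -> list[str]:
        return self.df["cmp"].tolist()

    @property
    def cmp_set(self) -> frozenset[str]:
        return frozenset(self.df["cmp"])

    @property
    def total_pixels(self) -> int:
        return int(self.df["count"].sum())


def _as_counter(pixels) -> Counter:
    if isinstance(pixels, Counter):
        return pixels
    if isinstance(pixels, Mapping):
        return Counter(pixels)
    return Counter(pixels)


def compile_cmp_table(
    pixels, n_markers: int | None = None, source_id: str | None = None
) -> CMPTable:
    """Tabulate a multiset of CMP bitstrings into a ranked frequency table.

    ``pixels`` may be an iterable of bitstrings or a mapping
    ``bitstring -> count``.  Rows are sorted by count descending; ties are
    broken by ascending lexicographic bitstring so that top-N cuts are
    reproducible.  All-zero (background) CMPs are rejected: only foreground
    phenotypes are tabulated.
    """
    counts = _as_counter(pixels)
    if counts:
        lengths = {len(c) for c in counts}
        if len(lengths) > 1:
            raise ValueError(f"inconsistent CMP bitstring lengths: {sorted(lengths)}")
        (length,) = lengths
        if n_markers is None:
            n_markers = length
        elif n_markers != length:
            raise ValueError(
                f"bitstring length {length} does not match panel size {n_markers}"
            )
        for c in counts:
            if set(c) - {"0", "1"}:
                raise ValueError(f"invalid CMP bitstring {c!r}")
            if "1" not in c:
                raise ValueError("all-zero CMP is background and cannot be tabulated")
    elif n_markers is None:
        n_markers = 0
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(
        {
            "rank": range(len(rows)),
            "cmp": [c for c, _ in rows],
            "count": [n for _, n in rows],
        }
    )
    return CMPTable(df=df, n_markers=n_markers, source_id=source_id)


def top_n(table: CMPTable, n: int = 54) -> CMPTable:
    """First ``min(n, len)`` rows of the table (the paper-style top-54 cut).

    The cut is deterministic because compile ordering already resolved ties.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return replace(table, df=table.df.head(n).reset_index(drop=True))


def marker_specific_table(table: CMPTable, marker: int, n: int = 54) -> CMPTable:
    """Restrict a table to CMPs containing ``marker`` (the "lead protein").

    The result is the subsequence of the full ranking whose CMPs have the
    marker bit set, re-ranked 0..len-1 but keeping the parent rank in
    ``original_rank``, truncated to ``n`` rows.
    """
    if not 0 <= marker < table.n_markers:
        raise ValueError(f"marker {marker} out of range for panel of {table.n_markers}")
    sel = table.df[table.df["cmp"].str[marker] == "1"].head(n)
    df = pd.DataFrame(
        {
            "rank": range(len(sel)),
            "cmp": sel["cmp"].to_numpy(),
            "count": sel["count"].to_numpy(),
            "original_rank": sel["rank"].to_numpy(),
        }
    )
    return replace(table, df=df)


def write_cmp_table(table: CMPTable, path: str | Path) -> None:
    """Write a CMP table as CSV with the bitstring quoted against mangling."""
    table.df.to_csv(path, index=False, quoting=csv.QUOTE_NONNUMERIC)


def read_cmp_table(path: str | Path, source_id: str | None = None) -> CMPTable:
    df = pd.read_csv(path, dtype={"cmp": str})
    n_markers = len(df["cmp"].iloc[0]) if len(df) else 0
    return CMPTable(df=df, n_markers=n_markers, source_id=source_id)
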