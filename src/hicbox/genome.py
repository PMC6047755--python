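"""Genome model: chromosome tables, genomic loci, and bin arithmetic.

Coordinates are 0-based half-open internally. Text interfaces (contact
lists, ``chr:start-end`` strings) are 1-based inclusive and converted on
parse, matching genome-browser convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

from .errors import InputError


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: display name, length in bp, and 0-based file index."""

    name: str
    length: int
    index: int


class ChromosomeTable:
    """Ordered set of chromosomes; indices are 0..n-1 in file order.

    Names must be unique and lengths positive.
    """

    def __init__(self, entries: Iterable[tuple[str, int]]):
        self._entries: list[Chromosome] = []
        self._by_name: dict[str, Chromosome] = {}
        for i, (name, length) in enumerate(entries):
            length = int(length)
            if length <= 0:
                raise InputError(f"chromosome {name!r} has non-positive length {length}")
            if name in self._by_name:
                raise InputError(f"duplicate chromosome name {name!r}")
            chrom = Chromosome(name, length, i)
            self._entries.append(chrom)
            self._by_name[name] = chrom
        if not self._entries:
            raise InputError("chromosome table is empty")

    @classmethod
    def from_file(cls, path) -> "ChromosomeTable":
        """Read a two-column ``name<TAB>length`` chrom.sizes file."""
        entries = []
        with open(path, "rt", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 2:
                    raise InputError(f"{path}:{lineno}: expected 'name<TAB>length'")
                try:
                    entries.append((parts[0], int(parts[1])))
                except ValueError:
                    raise InputError(f"{path}:{lineno}: bad length {parts[1]!r}") from None
        return cls(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[Chromosome]:
        return iter(self._entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, key) -> Chromosome:
        if isinstance(key, int):
            return self._entries[key]
        try:
            return self._by_name[key]
        except KeyError:
            raise InputError(f"unknown chromosome {key!r}") from None

    def names(self) -> list[str]:
        return [c.name for c in self._entries]

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromosomeTable) and self._entries == other._entries

    def __repr__(self) -> str:
        return f"ChromosomeTable({[(c.name, c.length) for c in self._entries]})"


@dataclass(frozen=True)
class GenomicLocus:
    """Half-open genomic interval: ``chrom``, 0-based ``start``, exclusive ``end``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise InputError(
                f"invalid locus {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def parse(cls, text: str, one_based: bool = True) -> "GenomicLocus":
        """Parse ``chr:start-end`` (1-based inclusive by default, commas allowed)."""
        chrom, _, span = text.rpartition(":")
        if not chrom:
            raise InputError(f"cannot parse locus {text!r}: missing ':'")
        lo, sep, hi = span.rpartition("-")
        if not sep or not lo:
            raise InputError(f"cannot parse locus {text!r}: expected start-end")
        try:
            start = int(lo.replace(",", ""))
            end = int(hi.replace(",", ""))
        except ValueError:
            raise InputError(f"cannot parse locus {text!r}: non-numeric bounds") from None
        if one_based:
            start -= 1
        return cls(chrom, start, end)

    def __str__(self) -> str:
        # 1-based inclusive, the display convention
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def clip(self, length: int) -> "GenomicLocus":
        """Clip to a chromosome of the given length."""
        return GenomicLocus(self.chrom, max(self.start, 0), min(self.end, length))


def bin_range(locus: GenomicLocus, resolution: int) -> tuple[int, int]:
    """Half-open bin span covered by ``locus`` at ``resolution``.

    Bins are 0-based, half-open: bin b covers [b*res, (b+1)*res). Returns
    (floor(start/res), ceil(end/res)).
    """
    if resolution <= 0:
        raise InputError(f"resolution must be positive, got {resolution}")
    return locus.start // resolution, math.ceil(locus.end / resolution)


def n_bins(length: int, resolution: int) -> int:
    """Number of bins covering a chromosome of ``length`` bp."""
    return math.ceil(length / resolution)
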