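"""Block-compressed, indexed, multi-resolution contact-map container.

The on-disk dialect is documented normatively in ``docs/FORMAT.md``. In
brief: a little-endian header (magic ``HICJ``, version 1, chromosome table,
resolution list) at offset 0, a body of independently DEFLATE-compressed
record blocks and normalization vectors, and a master index at the end of
the file whose offset is patched into the header after the body is
written. Intra-chromosomal data is stored as the upper triangle only
(bin_x <= bin_y); inter-chromosomal pairs are keyed with the lower
chromosome index first. The block grid is 256 bins per side, so any
rectangular query touches a predictable set of blocks, each retrievable
with a single ranged read.
"""

from __future__ import annotations

import math
import struct
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import normalization as norm
from .contacts import read_contacts, validate_contacts
from .errors import (
    ConfigError,
    CorruptBlock,
    MalformedContainer,
    NormNotAvailable,
    UnsupportedFormat,
)
from .genome import ChromosomeTable, n_bins
from .normalization import NormVector
from .remote import ByteSource, open_source

MAGIC = b"HICJ"
VERSION = 1
BLOCK_SIDE = 256
COMPRESSION_LEVEL = 6

#: Default bin sizes (bp, descending), truncated to those <= the longest
#: chromosome (the smallest is kept if none qualify).
DEFAULT_RESOLUTIONS = (2_500_000, 1_000_000, 500_000, 100_000, 25_000, 10_000)

_NORM_CODES = {norm.NORM_VC: 1, norm.NORM_VC_SQRT: 2, norm.NORM_BALANCED: 3}
_CODE_NORMS = {v: k for k, v in _NORM_CODES.items()}

_BLOCK_ENTRY = struct.Struct("<IIIIQQ")
_NORM_ENTRY = struct.Struct("<BIIQQ")


@dataclass(frozen=True)
class BlockIndexEntry:
    """Where one compressed block lives: (chr pair, resolution, block number)."""

    chr_pair: tuple[int, int]
    resolution: int
    block_number: int
    offset: int
    size: int


@dataclass
class ContactBlock:
    """Decompressed records of one block, sorted by (bin_x, bin_y)."""

    bin_x: np.ndarray
    bin_y: np.ndarray
    count: np.ndarray

    def __len__(self) -> int:
        return len(self.bin_x)

    @classmethod
    def empty(cls) -> "ContactBlock":
        return cls(
            np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.float64)
        )


@dataclass
class FileHeader:
    magic: bytes
    version: int
    genome_id: str
    master_index_offset: int
    chromosomes: ChromosomeTable
    resolutions: tuple[int, ...]
    header_size: int = 0


def default_resolutions(chrom_sizes: ChromosomeTable) -> tuple[int, ...]:
    longest = max(c.length for c in chrom_sizes)
    keep = tuple(r for r in DEFAULT_RESOLUTIONS if r <= longest)
    return keep if keep else (DEFAULT_RESOLUTIONS[-1],)


def n_block_cols(chrom_length: int, resolution: int) -> int:
    return math.ceil(n_bins(chrom_length, resolution) / BLOCK_SIDE)


# ---------------------------------------------------------------------------
# writing


def _encode_header(genome_id: str, chroms: ChromosomeTable, resolutions, master=0):
    parts = [MAGIC, struct.pack("<IQ", VERSION, master)]
    gid = genome_id.encode("utf-8")
    parts.append(struct.pack("<H", len(gid)))
    parts.append(gid)
    parts.append(struct.pack("<I", len(chroms)))
    for c in chroms:
        name = c.name.encode("utf-8")
        parts.append(struct.pack("<H", len(name)))
        parts.append(name)
        parts.append(struct.pack("<Q", c.length))
    parts.append(struct.pack("<I", len(resolutions)))
    for r in resolutions:
        parts.append(struct.pack("<I", r))
    return b"".join(parts)


def _block_payload(bx: np.ndarray, by: np.ndarray, cnt: np.ndarray) -> bytes:
    n = len(bx)
    return (
        struct.pack("<I", n)
        + bx.astype("<u4").tobytes()
        + by.astype("<u4").tobytes()
        + cnt.astype("<f4").tobytes()
    )


def _norm_payload(values: np.ndarray, converged: bool) -> bytes:
    return (
        struct.pack("<BI", 1 if converged else 0, len(values))
        + np.asarray(values, "<f8").tobytes()
    )


def build_container(
    contacts,
    chrom_sizes: ChromosomeTable,
    out_path: str,
    resolutions=None,
    norms=norm.STORED_NORM_TYPES,
    genome_id: str = "custom",
) -> None:
    """Bin a contact list at every resolution and write an indexed container.

    ``contacts`` is anything :func:`hicbox.contacts.read_contacts` accepts
    (path, stream, DataFrame, or iterable of tuples; 1-based positions,
    count defaults to 1). Normalization vectors for the requested types are
    computed from the full intra-chromosomal matrices and stored alongside.
    """
    if resolutions is None:
        resolutions = default_resolutions(chrom_sizes)
    resolutions = tuple(sorted({int(r) for r in resolutions}, reverse=True))
    if not resolutions:
        raise ConfigError("resolution list is empty")
    if any(r <= 0 for r in resolutions):
        raise ConfigError(f"resolutions must be positive: {resolutions}")
    for t in norms:
        if t not in norm.STORED_NORM_TYPES:
            raise ConfigError(f"unknown normalization type {t!r}")

    df = read_contacts(contacts)
    validate_contacts(df, chrom_sizes)

    # canonical orientation: lower chromosome index first; intra upper triangle
    ci1 = df["chrom1"].map(lambda c: chrom_sizes[c].index).to_numpy(np.int64, copy=True)
    ci2 = df["chrom2"].map(lambda c: chrom_sizes[c].index).to_numpy(np.int64, copy=True)
    p1 = df["pos1"].to_numpy(np.int64, copy=True) - 1  # to 0-based
    p2 = df["pos2"].to_numpy(np.int64, copy=True) - 1
    cnt = df["count"].to_numpy(np.float64, copy=True)
    swap = (ci1 > ci2) | ((ci1 == ci2) & (p1 > p2))
    ci1[swap], ci2[swap] = ci2[swap], ci1[swap].copy()
    p1[swap], p2[swap] = p2[swap], p1[swap].copy()

    order = np.lexsort((p2, p1, ci2, ci1))
    ci1, ci2, p1, p2, cnt = (a[order] for a in (ci1, ci2, p1, p2, cnt))

    block_entries: list[BlockIndexEntry] = []
    norm_entries: list[tuple[int, int, int, int, int]] = []
    # per (chrom, res): aggregated intra bins for norm computation
    intra_bins: dict[tuple[int, int], tuple] = {}

    with open(out_path, "wb") as fh:
        header = _encode_header(genome_id, chrom_sizes, resolutions)
        fh.write(header)

        pair_keys = ci1 * len(chrom_sizes) + ci2
        boundaries = np.flatnonzero(np.diff(pair_keys)) + 1
        starts = np.concatenate([[0], boundaries]) if len(ci1) else np.empty(0, int)
        ends = np.concatenate([boundaries, [len(ci1)]]) if len(ci1) else starts
        for s, e in zip(starts, ends):
            c1, c2 = int(ci1[s]), int(ci2[s])
            len2 = chrom_sizes[c2].length
            for res in resolutions:
                bx = p1[s:e] // res
                by = p2[s:e] // res
                # aggregate duplicate bin pairs
                nby = n_bins(len2, res)
                key = bx * nby + by
                uniq, inv = np.unique(key, return_inverse=True)
                agg = np.bincount(inv, weights=cnt[s:e])
                ubx, uby = uniq // nby, uniq % nby
                if c1 == c2:
                    intra_bins[(c1, res)] = (ubx, uby, agg)
                ncols = n_block_cols(len2, res)
                bnum = (ubx // BLOCK_SIDE) * ncols + (uby // BLOCK_SIDE)
                border = np.lexsort((uby, ubx, bnum))
                bnum, ubx, uby, agg = (a[border] for a in (bnum, ubx, uby, agg))
                cuts = np.flatnonzero(np.diff(bnum)) + 1
                for lo, hi in zip(
                    np.concatenate([[0], cuts]), np.concatenate([cuts, [len(bnum)]])
                ):
                    payload = zlib.compress(
                        _block_payload(ubx[lo:hi], uby[lo:hi], agg[lo:hi]),
                        COMPRESSION_LEVEL,
                    )
                    block_entries.append(
                        BlockIndexEntry(
                            (c1, c2), res, int(bnum[lo]), fh.tell(), len(payload)
                        )
                    )
                    fh.write(payload)

        # normalization vectors: every chromosome x resolution x type
        for chrom in chrom_sizes:
            for res in resolutions:
                nb = n_bins(chrom.length, res)
                binned = intra_bins.get((chrom.index, res))
                if binned is None:
                    bx = by = np.empty(0, np.int64)
                    agg = np.empty(0, np.float64)
                else:
                    bx, by, agg = binned
                row = norm.coverage_row_sums(bx, by, agg, nb)
                for t in norms:
                    if t == norm.NORM_BALANCED:
                        K = norm.sparse_symmetric(bx, by, agg, nb)
                        values, conv = norm.compute_balanced_norm(K)
                    else:
                        values, conv = norm.compute_coverage_norm(row, t), True
                    payload = zlib.compress(_norm_payload(values, conv), COMPRESSION_LEVEL)
                    norm_entries.append(
                        (_NORM_CODES[t], chrom.index, res, fh.tell(), len(payload))
                    )
                    fh.write(payload)

        master_offset = fh.tell()
        fh.write(struct.pack("<I", len(block_entries)))
        for be in block_entries:
            fh.write(
                _BLOCK_ENTRY.pack(
                    be.chr_pair[0],
                    be.chr_pair[1],
                    be.resolution,
                    be.block_number,
                    be.offset,
                    be.size,
                )
            )
        fh.write(struct.pack("<I", len(norm_entries)))
        for ne in norm_entries:
            fh.write(_NORM_ENTRY.pack(*ne))

        fh.seek(len(MAGIC) + 4)  # master_index_offset field
        fh.write(struct.pack("<Q", master_offset))


# ---------------------------------------------------------------------------
# reading


class _Prefix:
    """Incrementally pulled prefix of a byte source, for header parsing."""

    def __init__(self, source: ByteSource, initial: int = 4096):
        self._source = source
        self._buf = source.read(0, min(initial, source.total_size))
        self.pos = 0

    def take(self, n: int) -> bytes:
        end = self.pos + n
        if end > self._source.total_size:
            raise MalformedContainer(
                f"truncated container {self._source.uri}: header needs byte {end}, "
                f"file has {self._source.total_size}"
            )
        while end > len(self._buf):
            grow = min(len(self._buf), self._source.total_size - len(self._buf))
            self._buf += self._source.read(len(self._buf), grow)
        out = self._buf[self.pos : end]
        self.pos = end
        return out


def read_header(source: ByteSource) -> FileHeader:
    """Parse the header; reads a bounded prefix of the file only."""
    if source.total_size < 20:
        raise MalformedContainer(
            f"{source.uri}: {source.total_size} bytes is too small for a container"
        )
    pre = _Prefix(source)
    magic = pre.take(4)
    if magic != MAGIC:
        raise UnsupportedFormat(f"{source.uri}: bad magic {magic!r} (expected {MAGIC!r})")
    version, master = struct.unpack("<IQ", pre.take(12))
    if version != VERSION:
        raise UnsupportedFormat(f"{source.uri}: unsupported version {version}")
    if not (0 < master < source.total_size):
        raise MalformedContainer(f"{source.uri}: master index offset {master} out of file")
    (gid_len,) = struct.unpack("<H", pre.take(2))
    genome_id = pre.take(gid_len).decode("utf-8")
    (n_chrom,) = struct.unpack("<I", pre.take(4))
    entries = []
    for _ in range(n_chrom):
        (name_len,) = struct.unpack("<H", pre.take(2))
        name = pre.take(name_len).decode("utf-8")
        (length,) = struct.unpack("<Q", pre.take(8))
        entries.append((name, length))
    (n_res,) = struct.unpack("<I", pre.take(4))
    res = struct.unpack(f"<{n_res}I", pre.take(4 * n_res))
    if any(a <= b for a, b in zip(res, res[1:])):
        raise MalformedContainer(f"{source.uri}: resolutions not strictly decreasing")
    return FileHeader(
        magic=magic,
        version=version,
        genome_id=genome_id,
        master_index_offset=master,
        chromosomes=ChromosomeTable(entries),
        resolutions=tuple(res),
        header_size=pre.pos,
    )


class ContainerReader:
    """Random-access reader over a container byte source (local or remote).

    The master index is fetched once on first use; every block read is a
    single ranged read of exactly the block's compressed size.
    """

    def __init__(self, source, cache_bytes=None):
        if isinstance(source, ByteSource):
            self.source = source
        elif cache_bytes is None:
            self.source = open_source(source)
        else:
            self.source = open_source(source, cache_bytes)
        self.header = read_header(self.source)
        self._block_index: dict | None = None
        self._norm_index: dict | None = None

    # -- index ------------------------------------------------------------

    def _load_index(self) -> None:
        if self._block_index is not None:
            return
        off = self.header.master_index_offset
        size = self.source.total_size - off
        raw = self.source.read(off, size)
        try:
            (n_blocks,) = struct.unpack_from("<I", raw, 0)
            pos = 4
            blocks: dict = {}
            for _ in range(n_blocks):
                c1, c2, res, bnum, boff, bsize = _BLOCK_ENTRY.unpack_from(raw, pos)
                pos += _BLOCK_ENTRY.size
                blocks.setdefault((c1, c2, res), {})[bnum] = BlockIndexEntry(
                    (c1, c2), res, bnum, boff, bsize
                )
            (n_norms,) = struct.unpack_from("<I", raw, pos)
            pos += 4
            norms: dict = {}
            for _ in range(n_norms):
                code, chrom, res, noff, nsize = _NORM_ENTRY.unpack_from(raw, pos)
                pos += _NORM_ENTRY.size
                norms[(_CODE_NORMS[code], chrom, res)] = (noff, nsize)
        except (struct.error, KeyError) as exc:
            raise MalformedContainer(f"{self.source.uri}: bad master index: {exc}") from None
        self._block_index = blocks
        self._norm_index = norms

    def block_entries(self, c1: int, c2: int, resolution: int) -> dict:
        """Block-number -> entry mapping for one (pair, resolution); may be empty."""
        self._load_index()
        return self._block_index.get((c1, c2, resolution), {})

    def all_block_entries(self) -> list[BlockIndexEntry]:
        self._load_index()
        return [e for d in self._block_index.values() for e in d.values()]

    def stored_norm_types(self) -> tuple[str, ...]:
        self._load_index()
        seen = {k[0] for k in self._norm_index}
        return tuple(t for t in norm.STORED_NORM_TYPES if t in seen)

    # -- payloads ----------------------------------------------------------

    def read_block(self, entry: BlockIndexEntry) -> ContactBlock:
        """Decompress one block; exactly one ranged read of entry.size bytes."""
        raw = self.source.read(entry.offset, entry.size)
        try:
            payload = zlib.decompress(raw)
            (n,) = struct.unpack_from("<I", payload, 0)
            if len(payload) != 4 + 12 * n:
                raise ValueError(f"payload length {len(payload)} != {4 + 12 * n}")
        except (zlib.error, struct.error, ValueError) as exc:
            raise CorruptBlock(
                f"block {entry.block_number} of pair {entry.chr_pair} at "
                f"resolution {entry.resolution} is corrupt: {exc}",
                chr_pair=entry.chr_pair,
                resolution=entry.resolution,
                block_number=entry.block_number,
            ) from None
        bx = np.frombuffer(payload, "<u4", n, 4).astype(np.int64)
        by = np.frombuffer(payload, "<u4", n, 4 + 4 * n).astype(np.int64)
        cnt = np.frombuffer(payload, "<f4", n, 4 + 8 * n).astype(np.float64)
        return ContactBlock(bx, by, cnt)

    def read_norm_vector(
        self, norm_type: str, chrom_index: int, resolution: int
    ) -> NormVector:
        """Stored vector, or synthesized all-ones for NONE."""
        chrom = self.header.chromosomes[chrom_index]
        if norm_type == norm.NORM_NONE:
            return NormVector(
                norm_type,
                chrom_index,
                resolution,
                np.ones(n_bins(chrom.length, resolution)),
            )
        self._load_index()
        entry = self._norm_index.get((norm_type, chrom_index, resolution))
        if entry is None:
            raise NormNotAvailable(
                f"no {norm_type} vector for {chrom.name} at resolution {resolution}"
            )
        off, size = entry
        payload = zlib.decompress(self.source.read(off, size))
        conv, n = struct.unpack_from("<BI", payload, 0)
        values = np.frombuffer(payload, "<f8", n, 5).copy()
        return NormVector(norm_type, chrom_index, resolution, values, bool(conv))

    # -- convenience -------------------------------------------------------

    @property
    def chromosomes(self) -> ChromosomeTable:
        return self.header.chromosomes

    @property
    def resolutions(self) -> tuple[int, ...]:
        return self.header.resolutions

    def close(self) -> None:
        self.source.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
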