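"""Genomic tracks (BED, bedGraph, WIG, optionally BigWig) and BEDPE 2D
annotations, plus resampling onto a view's bin grid.

Coordinate conventions: BED/bedGraph/BEDPE are 0-based half-open; WIG is
1-based and converted on parse. Gzip-compressed files are auto-detected by
magic bytes. Strand is ignored — there is no strand semantics in a
contact-map overlay.
"""

from __future__ import annotations

import gzip
import io
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .errors import FormatError, RecordError
from .genome import GenomicLocus
from .remote import open_source

logger = logging.getLogger(__name__)

TRACK_KIND_INTERVAL = "interval"  # BED: features with an optional score
TRACK_KIND_SIGNAL = "signal"  # bedGraph / WIG / BigWig: non-overlapping values


@dataclass(frozen=True)
class Annotation2D:
    """A pair of anchors (e.g. one loop call), optionally colored/labelled."""

    anchor1: GenomicLocus
    anchor2: GenomicLocus
    color: tuple[int, int, int] | None = None
    label: str | None = None


class Track:
    """Named set of valued intervals, grouped by chromosome and sorted.

    Signal tracks must be non-overlapping; interval (BED) tracks may
    overlap, in which case resampled values average over the overlap.
    """

    def __init__(self, name: str, kind: str, intervals: Iterable[tuple[str, int, int, float]]):
        self.name = name
        self.kind = kind
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        buckets: dict[str, list] = {}
        for chrom, start, end, value in intervals:
            buckets.setdefault(chrom, []).append((start, end, value))
        for chrom, rows in buckets.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=np.float64)
            if kind == TRACK_KIND_SIGNAL and np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise RecordError(
                    f"track {name!r}: overlapping intervals on {chrom} near "
                    f"{chrom}:{starts[i + 1]}-{ends[i]}"
                )
            self._by_chrom[chrom] = (starts, ends, values)

    def __len__(self) -> int:
        return sum(len(s) for s, _, _ in self._by_chrom.values())

    def intervals(self) -> Iterator[tuple[GenomicLocus, float]]:
        for chrom in self._by_chrom:
            starts, ends, values = self._by_chrom[chrom]
            for s, e, v in zip(starts, ends, values):
                yield GenomicLocus(chrom, int(s), int(e)), float(v)

    def chrom_arrays(self, chrom: str):
        return self._by_chrom.get(chrom)


# ---------------------------------------------------------------------------
# parsing


def _as_lines(source) -> Iterator[str]:
    if isinstance(source, str):
        return iter(io.StringIO(source))
    return iter(source)


def _parse_color(field: str) -> tuple[int, int, int] | None:
    field = field.strip()
    if field.startswith("#") and len(field) == 7:
        return tuple(int(field[i : i + 2], 16) for i in (1, 3, 5))
    parts = field.split(",")
    if len(parts) == 3:
        try:
            r, g, b = (int(p) for p in parts)
            return (r, g, b)
        except ValueError:
            return None
    return None


def parse_bedpe(source, lenient: bool = False) -> list[Annotation2D]:
    """Parse BEDPE text into annotations.

    Needs >= 6 columns (chr1 start1 end1 chr2 start2 end2 [name score
    strand1 strand2 [color]]); comment/track/header rows are skipped.
    Invalid rows raise :class:`RecordError` with the line number, or are
    skipped with a warning under ``lenient``.
    """
    out: list[Annotation2D] = []
    for lineno, line in enumerate(_as_lines(source), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#") or line.startswith("track"):
            continue
        fields = line.split("\t")
        try:
            if len(fields) < 6:
                raise RecordError(
                    f"line {lineno}: BEDPE needs >= 6 columns, got {len(fields)}",
                    line_number=lineno,
                )
            try:
                s1, e1 = int(fields[1]), int(fields[2])
                s2, e2 = int(fields[4]), int(fields[5])
            except ValueError:
                # column-header row (e.g. "chr1  x1  x2 ...")
                logger.debug("skipping non-numeric BEDPE row %d: %r", lineno, line)
                continue
            if e1 < s1 or e2 < s2:
                raise RecordError(
                    f"line {lineno}: interval end before start", line_number=lineno
                )
            label = fields[6] if len(fields) > 6 and fields[6] not in (".", "") else None
            color = _parse_color(fields[10]) if len(fields) > 10 else None
            out.append(
                Annotation2D(
                    GenomicLocus(fields[0], s1, max(e1, s1 + 1)),
                    GenomicLocus(fields[3], s2, max(e2, s2 + 1)),
                    color=color,
                    label=label,
                )
            )
        except RecordError:
            if lenient:
                warnings.warn(f"skipping bad BEDPE line {lineno}", stacklevel=2)
                continue
            raise
    return out


def parse_bed(source, name: str = "bed") -> Track:
    """Parse BED (>= 3 columns); value is the score column when present, else 1."""
    rows = []
    for lineno, line in enumerate(_as_lines(source), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise RecordError(
                f"line {lineno}: BED needs >= 3 columns", line_number=lineno
            )
        try:
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 1.0
        except ValueError:
            raise RecordError(f"line {lineno}: bad BED row", line_number=lineno) from None
        if end < start:
            raise RecordError(f"line {lineno}: end before start", line_number=lineno)
        rows.append((fields[0], start, max(end, start + 1), value))
    return Track(name, TRACK_KIND_INTERVAL, rows)


def parse_signal(source, dialect: str, name: str | None = None) -> Track:
    """Parse a signal track: ``dialect`` is "bedGraph" or "wig"."""
    if dialect == "bedGraph":
        return _parse_bedgraph(source, name or "bedGraph")
    if dialect == "wig":
        return _parse_wig(source, name or "wig")
    raise FormatError(f"unknown signal dialect {dialect!r}")


def _parse_bedgraph(source, name: str) -> Track:
    rows = []
    for lineno, line in enumerate(_as_lines(source), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise RecordError(
                f"line {lineno}: bedGraph needs 4 columns", line_number=lineno
            )
        try:
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError:
            raise RecordError(f"line {lineno}: bad bedGraph row", line_number=lineno) from None
    return Track(name, TRACK_KIND_SIGNAL, rows)


def _parse_wig(source, name: str) -> Track:
    rows = []
    mode = None  # ("fixed", chrom, next_start0, step, span) | ("variable", chrom, span)
    for lineno, line in enumerate(_as_lines(source), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if line[0].isalpha() and not line.split()[0].replace(".", "").isdigit():
            word = line.split()[0]
            kv = dict(
                part.split("=", 1) for part in line.split()[1:] if "=" in part
            )
            if word == "fixedStep":
                try:
                    chrom = kv["chrom"]
                    start0 = int(kv["start"]) - 1  # WIG is 1-based
                    step = int(kv["step"])
                except KeyError as exc:
                    raise FormatError(f"line {lineno}: fixedStep missing {exc}") from None
                span = int(kv.get("span", 1))
                mode = ["fixed", chrom, start0, step, span]
            elif word == "variableStep":
                if "chrom" not in kv:
                    raise FormatError(f"line {lineno}: variableStep missing chrom")
                mode = ["variable", kv["chrom"], int(kv.get("span", 1))]
            else:
                raise FormatError(f"line {lineno}: unknown WIG declaration {word!r}")
            continue
        if mode is None:
            raise FormatError(f"line {lineno}: WIG data before any step declaration")
        if mode[0] == "fixed":
            _, chrom, start0, step, span = mode
            rows.append((chrom, start0, start0 + span, float(line.split()[0])))
            mode[2] = start0 + step
        else:
            _, chrom, span = mode
            parts = line.split()
            if len(parts) < 2:
                raise RecordError(
                    f"line {lineno}: variableStep rows need 'pos value'",
                    line_number=lineno,
                )
            pos0 = int(parts[0]) - 1
            rows.append((chrom, pos0, pos0 + span, float(parts[1])))
    return Track(name, TRACK_KIND_SIGNAL, rows)


# ---------------------------------------------------------------------------
# resampling


def track_values(track: Track, locus: GenomicLocus, nbins: int) -> np.ndarray:
    """Coverage-weighted mean of interval values per bin; NaN where uncovered.

    Bin b covers [start + b*w, start + (b+1)*w) with w = locus.length /
    nbins (fractional widths allowed so any locus maps onto any grid).
    """
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    out = np.full(nbins, np.nan)
    arrays = track.chrom_arrays(locus.chrom)
    if arrays is None:
        return out
    starts, ends, values = arrays
    w = locus.length / nbins
    weight = np.zeros(nbins)
    wsum = np.zeros(nbins)
    # ends are sorted only for non-overlapping (signal) tracks
    lo = (
        int(np.searchsorted(ends, locus.start, side="right"))
        if track.kind == TRACK_KIND_SIGNAL
        else 0
    )
    for s0, e0, v in zip(starts[lo:], ends[lo:], values[lo:]):
        if s0 >= locus.end:
            if track.kind == TRACK_KIND_SIGNAL:
                break
            continue
        s = max(int(s0), locus.start)
        e = min(int(e0), locus.end)
        if e <= s:
            continue
        b_lo = int((s - locus.start) / w)
        b_hi = min(int(np.ceil((e - locus.start) / w)), nbins)
        bins = np.arange(b_lo, b_hi)
        left = locus.start + bins * w
        right = left + w
        overlap = np.minimum(right, e) - np.maximum(left, s)
        overlap = np.clip(overlap, 0.0, None)
        weight[bins] += overlap
        wsum[bins] += overlap * v
    covered = weight > 0
    out[covered] = wsum[covered] / weight[covered]
    return out


# ---------------------------------------------------------------------------
# loading by URI


def _fetch_bytes(uri: str) -> bytes:
    src = open_source(uri)
    try:
        return src.read(0, src.total_size) if src.total_size else b""
    finally:
        src.close()


def _decode_text(blob: bytes) -> str:
    if blob[:2] == b"\x1f\x8b":
        blob = gzip.decompress(blob)
    return blob.decode("utf-8")


def _strip_gz(uri: str) -> str:
    return uri[:-3] if uri.endswith(".gz") else uri


def load_track(uri: str, name: str | None = None) -> Track:
    """Load a track from a local path or URL, dispatching on extension."""
    base = _strip_gz(uri.split("?")[0]).lower()
    if base.endswith((".bw", ".bigwig")):
        return read_bigwig(uri, name=name)
    if base.endswith(".bed"):
        dialect = "bed"
    elif base.endswith((".bedgraph", ".bdg")):
        dialect = "bedGraph"
    elif base.endswith(".wig"):
        dialect = "wig"
    else:
        raise FormatError(f"cannot infer track format from {uri!r}")
    text = _decode_text(_fetch_bytes(uri))
    track_name = name or uri.rsplit("/", 1)[-1]
    if dialect == "bed":
        return parse_bed(text, name=track_name)
    return parse_signal(text, dialect, name=track_name)


def load_annotations(uri: str, lenient: bool = False) -> list[Annotation2D]:
    """Load BEDPE 2D annotations from a local path or URL."""
    return parse_bedpe(_decode_text(_fetch_bytes(uri)), lenient=lenient)


def read_bigwig(uri: str, name: str | None = None) -> Track:
    """Read a BigWig file into a signal Track (requires pyBigWig)."""
    try:
        import pyBigWig
    except ImportError:
        raise FormatError(
            "BigWig support requires the optional pyBigWig dependency "
            "(pip install hicbox[bigwig])"
        ) from None
    bw = pyBigWig.open(uri)  # pyBigWig handles both paths and URLs
    try:
        rows = []
        for chrom in bw.chroms():
            for s, e, v in bw.intervals(chrom) or []:
                rows.append((chrom, s, e, float(v)))
    finally:
        bw.close()
    return Track(name or uri.rsplit("/", 1)[-1], TRACK_KIND_SIGNAL, rows)
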