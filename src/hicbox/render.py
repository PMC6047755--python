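"""Deterministic rasterization of contact matrices.

The heatmap maps value v to a color by linear interpolation between
``low_color`` (at 0) and ``high_color`` (at and beyond ``v_max``), with
round-half-up on each channel so renders are bit-reproducible across
platforms. Masked bins get ``mask_color``. Orientation: locus_x runs
left-to-right, locus_y top-to-bottom, so the diagonal of a square intra
view runs from the top-left corner.

``export_figure`` writes a PNG plus a sidecar text file holding the
session's shareable URL; decoding that URL re-renders the identical PNG.
Sessions referencing local files cannot be shared and get a ``local=true``
sidecar with the JSON session document instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .genome import GenomicLocus, bin_range
from .matrix import ContactMatrix
from .tracks import Annotation2D, Track, track_values

logger = logging.getLogger(__name__)

DEFAULT_LOW = (255, 255, 255)
DEFAULT_HIGH = (255, 0, 0)
DEFAULT_MASK = (220, 220, 220)
DEFAULT_ANNOTATION_COLOR = (0, 200, 200)

#: When no explicit saturation point is set, v_max = this multiple of the
#: mean nonzero unmasked value in the current view (deterministic, avoids
#: percentile sorting).
AUTO_VMAX_FACTOR = 5.0


@dataclass(frozen=True)
class ColorScale:
    """Linear white-to-red (by default) ramp saturating at ``v_max``.

    ``v_max=None`` means auto: resolved per view as 5x the mean nonzero
    unmasked value.
    """

    v_max: float | None = None
    low_color: tuple[int, int, int] = DEFAULT_LOW
    high_color: tuple[int, int, int] = DEFAULT_HIGH
    mask_color: tuple[int, int, int] = DEFAULT_MASK

    def __post_init__(self):
        if self.v_max is not None and not self.v_max > 0:
            raise ValueError(f"v_max must be positive, got {self.v_max}")


def resolve_vmax(scale: ColorScale, matrix: ContactMatrix) -> float:
    """The effective saturation point for one view."""
    if scale.v_max is not None:
        return scale.v_max
    vals = matrix.values[~matrix.mask & np.isfinite(matrix.values)]
    vals = vals[vals > 0]
    return AUTO_VMAX_FACTOR * float(vals.mean()) if len(vals) else 1.0


def map_color(value: float, scale: ColorScale, v_max: float | None = None):
    """Color of one value: t = min(v / v_max, 1), channels interpolated
    low->high with round-half-up; NaN maps to the mask color."""
    if v_max is None:
        v_max = scale.v_max
        if v_max is None:
            raise ValueError("scale has auto v_max; pass the resolved v_max")
    if value is None or not np.isfinite(value):
        return scale.mask_color
    t = min(float(value) / v_max, 1.0)
    return tuple(
        int(np.floor(lo + t * (hi - lo) + 0.5))
        for lo, hi in zip(scale.low_color, scale.high_color)
    )


def _colorize(matrix: ContactMatrix, scale: ColorScale, v_max: float) -> np.ndarray:
    """(n_y, n_x, 3) uint8 image of the matrix (rows = locus_y bins)."""
    vals = matrix.values.T  # rows = y, cols = x
    bad = ~np.isfinite(vals) | matrix.mask.T
    t = np.clip(np.where(bad, 0.0, vals) / v_max, 0.0, 1.0)
    img = np.empty(t.shape + (3,), dtype=np.uint8)
    for c in range(3):
        lo, hi = scale.low_color[c], scale.high_color[c]
        img[..., c] = np.floor(lo + t * (hi - lo) + 0.5).astype(np.uint8)
        img[..., c][bad] = scale.mask_color[c]
    return img


def _annotation_rects(
    ann: Annotation2D, matrix: ContactMatrix
) -> list[tuple[int, int, int, int]]:
    """Bin rectangles (x_lo, x_hi, y_lo, y_hi) for one annotation, clipped
    to the view; intra-chromosomal annotations appear at both mirror
    positions."""
    res = matrix.resolution
    x0, x1 = bin_range(matrix.locus_x, res)
    y0, y1 = bin_range(matrix.locus_y, res)
    rects = []
    placements = [(ann.anchor1, ann.anchor2)]
    if ann.anchor1.chrom == ann.anchor2.chrom:
        placements.append((ann.anchor2, ann.anchor1))
    for ax, ay in placements:
        if ax.chrom != matrix.locus_x.chrom or ay.chrom != matrix.locus_y.chrom:
            continue
        bx0, bx1 = bin_range(ax, res)
        by0, by1 = bin_range(ay, res)
        cx0, cx1 = max(bx0 - x0, 0), min(bx1 - x0, x1 - x0)
        cy0, cy1 = max(by0 - y0, 0), min(by1 - y0, y1 - y0)
        if cx0 < cx1 and cy0 < cy1:
            rects.append((cx0, cx1, cy0, cy1))
    return rects


def _draw_outline(img: np.ndarray, rect, pixels_per_bin: int, color) -> None:
    x_lo, x_hi, y_lo, y_hi = rect
    px0, px1 = x_lo * pixels_per_bin, x_hi * pixels_per_bin
    py0, py1 = y_lo * pixels_per_bin, y_hi * pixels_per_bin
    img[py0:py1, px0] = color
    img[py0:py1, px1 - 1] = color
    img[py0, px0:px1] = color
    img[py1 - 1, px0:px1] = color


def _track_strip(
    track: Track, locus: GenomicLocus, nbins: int, strip_px: int, pixels_per_bin: int
) -> np.ndarray:
    """Horizontal strip (strip_px, nbins*pixels_per_bin, 3): per-bin signal
    shaded white->blue by value / max |value|; NaN bins light gray."""
    vals = track_values(track, locus, nbins)
    finite = np.isfinite(vals)
    peak = np.max(np.abs(vals[finite])) if finite.any() else 0.0
    t = np.zeros(nbins) if peak == 0 else np.clip(np.abs(vals) / peak, 0, 1)
    strip = np.empty((strip_px, nbins, 3), dtype=np.uint8)
    color = np.array((30, 80, 200), dtype=np.float64)
    white = np.array((255, 255, 255), dtype=np.float64)
    row = np.floor(white + t[:, None] * (color - white) + 0.5).astype(np.uint8)
    row[~finite] = (235, 235, 235)
    strip[:] = row[None, :, :]
    return np.repeat(strip, pixels_per_bin, axis=1)


def render_heatmap(
    matrix: ContactMatrix,
    scale: ColorScale,
    annotations: list[Annotation2D] = (),
    tracks: list[Track] = (),
    pixels_per_bin: int = 2,
    track_px: int = 12,
) -> np.ndarray:
    """Rasterize one view to an (H, W, 3) uint8 array.

    Annotation rectangles become 1-px outlines at their bin rectangles
    (both mirror positions for intra-chromosomal views); tracks are
    resampled onto each axis' bin grid and drawn as flanking strips (x-axis
    above, y-axis left). The output is a pure function of its inputs.
    """
    if matrix.values.size == 0:
        raise ValueError("cannot render an empty matrix")
    v_max = resolve_vmax(scale, matrix)
    nx, ny = matrix.shape
    img = np.repeat(
        np.repeat(_colorize(matrix, scale, v_max), pixels_per_bin, axis=0),
        pixels_per_bin,
        axis=1,
    )
    for ann in annotations:
        rects = _annotation_rects(ann, matrix)
        if not rects:
            logger.debug("annotation %s out of view, omitted", ann)
        for rect in rects:
            _draw_outline(img, rect, pixels_per_bin, ann.color or DEFAULT_ANNOTATION_COLOR)

    if tracks:
        top = [
            _track_strip(t, matrix.locus_x, nx, track_px, pixels_per_bin)
            for t in tracks
        ]
        left = [
            np.transpose(
                _track_strip(t, matrix.locus_y, ny, track_px, pixels_per_bin),
                (1, 0, 2),
            )
            for t in tracks
        ]
        top_block = np.concatenate(top, axis=0)
        left_block = np.concatenate(left, axis=1)
        corner = np.full(
            (top_block.shape[0], left_block.shape[1], 3), 255, dtype=np.uint8
        )
        img = np.concatenate(
            [
                np.concatenate([corner, top_block], axis=1),
                np.concatenate([left_block, img], axis=1),
            ],
            axis=0,
        )
    return img


@dataclass
class FigureSpec:
    """A session plus raster parameters; fully determines the exported PNG."""

    session: object  # SessionState
    pixels_per_bin: int = 2
    track_px: int = 12


def render_session(spec: FigureSpec, container=None) -> np.ndarray:
    """Render the first map of a session to a pixel array.

    ``container`` may be passed to reuse an open reader; otherwise the
    map's URI is opened (local path or URL).
    """
    from .container import ContainerReader
    from .matrix import query_region
    from .tracks import load_annotations, load_track

    sess = spec.session
    m = sess.maps[0]
    reader = container if container is not None else ContainerReader(m.uri)
    try:
        matrix = query_region(
            reader, sess.locus_x, sess.locus_y, sess.resolution, m.norm
        )
        anns = []
        for a in sess.annotations:
            for item in load_annotations(a.uri):
                if item.color is None and a.color is not None:
                    item = Annotation2D(item.anchor1, item.anchor2, a.color, item.label)
                anns.append(item)
        trks = [load_track(t.uri, name=t.name or None) for t in sess.tracks]
        return render_heatmap(
            matrix,
            m.scale,
            annotations=anns,
            tracks=trks,
            pixels_per_bin=spec.pixels_per_bin,
            track_px=spec.track_px,
        )
    finally:
        if container is None:
            reader.close()


def export_figure(spec: FigureSpec, out_path: str, container=None):
    """Write a PNG and a sidecar session file; returns (png_path, sidecar).

    The sidecar holds the shareable URL when every source is remote.
    Sessions with local sources cannot be shared (a browser cannot hand its
    local files to another machine), so the sidecar then carries a
    ``local=true`` marker plus the JSON session document, with a warning.
    """
    from .session import LocalSourceError, encode_url, to_json

    img = render_session(spec, container=container)
    Image.fromarray(img).save(out_path, format="PNG")
    sidecar = str(out_path) + ".session.txt"
    try:
        content = encode_url(spec.session) + "\n"
    except LocalSourceError:
        warnings.warn(
            "session references local files; sidecar is not shareable",
            stacklevel=2,
        )
        content = "local=true\n" + to_json(spec.session) + "\n"
    with open(sidecar, "wt", encoding="utf-8") as fh:
        fh.write(content)
    return out_path, sidecar
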