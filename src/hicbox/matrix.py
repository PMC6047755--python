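"""Rectangular contact-map queries.

``query_region`` answers any (locus_x, locus_y) rectangle at a stored
resolution with a stored normalization, touching only the blocks that
intersect the rectangle (plus, for intra-chromosomal views straddling the
diagonal, the mirrored rectangle — each block is still read once).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .container import BLOCK_SIDE, ContainerReader, n_block_cols
from .errors import InternalError, ResolutionNotAvailable
from .genome import GenomicLocus, bin_range
from .normalization import NORM_NONE, NORM_TYPES, NormVector


@dataclass
class ContactMatrix:
    """Dense counts for one queried rectangle.

    ``values`` has shape (n_bins_x, n_bins_y); axis 0 follows ``locus_x``.
    Masked (filtered/unmappable) cells are NaN in ``values`` and True in
    ``mask``.
    """

    values: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    locus_x: GenomicLocus
    locus_y: GenomicLocus
    resolution: int
    norm_type: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def query_region(
    container: ContainerReader,
    locus_x: GenomicLocus,
    locus_y: GenomicLocus,
    resolution: int,
    norm_type: str = NORM_NONE,
) -> ContactMatrix:
    """Binned (and optionally normalized) counts for a rectangular view.

    Loci extending past their chromosome are clipped to its bounds.
    Intra-chromosomal rectangles are mirrored across the diagonal at
    assembly, so a full-square query is exactly symmetric.
    """
    if norm_type not in NORM_TYPES:
        raise InternalError(f"unknown norm type {norm_type!r}")
    table = container.chromosomes
    if resolution not in container.resolutions:
        raise ResolutionNotAvailable(resolution, container.resolutions)
    chrom_x = table[locus_x.chrom]  # raises InputError for unknown chromosomes
    chrom_y = table[locus_y.chrom]
    locus_x = locus_x.clip(chrom_x.length)
    locus_y = locus_y.clip(chrom_y.length)

    x0, x1 = bin_range(locus_x, resolution)
    y0, y1 = bin_range(locus_y, resolution)

    transposed = chrom_x.index > chrom_y.index
    if transposed:
        c1, c2 = chrom_y, chrom_x
        (r0, r1), (s0, s1) = (y0, y1), (x0, x1)
    else:
        c1, c2 = chrom_x, chrom_y
        (r0, r1), (s0, s1) = (x0, x1), (y0, y1)

    values = _assemble(
        container, c1.index, c2.index, c2.length, resolution, r0, r1, s0, s1
    )
    if transposed:
        values = values.T.copy()

    raw = ContactMatrix(
        values=values,
        mask=np.zeros(values.shape, dtype=bool),
        locus_x=locus_x,
        locus_y=locus_y,
        resolution=resolution,
        norm_type=NORM_NONE,
    )
    if norm_type == NORM_NONE:
        return raw
    nx = container.read_norm_vector(norm_type, chrom_x.index, resolution)
    ny = container.read_norm_vector(norm_type, chrom_y.index, resolution)
    return apply_normalization(raw, nx, ny)


def _assemble(container, c1, c2, len2, resolution, r0, r1, s0, s1) -> np.ndarray:
    """Dense rectangle [r0,r1) x [s0,s1) in stored orientation (c1 <= c2)."""
    entries = container.block_entries(c1, c2, resolution)
    out = np.zeros((r1 - r0, s1 - s0))
    if not entries:
        return out
    intra = c1 == c2
    ncols = n_block_cols(len2, resolution)

    needed: dict[int, object] = {}

    def collect(a0, a1, b0, b1):
        for br, bc in itertools.product(
            range(a0 // BLOCK_SIDE, (a1 - 1) // BLOCK_SIDE + 1),
            range(b0 // BLOCK_SIDE, (b1 - 1) // BLOCK_SIDE + 1),
        ):
            entry = entries.get(br * ncols + bc)
            if entry is not None:
                needed[entry.block_number] = entry

    collect(r0, r1, s0, s1)
    if intra:
        collect(s0, s1, r0, r1)  # mirror rectangle, upper-triangle storage

    for entry in needed.values():
        block = container.read_block(entry)
        sel = (block.bin_x >= r0) & (block.bin_x < r1) & (block.bin_y >= s0) & (
            block.bin_y < s1
        )
        np.add.at(out, (block.bin_x[sel] - r0, block.bin_y[sel] - s0), block.count[sel])
        if intra:
            mir = (
                (block.bin_y >= r0)
                & (block.bin_y < r1)
                & (block.bin_x >= s0)
                & (block.bin_x < s1)
                & (block.bin_x != block.bin_y)
            )
            np.add.at(
                out, (block.bin_y[mir] - r0, block.bin_x[mir] - s0), block.count[mir]
            )
    return out


def apply_normalization(
    raw: ContactMatrix, norm_x: NormVector, norm_y: NormVector
) -> ContactMatrix:
    """Divide by the outer product of per-bin factors; NaN factors mask cells."""
    x0, x1 = bin_range(raw.locus_x, raw.resolution)
    y0, y1 = bin_range(raw.locus_y, raw.resolution)
    vx = np.asarray(norm_x.values, dtype=np.float64)
    vy = np.asarray(norm_y.values, dtype=np.float64)
    if x1 > len(vx) or y1 > len(vy):
        raise InternalError(
            f"norm vector too short for view: need bins {x1}/{y1}, "
            f"have {len(vx)}/{len(vy)}"
        )
    vx = vx[x0:x1]
    vy = vy[y0:y1]
    if vx.shape[0] != raw.values.shape[0] or vy.shape[0] != raw.values.shape[1]:
        raise InternalError("norm vector slice does not match matrix shape")
    denom = np.outer(vx, vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = raw.values / denom
    mask = ~np.isfinite(denom) | raw.mask
    values[mask] = np.nan
    return ContactMatrix(
        values=values,
        mask=mask,
        locus_x=raw.locus_x,
        locus_y=raw.locus_y,
        resolution=raw.resolution,
        norm_type=norm_x.norm_type,
    )
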