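# The `.hicj` container dialect (normative)

Version 1. All integers are **little-endian**. All floats are IEEE 754.
Byte offsets are absolute file offsets. This dialect is this package's
own documented format; it is *not* byte-compatible with the canonical
`hic` layout, only analogous in capability (block-compressed, indexed,
multi-resolution, single-ranged-read per block).

## Layout overview

```
offset 0        HEADER            (written first, one field patched last)
...             BODY              (compressed blocks, then norm vectors)
master_offset   MASTER INDEX      (block index + norm-vector index)
EOF
```

A reader needs exactly two bounded reads to begin answering queries: the
header prefix at offset 0, and the span `[master_index_offset, EOF)`.

## Header

| field                 | type            | notes                                  |
|-----------------------|-----------------|----------------------------------------|
| magic                 | 4 bytes         | ASCII `HICJ`                           |
| version               | uint32          | `1`                                    |
| master_index_offset   | uint64          | placeholder `0` at first write, patched after the body |
| genome_id length      | uint16          |                                        |
| genome_id             | UTF-8 bytes     |                                        |
| n_chromosomes         | uint32          |                                        |
| per chromosome        |                 | name length (uint16), name (UTF-8), length (uint64) |
| n_resolutions         | uint32          |                                        |
| resolutions           | uint32 each     | bin sizes in bp, **strictly decreasing** |

Chromosome indices are implicit: 0..n−1 in header order. A file whose
magic differs is rejected as unsupported; a file whose structure cannot
be parsed (truncation, offsets beyond EOF, non-decreasing resolutions)
is rejected as malformed.

## Binning and storage conventions

* Bins are 0-based, half-open: bin `b` covers `[b*res, (b+1)*res)`.
  Positions in contact-list text are 1-based and converted on read
  (`bin = (pos - 1) // res`). The last bin of a chromosome may cover
  fewer than `res` bp.
* Intra-chromosomal matrices store the **upper triangle only**
  (`bin_x <= bin_y`); readers mirror at query time.
* Inter-chromosomal pairs are keyed with the **lower chromosome index
  first**; a query in the opposite orientation is served by transposing.
* Counts are 32-bit floats (accommodates pre-weighted input); a missing
  count column in input text means 1.

## Blocks

The bin grid of each (pair, resolution) is tiled into blocks of
**256 × 256 bins**. With `ncols = ceil(n_bins_chr2 / 256)`:

```
block_number = (bin_x // 256) * ncols + (bin_y // 256)
```

Only non-empty blocks are written. Each block is an independent
zlib/DEFLATE stream (level 6) of this payload:

| field    | type          | notes                           |
|----------|---------------|---------------------------------|
| n_records| uint32        |                                 |
| bin_x    | n × uint32    | sorted by (bin_x, bin_y)        |
| bin_y    | n × uint32    | columnar, after all bin_x       |
| count    | n × float32   |                                 |

A decompression failure or a payload whose length disagrees with
`4 + 12 * n_records` raises a corrupt-block error carrying the block's
identity.

## Normalization vectors

One vector per (norm type, chromosome, resolution), length
`ceil(chrom_length / res)`, for the stored types `VC`, `VC_SQRT`,
`BALANCED`. `NONE` is never stored; readers synthesize all-ones.
Filtered (zero-coverage) bins are NaN. Payload, zlib-compressed:

| field     | type         | notes                       |
|-----------|--------------|-----------------------------|
| converged | uint8        | 1 unless balancing hit max_iter |
| n_values  | uint32       |                             |
| values    | n × float64  | bit-exact round trip        |

## Master index

Written at the end of the file; `master_index_offset` in the header is
patched to point here after the body is complete, so a crashed write
never yields a file that parses.

```
uint32  n_block_entries
repeat: uint32 chr1_index, uint32 chr2_index, uint32 resolution,
        uint32 block_number, uint64 offset, uint64 compressed_size
uint32  n_norm_entries
repeat: uint8 norm_code (1=VC, 2=VC_SQRT, 3=BALANCED),
        uint32 chrom_index, uint32 resolution,
        uint64 offset, uint64 compressed_size
```

Blocks never overlap, every offset/size lies inside the file, and every
nonzero bin of every stored matrix is reachable through exactly one
block entry.

## Default resolutions

When the builder is not given an explicit list:
2,500,000; 1,000,000; 500,000; 100,000; 25,000; 10,000 bp — truncated to
those ≤ the longest chromosome (the smallest is kept if none qualify).
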