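# hicbox

**Indexed multi-resolution Hi-C contact-map container with partial remote
access, normalization, rendering, and shareable session URLs.**

Contact-mapping experiments such as Hi-C measure how often pairs of genomic
loci physically touch. The result is a *contact map*: a symmetric matrix
whose entry (i, j) counts contacts between genomic bins i and j, usually
drawn as a heatmap where loops appear as bright peaks off the diagonal and
contact domains as bright squares along it. Real maps are far too large to
load whole, so practical viewers keep them in a compressed, indexed,
multi-resolution container and fetch only the byte ranges each view needs —
directly from a plain file server, with no application code on the server
side.

hicbox is a library + CLI implementing that stack for people who build or
test contact-map tooling:

* a documented block-compressed container dialect (`.hicj`, see
  [docs/FORMAT.md](docs/FORMAT.md)) with a master index, written once and
  queryable at any stored resolution;
* uniform byte-range access over local files and HTTP (64 KiB chunk cache,
  transfer accounting, graceful fallback for servers without `Range`
  support), so a view query costs header + index + touched blocks, not the
  file;
* normalization vectors computed at build time — vanilla coverage (VC),
  VC_SQRT, and matrix balancing (iterative proportional scaling), applied
  as c′ᵢⱼ = cᵢⱼ/(vᵢvⱼ);
* parsers for BED / bedGraph / WIG / BEDPE (BigWig optional) and
  resampling onto a view's bin grid;
* deterministic heatmap rendering with annotation outlines and track
  strips, exporting a PNG plus a sidecar *shareable URL* that encodes the
  complete viewer state — decoding it reproduces the identical figure;
* a synthetic Hi-C generator (power-law distance decay, loops, domains)
  with ground truth, so the whole stack is testable without downloading
  anything.

## Worked example

Simulate a 5 Mb chromosome with one loop (8× enrichment between anchors at
1.0 and 2.0 Mb) and one domain, build a container, inspect and query it:

```bash
$ cat demo.json
{
 "chrom": "chrS", "chrom_length": 5000000, "n_contacts": 500000,
 "resolution": 10000,
 "loops":   [{"anchor1": 1000000, "anchor2": 2000000, "enrichment": 8.0, "radius": 20000}],
 "domains": [{"start": 3000000, "end": 3500000, "enrichment": 3.0}]
}

$ hicbox simulate --config demo.json --seed 7 -o demo
emitted 500787 contacts -> demo.contacts.tsv (+ demo.chrom.sizes, demo.truth.json)

$ hicbox build demo.contacts.tsv demo.chrom.sizes -o demo.hicj --res 100000,10000
wrote demo.hicj

$ hicbox info demo.hicj
genome: custom
chromosomes:
  chrS	5000000
resolutions: 100000, 10000
norms: NONE, VC, VC_SQRT, BALANCED
```

The emitted total (500,787) is a Poisson realization of the requested
500,000 expected contacts; `demo.truth.json` records the generator's
ground truth, including each loop's expected center/donut enrichment.

Dump the balanced counts around the loop anchor pair (global bin indices
at 10 kb; the loop anchors sit in bins 100 and 200, and the 2×2
neighbourhood is strongly enriched over the ~1.0 expected at matched
distance):

```bash
$ hicbox dump demo.hicj chrS:990001-1010000 chrS:1990001-2010000 --res 10000 --norm BALANCED
99	199	14.23611299
99	200	9.823446708
100	199	8.429402095
100	200	6.107430549
```

Render a figure with a deterministic color scale saturating at 3.0:

```bash
$ hicbox render demo.hicj chrS:500001-2500000 --res 10000 --cmax 3 -o demo.png
wrote demo.png (+ demo.png.session.txt)
```

`demo.png.session.txt` holds the session for this exact view. For remote
maps it is a shareable URL — anyone decoding it re-renders the identical
PNG; for local files like this one it carries a `local=true` marker plus
the JSON session document (local files cannot travel inside a link). The
same state converts between URL and JSON with `hicbox url --to-json` /
`--from-json`.

The library mirrors everything the CLI does:

```python
from hicbox import ContainerReader, GenomicLocus, query_region

with ContainerReader("https://example.org/maps/demo.hicj") as reader:
    m = query_region(
        reader,
        GenomicLocus("chrS", 500_000, 2_500_000),
        GenomicLocus("chrS", 500_000, 2_500_000),
        resolution=10_000,
        norm_type="BALANCED",
    )
    print(m.values.shape, reader.source.stats.as_dict())
```

Only the bytes for the touched blocks (plus header and index) cross the
wire; `stats` shows the accounting.

## Documentation

* [docs/FORMAT.md](docs/FORMAT.md) — the normative `.hicj` container
  dialect.
* [docs/methods.md](docs/methods.md) — models, algorithms, parameter
  defaults, design decisions and known limitations.
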