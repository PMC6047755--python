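# Methods

## What this package models

Contact-mapping assays (Hi-C and relatives) measure how often pairs of
genomic loci touch in 3D. The data product is a *contact map*: a symmetric
matrix whose entry (i, j) counts contacts between genomic bins i and j at
some bin size ("resolution"). Maps are huge (up to trillions of pixels at
kb resolution), so practical viewers never load a whole file: they keep the
map in an indexed, block-compressed container and fetch only the byte
ranges needed for the current view, whether the file is local or behind a
plain HTTP server. hicbox implements that container and access model as a
library and CLI, plus the surrounding display semantics: per-bin
normalization, deterministic heatmap rendering with 1D-track and 2D-
annotation overlays, and a complete, canonical serialization of viewer
state into a shareable URL.

## Container and query model

The `.hicj` dialect is specified normatively in `FORMAT.md`. Design
choices worth explaining:

* **Block grid of 256×256 bins, upper triangle only.** Any rectangular
  view intersects a predictable set of blocks; each block is one ranged
  read of exactly its compressed size. Intra-chromosomal rectangles that
  straddle the diagonal also collect the blocks of the mirrored rectangle;
  each block is still read once, and mirroring happens at assembly
  (off-diagonal records are added at both (i, j) and (j, i)).
* **Header first, master index last.** The header is written with a
  placeholder index offset that is patched after the body, so readers can
  bootstrap from a bounded prefix plus one indexed span, and an
  interrupted write never produces a file that parses.
* **Counts as float32.** Inputs may carry fractional, pre-weighted counts.
  Integer-count fixtures below 2^24 round-trip exactly, which is why the
  binning tests can assert exact equality.

Aggregation consistency across resolutions holds exactly on the
upper-triangle representation: a coarse diagonal cell contains each
off-diagonal fine pair once, while the mirrored square view contains it
twice. The tests assert the identity in that form.

## Remote access and the transfer bound

Reads go through a cache of 64 KiB-aligned chunks (LRU, 32 MiB default).
Each missing chunk is fetched with its own `Range` request, so the
overhead of any single request over the span it serves is strictly less
than one chunk; the transfer cost of a view is therefore bounded by
(header span) + (master index span) + (touched compressed block sizes) +
one chunk per request, which the test suite asserts against transfer
counters on a ≥100-block fixture. Repeating a view costs zero bytes.
Servers that ignore `Range` (a 200 with the full body) are handled by
buffering the body once and flagging `range_unsupported`: correctness is
preserved, efficiency degraded. Redirects are followed (up to 5 hops);
there is no authentication support. Caching policy is an engineering
default — nothing in the display contract constrains it.

## Normalization

Normalized counts are c'ᵢⱼ = cᵢⱼ / (vᵢ·vⱼ). Three stored families:

* **VC** — vᵢ = rowᵢ / mean(nonzero rows); **VC_SQRT** — its square root.
* **BALANCED** — symmetric iterative proportional scaling: repeat
  vᵢ ← vᵢ·√(sᵢ / mean(s)), where sᵢ is the current normalized row sum,
  until the max relative deviation of unmasked row sums is < 1e-5 or 200
  iterations. A uniform matrix is a fixed point (vector of ones). The
  update depends only on ratios, so the vector is exactly invariant under
  global count scaling. On non-convergence the best iterate is returned
  flagged `converged=false`.

Only zero-coverage bins are masked (NaN factors; masked cells are NaN in
normalized views). There is no percentile filter: the mask rule stays
transparent and testable. This matters for interpretation: on matrices
whose support is *disconnected*, per-component row sums equalize
internally but not to the global mean, so balancing honestly reports
non-convergence — and two independent implementations of the iteration
can diverge on such inputs. The oracle tests therefore check the
*applied* vector on arbitrary fixtures, and the vector *derivation*
against an independent dense implementation on connected matrices, where
the iteration is well-behaved. A Knight–Ruiz solver would converge faster
on hard cases but is not required for the display contract.

Vectors are computed at build time from the full intra-chromosomal matrix
at each resolution and stored; queries only read them. Chromosomes with
no intra-chromosomal data get all-NaN vectors, so normalized
inter-chromosomal views involving them are fully masked.

## Tracks and 2D annotations

BED/bedGraph/BEDPE are 0-based half-open; WIG is 1-based and converted on
parse; gzip is auto-detected by magic bytes; BigWig is available behind
the same `Track` contract when pyBigWig is installed. Resampling onto a
view's bin grid uses the coverage-weighted mean of interval values per
bin, NaN where nothing overlaps; this makes nested grids consistent
(a coarse bin is the coverage-weighted mean of its children). Strand is
ignored — a contact-map overlay has no strand semantics.

## Rendering

`map_color` interpolates linearly from `low_color` (value 0) to
`high_color` (saturating at `v_max`), with **round-half-up** per channel
so renders are bit-reproducible across platforms; NaN/masked cells get
`mask_color`. The default ramp is white→red, the conventional contact-map
palette. When `v_max` is unset it resolves to 5× the mean nonzero
unmasked value of the current view — deterministic and data-driven,
avoiding a percentile sort. Orientation: locus_x left→right, locus_y
top→bottom (the diagonal of a square view runs from the top-left).
Annotations are drawn as 1-px outlines at their bin rectangles, at both
mirror positions for intra-chromosomal views; annotations outside the
view are silently omitted (logged at debug). Track strips are resampled
to the axis grids and attached above (x) and left (y) of the heatmap.
Figures render the first map of a session. `export_figure` writes the PNG
plus a sidecar containing the session URL; decoding the sidecar re-renders
the identical PNG. Sessions referencing local paths cannot be shared, so
their sidecar carries a `local=true` marker and the JSON session document
instead, with a warning.

## Session URLs

The `v=1` query-string schema is documented in `hicbox/session.py`. Keys
are emitted in a fixed canonical order and every free-text field is
percent-encoded individually (list items joined with `,`, fields within
an item with `|`), so encoding is deterministic — equal states produce
byte-identical URLs, and URL equality is state equality. Decoding is
lossless, rejects missing required keys by name, and ignores unknown keys
with a warning (forward compatibility). Loci are written 1-based
inclusive (`chr:start-end`) for human readability and converted to the
internal 0-based half-open convention on decode. Floats use the shortest
round-trip decimal (`repr`). The string carries no timestamps or session
tokens, so links never expire. The same state is also readable/writable
as a JSON document (where local paths are allowed, since JSON documents
are a local workflow).

## Synthetic maps and what they do (not) show

The generator works on one synthetic chromosome (`chrS`, 5 Mb) at a
working resolution of 10 kb by default, keeping every fixture in-memory
and fast. Expected intensity for a bin pair at separation d bins is

λᵢⱼ = C · (d·r + d₀)^(−α) · Π domain factors · Π loop factors,

with loop factors 1 + (f_loop − 1)·exp(−dist²/(2σ²)), σ = radius/r bins,
and a constant domain factor f_dom when both bins lie inside the domain.
The additive-peak form makes the far field exactly the decay law, so loop
enrichment is measurable against a matched-distance donut. C is set so
Σλ = n_contacts; realized counts are independent Poisson draws per pixel
(simpler variance accounting than a multinomial), emitted upper-triangle
only as individual records. Defaults: α = 1 (the conventional
contact-probability scaling regime), d₀ = one bin (keeps the diagonal
finite), loop radius 20 kb (σ = 2 bins, a focal peak that is visible at
10 kb resolution without bleeding into the donut), n_contacts = 5×10⁵
(enough for a stable decay fit over 10–100-bin separations at this grid).
With α = 1 and d₀ = r the fitted log–log slope over 10–100 bins is ≈
−0.96, not exactly −1, because the offset flattens small separations;
the ±0.1 acceptance window accounts for this.

Ground truth (config plus each loop's expected center/donut enrichment on
the λ grid) is serialized next to the contact list, and loop anchors can
be exported as BEDPE bin rectangles, which is how the renderer tests know
exactly which pixels an outline must land on.

What the generator does *not* emulate: inter-chromosomal contacts, A/B
compartment plaids, polymer-physics realism, mappability artifacts, or
replicate noise. Passing tests show the machinery is correct on maps with
known decay/loop/domain structure — not that any biological claim holds.
A config with f_loop = 1 stands in qualitatively for a cohesin-degraded
condition (loops erased, decay intact); no biological fidelity is
claimed. The f_loop = 1 check uses the same ≥2 center/donut detection
threshold as the f_loop = 8 check: "erased" means the peak is no longer
detectable, not that the noisy ratio is exactly 1.

## Problem sizes used in tests and the acceptance script

Fixtures are sized for a single CPU: toy genomes of 1 kb/800 bp for
oracle equivalence (25–100 random fixtures), a 5 Mb / 1 kb-resolution map
(~1.6 MB file, 210 blocks) for transfer-bound and local/remote
equivalence checks, 200×200 matrices for balancing, 500 randomized
sessions for URL round-trips, and 5×10⁵-contact simulations for
generator fidelity. These sizes make the whole suite run in well under a
minute while every check still exercises the full pipeline.

## Known limitations

* Queries never span chromosomes; views larger than a chromosome are
  clipped to its bounds.
* No observed/expected views, map superposition, or differencing.
* Genome-wide (inter-chromosomal-aware) balancing is out of scope; vectors
  come from intra-chromosomal matrices only.
* The URL schema is this package's own dialect; no attempt is made to be
  wire-compatible with any deployed viewer's links.
* Track support covers BED, bedGraph, WIG, BEDPE and (optionally) BigWig;
  tabix-indexed remote slicing of tracks is not implemented — track files
  are fetched whole, which is fine at track sizes typical for overlays.
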