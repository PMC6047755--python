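"""Complete viewer state as a shareable, versioned URL query string.

The schema (``v=1``) is this package's own documented dialect. Encoding is
canonical — keys in fixed order, every free-text field percent-encoded —
so equal states produce byte-identical URLs and URL equality doubles as
state equality. Decoding is lossless and forward-compatible: unknown keys
produce a warning, not an error. The string carries no timestamps or
tokens, so links do not expire.

Keys (canonical order):

=============  ==============================================================
``v``          schema version (required, ``1``)
``hicUrl``     comma-separated maps; each ``uri|name`` (fields %-encoded)
``locusX``     ``chr:start-end``, 1-based inclusive (%-encoded)
``locusY``     same for the second axis
``res``        bin size in bp
``norm``       per-map normalization, comma-separated (NONE/VC/VC_SQRT/BALANCED)
``cmax``       per-map color-scale saturation; a float or ``auto``
``colors``     per-map ``LOW-HIGH-MASK`` RRGGBB triples (optional)
``tracks``     comma-separated ``uri|name|RRGGBB`` items (optional)
``annotations`` comma-separated ``uri|RRGGBB`` items (optional)
=============  ==============================================================

Local file paths are rejected at encode time: a link to a file on one
machine's disk cannot recreate the view on another.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from urllib.parse import quote, unquote

from .errors import LocalSourceError, SchemaError
from .genome import GenomicLocus
from .normalization import NORM_TYPES
from .remote import is_remote
from .render import ColorScale

SCHEMA_VERSION = 1

_KEY_ORDER = (
    "v",
    "hicUrl",
    "locusX",
    "locusY",
    "res",
    "norm",
    "cmax",
    "colors",
    "tracks",
    "annotations",
)
_REQUIRED = ("v", "hicUrl", "locusX", "locusY", "res", "norm", "cmax")

DEFAULT_TRACK_COLOR = (30, 80, 200)
DEFAULT_ANNOTATION_COLOR = (0, 200, 200)


@dataclass(frozen=True)
class MapSource:
    uri: str
    name: str = ""
    norm: str = "NONE"
    scale: ColorScale = field(default_factory=ColorScale)


@dataclass(frozen=True)
class TrackSource:
    uri: str
    name: str = ""
    color: tuple[int, int, int] = DEFAULT_TRACK_COLOR


@dataclass(frozen=True)
class AnnotationSource:
    uri: str
    color: tuple[int, int, int] = DEFAULT_ANNOTATION_COLOR


@dataclass(frozen=True)
class SessionState:
    """Everything needed to reproduce a view: sources, loci, resolution,
    normalization, color scales, overlays."""

    maps: tuple[MapSource, ...]
    locus_x: GenomicLocus
    locus_y: GenomicLocus
    resolution: int
    tracks: tuple[TrackSource, ...] = ()
    annotations: tuple[AnnotationSource, ...] = ()
    schema_version: int = SCHEMA_VERSION

    def validate(self) -> None:
        if not self.maps:
            raise SchemaError("a session needs at least one map")
        for m in self.maps:
            if m.norm not in NORM_TYPES:
                raise SchemaError(f"unknown normalization {m.norm!r}")
        if self.resolution <= 0:
            raise SchemaError(f"resolution must be positive, got {self.resolution}")


def _hex(color: tuple[int, int, int]) -> str:
    return "%02X%02X%02X" % tuple(color)


def _unhex(text: str, key: str) -> tuple[int, int, int]:
    if len(text) != 6:
        raise SchemaError(f"key {key!r}: bad color {text!r}")
    try:
        return tuple(int(text[i : i + 2], 16) for i in (0, 2, 4))
    except ValueError:
        raise SchemaError(f"key {key!r}: bad color {text!r}") from None


def _fmt_float(x: float) -> str:
    return repr(float(x))


def _locus_str(locus: GenomicLocus) -> str:
    return f"{locus.chrom}:{locus.start + 1}-{locus.end}"


def encode_url(state: SessionState, base: str | None = None) -> str:
    """Serialize a session as a canonical query string (optionally appended
    to ``base``). Local file paths raise :class:`LocalSourceError`."""
    state.validate()
    for uri in (
        [m.uri for m in state.maps]
        + [t.uri for t in state.tracks]
        + [a.uri for a in state.annotations]
    ):
        if not is_remote(uri):
            raise LocalSourceError(
                f"{uri!r} is a local path; local files cannot be shared by URL"
            )
    q = lambda s: quote(s, safe="")
    pairs: list[tuple[str, str]] = [
        ("v", str(state.schema_version)),
        ("hicUrl", ",".join(f"{q(m.uri)}|{q(m.name)}" for m in state.maps)),
        ("locusX", q(_locus_str(state.locus_x))),
        ("locusY", q(_locus_str(state.locus_y))),
        ("res", str(state.resolution)),
        ("norm", ",".join(m.norm for m in state.maps)),
        (
            "cmax",
            ",".join(
                "auto" if m.scale.v_max is None else _fmt_float(m.scale.v_max)
                for m in state.maps
            ),
        ),
        (
            "colors",
            ",".join(
                f"{_hex(m.scale.low_color)}-{_hex(m.scale.high_color)}-{_hex(m.scale.mask_color)}"
                for m in state.maps
            ),
        ),
    ]
    if state.tracks:
        pairs.append(
            (
                "tracks",
                ",".join(
                    f"{q(t.uri)}|{q(t.name)}|{_hex(t.color)}" for t in state.tracks
                ),
            )
        )
    if state.annotations:
        pairs.append(
            ("annotations", ",".join(f"{q(a.uri)}|{_hex(a.color)}" for a in state.annotations))
        )
    query = "&".join(f"{k}={v}" for k, v in pairs)
    if base:
        sep = "&" if "?" in base else "?"
        return f"{base}{sep}{query}"
    return query


def decode_url(url: str) -> SessionState:
    """Reconstruct a session from a URL or bare query string.

    Missing required keys raise :class:`SchemaError` naming the key;
    unknown keys are ignored with a warning (forward compatibility).
    """
    query = url.split("?", 1)[1] if "?" in url else url
    query = query.split("#", 1)[0]
    fields: dict[str, str] = {}
    for part in query.split("&"):
        if not part:
            continue
        if "=" not in part:
            raise SchemaError(f"malformed query fragment {part!r}")
        k, v = part.split("=", 1)
        fields[k] = v
    for key in _REQUIRED:
        if key not in fields:
            raise SchemaError(f"missing required key {key!r}")
    for key in fields:
        if key not in _KEY_ORDER:
            warnings.warn(f"ignoring unknown session key {key!r}", stacklevel=2)
    try:
        version = int(fields["v"])
    except ValueError:
        raise SchemaError(f"key 'v': bad version {fields['v']!r}") from None
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {version}")

    map_items = fields["hicUrl"].split(",")
    norms = fields["norm"].split(",")
    cmaxes = fields["cmax"].split(",")
    color_items = (
        fields["colors"].split(",")
        if "colors" in fields
        else ["-".join([_hex(ColorScale().low_color), _hex(ColorScale().high_color), _hex(ColorScale().mask_color)])]
        * len(map_items)
    )
    if not (len(map_items) == len(norms) == len(cmaxes) == len(color_items)):
        raise SchemaError(
            "per-map keys disagree in length: "
            f"hicUrl={len(map_items)} norm={len(norms)} cmax={len(cmaxes)} "
            f"colors={len(color_items)}"
        )
    maps = []
    for item, norm, cmax, colors in zip(map_items, norms, cmaxes, color_items):
        parts = item.split("|")
        uri = unquote(parts[0])
        name = unquote(parts[1]) if len(parts) > 1 else ""
        if norm not in NORM_TYPES:
            raise SchemaError(f"key 'norm': unknown normalization {norm!r}")
        if cmax == "auto":
            v_max = None
        else:
            try:
                v_max = float(cmax)
            except ValueError:
                raise SchemaError(f"key 'cmax': bad value {cmax!r}") from None
        triple = colors.split("-")
        if len(triple) != 3:
            raise SchemaError(f"key 'colors': bad item {colors!r}")
        scale = ColorScale(
            v_max,
            _unhex(triple[0], "colors"),
            _unhex(triple[1], "colors"),
            _unhex(triple[2], "colors"),
        )
        maps.append(MapSource(uri, name, norm, scale))

    def parse_locus(key: str) -> GenomicLocus:
        try:
            return GenomicLocus.parse(unquote(fields[key]), one_based=True)
        except Exception:
            raise SchemaError(f"key {key!r}: unparseable locus {fields[key]!r}") from None

    try:
        resolution = int(fields["res"])
    except ValueError:
        raise SchemaError(f"key 'res': bad resolution {fields['res']!r}") from None

    tracks = []
    if fields.get("tracks"):
        for item in fields["tracks"].split(","):
            parts = item.split("|")
            if len(parts) != 3:
                raise SchemaError(f"key 'tracks': bad item {item!r}")
            tracks.append(
                TrackSource(unquote(parts[0]), unquote(parts[1]), _unhex(parts[2], "tracks"))
            )
    annotations = []
    if fields.get("annotations"):
        for item in fields["annotations"].split(","):
            parts = item.split("|")
            if len(parts) != 2:
                raise SchemaError(f"key 'annotations': bad item {item!r}")
            annotations.append(
                AnnotationSource(unquote(parts[0]), _unhex(parts[1], "annotations"))
            )

    state = SessionState(
        maps=tuple(maps),
        locus_x=parse_locus("locusX"),
        locus_y=parse_locus("locusY"),
        resolution=resolution,
        tracks=tuple(tracks),
        annotations=tuple(annotations),
        schema_version=version,
    )
    state.validate()
    return state


# ---------------------------------------------------------------------------
# JSON session documents (same field semantics; local paths allowed)


def to_json(state: SessionState, indent: int | None = 2) -> str:
    state.validate()
    doc = {
        "version": state.schema_version,
        "maps": [
            {
                "uri": m.uri,
                "name": m.name,
                "norm": m.norm,
                "cmax": m.scale.v_max,
                "colors": {
                    "low": _hex(m.scale.low_color),
                    "high": _hex(m.scale.high_color),
                    "mask": _hex(m.scale.mask_color),
                },
            }
            for m in state.maps
        ],
        "locusX": _locus_str(state.locus_x),
        "locusY": _locus_str(state.locus_y),
        "res": state.resolution,
        "tracks": [
            {"uri": t.uri, "name": t.name, "color": _hex(t.color)} for t in state.tracks
        ],
        "annotations": [
            {"uri": a.uri, "color": _hex(a.color)} for a in state.annotations
        ],
    }
    return json.dumps(doc, indent=indent, ensure_ascii=False)


def from_json(text: str) -> SessionState:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"bad session JSON: {exc}") from None
    for key in ("version", "maps", "locusX", "locusY", "res"):
        if key not in doc:
            raise SchemaError(f"missing required key {key!r}")
    maps = tuple(
        MapSource(
            m["uri"],
            m.get("name", ""),
            m.get("norm", "NONE"),
            ColorScale(
                m.get("cmax"),
                _unhex(m.get("colors", {}).get("low", "FFFFFF"), "colors"),
                _unhex(m.get("colors", {}).get("high", "FF0000"), "colors"),
                _unhex(m.get("colors", {}).get("mask", "DCDCDC"), "colors"),
            ),
        )
        for m in doc["maps"]
    )
    state = SessionState(
        maps=maps,
        locus_x=GenomicLocus.parse(doc["locusX"], one_based=True),
        locus_y=GenomicLocus.parse(doc["locusY"], one_based=True),
        resolution=int(doc["res"]),
        tracks=tuple(
            TrackSource(t["uri"], t.get("name", ""), _unhex(t.get("color", "1E50C8"), "tracks"))
            for t in doc.get("tracks", [])
        ),
        annotations=tuple(
            AnnotationSource(a["uri"], _unhex(a.get("color", "00C8C8"), "annotations"))
            for a in doc.get("annotations", [])
        ),
        schema_version=int(doc["version"]),
    )
    state.validate()
    return state
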