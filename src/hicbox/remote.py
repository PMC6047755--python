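"""Uniform byte-range access over local files and HTTP.

Every view query is answered by fetching only the bytes it needs: reads go
through a chunk cache (64 KiB-aligned chunks, LRU eviction, 32 MiB default
capacity). Each missing chunk is fetched with its own request, so the
overhead of any request over the span it serves is strictly less than one
chunk. :class:`TransferStats` exposes the accounting.

HTTP uses stdlib ``urllib`` with ``Range`` headers. Servers that ignore
Range (respond 200 with the full body) still work: the body is buffered
once and the ``range_unsupported`` flag is set.
"""

from __future__ import annotations

import os
import urllib.error
import urllib.request
from collections import OrderedDict
from dataclasses import dataclass, field

from .errors import NotFound, RangeError, RemoteError

CHUNK_SIZE = 64 * 1024
DEFAULT_CACHE_BYTES = 32 * 1024 * 1024
MAX_REDIRECTS = 5


@dataclass
class TransferStats:
    """Counters for one byte source; reset only explicitly."""

    requests: int = 0
    bytes_fetched: int = 0
    cache_hits: int = 0
    range_unsupported: bool = False

    def reset(self) -> None:
        self.requests = 0
        self.bytes_fetched = 0
        self.cache_hits = 0

    def as_dict(self) -> dict:
        return {
            "requests": self.requests,
            "bytes_fetched": self.bytes_fetched,
            "cache_hits": self.cache_hits,
            "range_unsupported": self.range_unsupported,
        }


class _ChunkCache:
    """LRU cache of fixed-size aligned chunks, bounded in bytes."""

    def __init__(self, capacity_bytes: int):
        self.capacity = capacity_bytes
        self._chunks: OrderedDict[int, bytes] = OrderedDict()
        self._size = 0

    def get(self, index: int) -> bytes | None:
        chunk = self._chunks.get(index)
        if chunk is not None:
            self._chunks.move_to_end(index)
        return chunk

    def put(self, index: int, data: bytes) -> None:
        if index in self._chunks:
            return
        self._chunks[index] = data
        self._size += len(data)
        while self._size > self.capacity and len(self._chunks) > 1:
            _, evicted = self._chunks.popitem(last=False)
            self._size -= len(evicted)


class ByteSource:
    """Random-access byte reader with caching and transfer accounting.

    Subclasses implement :meth:`_fetch` (raw span fetch) and report
    ``total_size`` at construction.
    """

    kind = "abstract"

    def __init__(self, uri: str, total_size: int, cache_bytes: int = DEFAULT_CACHE_BYTES):
        self.uri = uri
        self.total_size = total_size
        self.stats = TransferStats()
        self._cache = _ChunkCache(cache_bytes)

    def read(self, offset: int, length: int) -> bytes:
        """Return exactly ``length`` bytes starting at ``offset``."""
        if offset < 0 or length < 1:
            raise ValueError(f"bad span offset={offset} length={length}")
        if offset + length > self.total_size:
            raise RangeError(
                f"span [{offset}, {offset + length}) beyond end of "
                f"{self.uri} (size {self.total_size})"
            )
        first = offset // CHUNK_SIZE
        last = (offset + length - 1) // CHUNK_SIZE
        parts = []
        for idx in range(first, last + 1):
            chunk = self._cache.get(idx)
            if chunk is None:
                start = idx * CHUNK_SIZE
                want = min(CHUNK_SIZE, self.total_size - start)
                chunk = self._fetch(start, want)
                self.stats.requests += 1
                self.stats.bytes_fetched += len(chunk)
                self._cache.put(idx, chunk)
            else:
                self.stats.cache_hits += 1
            parts.append(chunk)
        blob = b"".join(parts)
        skip = offset - first * CHUNK_SIZE
        return blob[skip : skip + length]

    def _fetch(self, offset: int, length: int) -> bytes:
        raise NotImplementedError

    def close(self) -> None:
        pass

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class LocalByteSource(ByteSource):
    """POSIX file source."""

    kind = "local"

    def __init__(self, path: str, cache_bytes: int = DEFAULT_CACHE_BYTES):
        if not os.path.isfile(path):
            raise NotFound(f"no such file: {path}")
        super().__init__(path, os.path.getsize(path), cache_bytes)
        self._fh = open(path, "rb")

    def _fetch(self, offset: int, length: int) -> bytes:
        self._fh.seek(offset)
        data = self._fh.read(length)
        if len(data) != length:
            raise RangeError(f"short read from {self.uri} at {offset}")
        return data

    def close(self) -> None:
        self._fh.close()


class _LimitedRedirectHandler(urllib.request.HTTPRedirectHandler):
    max_redirections = MAX_REDIRECTS


_OPENER = urllib.request.build_opener(_LimitedRedirectHandler)


class HTTPByteSource(ByteSource):
    """HTTP(S) source using Range requests.

    Size discovery tries HEAD, then a 1-byte ranged GET. If the server
    answers a ranged GET with 200 (full body), the body is buffered once,
    ``stats.range_unsupported`` is set, and later reads are served from the
    buffer.
    """

    kind = "http"

    def __init__(self, url: str, cache_bytes: int = DEFAULT_CACHE_BYTES):
        self._full_body: bytes | None = None
        total = self._discover_size(url)
        super().__init__(url, total, cache_bytes)

    def _discover_size(self, url: str) -> int:
        req = urllib.request.Request(url, method="HEAD")
        try:
            with _OPENER.open(req) as resp:
                size = resp.headers.get("Content-Length")
                if size is not None:
                    return int(size)
        except urllib.error.HTTPError as exc:
            if exc.code >= 400 and exc.code not in (405, 501):
                raise RemoteError(f"HTTP {exc.code} for {url}", status=exc.code) from None
        except urllib.error.URLError as exc:
            raise RemoteError(f"cannot reach {url}: {exc.reason}") from None
        # HEAD refused or gave no length: ask for the first byte
        req = urllib.request.Request(url, headers={"Range": "bytes=0-0"})
        try:
            with _OPENER.open(req) as resp:
                if resp.status == 206:
                    content_range = resp.headers.get("Content-Range", "")
                    if "/" in content_range:
                        return int(content_range.rsplit("/", 1)[1])
                body = resp.read()
                self._full_body = body
                return len(body)
        except urllib.error.HTTPError as exc:
            raise RemoteError(f"HTTP {exc.code} for {url}", status=exc.code) from None
        except urllib.error.URLError as exc:
            raise RemoteError(f"cannot reach {url}: {exc.reason}") from None

    def _fetch(self, offset: int, length: int) -> bytes:
        if self._full_body is not None:
            return self._full_body[offset : offset + length]
        end = offset + length - 1
        req = urllib.request.Request(self.uri, headers={"Range": f"bytes={offset}-{end}"})
        try:
            with _OPENER.open(req) as resp:
                body = resp.read()
                if resp.status == 200 and len(body) != length:
                    # server ignored Range: keep the full body, degrade gracefully
                    self._full_body = body
                    self.stats.range_unsupported = True
                    self.stats.bytes_fetched += len(body) - length  # account the buffer
                    return body[offset : offset + length]
                if len(body) != length:
                    raise RemoteError(
                        f"{self.uri}: expected {length} bytes at {offset}, got {len(body)}"
                    )
                return body
        except urllib.error.HTTPError as exc:
            raise RemoteError(f"HTTP {exc.code} for {self.uri}", status=exc.code) from None
        except urllib.error.URLError as exc:
            raise RemoteError(f"cannot reach {self.uri}: {exc.reason}") from None


def open_source(uri: str, cache_bytes: int = DEFAULT_CACHE_BYTES) -> ByteSource:
    """Open a local path or http(s) URL as a :class:`ByteSource`."""
    if uri.startswith("http://") or uri.startswith("https://"):
        return HTTPByteSource(uri, cache_bytes)
    return LocalByteSource(uri, cache_bytes)


def is_remote(uri: str) -> bool:
    return uri.startswith("http://") or uri.startswith("https://")
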