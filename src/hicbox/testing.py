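"""Loopback HTTP fixtures for exercising ranged remote access.

:func:`serve` starts a throwaway HTTP server on 127.0.0.1 serving an
in-memory mapping of paths to byte payloads, with optional Range support
(disable it to exercise the full-body fallback) and redirect aliases.
"""

from __future__ import annotations

import re
import threading
from contextlib import contextmanager
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

_RANGE_RE = re.compile(r"bytes=(\d+)-(\d*)$")


def _make_handler(files: dict, support_range: bool, redirects: dict):
    class Handler(BaseHTTPRequestHandler):
        protocol_version = "HTTP/1.1"

        def log_message(self, *args):  # keep test output quiet
            pass

        def _lookup(self):
            path = self.path
            if path in redirects:
                self.send_response(302)
                self.send_header("Location", redirects[path])
                self.send_header("Content-Length", "0")
                self.end_headers()
                return None
            body = files.get(path)
            if body is None:
                self.send_response(404)
                self.send_header("Content-Length", "0")
                self.end_headers()
                return None
            return body

        def do_HEAD(self):
            body = self._lookup()
            if body is None:
                return
            self.send_response(200)
            self.send_header("Content-Length", str(len(body)))
            self.send_header("Accept-Ranges", "bytes" if support_range else "none")
            self.end_headers()

        def do_GET(self):
            body = self._lookup()
            if body is None:
                return
            range_header = self.headers.get("Range")
            if support_range and range_header:
                m = _RANGE_RE.match(range_header.strip())
                if not m:
                    self.send_response(416)
                    self.send_header("Content-Length", "0")
                    self.end_headers()
                    return
                start = int(m.group(1))
                end = int(m.group(2)) if m.group(2) else len(body) - 1
                end = min(end, len(body) - 1)
                if start >= len(body):
                    self.send_response(416)
                    self.send_header("Content-Length", "0")
                    self.end_headers()
                    return
                chunk = body[start : end + 1]
                self.send_response(206)
                self.send_header("Content-Range", f"bytes {start}-{end}/{len(body)}")
                self.send_header("Content-Length", str(len(chunk)))
                self.end_headers()
                self.wfile.write(chunk)
            else:
                self.send_response(200)
                self.send_header("Content-Length", str(len(body)))
                self.end_headers()
                self.wfile.write(body)

    return Handler


@contextmanager
def serve(files: dict, support_range: bool = True, redirects: dict | None = None):
    """Serve ``{url_path: bytes}`` on a loopback port; yields the base URL.

    Paths must start with "/". ``redirects`` maps paths to Location values
    (302). The server shuts down on context exit.
    """
    handler = _make_handler(dict(files), support_range, dict(redirects or {}))
    server = ThreadingHTTPServer(("127.0.0.1", 0), handler)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    try:
        yield f"http://127.0.0.1:{server.server_address[1]}"
    finally:
        server.shutdown()
        server.server_close()
        thread.join(timeout=5)
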