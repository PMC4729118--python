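"""RESTful region-query service (the *bedserver*) and its client source.

The server holds a directory of per-sample, start-sorted BED files with
sidecar linear indexes and answers region queries over HTTP, returning
only the records the chart needs:

* ``GET /v1/samples`` — JSON list of sample identifiers.
* ``GET /v1/data/{sample}?chrom=C&start=S&end=E`` — JSON array of
  ``[chrom, start, end, value]`` rows overlapping the half-open region,
  served through the sidecar index (seek + bounded scan, never a full
  file read).

Errors: unknown sample -> 404; malformed or empty (start >= end)
coordinates -> 400.  The client :class:`HttpSource` satisfies the same
query contract as the in-memory sources, so the chart layer cannot tell
the backends apart.
"""

from __future__ import annotations

import json
import threading
import urllib.parse
import urllib.request
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from os import PathLike
from pathlib import Path
from typing import Optional, Union

from .bed_io import BedRecord
from .genomic_model import GenomicRegion
from .sources import (
    IndexedFileSource,
    SourceQuery,
    _sample_name,
)

PathArg = Union[str, PathLike]


class BedServerApp:
    """Request-independent state: sample -> indexed file source."""

    def __init__(self, data_dir: PathArg):
        self.data_dir = Path(data_dir)
        paths = sorted(
            p
            for p in self.data_dir.iterdir()
            if p.is_file()
            and (p.suffix in (".bed", ".bedgraph", ".bedGraph"))
        )
        if not paths:
            raise FileNotFoundError(f"no BED files found in {self.data_dir}")
        self.sources = {
            _sample_name(p): IndexedFileSource(p) for p in paths
        }

    def samples(self) -> list[str]:
        return sorted(self.sources)

    def query(self, sample: str, region: GenomicRegion) -> list[BedRecord]:
        return self.sources[sample].query(SourceQuery(sample, region))


class _Handler(BaseHTTPRequestHandler):
    app: BedServerApp  # set on the subclass by make_server
    protocol_version = "HTTP/1.1"

    def log_message(self, fmt, *args):  # quiet by default
        pass

    def _send_json(self, status: int, payload) -> None:
        body = json.dumps(payload, separators=(",", ":")).encode("utf-8")
        self.send_response(status)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def do_GET(self) -> None:  # noqa: N802 (http.server API)
        parsed = urllib.parse.urlparse(self.path)
        parts = [p for p in parsed.path.split("/") if p]
        if parts == ["v1", "samples"]:
            self._send_json(200, self.app.samples())
            return
        if len(parts) == 3 and parts[:2] == ["v1", "data"]:
            sample = urllib.parse.unquote(parts[2])
            if sample not in self.app.sources:
                self._send_json(404, {"error": f"unknown sample {sample!r}"})
                return
            params = urllib.parse.parse_qs(parsed.query)
            try:
                chrom = params["chrom"][0]
                start = int(params["start"][0])
                end = int(params["end"][0])
            except (KeyError, ValueError, IndexError):
                self._send_json(
                    400, {"error": "require chrom=&start=&end= integer params"}
                )
                return
            if not chrom or start < 0 or start >= end:
                self._send_json(
                    400, {"error": f"invalid region {chrom}:{start}-{end}"}
                )
                return
            records = self.app.query(sample, GenomicRegion(chrom, start, end))
            self._send_json(
                200, [[r.chrom, r.start, r.end, r.value] for r in records]
            )
            return
        self._send_json(404, {"error": "not found"})


def make_server(
    data_dir: PathArg, host: str = "127.0.0.1", port: int = 0
) -> ThreadingHTTPServer:
    """Create (but do not start) the HTTP server; port 0 picks a free port."""
    app = BedServerApp(data_dir)
    handler = type("BoundHandler", (_Handler,), {"app": app})
    return ThreadingHTTPServer((host, port), handler)


def serve(data_dir: PathArg, host: str = "127.0.0.1", port: int = 8765) -> None:
    """Run the bedserver until interrupted."""
    server = make_server(data_dir, host, port)
    try:
        server.serve_forever()
    finally:
        server.server_close()


class ServerThread:
    """Context manager running a bedserver in a background thread (tests, demos)."""

    def __init__(self, data_dir: PathArg, host: str = "127.0.0.1"):
        self.server = make_server(data_dir, host, 0)
        self.thread = threading.Thread(
            target=self.server.serve_forever, daemon=True
        )

    @property
    def base_url(self) -> str:
        host, port = self.server.server_address[:2]
        return f"http://{host}:{port}"

    def __enter__(self) -> "ServerThread":
        self.thread.start()
        return self

    def __exit__(self, *exc) -> None:
        self.server.shutdown()
        self.server.server_close()
        self.thread.join(timeout=5)


class HttpSource:
    """Client source speaking the /v1 API; interchangeable with file sources."""

    def __init__(self, base_url: str, timeout: float = 10.0):
        self.base_url = base_url.rstrip("/")
        self.timeout = timeout

    def _get_json(self, path: str):
        with urllib.request.urlopen(
            self.base_url + path, timeout=self.timeout
        ) as resp:
            return json.loads(resp.read().decode("utf-8"))

    def samples(self) -> list[str]:
        return self._get_json("/v1/samples")

    def query(self, q: SourceQuery) -> list[BedRecord]:
        region = q.region
        qs = urllib.parse.urlencode(
            {"chrom": region.chrom, "start": region.start, "end": region.end}
        )
        path = f"/v1/data/{urllib.parse.quote(q.sample)}?{qs}"
        rows = self._get_json(path)
        return [BedRecord(c, s, e, float(v)) for c, s, e, v in rows]
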