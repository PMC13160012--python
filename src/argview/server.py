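"""Stateless HTTP service streaming window payloads for one dataset.

One dataset per server process, loaded at startup. Every response is a pure
function of the URL, so any GET may be repeated or cached byte-for-byte:

* ``GET /info`` — dataset summary (JSON);
* ``GET /window?start=&end=[&max_trees=&time_scale=&slot_mode=&tip_order=
  &gap=&color=&samples=]`` — Arrow IPC window payload;
* ``GET /metadata/{column}`` — category palette (JSON);
* ``GET /search?column=&query=[&mode=]`` — matching sample ids (JSON);
* ``GET /difftrack`` — whole-genome Robinson-Foulds bedGraph (text).

Invalid parameters give 400 with the validation message, unknown columns
404, and a window covering more than ``max_trees`` local trees gives 413
telling the client to zoom in (only trees in the visible window are served).
"""

from __future__ import annotations

import json
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Tuple
from urllib.parse import parse_qs, urlparse

from .annotate import PALETTE_12, assign_colors, search_samples
from .layout import LayoutConfig
from .localtrees import breakpoints, sweep
from .model import TreeSequenceData, ValidationError
from .payload import SCHEMA_VERSION
from .topodiff import diff_consecutive, diff_track_text
from .window import WindowRequest, window_payload


class _JsonError(Exception):
    def __init__(self, status: int, message: str):
        super().__init__(message)
        self.status = status


def _q1(query, name, default=None, cast=str):
    vals = query.get(name)
    if not vals:
        if default is None and cast is not str:
            return None
        return default
    try:
        return cast(vals[0])
    except (TypeError, ValueError):
        raise _JsonError(400, f"invalid value for {name!r}: {vals[0]!r}") from None


def _parse_window_request(query, default_config: LayoutConfig, max_trees: int) -> WindowRequest:
    start = _q1(query, "start", cast=float)
    end = _q1(query, "end", cast=float)
    if start is None or end is None:
        raise _JsonError(400, "window requires start and end")
    config = LayoutConfig(
        time_scale=_q1(query, "time_scale", default_config.time_scale),
        slot_mode=_q1(query, "slot_mode", default_config.slot_mode),
        tip_order=_q1(query, "tip_order", default_config.tip_order),
        tree_gap_fraction=_q1(
            query, "gap", default_config.tree_gap_fraction, cast=float
        ),
    )
    subset = None
    if query.get("samples"):
        subset = tuple(int(s) for s in query["samples"][0].split(",") if s.strip())
    return WindowRequest(
        start=start,
        end=end,
        max_trees=_q1(query, "max_trees", max_trees, cast=int),
        config=config,
        color_column=_q1(query, "color"),
        sample_subset=subset,
    )


class ArgViewApp:
    """URL -> response logic, independent of the socket layer (testable directly)."""

    def __init__(
        self,
        ts: TreeSequenceData,
        config: LayoutConfig = LayoutConfig(),
        max_trees: int = 500,
        sequence_name: str = "seq",
    ):
        self.ts = ts
        self.config = config
        self.max_trees = max_trees
        self.sequence_name = sequence_name
        self._n_trees = len(breakpoints(ts)) - 1

    def handle(self, path_query: str) -> Tuple[int, str, bytes]:
        """Returns (status, content_type, body)."""
        parsed = urlparse(path_query)
        path = parsed.path.rstrip("/") or "/"
        query = parse_qs(parsed.query)
        try:
            if path == "/info":
                return self._info()
            if path == "/window":
                return self._window(query)
            if path.startswith("/metadata/"):
                return self._metadata(path.split("/", 2)[2])
            if path == "/search":
                return self._search(query)
            if path == "/difftrack":
                return self._difftrack()
            raise _JsonError(404, f"no such endpoint: {path}")
        except _JsonError as exc:
            return self._error(exc.status, str(exc))
        except ValidationError as exc:
            return self._error(400, str(exc))

    @staticmethod
    def _json(obj, status: int = 200) -> Tuple[int, str, bytes]:
        body = json.dumps(obj, sort_keys=True).encode()
        return status, "application/json", body

    def _error(self, status: int, message: str) -> Tuple[int, str, bytes]:
        return self._json({"error": message, "status": status}, status)

    def _info(self):
        meta_cols = [] if self.ts.metadata is None else sorted(self.ts.metadata.columns)
        return self._json(
            {
                "sequence_length": self.ts.sequence_length,
                "n_samples": self.ts.num_samples,
                "n_trees": self._n_trees,
                "metadata_columns": meta_cols,
                "schema_version": SCHEMA_VERSION,
            }
        )

    def _window(self, query):
        request = _parse_window_request(query, self.config, self.max_trees)
        if request.color_column is not None:
            if self.ts.metadata is None or request.color_column not in self.ts.metadata.columns:
                raise _JsonError(404, f"unknown metadata column {request.color_column!r}")
        data, result = window_payload(self.ts, request)
        if result.truncated:
            return self._error(
                413,
                f"window covers more than max_trees={request.max_trees} local "
                "trees; zoom in to a smaller genomic window",
            )
        return 200, "application/vnd.apache.arrow.stream", data

    def _metadata(self, column: str):
        if self.ts.metadata is None or column not in self.ts.metadata.columns:
            raise _JsonError(404, f"unknown metadata column {column!r}")
        palette = assign_colors(self.ts.metadata, column)
        return self._json(
            {
                "column": column,
                "labels": palette.labels,
                "color_index": palette.color_index,
                "colors": [PALETTE_12[i] for i in palette.color_index],
            }
        )

    def _search(self, query):
        column = _q1(query, "column")
        if column is None:
            raise _JsonError(400, "search requires a column")
        if self.ts.metadata is None or column not in self.ts.metadata.columns:
            raise _JsonError(404, f"unknown metadata column {column!r}")
        text = _q1(query, "query", "")
        mode = _q1(query, "mode", "exact")
        ids = search_samples(self.ts.metadata, column, text, mode)
        return self._json({"column": column, "query": text, "mode": mode, "samples": ids})

    def _difftrack(self):
        trees = list(sweep(self.ts))
        diffs = diff_consecutive(trees, self.ts) if len(trees) > 1 else []
        text = diff_track_text(diffs, trees, sequence_name=self.sequence_name)
        return 200, "text/plain", text.encode()


def make_server(
    ts: TreeSequenceData,
    host: str = "127.0.0.1",
    port: int = 8080,
    config: LayoutConfig = LayoutConfig(),
    max_trees: int = 500,
) -> ThreadingHTTPServer:
    """Build (but do not start) the HTTP server; call serve_forever() to run."""
    app = ArgViewApp(ts, config=config, max_trees=max_trees)

    class Handler(BaseHTTPRequestHandler):
        def do_GET(self):  # noqa: N802 (stdlib naming)
            status, ctype, body = app.handle(self.path)
            self.send_response(status)
            self.send_header("Content-Type", ctype)
            self.send_header("Content-Length", str(len(body)))
            self.send_header("Cache-Control", "public, max-age=3600")
            self.end_headers()
            self.wfile.write(body)

        def log_message(self, fmt, *args):
            pass  # quiet by default; CLI layer logs

    server = ThreadingHTTPServer((host, port), Handler)
    server.app = app  # type: ignore[attr-defined]
    return server


def serve(ts: TreeSequenceData, host: str = "127.0.0.1", port: int = 8080, **kwargs) -> None:
    """Load-and-serve entry point; blocks until interrupted."""
    server = make_server(ts, host, port, **kwargs)
    try:
        server.serve_forever()
    finally:
        server.server_close()
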