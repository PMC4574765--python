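"""HTTP data-engine service: the REST face of the analysis library.

A thin, read-only WSGI application exposing the dataset endpoints

* ``GET /genes``              — all gene ids, dataset order
* ``GET /fc/{g1+g2+...}``     — per-gene log2 fold change (null if absent)
* ``GET /pvalues/{g1+...}``   — per-gene raw and BH-adjusted p
* ``GET /exprs/{g1+...}``     — raw expression rows with sample ids
* ``GET /pathway/{id}``       — pathway graph document merged with the
  expression overlay for the current dataset

Every payload is value-identical to the corresponding library call —
the HTTP layer is transport, not logic.  Multi-gene queries use the
``+`` separator (the KEGG REST convention); commas are rejected with a
hint.  Absent genes are ``null`` with status 200, never 404: a pathway
query routinely includes genes that are off the array.  404 is reserved
for unknown routes and unresolvable pathways.

Statistics are computed once per dataset at startup (BH over the full
gene universe) and served from memory, so repeated identical requests
return identical bodies.  Default port 8888.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from wsgiref.simple_server import WSGIRequestHandler, make_server

from . import kgml as kgml_mod
from .keggclient import KeggClient, TransportError, offline_fetcher, url_fetcher
from .overlay import build_overlay
from .stats import (
    ExpressionDataset,
    differential_expression,
    load_dataset,
    mean_log2_fold_change,
    raw_expression,
)

__all__ = ["ApiConfig", "DataEngineApp", "request", "serve"]

logger = logging.getLogger("pathexpress.api")


@dataclass
class ApiConfig:
    """Configuration for one service instance."""

    matrix_file: str | None = None
    design_file: str | None = None
    reference_group: str | None = None
    port: int = 8888
    alpha: float = 0.05
    color_limit: float = 2.0
    cache_dir: str = ".pathexpress-cache"
    offline: bool = False
    kegg_base_url: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.port < 65536:
            raise ValueError(f"port {self.port} outside the TCP range")


class DataEngineApp:
    """WSGI application over a dataset and a (cached) KEGG client."""

    def __init__(
        self,
        dataset: ExpressionDataset | None = None,
        kegg: KeggClient | None = None,
        alpha: float = 0.05,
        color_limit: float = 2.0,
    ):
        self.dataset = dataset
        self.kegg = kegg
        self.alpha = alpha
        self.color_limit = color_limit
        self._stats = differential_expression(dataset) if dataset is not None else None
        self._stats_by_gene = (
            {s.gene_id: s for s in self._stats} if self._stats is not None else {}
        )

    @classmethod
    def from_config(cls, cfg: ApiConfig) -> "DataEngineApp":
        dataset = None
        if cfg.matrix_file and cfg.design_file and cfg.reference_group:
            dataset = load_dataset(cfg.matrix_file, cfg.design_file, cfg.reference_group)
        fetcher = offline_fetcher if cfg.offline else url_fetcher(
            cfg.kegg_base_url or "https://rest.kegg.jp"
        )
        kegg = KeggClient(cfg.cache_dir, fetcher)
        return cls(dataset, kegg, cfg.alpha, cfg.color_limit)

    # -- WSGI plumbing ---------------------------------------------------

    def __call__(self, environ, start_response):
        t0 = time.perf_counter()
        path = environ.get("PATH_INFO", "/")
        status, payload = self.handle(path)
        body = json.dumps(payload).encode()
        reason = {200: "OK", 400: "Bad Request", 404: "Not Found",
                  503: "Service Unavailable"}.get(status, "OK")
        start_response(
            f"{status} {reason}",
            [("Content-Type", "application/json"),
             ("Content-Length", str(len(body)))],
        )
        logger.info(
            "%s status=%d latency_ms=%.2f", path, status,
            1000 * (time.perf_counter() - t0),
        )
        return [body]

    # -- routing ---------------------------------------------------------

    def handle(self, path: str) -> tuple[int, object]:
        """Dispatch one GET path; returns (status, JSON-serializable payload)."""
        if path != "/" and path.endswith("/"):
            path = path.rstrip("/")
        if path == "/genes":
            return self._genes()
        for prefix, handler in (
            ("/fc/", self._fc),
            ("/pvalues/", self._pvalues),
            ("/exprs/", self._exprs),
        ):
            if path == prefix.rstrip("/"):  # e.g. "/fc" with no genes
                return 400, {"error": "no gene ids given"}
            if path.startswith(prefix):
                spec = path[len(prefix):]
                genes, err = _split_genes(spec)
                if err is not None:
                    return 400, {"error": err}
                return handler(genes)
        if path.startswith("/pathway/"):
            return self._pathway(path[len("/pathway/"):])
        return 404, {"error": f"unknown route {path!r}"}

    def _need_dataset(self):
        if self.dataset is None:
            return 503, {"error": "no dataset loaded"}
        return None

    def _genes(self):
        missing = self._need_dataset()
        if missing:
            return missing
        return 200, self.dataset.gene_ids

    def _fc(self, genes: list[str]):
        missing = self._need_dataset()
        if missing:
            return missing
        return 200, mean_log2_fold_change(self.dataset, genes)

    def _pvalues(self, genes: list[str]):
        missing = self._need_dataset()
        if missing:
            return missing
        out = {}
        for g in genes:
            s = self._stats_by_gene.get(g)
            out[g] = None if s is None else {"p": s.p_value, "q": s.q_value}
        return 200, out

    def _exprs(self, genes: list[str]):
        missing = self._need_dataset()
        if missing:
            return missing
        return 200, raw_expression(self.dataset, genes)

    def _pathway(self, pathway_id: str):
        if self.kegg is None:
            return 503, {"error": "no KEGG client configured"}
        try:
            kgml_text, _image = self.kegg.fetch_pathway(pathway_id)
        except ValueError as exc:
            return 400, {"error": str(exc)}
        except TransportError as exc:
            return 404, {"error": str(exc)}
        graph = kgml_mod.parse_kgml(kgml_text)
        doc = kgml_mod.graph_to_view_document(graph)
        stats = self._stats if self._stats is not None else []
        doc["overlay"] = build_overlay(
            graph, stats, alpha=self.alpha, limit=self.color_limit
        ).to_json_document()
        return 200, doc


def _split_genes(spec: str) -> tuple[list[str], str | None]:
    if not spec:
        return [], "no gene ids given"
    if "," in spec:
        return [], "comma separator not supported; separate gene ids with '+'"
    genes = spec.split("+")
    if any(not g for g in genes):
        return [], "empty gene id in query"
    return genes, None


def request(app: DataEngineApp, path: str) -> tuple[int, object]:
    """Call the WSGI app in-process; returns (status code, decoded JSON body).

    The canonical way to exercise the service without a socket — tests and
    examples go through the same routing and serialization as HTTP clients.
    """
    captured: dict = {}

    def start_response(status, headers):
        captured["status"] = int(status.split()[0])

    chunks = app({"PATH_INFO": path, "REQUEST_METHOD": "GET"}, start_response)
    body = b"".join(chunks)
    return captured["status"], json.loads(body)


class _QuietHandler(WSGIRequestHandler):
    def log_message(self, *args):  # request logging goes through `logger`
        pass


def serve(app: DataEngineApp, port: int = 8888, host: str = "0.0.0.0") -> None:
    """Run the service with the stdlib WSGI server (blocks)."""
    with make_server(host, port, app, handler_class=_QuietHandler) as httpd:
        logger.info("data engine listening on %s:%d", host, port)
        httpd.serve_forever()
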