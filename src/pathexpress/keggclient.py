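"""Caching client for KEGG-style REST resources.

Every response is cached on disk, keyed deterministically by resource
path, so repeated pathway views cost no remote round-trips and an offline
deployment can run entirely from a pre-populated cache.  The transport is
an injected *fetcher* — any callable mapping a resource path to bytes —
so tests and offline use never touch the network; :func:`url_fetcher`
builds the real HTTP transport over the configured base URL.

Cache policy: entries never expire automatically (pathway payloads change
rarely and pinning favors reproducibility); :meth:`ResponseCache.purge`
removes them explicitly.  Keys are the percent-encoded resource path —
filesystem-safe, injective, and transparent to inspect.
"""

from __future__ import annotations

import re
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

__all__ = [
    "Fetcher",
    "TransportError",
    "GeneRecordError",
    "GeneRecord",
    "ResponseCache",
    "KeggClient",
    "cache_key",
    "cached_get",
    "parse_gene_record",
    "url_fetcher",
    "offline_fetcher",
    "KEGG_REST_BASE",
]

Fetcher = Callable[[str], bytes]

KEGG_REST_BASE = "https://rest.kegg.jp"

_PATHWAY_ID_RE = re.compile(r"^[a-z]{2,4}\d{5}$")


class TransportError(RuntimeError):
    """A remote fetch failed (network error, offline mode, stub refusal)."""


class GeneRecordError(ValueError):
    """Text is not a KEGG flat-file gene record."""


def cache_key(resource_path: str) -> str:
    """Deterministic, filesystem-safe, injective key for a resource path.

    Percent-encoding with no safe characters, plus encoding of ``.`` so
    that paths like ``"."``/``".."`` cannot yield special filenames (the
    encoder never emits a literal ``%2E`` otherwise, so this stays
    injective).
    """
    return urllib.parse.quote(resource_path, safe="").replace(".", "%2E")


class ResponseCache:
    """Byte-payload cache, one file per resource, persistent across processes."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def path_for(self, resource_path: str) -> Path:
        return self.directory / cache_key(resource_path)

    def get(self, resource_path: str) -> bytes | None:
        p = self.path_for(resource_path)
        return p.read_bytes() if p.exists() else None

    def put(self, resource_path: str, payload: bytes) -> None:
        # Write-then-rename so a crash mid-write never poisons the cache.
        target = self.path_for(resource_path)
        tmp = target.with_name(target.name + f".tmp{time.monotonic_ns()}")
        tmp.write_bytes(payload)
        tmp.replace(target)

    def purge(self) -> int:
        """Remove every cached entry; returns the number removed."""
        n = 0
        for p in self.directory.iterdir():
            if p.is_file():
                p.unlink()
                n += 1
        return n


def cached_get(cache: ResponseCache, resource_path: str, fetcher: Fetcher) -> bytes:
    """Return the cached payload for ``resource_path``, fetching once on a miss.

    A failed fetch propagates and stores nothing, so the cache is never
    poisoned; a successful fetch persists on disk across process restarts.
    """
    hit = cache.get(resource_path)
    if hit is not None:
        return hit
    payload = fetcher(resource_path)
    cache.put(resource_path, payload)
    return payload


@dataclass(frozen=True)
class GeneRecord:
    """Parsed KEGG flat-file gene entry (NAME / DEFINITION / PATHWAY sections)."""

    gene_id: str
    name: tuple[str, ...]
    definition: str
    pathways: tuple[tuple[str, str], ...]


def parse_gene_record(flat_text: str) -> GeneRecord:
    """Parse a KEGG flat-file gene record.

    The flat format keys each section by a keyword in the first 12 columns;
    indented lines continue the previous section.  NAME aliases are
    comma-separated and may span continuation lines; each PATHWAY line is
    one (pathway id, pathway name) pair, file order preserved.
    """
    sections: list[tuple[str, list[str]]] = []
    for line in flat_text.splitlines():
        if line.startswith("///") or not line.strip():
            continue
        keyword = line[:12].strip()
        body = line[12:].strip()
        if keyword:
            sections.append((keyword, [body]))
        elif sections:
            sections[-1][1].append(body)

    by_key: dict[str, list[str]] = {}
    for key, lines in sections:
        by_key.setdefault(key, []).extend(lines)

    if "ENTRY" not in by_key:
        raise GeneRecordError("missing ENTRY line; not a KEGG flat-file record")
    entry_fields = by_key["ENTRY"][0].split()
    gene_id = entry_fields[0] if entry_fields else ""
    if not gene_id:
        raise GeneRecordError("ENTRY line carries no identifier")

    name = tuple(
        alias.strip()
        for alias in ",".join(by_key.get("NAME", [])).split(",")
        if alias.strip()
    )
    definition = " ".join(by_key.get("DEFINITION", []))
    pathways = []
    for line in by_key.get("PATHWAY", []):
        pid, _, pname = line.partition(" ")
        pathways.append((pid.strip(), pname.strip()))
    return GeneRecord(gene_id, name, definition, tuple(pathways))


def url_fetcher(base_url: str = KEGG_REST_BASE, timeout: float = 30.0) -> Fetcher:
    """HTTP transport resolving resource paths against ``base_url``."""

    def fetch(resource_path: str) -> bytes:
        url = base_url.rstrip("/") + "/" + resource_path.lstrip("/")
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                return resp.read()
        except OSError as exc:
            raise TransportError(f"fetch of {url} failed: {exc}") from exc

    return fetch


def offline_fetcher(resource_path: str) -> bytes:
    """Fetcher for offline mode: any cache miss is an error."""
    raise TransportError(
        f"offline mode: {resource_path!r} is not cache-resident"
    )


class KeggClient:
    """High-level access to pathways and gene records, always through the cache."""

    def __init__(self, cache_dir: str | Path, fetcher: Fetcher = offline_fetcher):
        self.cache = ResponseCache(cache_dir)
        self.fetcher = fetcher

    def get(self, resource_path: str) -> bytes:
        return cached_get(self.cache, resource_path, self.fetcher)

    def fetch_pathway(self, pathway_id: str) -> tuple[str, bytes]:
        """KGML text and background-image bytes for one pathway.

        The id must match the KEGG form (organism code + 5 digits, e.g.
        ``hsa04614``); validation happens before any fetch.
        """
        if not _PATHWAY_ID_RE.match(pathway_id):
            raise ValueError(
                f"invalid pathway id {pathway_id!r}; expected e.g. 'hsa04614'"
            )
        kgml = self.get(f"get/{pathway_id}/kgml").decode()
        image = self.get(f"get/{pathway_id}/image")
        return kgml, image

    def fetch_gene_record(self, gene_id: str) -> GeneRecord:
        if not gene_id:
            raise ValueError("empty gene id")
        return parse_gene_record(self.get(f"get/{gene_id}").decode())

    def purge_cache(self) -> int:
        return self.cache.purge()
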