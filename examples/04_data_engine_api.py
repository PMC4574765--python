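"""Query the data-engine REST endpoints in process.

The WSGI app serves exactly what the library computes; here we call it
without a socket via `request`, the same code path an HTTP client hits
(run `pathexpress serve ... --port 8888` for the real server).
"""

import tempfile

from pathexpress.api import DataEngineApp, request
from pathexpress.keggclient import KeggClient
from pathexpress.synthetic import generate_dataset, generate_kgml_fixture

ds, _ = generate_dataset(100, 8, 10, seed=3)
xml = generate_kgml_fixture(8, 2, 5, seed=4, gene_pool=list(ds.gene_ids),
                            pathway_id="syn04614")


def fixture_fetcher(path: str) -> bytes:  # offline stand-in for rest.kegg.jp
    return {"get/syn04614/kgml": xml.encode(), "get/syn04614/image": b"png"}[path]


with tempfile.TemporaryDirectory() as cache_dir:
    app = DataEngineApp(ds, KeggClient(cache_dir, fixture_fetcher))

    status, genes = request(app, "/genes")
    print(f"GET /genes -> {status}, {len(genes)} gene ids")

    q = "+".join(genes[:2]) + "+not_on_array"
    for route in (f"/fc/{q}", f"/pvalues/{q}"):
        status, body = request(app, route)
        print(f"GET {route.split('/')[1]}/... -> {status}: {body}")

    status, doc = request(app, "/pathway/syn04614")
    framed = sum(1 for s in doc["overlay"]["styles"].values() if s["frame"])
    print(f"GET /pathway/syn04614 -> {status}: {len(doc['nodes'])} nodes, "
          f"{framed} significance-framed")

    status, body = request(app, "/fc/a,b")
    print(f"GET /fc/a,b -> {status} ({body['error']})")
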