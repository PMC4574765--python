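"""The response cache: every remote resource is fetched at most once.

A counting stub stands in for the KEGG REST transport; the second pathway
view and even a 'process restart' (a fresh client over the same cache
directory) cost zero fetches.  Also parses a KEGG flat-file gene record.
"""

import tempfile

from pathexpress.keggclient import KeggClient, parse_gene_record
from pathexpress.synthetic import generate_kgml_fixture

xml = generate_kgml_fixture(5, 1, 3, seed=9, pathway_id="syn00010")
calls = []


def counting_fetcher(path: str) -> bytes:
    calls.append(path)
    return {"get/syn00010/kgml": xml.encode(), "get/syn00010/image": b"png"}[path]


with tempfile.TemporaryDirectory() as cache_dir:
    client = KeggClient(cache_dir, counting_fetcher)
    client.fetch_pathway("syn00010")
    client.fetch_pathway("syn00010")
    print(f"two pathway views -> {len(calls)} transport calls: {calls}")

    restarted = KeggClient(cache_dir, counting_fetcher)  # same cache dir
    restarted.fetch_pathway("syn00010")
    print(f"after restart     -> still {len(calls)} transport calls")

record = parse_gene_record(
    "ENTRY       1359              CDS       T01001\n"
    "NAME        CPA3, MC-CPA\n"
    "DEFINITION  (RefSeq) carboxypeptidase A3\n"
    "PATHWAY     hsa04614  Renin-angiotensin system\n"
    "///\n"
)
print(f"gene {record.gene_id} ({record.name[0]}): {record.definition}")
print(f"member of: {[f'{pid} {name}' for pid, name in record.pathways]}")
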