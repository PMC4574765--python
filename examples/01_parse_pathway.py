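"""Parse a KGML pathway file into a graph and export it as a view document.

Uses the repository's synthetic renin-angiotensin pathway fixture (a small
hand-built stand-in following KEGG's hsa04614 conventions).
"""

from pathlib import Path

from pathexpress import graph_to_view_document, parse_kgml, pathway_gene_ids

kgml_path = Path(__file__).parents[1] / "tests" / "data" / "hsa04614_synthetic.xml"
graph = parse_kgml(kgml_path.read_text())

print(f"pathway {graph.pathway_id}: {graph.title!r} ({graph.organism})")
print(f"{len(graph.nodes)} nodes, {len(graph.edges)} edges")
for node in graph.nodes[:4]:
    print(f"  entry {node.entry_id}: {node.node_type.value:9s} {node.label:6s} "
          f"at ({node.x:.0f}, {node.y:.0f})  ids={list(node.kegg_ids)}")
print("gene ids on the map:", pathway_gene_ids(graph))

doc = graph_to_view_document(graph)
print(f"view document: {len(doc['nodes'])} node records, "
      f"{len(doc['edges'])} edge records (coordinates kept in image pixels)")
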