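"""Color a pathway's nodes by fold change and frame the significant ones.

Builds a matched dataset + pathway pair (the pathway's gene entries draw
their ids from the dataset), runs the statistics, and maps them to the
diverging blue-white-red fill plus a significance frame at q <= 0.05.
"""

from pathexpress import build_overlay, differential_expression, parse_kgml
from pathexpress.overlay import fold_change_to_color
from pathexpress.synthetic import generate_dataset, generate_kgml_fixture

ds, truth = generate_dataset(300, 10, 30, effect_size=2.0, noise_sd=1.0, seed=5)
xml = generate_kgml_fixture(
    n_gene_nodes=15, n_compound_nodes=3, n_edges=10, seed=6,
    gene_pool=list(ds.gene_ids),
)
graph = parse_kgml(xml)

style = build_overlay(graph, differential_expression(ds), alpha=0.05, limit=2.0)
framed = style.framed_entry_ids()
print(f"{len(graph.nodes)} nodes styled; {len(framed)} carry a significance frame")
for eid in framed:
    r = style.records[eid]
    print(f"  entry {eid}: gene {r.source_gene}  log2FC={r.log2_fc:+.2f}  "
          f"q={r.q_value:.1e}  fill={r.fill_color}  frame={r.frame_color}")

print("color scale anchors: "
      f"-2 -> {fold_change_to_color(-2.0)}  0 -> {fold_change_to_color(0.0)}  "
      f"+2 -> {fold_change_to_color(2.0)}  (clamped beyond +/-2 log2 units)")
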