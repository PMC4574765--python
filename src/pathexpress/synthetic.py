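"""Synthetic expression datasets and KGML fixtures with known ground truth.

Real deployments of this kind of tool sit on cohort expression data and a
live KEGG mirror; neither can be assumed while developing or testing.
This module generates both sides offline:

* two-group log2 expression matrices with a planted set of differentially
  expressed genes — per gene a baseline ``b_g ~ Normal(7, 2)`` (a rough
  log2-microarray intensity range), reference samples ``Normal(b_g, σ)``
  and case samples ``Normal(b_g + δ·[g ∈ DE], σ)``;
* well-formed KGML pathway documents whose gene entries can draw their
  KEGG ids from the dataset's gene universe, so pathway and dataset
  fixtures join exactly like a real pathway joins a real array.

All randomness flows through one ``numpy`` Generator seeded explicitly;
a fixed seed reproduces byte-identical outputs.  Written datasets carry a
JSON truth manifest recording the planted structure.

What this generator does *not* emulate: probe effects, batch structure,
missing values, correlated genes.  Calibration results on these fixtures
speak to the statistics under the model's assumptions, not to artifacts
of real arrays.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .stats import ExpressionDataset

__all__ = [
    "SyntheticTruth",
    "generate_dataset",
    "write_dataset",
    "generate_kgml_fixture",
]

REFERENCE_GROUP = "low"
CASE_GROUP = "high"

BASELINE_MEAN = 7.0
BASELINE_SD = 2.0

_RELATION_SUBTYPES = (
    "activation",
    "inhibition",
    "expression",
    "binding/association",
    "compound",
)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure of one generated dataset."""

    de_gene_ids: tuple[str, ...]
    effect_size: float
    noise_sd: float
    n_per_group: int
    seed: int


def generate_dataset(
    n_genes: int,
    n_per_group: int,
    n_de: int,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Two-group log2 expression matrix with ``n_de`` planted DE genes.

    The case group is shifted by ``effect_size`` log2 units on the DE
    genes only; groups are ``high`` (case) vs ``low`` (reference), mirroring
    a high-vs-low exposure contrast.
    """
    if n_de > n_genes:
        raise ValueError(f"n_de={n_de} exceeds n_genes={n_genes}")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")

    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], int)
    de_mask = np.zeros(n_genes, dtype=bool)
    de_mask[de_idx] = True

    baselines = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)
    ref = rng.normal(baselines[:, None], noise_sd, size=(n_genes, n_per_group))
    case_means = baselines + effect_size * de_mask
    case = rng.normal(case_means[:, None], noise_sd, size=(n_genes, n_per_group))

    ref_samples = [f"{REFERENCE_GROUP}_{j:03d}" for j in range(n_per_group)]
    case_samples = [f"{CASE_GROUP}_{j:03d}" for j in range(n_per_group)]
    values = pd.DataFrame(
        np.hstack([ref, case]),
        index=pd.Index(gene_ids, name="gene"),
        columns=ref_samples + case_samples,
    )
    groups = {s: REFERENCE_GROUP for s in ref_samples}
    groups.update({s: CASE_GROUP for s in case_samples})

    ds = ExpressionDataset(values=values, groups=groups, reference_group=REFERENCE_GROUP)
    truth = SyntheticTruth(
        de_gene_ids=tuple(sorted(np.array(gene_ids)[de_mask])),
        effect_size=effect_size,
        noise_sd=noise_sd,
        n_per_group=n_per_group,
        seed=seed,
    )
    return ds, truth


def write_dataset(
    ds: ExpressionDataset,
    truth: SyntheticTruth,
    directory: str | Path,
) -> tuple[Path, Path, Path]:
    """Write matrix.tsv, design.tsv and a truth.json manifest; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix = directory / "matrix.tsv"
    design = directory / "design.tsv"
    manifest = directory / "truth.json"
    ds.values.to_csv(matrix, sep="\t", float_format="%.10g")
    pd.DataFrame(
        {"sample": ds.sample_ids, "group": [ds.groups[s] for s in ds.sample_ids]}
    ).to_csv(design, sep="\t", index=False)
    payload = asdict(truth) | {"reference_group": ds.reference_group}
    payload["de_gene_ids"] = list(payload["de_gene_ids"])
    manifest.write_text(json.dumps(payload, indent=1))
    return matrix, design, manifest


def _graphics(parent: etree._Element, name: str, x: int, y: int, ntype: str) -> None:
    etree.SubElement(
        parent,
        "graphics",
        name=name,
        x=str(x),
        y=str(y),
        width="46",
        height="17",
        type="rectangle" if ntype != "compound" else "circle",
        fgcolor="#000000",
        bgcolor="#FFFFFF",
    )


def generate_kgml_fixture(
    n_gene_nodes: int,
    n_compound_nodes: int,
    n_edges: int,
    seed: int = 0,
    gene_pool: list[str] | None = None,
    n_map_nodes: int = 0,
    n_group_nodes: int = 0,
    n_reactions: int = 0,
    pathway_id: str = "syn00001",
) -> str:
    """Well-formed KGML text with the requested entry and relation counts.

    ``n_edges`` counts ``relation`` elements; reactions (each joining 1–2
    substrate to 1–2 product compound entries, adding their cross-product
    edges on parse) are requested separately via ``n_reactions``.  Gene
    entries draw KEGG ids from ``gene_pool`` when given, enabling joint
    dataset+pathway fixtures; group entries reference two gene members.
    """
    rng = np.random.default_rng(seed)
    n_nodes = n_gene_nodes + n_compound_nodes + n_map_nodes + n_group_nodes
    if n_edges > n_nodes * (n_nodes - 1):
        raise ValueError(
            f"n_edges={n_edges} exceeds the {n_nodes * (n_nodes - 1)} ordered "
            f"pairs available on {n_nodes} nodes"
        )
    if n_group_nodes and n_gene_nodes < 2:
        raise ValueError("group entries need at least 2 gene entries as members")
    if n_reactions and n_compound_nodes < 2:
        raise ValueError("reactions need at least 2 compound entries")

    root = etree.Element(
        "pathway",
        name=f"path:{pathway_id}",
        org=pathway_id[:3],
        number=pathway_id[-5:],
        title=f"Synthetic pathway {pathway_id}",
        image=f"https://example.invalid/{pathway_id}.png",
    )

    next_id = 1
    gene_ids: list[str] = []
    compound_ids: list[str] = []
    all_ids: list[str] = []

    for i in range(n_gene_nodes):
        eid = str(next_id)
        next_id += 1
        if gene_pool:
            k = int(rng.integers(1, min(2, len(gene_pool)) + 1))
            picks = list(rng.choice(gene_pool, size=k, replace=False))
        else:
            picks = [f"syn:{1000 + i}"]
        entry = etree.SubElement(root, "entry", id=eid, name=" ".join(picks), type="gene")
        label = f"SYG{i + 1}"
        _graphics(entry, f"{label}, {label}b", int(rng.integers(40, 900)),
                  int(rng.integers(40, 600)), "gene")
        gene_ids.append(eid)
        all_ids.append(eid)

    for i in range(n_compound_nodes):
        eid = str(next_id)
        next_id += 1
        entry = etree.SubElement(
            root, "entry", id=eid, name=f"cpd:C{90000 + i}", type="compound"
        )
        _graphics(entry, f"C{90000 + i}", int(rng.integers(40, 900)),
                  int(rng.integers(40, 600)), "compound")
        compound_ids.append(eid)
        all_ids.append(eid)

    for i in range(n_map_nodes):
        eid = str(next_id)
        next_id += 1
        entry = etree.SubElement(
            root, "entry", id=eid, name=f"path:syn{10000 + i}", type="map"
        )
        _graphics(entry, f"Linked map {i + 1}", int(rng.integers(40, 900)),
                  int(rng.integers(40, 600)), "map")
        all_ids.append(eid)

    for i in range(n_group_nodes):
        eid = str(next_id)
        next_id += 1
        entry = etree.SubElement(root, "entry", id=eid, name="undefined", type="group")
        _graphics(entry, "", int(rng.integers(40, 900)), int(rng.integers(40, 600)),
                  "group")
        for member in rng.choice(gene_ids, size=2, replace=False):
            etree.SubElement(entry, "component", id=str(member))
        all_ids.append(eid)

    # relations: distinct ordered pairs, sampled without replacement
    pairs = [(a, b) for a in all_ids for b in all_ids if a != b]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    for idx in chosen:
        src, dst = pairs[int(idx)]
        rel = etree.SubElement(root, "relation", entry1=src, entry2=dst, type="PPrel")
        etree.SubElement(
            rel, "subtype",
            name=str(rng.choice(_RELATION_SUBTYPES)),
            value="-->",
        )

    for i in range(n_reactions):
        rxn = etree.SubElement(
            root, "reaction",
            id=str(next_id),
            name=f"rn:R{10000 + i}",
            type=str(rng.choice(["reversible", "irreversible"])),
        )
        next_id += 1
        n_sub = int(rng.integers(1, min(2, len(compound_ids)) + 1))
        n_prod = int(rng.integers(1, min(2, len(compound_ids)) + 1))
        for cid in rng.choice(compound_ids, size=n_sub, replace=False):
            etree.SubElement(rxn, "substrate", id=str(cid), name=f"cpd:sub{cid}")
        for cid in rng.choice(compound_ids, size=n_prod, replace=False):
            etree.SubElement(rxn, "product", id=str(cid), name=f"cpd:prod{cid}")

    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()
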