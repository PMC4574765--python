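from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from pathexpress.stats import ExpressionDataset
from pathexpress.synthetic import generate_dataset, generate_kgml_fixture

DATA_DIR = Path(__file__).parent / "data"

MINIMAL_KGML = """<?xml version="1.0"?>
<pathway name="path:tst00001" org="tst" number="00001" title="Minimal" image="img.png">
  <entry id="1" name="tst:100 tst:101" type="gene">
    <graphics name="GENEA, aliasA" x="10" y="20" width="46" height="17" type="rectangle"/>
  </entry>
  <entry id="2" name="tst:200" type="gene">
    <graphics name="GENEB" x="90" y="20" width="46" height="17" type="rectangle"/>
  </entry>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
</pathway>
"""


@pytest.fixture
def minimal_kgml() -> str:
    return MINIMAL_KGML


@pytest.fixture(scope="session")
def renin_angiotensin_kgml() -> str:
    return (DATA_DIR / "hsa04614_synthetic.xml").read_text()


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """2 genes x 4 samples, hand-sized so expectations are arithmetic."""
    values = pd.DataFrame(
        [[1.0, 3.0, 5.0, 7.0], [2.0, 2.0, 2.0, 2.0]],
        index=["gA", "gB"],
        columns=["s1", "s2", "s3", "s4"],
    )
    groups = {"s1": "low", "s2": "low", "s3": "high", "s4": "high"}
    return ExpressionDataset(values=values, groups=groups, reference_group="low")


@pytest.fixture(scope="session")
def synthetic_pair():
    """Dataset + matched KGML fixture whose gene entries draw from the dataset."""
    ds, truth = generate_dataset(
        n_genes=300, n_per_group=10, n_de=30, effect_size=2.0, noise_sd=1.0, seed=11
    )
    xml = generate_kgml_fixture(
        n_gene_nodes=25,
        n_compound_nodes=4,
        n_edges=20,
        seed=12,
        gene_pool=list(ds.gene_ids),
        n_map_nodes=1,
        n_group_nodes=2,
        n_reactions=2,
        pathway_id="syn04614",
    )
    return ds, truth, xml


class CountingFetcher:
    """Stub transport: serves canned payloads and counts every call."""

    def __init__(self, payloads: dict[str, bytes]):
        self.payloads = payloads
        self.calls: list[str] = []

    def __call__(self, path: str) -> bytes:
        self.calls.append(path)
        return self.payloads[path]


class FailingFetcher:
    """Stub transport that refuses every call — asserts cache residency."""

    def __init__(self):
        self.calls: list[str] = []

    def __call__(self, path: str) -> bytes:
        self.calls.append(path)
        raise AssertionError(f"unexpected fetch of {path!r}")


@pytest.fixture
def counting_fetcher_factory():
    return CountingFetcher


@pytest.fixture
def failing_fetcher():
    return FailingFetcher()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
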