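import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from tcss.annotations import parse_gaf, reduce_to_most_specific
from tcss.clustering import cluster
from tcss.ontology import OntologyDAG, Term, parse_obo

DATA = Path(__file__).parent / "data"

#: topology cutoff used by the worked fixture's frozen tables
WORKED_CUTOFF = 1.1


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def worked_dag():
    return parse_obo(DATA / "worked.obo", "CC")


@pytest.fixture(scope="session")
def worked_ann(worked_dag):
    ann = parse_gaf(DATA / "worked.gaf", worked_dag)
    return reduce_to_most_specific(ann, worked_dag)


@pytest.fixture(scope="session")
def worked_clustering(worked_dag, worked_ann):
    return cluster(worked_dag, worked_ann, WORKED_CUTOFF)


@pytest.fixture(scope="session")
def worked_tables():
    return json.loads((DATA / "worked_tables.json").read_text())


@pytest.fixture(scope="session")
def worked_scores():
    return pd.read_csv(DATA / "worked_scores.tsv", sep="\t")


def random_dag(seed: int, n_terms: int, max_parents: int = 3) -> OntologyDAG:
    """Random single-root DAG: node i > 0 gets 1..max_parents earlier parents."""
    rng = np.random.default_rng(seed)
    ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    terms = {
        t: Term(id=t, name=f"random term {i}", namespace="cellular_component")
        for i, t in enumerate(ids)
    }
    edges = []
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        for j in rng.choice(i, size=k, replace=False):
            edges.append((ids[i], ids[int(j)], "is_a"))
    return OntologyDAG("cellular_component", terms, edges)
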