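"""Shared fixtures: the default simulated study, one full pipeline run, and
small hand-made matrices.  Heavy artifacts are session-scoped."""

from __future__ import annotations

import collections
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from limbtraj import (
    ClusterSpec,
    CountMatrix,
    SimulationConfig,
    default_config,
    generate_dataset,
    run_all,
    simulated_pipeline_config,
)
from limbtraj.trajectory import leaf_label

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size two-condition study (seed 42) with ground truth."""
    return generate_dataset(default_config(seed=42))


@pytest.fixture(scope="session")
def default_run():
    """One full-scale end-to-end pipeline run on the default study."""
    return run_all(simulated_pipeline_config(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """A 0.3-scale copy of the study for faster per-module tests."""
    return generate_dataset(default_config(seed=7, n_scale=0.3))


@pytest.fixture()
def tiny_matrix():
    """Hand-written 3-cell x 4-gene count matrix."""
    counts = np.array(
        [
            [5, 0, 2, 1],
            [0, 0, 0, 3],
            [10, 1, 0, 0],
        ]
    )
    return CountMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=["c1", "c2", "c3"],
        gene_symbols=["g1", "g2", "Apop01", "g3"],
        condition="unwounded",
    )


def truth_cluster_mapping(result) -> dict[str, str]:
    """Map each predicted '<cluster>|<condition>' to its majority ground-truth
    cluster name."""
    truth = result.truth
    mapping = {}
    for cond, lab in result.labelings.items():
        tl = truth.labels_for(lab.cell_ids)
        for cid in set(lab.labels):
            counter = collections.Counter(
                t for t, p in zip(tl, lab.labels) if p == cid
            )
            mapping[f"{cid}|{cond}"] = counter.most_common(1)[0][0]
    return mapping


def expected_designations(result) -> list[tuple[str, set[str]]]:
    """(predicted label, expected ground-truth labels) per designated type."""
    mapping = truth_cluster_mapping(result)
    types = {t.name: t for t in result.cell_types}
    out = []
    for d in result.designations:
        t = types[d.cell_type]
        exp = {
            result.truth.expected_designation[mapping[leaf_label(c, cond)]]
            for c, cond in t.member_clusters
        }
        out.append((d.label, exp))
    return out


def random_binary_tree(rng: np.random.Generator, n_leaves: int):
    """Uniform-ish random rooted binary tree with random condition labels,
    ultrametric heights.  Returns (Dendrogram, leaf labels)."""
    from limbtraj.trajectory import Dendrogram, Node

    nodes = [
        Node(height=0.0, name=f"L{i}|{rng.choice(['unwounded', 'wounded'])}")
        for i in range(n_leaves)
    ]
    height = 0.0
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = sorted((int(i), int(j)))
        height += float(rng.uniform(0.01, 1.0))
        merged = Node(height=height, children=(nodes[i], nodes[j]))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    d = Dendrogram(root=nodes[0])
    return d, d.leaves()
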