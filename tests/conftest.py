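"""Shared fixtures and random-structure generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phylostack as ps
from phylostack.tree import Hierarchy, TaxonNode

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_tree(rng: np.random.Generator, n_leaves: int, max_children: int = 4) -> Hierarchy:
    """Random rooted tree with ``n_leaves`` leaves L0..L{n-1} (in leaf order)."""
    counter = [0]
    nodes: dict[str, TaxonNode] = {}

    def build(lo: int, hi: int, parent: str | None) -> str:
        if hi - lo == 1:
            nid = f"L{lo}"
            nodes[nid] = TaxonNode(nid, nid, parent)
            return nid
        counter[0] += 1
        nid = f"N{counter[0]}"
        nodes[nid] = TaxonNode(nid, nid, parent)
        k = hi - lo
        m = int(rng.integers(2, min(max_children, k) + 1))
        cuts = sorted(rng.choice(np.arange(lo + 1, hi), size=m - 1, replace=False).tolist())
        bounds = [lo, *cuts, hi]
        for a, b in zip(bounds[:-1], bounds[1:]):
            nodes[nid].children.append(build(a, b, nid))
        return nid

    root = build(0, n_leaves, None)
    return Hierarchy(nodes, root)


def random_collapse_set(rng: np.random.Generator, h: Hierarchy, p: float = 0.3) -> frozenset[str]:
    internal = [n for n in h.preorder() if not h.is_leaf(n)]
    return frozenset(n for n in internal if rng.random() < p)


def random_abundance(
    rng: np.random.Generator, h: Hierarchy, n_samples: int = 5, integer: bool = True
) -> ps.AbundanceTable:
    labels = h.leaf_labels
    if integer:
        vals = rng.integers(0, 50, size=(n_samples, len(labels))).astype(float)
    else:
        vals = rng.random((n_samples, len(labels))) * 10
    return ps.AbundanceTable.from_arrays(
        [f"s{i}" for i in range(n_samples)], labels, vals
    )


def tree_signature(h: Hierarchy, node: str | None = None):
    """Structural fingerprint: nested (label, children) tuples from the root."""
    node = node if node is not None else h.root
    return (h.label(node), tuple(tree_signature(h, c) for c in h.children(node)))


@pytest.fixture
def ktree() -> Hierarchy:
    """K1 → {P1 → {O1, O2}, P2 → {O3}} via the taxonomy-table route."""
    t = ps.TaxonomyTable(
        ranks=["Kingdom", "Phylum", "Order"],
        rows=[["K1", "P1", "O1"], ["K1", "P1", "O2"], ["K1", "P2", "O3"]],
    )
    return ps.taxonomy_to_tree(t)


@pytest.fixture
def kabundance() -> ps.AbundanceTable:
    return ps.AbundanceTable.from_arrays(
        ["s1", "s2"], ["O1", "O2", "O3"], [[2.0, 3.0, 5.0], [1.0, 4.0, 2.0]]
    )
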