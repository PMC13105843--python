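"""Synthetic taxonomy tables and group-structured abundance matrices.

The generator emulates the shape of a two-arm 16S-style study: a random
taxonomy over a configurable number of leaves (OTUs), two sample groups
(control vs. treatment), zero-inflated log-normal counts, and a *planted*
multiplicative fold change on one target subtree in the treatment group —
the kind of coarse compositional shift (one clade up, the rest relatively
down) that a linked tree/barplot view is meant to surface.  Counts are
rounded log-normals rather than multinomial draws, so raw per-sample totals
differ across samples, exercising the "abundances need not sum to one"
path.

Treatment values on the target leaves are draws from the control
distribution scaled by the fold *before* rounding, so the planted signal is
recoverable: with noise off, the treatment-group mean on the target leaves
is exactly ``fold`` × the control mean.

Everything is driven by a mandatory seed; the same spec always produces the
same tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import AbundanceTable, TaxonomyTable
from .tree import Hierarchy

__all__ = ["SyntheticSpec", "SyntheticSpecError", "synth", "synth_tree"]


class SyntheticSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for one synthetic dataset.

    Defaults sketch a modest two-arm gut-microbiome experiment: 20 samples
    per group, 24 OTUs organized under Kingdom/Phylum/Class ranks, log-normal
    abundances with within-sample log-scale spread 0.9 and leaf-to-leaf
    baseline spread 0.9, 20% structural zeros, and a 4-fold enrichment of
    one phylum in the treatment group.
    """

    seed: int
    n_samples: int = 20  # per group
    group_names: tuple[str, str] = ("control", "treatment")
    target: str | None = None  # node label carrying the fold; None -> largest phylum
    fold: float = 4.0
    n_leaves: int = 24
    depth: int = 4  # rank levels including the leaf level
    ranks: tuple[str, ...] = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus")
    log_mean: float = 3.0  # location of leaf baselines (log scale)
    leaf_sigma: float = 0.9  # spread of leaf baselines across taxa
    log_sigma: float = 0.9  # within-sample log-scale noise
    zero_prob: float = 0.2  # structural zero probability
    round_counts: bool = True

    def __post_init__(self):
        if self.fold <= 0:
            raise SyntheticSpecError("fold must be positive")
        if not (0 <= self.zero_prob <= 1):
            raise SyntheticSpecError("zero_prob must lie in [0,1]")
        if self.n_leaves < 2 or self.n_samples < 1:
            raise SyntheticSpecError("need at least 2 leaves and 1 sample per group")
        if not (2 <= self.depth <= len(self.ranks) + 1):
            raise SyntheticSpecError(f"depth must lie in [2, {len(self.ranks) + 1}]")


def synth_taxonomy(spec: SyntheticSpec, rng: np.random.Generator) -> TaxonomyTable:
    """Random taxonomy: recursive contiguous splits of the leaf set per rank.

    Level 0 is a single kingdom, so the converted tree is rooted there; each
    subsequent internal rank splits every block into 1–3 sub-blocks; the
    final level names the leaves ``OTU_1 … OTU_n``.
    """
    n_internal_levels = spec.depth - 1
    rank_names = list(spec.ranks[:n_internal_levels]) + ["OTU"]
    prefixes = [r[0].upper() for r in rank_names[:n_internal_levels]]
    counters = [0] * n_internal_levels

    # blocks: list of (indices, path) expanded level by level
    blocks: list[tuple[list[int], list[str]]] = [(list(range(spec.n_leaves)), [])]
    for level in range(n_internal_levels):
        new_blocks: list[tuple[list[int], list[str]]] = []
        for indices, path in blocks:
            if level == 0:
                parts = [indices]  # single kingdom
            else:
                # the first split always yields >=2 phyla so the planted clade
                # has a non-trivial complement (one clade up vs. the rest)
                lo = 2 if (level == 1 and len(indices) >= 2) else 1
                m = int(rng.integers(lo, min(3, len(indices)) + 1))
                if m == 1:
                    parts = [indices]
                else:
                    cuts = sorted(rng.choice(range(1, len(indices)), size=m - 1, replace=False))
                    parts = [indices[i:j] for i, j in zip([0] + cuts, cuts + [len(indices)])]
            for part in parts:
                counters[level] += 1
                name = f"{prefixes[level]}{counters[level]}"
                new_blocks.append((part, path + [name]))
        blocks = new_blocks

    rows: list[list[str | None]] = [[] for _ in range(spec.n_leaves)]
    for indices, path in blocks:
        for idx in indices:
            rows[idx] = list(path) + [f"OTU_{idx + 1}"]
    return TaxonomyTable(ranks=rank_names, rows=rows)


def synth_tree(spec: SyntheticSpec) -> Hierarchy:
    """Just the hierarchy of :func:`synth` (same seed, same tree)."""
    from .tables import taxonomy_to_tree

    rng = np.random.default_rng(spec.seed)
    return taxonomy_to_tree(synth_taxonomy(spec, rng))


def _resolve_target(h: Hierarchy, spec: SyntheticSpec) -> str:
    if spec.target is None:
        # largest child of the root: the strongest, most stable planted signal
        kids = h.children(h.root)
        sizes = [len(h.leaves_under(k)) for k in kids]
        return kids[int(np.argmax(sizes))]
    hits = h.find_by_label(spec.target)
    if not hits:
        raise SyntheticSpecError(f"target node {spec.target!r} absent from generated tree")
    return hits[0]


def synth(spec: SyntheticSpec) -> tuple[TaxonomyTable, AbundanceTable, dict[str, str]]:
    """Generate (taxonomy table, abundance table, sample→group metadata).

    Sample ids are ``<group>_<k>``; the abundance rows list the first group
    then the second.  The planted fold multiplies the treatment group's
    target-subtree draws before optional rounding.
    """
    from .tables import taxonomy_to_tree

    rng = np.random.default_rng(spec.seed)
    taxonomy = synth_taxonomy(spec, rng)
    h = taxonomy_to_tree(taxonomy)
    target_id = _resolve_target(h, spec)
    target_leaves = set(h.leaves_under(target_id))
    leaf_labels = h.leaf_labels
    L = len(leaf_labels)
    target_mask = np.array([lid in target_leaves for lid in h.leaf_order])

    mu = rng.normal(spec.log_mean, spec.leaf_sigma, size=L)  # leaf baselines
    ctrl_name, trt_name = spec.group_names
    n = spec.n_samples

    def draw(group_size: int, fold: float) -> np.ndarray:
        x = np.exp(rng.normal(mu[None, :], spec.log_sigma, size=(group_size, L)))
        x[:, target_mask] *= fold
        if spec.zero_prob > 0:
            x[rng.random((group_size, L)) < spec.zero_prob] = 0.0
        return np.rint(x) if spec.round_counts else x

    ctrl = draw(n, 1.0)
    trt = draw(n, spec.fold)
    width = len(str(n))
    sample_ids = [f"{ctrl_name}_{i + 1:0{width}d}" for i in range(n)] + [
        f"{trt_name}_{i + 1:0{width}d}" for i in range(n)
    ]
    values = np.vstack([ctrl, trt])
    abundance = AbundanceTable.from_arrays(sample_ids, leaf_labels, values)
    metadata = {sid: (ctrl_name if i < n else trt_name) for i, sid in enumerate(sample_ids)}
    return taxonomy, abundance, metadata


def target_node(spec: SyntheticSpec) -> str:
    """Node id of the planted-fold subtree for a given spec (tree is seed-determined)."""
    return _resolve_target(synth_tree(spec), spec)
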