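"""Preliminary clade inference for glucan-synthase sequence sets.

The workflow mirrors the classic distance-based preliminary step used to
assign GT2 sequences to sub-family clades before any likelihood phylogeny:
sequence-set refinement (insertion filter, one sequence per taxon),
pairwise Jukes--Cantor distances with pairwise gap deletion, UPGMA
agglomeration, and extraction of ``k`` clades from the resulting
ultrametric tree.

Jukes--Cantor is applied in its classic 4-state form by default, which is
what general-purpose alignment suites label "Jukes-Cantor" even for
proteins; a principled 20-state variant is available via ``n_states=20``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import SequenceRecord

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "UltrametricTree",
    "p_distance",
    "jc_distance",
    "distance_matrix",
    "upgma",
    "filter_insertions",
    "dedupe_taxa",
    "extract_clades",
]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances in substitutions/site."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape must match label count")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")


@dataclass(frozen=True)
class TreeNode:
    """Node of a rooted ultrametric tree; leaves sit at height 0."""

    height: float
    name: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]


@dataclass(frozen=True)
class UltrametricTree:
    """Rooted binary UPGMA tree with node heights."""

    root: TreeNode

    def __post_init__(self) -> None:
        def check(node: TreeNode) -> None:
            for child in node.children:
                if child.height > node.height + 1e-9:
                    raise ValueError("parent height must be >= child height")
                check(child)

        check(self.root)

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Proportion of mismatches over comparable sites (pairwise deletion).

    Sites where either sequence has a gap or ``X`` are excluded.  Returns
    ``(p, n_comparable)``.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    skip = {"-", "X"}
    comparable = 0
    mismatch = 0
    for ca, cb in zip(a.upper(), b.upper()):
        if ca in skip or cb in skip:
            continue
        comparable += 1
        if ca != cb:
            mismatch += 1
    if comparable == 0:
        raise ValueError("no comparable sites between sequences")
    return mismatch / comparable, comparable


def jc_distance(p: float, n_states: int = 4) -> float:
    """Jukes--Cantor correction of an observed mismatch fraction.

    ``d = -(b) ln(1 - p/b)`` with ``b = (n_states - 1)/n_states``; the
    classic nucleotide-style 4-state form (b = 3/4) is the default, with
    the 20-state protein variant (b = 19/20) selectable.
    """
    if n_states not in (4, 20):
        raise ValueError("n_states must be 4 or 20")
    b = (n_states - 1) / n_states
    if not 0 <= p <= 1:
        raise ValueError("p must be a fraction in [0, 1]")
    if p >= b:
        raise ValueError(f"saturated distance: p={p} at/above {b}")
    return -b * math.log(1.0 - p / b)


def distance_matrix(records: Sequence[SequenceRecord], n_states: int = 4) -> DistanceMatrix:
    """Jukes--Cantor distance matrix from aligned records."""
    labels = [r.id for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        p, _ = p_distance(records[i].residues, records[j].residues)
        d[i, j] = d[j, i] = jc_distance(p, n_states=n_states)
    return DistanceMatrix(labels=labels, d=d)


def upgma(m: DistanceMatrix) -> UltrametricTree:
    """Standard UPGMA agglomeration.

    Iteratively merges the minimum-distance cluster pair; inter-cluster
    distance is the size-weighted average, node height is half the merge
    distance.  Ties are broken by the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest leaf).
    """
    if len(m.labels) < 2:
        raise ValueError("UPGMA needs at least two labels")
    clusters: dict[str, tuple[TreeNode, int]] = {
        lab: (TreeNode(height=0.0, name=lab), 1) for lab in m.labels
    }
    dist: dict[frozenset[str], float] = {}
    for i, j in itertools.combinations(range(len(m.labels)), 2):
        dist[frozenset((m.labels[i], m.labels[j]))] = m.d[i, j]

    while len(clusters) > 1:
        best: tuple[float, str, str] | None = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d_ab = dist[frozenset((a, b))]
            cand = (d_ab, a, b)
            if best is None or cand < best:
                best = cand
        d_ab, a, b = best
        node_a, size_a = clusters.pop(a)
        node_b, size_b = clusters.pop(b)
        merged = TreeNode(height=d_ab / 2.0, children=(node_a, node_b))
        label = min(a, b)
        for other in clusters:
            d_new = (
                size_a * dist.pop(frozenset((a, other)))
                + size_b * dist.pop(frozenset((b, other)))
            ) / (size_a + size_b)
            dist[frozenset((label, other))] = d_new
        dist.pop(frozenset((a, b)))
        clusters[label] = (merged, size_a + size_b)

    (root, _), = clusters.values()
    return UltrametricTree(root=root)


@dataclass
class RemovalLog:
    """Ids removed by a refinement filter, with the reason."""

    removed: dict[str, str] = field(default_factory=dict)

    def __contains__(self, item: str) -> bool:
        return item in self.removed


def filter_insertions(
    records: Sequence[SequenceRecord],
    max_run: int = 10,
    rare_column_fraction: float = 0.1,
) -> tuple[list[SequenceRecord], RemovalLog]:
    """Drop sequences carrying long insertions relative to the alignment.

    A column is an *insert column* if fewer than ``rare_column_fraction``
    of sequences have a residue there.  A sequence is removed if more than
    ``max_run`` of its consecutive residues (strict ``>``) lie in insert
    columns.
    """
    if not records:
        return [], RemovalLog()
    lengths = {len(r) for r in records}
    if len(lengths) > 1:
        raise ValueError("records must be aligned")
    n = len(records)
    occupancy = np.zeros(lengths.pop(), dtype=int)
    for rec in records:
        occupancy += np.frombuffer(rec.residues.encode(), dtype=np.uint8) != ord("-")
    insert_col = occupancy / n < rare_column_fraction

    kept: list[SequenceRecord] = []
    log = RemovalLog()
    for rec in records:
        run = best_run = 0
        run_start = best_start = None
        for col, ch in enumerate(rec.residues):
            if ch == "-":
                continue  # gaps do not interrupt a residue run
            if insert_col[col]:
                if run == 0:
                    run_start = col
                run += 1
                if run > best_run:
                    best_run, best_start = run, run_start
            else:
                run = 0
        if best_run > max_run:
            log.removed[rec.id] = (
                f"insertion run of {best_run} residues starting at column {best_start}"
            )
        else:
            kept.append(rec)
    return kept, log


def dedupe_taxa(
    records: Sequence[SequenceRecord],
    taxon_of: Mapping[str, str],
) -> tuple[list[SequenceRecord], RemovalLog]:
    """Keep one record per taxon: the longest ungapped sequence, ties by id."""
    for rec in records:
        if rec.id not in taxon_of:
            raise ValueError(f"no taxon label for sequence {rec.id!r}")
    best: dict[str, SequenceRecord] = {}
    for rec in records:
        taxon = taxon_of[rec.id]
        incumbent = best.get(taxon)
        if incumbent is None or (-rec.ungapped_length, rec.id) < (
            -incumbent.ungapped_length,
            incumbent.id,
        ):
            best[taxon] = rec
    keep_ids = {rec.id for rec in best.values()}
    log = RemovalLog()
    kept = []
    for rec in records:
        if rec.id in keep_ids:
            kept.append(rec)
        else:
            log.removed[rec.id] = (
                f"taxon {taxon_of[rec.id]!r} already represented by a longer/earlier sequence"
            )
    return kept, log


def extract_clades(tree: UltrametricTree, k: int) -> dict[str, int]:
    """Cut an ultrametric tree into exactly ``k`` leaf groups.

    Groups are produced by repeatedly splitting the group whose root is
    highest until ``k`` groups exist; equal-height candidates are a tie
    (flagged via a warning) broken towards the node containing the
    lexicographically smallest leaf.  Clade indices are assigned by the
    alphabetical order of each clade's smallest leaf label.
    """
    leaves = tree.leaf_names
    if not 1 <= k <= len(leaves):
        raise ValueError(f"k must be between 1 and the leaf count ({len(leaves)})")
    groups: list[TreeNode] = [tree.root]
    while len(groups) < k:
        splittable = [g for g in groups if not g.is_leaf]
        heights = sorted({g.height for g in splittable}, reverse=True)
        top = [g for g in splittable if g.height == heights[0]]
        if len(top) > 1 or (len(heights) > 1 and np.isclose(heights[0], heights[1])):
            warnings.warn(
                "tie between candidate cut heights; splitting the higher/"
                "lexicographically earliest node",
                stacklevel=2,
            )
        target = min(top, key=lambda g: min(leaf.name for leaf in g.leaves()))
        groups.remove(target)
        groups.extend(target.children)
    ordered = sorted(groups, key=lambda g: min(leaf.name for leaf in g.leaves()))
    return {
        leaf.name: idx for idx, g in enumerate(ordered) for leaf in g.leaves()
    }
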