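"""Small helpers around Bio.Phylo for ultrametric species trees.

Branch lengths are in million years (MYA); trees are rooted and binary,
with all leaves at equal depth (ultrametric), so the divergence time of two
species is the age of their most recent common ancestor.
"""

from __future__ import annotations

import io
from typing import Iterable

import numpy as np
from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree


def random_ultrametric_tree(
    species: list[str], depth_mya: float, rng: np.random.Generator
) -> Tree:
    """Random rooted binary ultrametric tree over ``species``.

    Built by recursive random bipartition; every split node is placed at a
    random age strictly between its parent's age and zero, so all leaf
    depths equal ``depth_mya``.
    """
    if len(species) < 1:
        raise ValueError("need at least one species")

    def build(names: list[str], node_age: float) -> tuple[Clade, float]:
        if len(names) == 1:
            return Clade(name=names[0]), 0.0
        k = int(rng.integers(1, len(names)))
        idx = rng.permutation(len(names))
        halves = ([names[i] for i in idx[:k]], [names[i] for i in idx[k:]])
        node = Clade()
        for half in halves:
            child_age = float(node_age * rng.uniform(0.3, 0.9)) if len(half) > 1 else 0.0
            child, actual_age = build(half, child_age)
            child.branch_length = node_age - actual_age
            node.clades.append(child)
        return node, node_age

    root, _ = build(list(species), float(depth_mya))
    root.branch_length = 0.0
    return Tree(root=root, rooted=True)


def leaf_depths(tree: Tree) -> dict[str, float]:
    return {leaf.name: float(tree.distance(tree.root, leaf)) for leaf in tree.get_terminals()}


def tree_depth(tree: Tree) -> float:
    return max(leaf_depths(tree).values())


def divergence_times(tree: Tree) -> dict[tuple[str, str], float]:
    """Age of the MRCA for every unordered leaf pair (half the path length)."""
    leaves = tree.get_terminals()
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            t = float(tree.distance(a, b)) / 2.0
            out[(a.name, b.name)] = t
            out[(b.name, a.name)] = t
    return out


def iter_branches(tree: Tree) -> Iterable[tuple[Clade, Clade]]:
    """Yield (parent, child) over all branches, preorder."""
    for parent in tree.find_clades(order="preorder"):
        for child in parent.clades:
            yield parent, child


def to_newick(tree: Tree) -> str:
    buf = io.StringIO()
    Phylo.write(tree, buf, "newick")
    return buf.getvalue().strip()


def from_newick(text: str) -> Tree:
    return Phylo.read(io.StringIO(text), "newick")
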