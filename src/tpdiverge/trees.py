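"""Thin helpers over dendropy trees: Newick IO and path-length geometry.

All downstream algorithms (MAD rooting, Brownian-motion ancestral state
reconstruction) consume plain path-length information, computed here once
per tree: distances from every node to every tip.  Distances are a
property of the weighted tree graph and do not depend on where the tree
happens to be rooted.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np

NEWICK_PRECISION = ".10g"


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read one Newick tree from a file path or a literal newick string."""
    data = str(source)
    if not data.lstrip().startswith("("):
        data = Path(source).read_text()
    tree = dendropy.Tree.get(data=data, schema="newick",
                             preserve_underscores=True)
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialise to Newick with branch lengths at 10 significant digits."""
    text = tree.as_string(
        schema="newick",
        real_value_format_specifier=NEWICK_PRECISION,
        suppress_rooting=False,
    )
    if path is not None:
        Path(path).write_text(text)
    return text


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def is_rooted_bifurcating(tree: dendropy.Tree) -> bool:
    """True when the seed node has exactly two children (a genuine root)."""
    return len(tree.seed_node.child_nodes()) == 2


def deroot(tree: dendropy.Tree) -> dendropy.Tree:
    """Return an unrooted copy (root collapsed into a basal multifurcation)."""
    clone = tree.clone(depth=1)
    clone.deroot()
    clone.is_rooted = False
    return clone


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    return max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )


def _adjacency(tree: dendropy.Tree) -> dict:
    adj: dict = {}
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        w = edge.length if edge.length is not None else 0.0
        adj.setdefault(edge.tail_node, []).append((edge.head_node, w))
        adj.setdefault(edge.head_node, []).append((edge.tail_node, w))
    return adj


def node_tip_distances(tree: dendropy.Tree):
    """Path lengths from every node to every tip.

    Returns ``(labels, nodes, dist)`` where ``labels`` is the tip label
    list fixing column order, ``nodes`` lists all nodes, and ``dist`` maps
    ``id(node)`` to a float array of distances to each tip in order.
    """
    labels = tip_labels(tree)
    leaves = list(tree.leaf_node_iter())
    nodes = list(tree.preorder_node_iter())
    adj = _adjacency(tree)
    dist = {id(n): np.zeros(len(labels)) for n in nodes}
    for j, leaf in enumerate(leaves):
        seen = {id(leaf)}
        stack = [(leaf, 0.0)]
        while stack:
            node, d = stack.pop()
            dist[id(node)][j] = d
            for nbr, w in adj.get(node, ()):
                if id(nbr) not in seen:
                    seen.add(id(nbr))
                    stack.append((nbr, d + w))
    return labels, nodes, dist


def tip_distance_matrix(tree: dendropy.Tree):
    """Tip-to-tip path-length matrix, with the label order defining indices."""
    labels, nodes, dist = node_tip_distances(tree)
    leaves = [n for n in nodes if n.is_leaf()]
    order = {leaf.taxon.label: leaf for leaf in leaves}
    D = np.zeros((len(labels), len(labels)))
    for i, lab in enumerate(labels):
        D[i, :] = dist[id(order[lab])]
    return labels, D
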