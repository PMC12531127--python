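"""Minimal-ancestral-deviation (MAD) rooting.

A molecular-clock-free rooting criterion: the root is the point on the
tree at which implied ancestor–tip distances deviate least, in a relative
sense, from the clock expectation.  For a candidate root position rho on a
branch, every tip pair (b, c) whose connecting path crosses the root
implies that rho is their common ancestor; under a strict clock rho would
sit at the path midpoint, and the relative deviation of the pair is

    r_bc = | 2 * d(rho, c) / d(b, c)  -  1 |

(symmetric in b and c).  The branch score is the root-mean-square of
r_bc over all root-straddling tip pairs, minimised analytically over the
position on the branch (an ordinary least-squares problem, clipped to the
branch); the tree is rooted at the global minimiser over branches.  Ties
break toward the earliest branch in a preorder enumeration of the input.

The objective is scale-free: multiplying all branch lengths by a constant
changes no deviation, so the chosen root is invariant under uniform
rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .trees import is_rooted_bifurcating, node_tip_distances


@dataclass(frozen=True)
class MADResult:
    """A MAD-rooted tree plus the deviation score of the chosen root."""

    tree: dendropy.Tree
    score: float
    root_position: float  # distance of the root from the chosen edge's head node


def _branch_objective(d_head_c: np.ndarray, d_tail_b: np.ndarray, length: float):
    """Minimise the RMS pair deviation over the root position on one branch.

    ``d_head_c``: distances from the head (child-side) node to tips below
    the branch; ``d_tail_b``: distances from the tail node to tips above.
    Returns ``(score, x)`` with x the optimal distance of the root from the
    head node, clipped to [0, length].
    """
    # pairwise tip-tip distances through this branch
    d_bc = d_tail_b[:, None] + length + d_head_c[None, :]
    ok = d_bc > 0
    if not ok.any():
        return np.inf, 0.0
    a = np.where(ok, 2.0 * d_head_c[None, :] / np.where(ok, d_bc, 1.0) - 1.0, 0.0)
    k = np.where(ok, 2.0 / np.where(ok, d_bc, 1.0), 0.0)
    denom = float((k * k).sum())
    x = 0.0 if denom == 0 else float(-(a * k).sum() / denom)
    x = min(max(x, 0.0), length)
    r = a + k * x
    score = float(np.sqrt((r[ok] ** 2).mean()))
    return score, x


def mad_root(tree: dendropy.Tree) -> MADResult:
    """Root an unrooted tree by minimal ancestral deviation.

    Requires >= 3 tips and an unrooted input (use :func:`tpdiverge.trees.deroot`
    first if needed); branch lengths must be non-negative.
    """
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if n_tips < 3:
        raise ValueError("MAD rooting requires at least 3 tips")
    if tree.is_rooted and is_rooted_bifurcating(tree):
        raise ValueError("input tree is already rooted; deroot it first")

    work = tree.clone(depth=1)
    labels, _, dist = node_tip_distances(work)
    index = {lab: i for i, lab in enumerate(labels)}

    best = None  # (score, edge_order, edge, x)
    for order, edge in enumerate(work.preorder_edge_iter()):
        if edge.tail_node is None:
            continue
        length = edge.length if edge.length is not None else 0.0
        if length < 0:
            raise ValueError("negative branch length")
        below = [index[l.taxon.label] for l in edge.head_node.leaf_iter()]
        above = [i for i in range(len(labels)) if i not in set(below)]
        if not above or not below:
            continue
        d_head_c = dist[id(edge.head_node)][below]
        d_tail_b = dist[id(edge.tail_node)][above]
        score, x = _branch_objective(d_head_c, d_tail_b, length)
        if best is None or score < best[0]:
            best = (score, order, edge, x)

    if best is None:
        raise ValueError("no rootable branch found")
    score, _, edge, x = best
    length = edge.length if edge.length is not None else 0.0
    # split the winning edge at x from its head node and root there
    work.reroot_at_edge(edge, length1=length - x, length2=x,
                        update_bipartitions=False)
    work.is_rooted = True
    return MADResult(tree=work, score=score, root_position=x)
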