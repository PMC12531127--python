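"""Continuous-trait ancestral state reconstruction under Brownian motion.

The trait (a per-species mean of window net charge or phosphorylatable
count) is modelled as Brownian motion (BM) with rate sigma^2 along the
rooted tree: the covariance of two tips is sigma^2 times their shared
path length from the root.  Estimation is generalised least squares
(GLS) on that covariance:

* root state  a_hat = (1' S^-1 x) / (1' S^-1 1), with S the shared-path
  matrix and x the tip values;
* sigma^2 by maximum likelihood, (x - a_hat)' S^-1 (x - a_hat) / n
  (REML with divisor n-1 available by flag);
* each internal node's state by the re-rooting identity: the estimate at
  a node equals the GLS root estimate of the same tree re-rooted at that
  node, with variance sigma^2 / (1' S_a^-1 1).  This is the standard fast
  reconstruction convention; the shared-path matrix of the re-rooted tree
  is obtained purely from path lengths,
  S_a[i, j] = (d(a, i) + d(a, j) - d(i, j)) / 2.

Confidence intervals are mean +- 1.96 sqrt(var).  Zero-length branches
are inflated to a configurable epsilon (default 1e-8 x tree height)
before inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .trees import is_rooted_bifurcating, node_tip_distances, tree_height

Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class BMParams:
    sigma2: float
    root_state: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")


@dataclass(frozen=True)
class ASRNodeEstimate:
    node_id: str
    parent_id: str | None
    state_mean: float
    state_var: float
    ci95: tuple[float, float]
    is_tip: bool


def _label_nodes(tree: dendropy.Tree) -> dict[int, str]:
    """Stable ids: tip taxon labels; internal nodes numbered in preorder."""
    ids = {}
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            ids[id(node)] = node.taxon.label
        else:
            existing = node.label
            ids[id(node)] = existing if existing else f"node{counter}"
            counter += 1
    return ids


def asr_bm(
    tree: dendropy.Tree,
    traits: dict[str, float],
    reml: bool = False,
    zero_branch_epsilon: float | None = None,
) -> tuple[BMParams, list[ASRNodeEstimate]]:
    """Maximum-likelihood BM ancestral states on a rooted tree.

    ``traits`` maps tip labels to finite values and must cover every tip.
    Returns the fitted :class:`BMParams` and one :class:`ASRNodeEstimate`
    per node (tips carry their observation with zero variance).
    """
    if not (tree.is_rooted or is_rooted_bifurcating(tree)):
        raise ValueError("asr_bm requires a rooted tree")
    work = tree.clone(depth=1)

    height = tree_height(work)
    eps = zero_branch_epsilon
    if eps is None:
        eps = 1e-8 * (height if height > 0 else 1.0)
    for edge in work.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None or edge.length <= 0:
            edge.length = eps

    labels, nodes, dist = node_tip_distances(work)
    missing = [lab for lab in labels if lab not in traits]
    if missing:
        raise ValueError(f"missing trait values for tips: {missing}")
    x = np.array([float(traits[lab]) for lab in labels])
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite trait values")
    n = len(labels)

    leaves = {node.taxon.label: node for node in nodes if node.is_leaf()}
    D = np.vstack([dist[id(leaves[lab])] for lab in labels])
    ones = np.ones(n)

    def gls_at(node) -> tuple[float, float]:
        """GLS mean at *node* and the quadratic form 1' S_a^-1 1."""
        da = dist[id(node)]
        S = 0.5 * (da[:, None] + da[None, :] - D)
        try:
            Si1 = np.linalg.solve(S, ones)
            Six = np.linalg.solve(S, x)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular BM covariance matrix") from exc
        denom = float(ones @ Si1)
        return float(ones @ Six) / denom, denom

    root = work.seed_node
    root_state, root_denom = gls_at(root)
    d_root = dist[id(root)]
    S_root = 0.5 * (d_root[:, None] + d_root[None, :] - D)
    resid = x - root_state
    quad = float(resid @ np.linalg.solve(S_root, resid))
    sigma2 = quad / (n - 1 if reml else n)

    ids = _label_nodes(work)
    estimates = []
    for node in work.preorder_node_iter():
        parent = node.parent_node
        parent_id = ids[id(parent)] if parent is not None else None
        if node.is_leaf():
            value = float(traits[node.taxon.label])
            estimates.append(
                ASRNodeEstimate(ids[id(node)], parent_id, value, 0.0,
                                (value, value), True)
            )
        else:
            mean, denom = gls_at(node)
            var = sigma2 / denom
            half = Z95 * np.sqrt(var)
            estimates.append(
                ASRNodeEstimate(ids[id(node)], parent_id, mean, var,
                                (mean - half, mean + half), False)
            )
    return BMParams(sigma2=sigma2, root_state=root_state), estimates


def asr_table(estimates: list[ASRNodeEstimate]) -> pd.DataFrame:
    """Tidy per-node table of the reconstruction."""
    return pd.DataFrame(
        {
            "node": [e.node_id for e in estimates],
            "parent": [e.parent_id for e in estimates],
            "is_tip": [e.is_tip for e in estimates],
            "state_mean": [e.state_mean for e in estimates],
            "state_var": [e.state_var for e in estimates],
            "ci_low": [e.ci95[0] for e in estimates],
            "ci_high": [e.ci95[1] for e in estimates],
        }
    )


def welch_t(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t statistic and two-sided p-value.

    Degenerate zero-variance inputs fall back to the limit values
    (t = 0, p = 1 for equal means; p = 0 otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def ancestor_group_compare(groups: dict[str, list[float]]) -> pd.DataFrame:
    """Pairwise Welch comparisons of ancestor-state values between groups.

    ``groups`` maps a group name (e.g. a clade) to the collection of
    reconstructed ancestor means being compared.  Returns one row per
    unordered pair with the t statistic and two-sided p-value.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            t, p = welch_t(groups[g1], groups[g2])
            rows.append({"group1": g1, "group2": g2, "t": t, "p": p})
    return pd.DataFrame(rows)
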