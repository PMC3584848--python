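"""Independent reference implementations used only to check the package.

These deliberately avoid the package's optimized code paths: the clustering
oracle re-scans every active cluster pair and recomputes each linkage as a
direct mean over member pairs (O(n^3) per run), and the tree-score oracle
exhaustively enumerates every rooted clade.
"""

from __future__ import annotations

import numpy as np


def naive_average_linkage(values: np.ndarray, merge_cutoff: float = np.inf):
    """Direct agglomeration by full recomputation.

    Returns the merge log as a list of (left_node_id, right_node_id, score)
    with the same node-id convention as the package: leaves 0..n-1, new
    nodes numbered in merge order, ties broken on the lexicographically
    smallest (min id, max id) pair.
    """
    n = values.shape[0]
    clusters = {i: [i] for i in range(n)}  # node id -> leaf indices
    next_id = n
    log = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                pairs = [values[i, j] for i in clusters[a] for j in clusters[b]]
                score = sum(pairs) / len(pairs)
                key = (score, a, b)
                if best is None or key < best:
                    best = key
        score, a, b = best
        if score > merge_cutoff:
            break
        log.append((a, b, score))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return log


def exhaustive_tree_score(tree, species: str) -> float:
    """Min over all rooted clades containing every species leaf."""
    targets = {leaf.node_id for leaf in tree.leaves_of_species(species)}
    if not targets:
        raise ValueError(f"species {species!r} absent")

    def leaf_ids(nid):
        node = tree.node(nid)
        if node.is_leaf:
            return {nid}
        out = set()
        for c in node.children:
            out |= leaf_ids(c)
        return out

    best = None
    for nid in tree.clades():
        leaves = leaf_ids(nid)
        if targets <= leaves and (best is None or len(leaves) < best):
            best = len(leaves)
    return len(targets) / best
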