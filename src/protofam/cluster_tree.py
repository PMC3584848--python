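"""Agglomerative merge tree over a capped E-value matrix.

Clustering starts from singletons and repeatedly merges the two clusters
with the lowest linkage, where linkage(A, B) is the arithmetic mean of the
pairwise E-values over all inter-cluster protein pairs.  Two coordinates are
attached to every cluster:

* ProtoLevel (PL): 0 for singleton leaves, 100 at the final merge, linear in
  the merge index in between.  PL is the depth coordinate used to prune the
  hierarchy to family-granularity roots (PL <= 70 by default).
* LifeTime (LT): the number of merge steps a cluster survives between its
  creation and its absorption into a parent.  Clusters with LT >= 10 are the
  default "stable" set used for mapping.

Linkage is maintained through the exact Lance-Williams mean update on
accumulated pairwise sums, so every linkage equals the direct mean over
member pairs up to summation order.  Ties are broken on the lexicographically
smallest (min node id, max node id) pair, which makes trees bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .similarity import E_CAP, SimilarityMatrix


class Sentinel:
    """Named singleton used for out-of-band results (EXCLUDED, UNMAPPED)."""

    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return self._name


#: Returned by :func:`proroot` for nodes whose own PL exceeds the root cutoff;
#: such clusters sit too high in the hierarchy to anchor annotation inference.
EXCLUDED = Sentinel("EXCLUDED")


@dataclass
class ClusterNode:
    """One cluster of the merge hierarchy."""

    node_id: int
    members: frozenset
    children: tuple = ()
    birth_step: int = 0
    death_step: int | None = None  # None: survives to the end of the run
    parent: int | None = None
    pl: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class StabilityParams:
    """Pruning thresholds: LT >= lt_min for stable clusters, PL <= pl_root for roots."""

    lt_min: int = 10
    pl_root: float = 70.0
    merge_cutoff: float = E_CAP  # merge everything into one root by default

    def __post_init__(self) -> None:
        if not (0 < self.pl_root <= 100):
            raise ValueError(f"pl_root must be in (0, 100], got {self.pl_root}")
        if self.lt_min < 0:
            raise ValueError(f"lt_min must be >= 0, got {self.lt_min}")


@dataclass(frozen=True)
class MergeStep:
    step: int
    left: int
    right: int
    score: float
    new_node: int


class MergeTree:
    """The full agglomerative hierarchy plus its merge log."""

    def __init__(self, ids: Sequence[str], nodes: dict, merge_log: list) -> None:
        self.ids = list(ids)
        self.nodes = nodes
        self.merge_log = merge_log
        self.n_merges = len(merge_log)

    # -- basic access -------------------------------------------------------

    def node(self, node_id: int) -> ClusterNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}") from None

    @property
    def roots(self) -> list[int]:
        return [n.node_id for n in self.nodes.values() if n.parent is None]

    def leaf_node(self, protein_id: str) -> int:
        """Node id of a protein's singleton leaf (leaves are ids 0..n-1)."""
        try:
            return self.ids.index(protein_id)
        except ValueError:
            raise KeyError(f"unknown protein id {protein_id!r}") from None

    def ancestors(self, node_id: int) -> Iterator[int]:
        """Node ids strictly above ``node_id``, bottom-up."""
        cur = self.node(node_id)
        while cur.parent is not None:
            yield cur.parent
            cur = self.node(cur.parent)

    def lifetime(self, node_id: int) -> int:
        """Merge steps survived; surviving roots die at step n_merges + 1."""
        node = self.node(node_id)
        death = node.death_step if node.death_step is not None else self.n_merges + 1
        return death - node.birth_step

    # -- export -------------------------------------------------------------

    def node_table(self) -> pd.DataFrame:
        rows = []
        for node in sorted(self.nodes.values(), key=lambda n: n.node_id):
            rows.append(
                {
                    "node_id": node.node_id,
                    "birth_step": node.birth_step,
                    "death_step": node.death_step,
                    "pl": node.pl,
                    "lt": self.lifetime(node.node_id),
                    "size": node.size,
                    "parent": node.parent,
                    "members": ";".join(sorted(node.members)),
                }
            )
        return pd.DataFrame(rows)

    def to_newick(self) -> str:
        """Newick with internal labels ``nodeID|pl=..|lt=..``; one tree per root."""

        def render(nid: int) -> str:
            node = self.nodes[nid]
            if node.is_leaf:
                return next(iter(node.members))
            inner = ",".join(render(c) for c in node.children)
            pl = "NA" if node.pl is None else f"{node.pl:.4g}"
            # quoted so the |pl=..|lt=.. payload survives strict newick parsers
            return f"({inner})'{node.node_id}|pl={pl}|lt={self.lifetime(nid)}'"

        return "".join(render(r) + ";\n" for r in sorted(self.roots))

    def to_json_dict(self) -> dict:
        """Compact replayable form: protein ids plus the merge log."""
        return {
            "ids": self.ids,
            "merge_log": [
                [s.step, s.left, s.right, s.score, s.new_node] for s in self.merge_log
            ],
        }

    @classmethod
    def from_json_dict(cls, payload: dict) -> "MergeTree":
        ids = payload["ids"]
        nodes = {
            i: ClusterNode(node_id=i, members=frozenset({pid}))
            for i, pid in enumerate(ids)
        }
        merge_log = []
        for step, left, right, score, new_id in payload["merge_log"]:
            members = nodes[left].members | nodes[right].members
            nodes[new_id] = ClusterNode(
                node_id=new_id,
                members=members,
                children=(left, right),
                birth_step=step,
            )
            nodes[left].death_step = nodes[right].death_step = step
            nodes[left].parent = nodes[right].parent = new_id
            merge_log.append(MergeStep(step, left, right, score, new_id))
        tree = cls(ids, nodes, merge_log)
        assign_protolevel(tree)
        return tree


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_tree(m: SimilarityMatrix, params: StabilityParams | None = None) -> MergeTree:
    """Run average-linkage agglomeration on a similarity matrix.

    At each step the globally lowest-linkage active pair merges; on exact
    linkage ties the pair with the lexicographically smallest
    (min node id, max node id) wins.  Merging stops when the lowest linkage
    exceeds ``params.merge_cutoff`` (never, with the default cutoff at the
    cap), otherwise a single root remains.  ProtoLevels are assigned before
    returning.
    """
    params = params or StabilityParams()
    n = m.n
    if n < 2:
        raise ValueError("build_tree needs at least 2 proteins")
    if not np.array_equal(m.values, m.values.T):
        raise ValueError("similarity matrix is not symmetric")

    # slot state: slot i currently holds cluster `slot_node[i]`
    sums = m.values.astype(float).copy()  # pairwise E-value sums between slots
    np.fill_diagonal(sums, 0.0)
    sizes = np.ones(n, dtype=float)
    slot_node = list(range(n))
    active = np.ones(n, dtype=bool)

    linkage = sums.copy()  # mean E-value between slots
    inf = np.inf
    np.fill_diagonal(linkage, inf)

    nodes = {
        i: ClusterNode(node_id=i, members=frozenset({pid}))
        for i, pid in enumerate(m.ids)
    }
    merge_log: list[MergeStep] = []
    next_id = n
    step = 0
    n_active = n

    while n_active > 1:
        flat = np.argmin(linkage)
        i, j = divmod(int(flat), n)
        lo = linkage[i, j]
        if lo > params.merge_cutoff:
            break
        # resolve exact ties on the (min node id, max node id) pair
        ties = np.argwhere(linkage == lo)
        if len(ties) > 2:  # (i, j) and (j, i) are both present
            best = None
            for a, b in ties:
                if a >= b:
                    continue
                na, nb = slot_node[a], slot_node[b]
                key = (min(na, nb), max(na, nb))
                if best is None or key < best[0]:
                    best = (key, int(a), int(b))
            _, i, j = best
        else:
            i, j = (i, j) if i < j else (j, i)

        step += 1
        left, right = sorted((slot_node[i], slot_node[j]))
        new_members = nodes[left].members | nodes[right].members
        nodes[next_id] = ClusterNode(
            node_id=next_id,
            members=new_members,
            children=(left, right),
            birth_step=step,
        )
        for child in (left, right):
            nodes[child].death_step = step
            nodes[child].parent = next_id
        merge_log.append(MergeStep(step, left, right, float(lo), next_id))

        # exact Lance-Williams mean update on accumulated sums
        sums[i, :] += sums[j, :]
        sums[:, i] = sums[i, :]
        sizes[i] += sizes[j]
        slot_node[i] = next_id
        active[j] = False
        n_active -= 1
        next_id += 1

        linkage[i, :] = sums[i, :] / (sizes[i] * sizes)
        linkage[i, ~active] = inf
        linkage[i, i] = inf
        linkage[:, i] = linkage[i, :]
        linkage[j, :] = inf
        linkage[:, j] = inf

    tree = MergeTree(m.ids, nodes, merge_log)
    assign_protolevel(tree)
    return tree


def assign_protolevel(tree: MergeTree) -> MergeTree:
    """Set PL = 100 * birth_step / n_merges on every node (0 for singletons)."""
    denom = tree.n_merges
    for node in tree.nodes.values():
        node.pl = 0.0 if denom == 0 else 100.0 * node.birth_step / denom
    return tree


def lifetime(tree: MergeTree, node_id: int) -> int:
    """Stability of a cluster in merge steps (see :meth:`MergeTree.lifetime`)."""
    return tree.lifetime(node_id)


def stable_clusters(
    tree: MergeTree,
    params: StabilityParams | None = None,
    include_singletons: bool = False,
) -> set:
    """Node ids with LifeTime >= ``params.lt_min``.

    By default only merged clusters (size >= 2) are considered: a cluster is
    something the agglomeration created, so at LT = 0 the stable set is the
    full binary hierarchy with about as many clusters as proteins.  Pass
    ``include_singletons=True`` to let long-lived leaves qualify as well.
    An empty result (an impossible threshold) raises a warning, not an error.
    """
    params = params or StabilityParams()
    stable = {
        nid
        for nid, node in tree.nodes.items()
        if (include_singletons or not node.is_leaf)
        and tree.lifetime(nid) >= params.lt_min
    }
    if not stable:
        warnings.warn(
            f"no stable clusters at lt_min={params.lt_min}", stacklevel=2
        )
    return stable


def proroot(tree: MergeTree, node_id: int, pl_root: float = 70.0):
    """Climb to the highest ancestor-or-self with PL <= ``pl_root``.

    Returns :data:`EXCLUDED` when the node itself already sits above the
    cutoff; such clusters are dropped from the annotation scheme.
    """
    node = tree.node(node_id)
    if node.pl is None:
        raise ValueError("ProtoLevels not assigned; call assign_protolevel first")
    if node.pl > pl_root:
        return EXCLUDED
    cur = node
    while cur.parent is not None and tree.node(cur.parent).pl <= pl_root:
        cur = tree.node(cur.parent)
    return cur.node_id
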