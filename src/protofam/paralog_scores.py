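"""Paralog identification and the divergence / imbalance statistics.

Paralogs are two or more proteins of one species mapped to the same
cluster.  Three statistics summarize them:

* Tree Score (TS): on a guide tree over a cluster's proteins, the number of
  species-of-interest leaves divided by the leaf count of the smallest
  rooted clade containing all of them.  TS = 1 means the species forms a
  pure clade (recent, low-divergence duplications); small TS means the
  paralogs intermix with other proteins.
* Taxonomy Balance (TB): within a shared root, the ratio of one species'
  protein count to a reference species' count; extremes (>= 10, <= 0.1)
  flag lineage-specific amplification.
* Amplification ratio: proteins of the species under a root divided by the
  number of distinct stable clusters they occupy; large values indicate
  recent duplication blocks that merged in few steps.

Guide trees are built with UPGMA under a deterministic lowest-id tie-break.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .cluster_tree import Sentinel
from .mapping import MappingResult

#: Taxonomy balance when one of the two species is absent from the root.
UNDEFINED = Sentinel("UNDEFINED")


# ---------------------------------------------------------------------------
# Paralog counting
# ---------------------------------------------------------------------------

@dataclass
class ParalogReport:
    """Clusters holding >= min_count proteins of one species, plus size buckets."""

    level: str
    min_count: int
    clusters: list  # (cluster_id, count), descending count
    buckets: dict

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_proteins(self) -> int:
        return sum(c for _, c in self.clusters)


def find_paralogs(
    mapping: MappingResult,
    level: str = "map",
    min_count: int = 2,
) -> ParalogReport:
    """Count the query species' proteins per cluster at the chosen level.

    ``level`` is ``"map"`` (best stable clusters) or ``"root"`` (lifted
    ProRoots).  Buckets report the >= 10 and > 20 paralog strata alongside
    the basic >= min_count count.
    """
    if level not in ("map", "root"):
        raise ValueError(f"level must be 'map' or 'root', got {level!r}")
    counts: dict = {}
    for a in mapping:
        if not a.is_mapped:
            continue
        key = a.cluster if level == "map" else a.root
        if level == "root" and a.is_excluded:
            continue
        counts[key] = counts.get(key, 0) + 1
    clusters = sorted(
        ((c, n) for c, n in counts.items() if n >= min_count),
        key=lambda t: (-t[1], t[0]),
    )
    buckets = {
        f">={min_count}": len(clusters),
        ">=10": sum(1 for _, n in clusters if n >= 10),
        ">20": sum(1 for _, n in clusters if n > 20),
    }
    return ParalogReport(level, min_count, clusters, buckets)


# ---------------------------------------------------------------------------
# Guide trees (UPGMA)
# ---------------------------------------------------------------------------

@dataclass
class GuideNode:
    node_id: int
    children: tuple = ()
    parent: int | None = None
    name: str | None = None
    species: str | None = None
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children


class GuideTree:
    """Rooted binary leaf-labeled tree over one cluster's proteins."""

    def __init__(self, nodes: dict, root_id: int) -> None:
        self.nodes = nodes
        self.root_id = root_id
        self._leafcount: dict = {}
        self._depth: dict = {}
        self._annotate(root_id, 0)

    def _annotate(self, nid: int, depth: int) -> int:
        self._depth[nid] = depth
        node = self.nodes[nid]
        if node.is_leaf:
            self._leafcount[nid] = 1
        else:
            self._leafcount[nid] = sum(
                self._annotate(c, depth + 1) for c in node.children
            )
        return self._leafcount[nid]

    def node(self, nid: int) -> GuideNode:
        return self.nodes[nid]

    def leaves(self) -> list:
        return [n for n in self.nodes.values() if n.is_leaf]

    def leaves_of_species(self, species: str) -> list:
        return [n for n in self.leaves() if n.species == species]

    def subtree_leaf_count(self, nid: int) -> int:
        return self._leafcount[nid]

    def lca(self, node_ids: Sequence[int]) -> int:
        """Lowest common ancestor of a non-empty set of nodes."""
        if not node_ids:
            raise ValueError("lca of an empty node set")
        cur = node_ids[0]
        for other in node_ids[1:]:
            a, b = cur, other
            while self._depth[a] > self._depth[b]:
                a = self.nodes[a].parent
            while self._depth[b] > self._depth[a]:
                b = self.nodes[b].parent
            while a != b:
                a, b = self.nodes[a].parent, self.nodes[b].parent
            cur = a
        return cur

    def clades(self) -> Iterable[int]:
        """All rooted clades = every node (leaf or internal) with its descendants."""
        return self.nodes.keys()

    # -- Newick I/O ---------------------------------------------------------

    def to_newick(self) -> str:
        # branch lengths derived from the ultrametric merge heights
        def render_len(nid: int) -> str:
            node = self.nodes[nid]
            body = (
                (node.name or f"L{nid}")
                if node.is_leaf
                else "(" + ",".join(render_len(c) for c in node.children) + ")"
            )
            if node.parent is None:
                return body
            length = max(self.nodes[node.parent].height - node.height, 0.0)
            return f"{body}:{length:.6g}"

        return render_len(self.root_id) + ";"

    @classmethod
    def from_newick(cls, text: str, species: Mapping[str, str] | None = None) -> "GuideTree":
        """Parse a rooted binary Newick tree (via dendropy)."""
        dtree = dendropy.Tree.get(data=text, schema="newick")
        nodes: dict = {}
        counter = itertools.count()

        def convert(dnode) -> int:
            children = [convert(c) for c in dnode.child_nodes()]
            nid = next(counter)
            if children and len(children) != 2:
                raise ValueError("guide tree must be binary")
            name = dnode.taxon.label if dnode.taxon else None
            nodes[nid] = GuideNode(
                node_id=nid,
                children=tuple(children),
                name=name,
                species=(species or {}).get(name) if name else None,
            )
            for c in children:
                nodes[c].parent = nid
            return nid

        root = convert(dtree.seed_node)
        return cls(nodes, root)


def build_guide_tree(
    d: np.ndarray,
    labels: Sequence[str],
    species: Mapping[str, str] | None = None,
) -> GuideTree:
    """UPGMA on a symmetric distance matrix with deterministic tie-breaks.

    On equal mean distances the pair with the lexicographically smallest
    (min cluster id, max cluster id) merges first, where leaves take ids
    0..n-1 in label order and internal nodes take ids in creation order.
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if n < 2:
        raise ValueError("guide tree needs at least 2 leaves")
    if d.shape != (n, n):
        raise ValueError(f"distance matrix shape {d.shape} does not match {n} labels")
    if not np.array_equal(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    if np.any(d < 0) or np.any(np.diag(d) != 0):
        raise ValueError("distances must be non-negative with a zero diagonal")

    nodes = {
        i: GuideNode(
            node_id=i, name=labels[i], species=(species or {}).get(labels[i])
        )
        for i in range(n)
    }
    sums = d.copy()
    sizes = np.ones(n)
    slot_node = list(range(n))
    active = np.ones(n, dtype=bool)
    dist = sums.copy()
    np.fill_diagonal(dist, np.inf)
    next_id = n
    n_active = n
    while n_active > 1:
        flat = np.argmin(dist)
        i, j = divmod(int(flat), n)
        lo = dist[i, j]
        ties = np.argwhere(dist == lo)
        best = None
        for a, b in ties:
            if a >= b:
                continue
            na, nb = slot_node[a], slot_node[b]
            key = (min(na, nb), max(na, nb))
            if best is None or key < best[0]:
                best = (key, int(a), int(b))
        _, i, j = best
        left, right = sorted((slot_node[i], slot_node[j]))
        nodes[next_id] = GuideNode(
            node_id=next_id, children=(left, right), height=lo / 2.0
        )
        nodes[left].parent = nodes[right].parent = next_id
        sums[i, :] += sums[j, :]
        sums[:, i] = sums[i, :]
        sizes[i] += sizes[j]
        slot_node[i] = next_id
        active[j] = False
        n_active -= 1
        next_id += 1
        dist[i, :] = sums[i, :] / (sizes[i] * sizes)
        dist[i, ~active] = np.inf
        dist[i, i] = np.inf
        dist[:, i] = dist[i, :]
        dist[j, :] = np.inf
        dist[:, j] = np.inf
    return GuideTree(nodes, next_id - 1)


# ---------------------------------------------------------------------------
# Tree Score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeScoreResult:
    species: str
    d_count: int
    min_subtree_leaves: int
    ts: float


def tree_score(tree: GuideTree, species_of_interest: str) -> TreeScoreResult:
    """TS = |D| / leaves(smallest rooted clade containing all of D).

    D is the set of leaves of the species of interest; the smallest such
    clade is the one rooted at their lowest common ancestor.  Errors when
    the species is absent from the tree.
    """
    d_leaves = tree.leaves_of_species(species_of_interest)
    if not d_leaves:
        raise ValueError(f"species {species_of_interest!r} absent from the guide tree")
    lca = tree.lca([leaf.node_id for leaf in d_leaves])
    min_leaves = tree.subtree_leaf_count(lca)
    return TreeScoreResult(
        species=species_of_interest,
        d_count=len(d_leaves),
        min_subtree_leaves=min_leaves,
        ts=len(d_leaves) / min_leaves,
    )


def ts_summary(
    entries: Iterable[tuple],
    strata: Sequence[tuple] = ((2, 2), (3, 9), (10, None)),
    bin_width: float = 0.1,
    divergence_cutoff: float = 0.2,
) -> dict:
    """Histogram of TS values partitioned by paralog-count strata.

    ``entries`` yields ``(n_paralogs, ts)`` pairs.  Bins cover [0, 1] with
    the given width (the last bin is closed at 1.0); the summary reports the
    fraction of clusters below the high-divergence cutoff.
    """
    n_bins = int(round(1.0 / bin_width))
    edges = [i * bin_width for i in range(n_bins + 1)]

    def stratum_name(lo, hi):
        if hi is None:
            return f">={lo}"
        return str(lo) if lo == hi else f"{lo}-{hi}"

    hists = {stratum_name(lo, hi): [0] * n_bins for lo, hi in strata}
    total = 0
    below = 0
    for count, ts in entries:
        if not (0.0 < ts <= 1.0):
            raise ValueError(f"tree score {ts} outside (0, 1]")
        total += 1
        if ts < divergence_cutoff:
            below += 1
        b = min(int(ts / bin_width), n_bins - 1)
        for lo, hi in strata:
            if count >= lo and (hi is None or count <= hi):
                hists[stratum_name(lo, hi)][b] += 1
    return {
        "bin_edges": edges,
        "strata": hists,
        "n_clusters": total,
        "divergence_cutoff": divergence_cutoff,
        "fraction_high_divergence": below / total if total else 0.0,
    }


# ---------------------------------------------------------------------------
# Taxonomy Balance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonomyBalance:
    cluster: object
    count_a: int
    count_b: int
    tb: Fraction  # exact ratio, so the inversion identity tb_ab * tb_ba == 1 holds
    log2_tb: float


def taxonomy_balance(count_a: int, count_b: int, cluster=None):
    """TB = count_a / count_b; :data:`UNDEFINED` unless both counts >= 1.

    The ratio is kept as an exact fraction of the two integer counts;
    ``float(result.tb)`` gives the usual real value.
    """
    if count_a < 1 or count_b < 1:
        return UNDEFINED
    tb = Fraction(int(count_a), int(count_b))
    return TaxonomyBalance(cluster, count_a, count_b, tb, math.log2(tb))


def taxonomy_balance_table(
    mappings: Mapping[str, MappingResult],
    species_a: str,
    species_b: str,
    high: float = 10.0,
    low: float = 0.1,
) -> dict:
    """Per-root TB for roots shared by both species, plus the extreme lists."""
    counts: dict = {}
    for sp in (species_a, species_b):
        for a in mappings[sp]:
            if not a.is_mapped or a.is_excluded:
                continue
            counts.setdefault(a.root, {species_a: 0, species_b: 0})[sp] += 1
    rows = []
    for root in sorted(counts, key=str):
        res = taxonomy_balance(
            counts[root][species_a], counts[root][species_b], cluster=root
        )
        if res is UNDEFINED:
            continue
        rows.append(res)
    frame = pd.DataFrame(
        [
            {
                "root": r.cluster,
                f"n_{species_a}": r.count_a,
                f"n_{species_b}": r.count_b,
                "tb": float(r.tb),
                "log2_tb": r.log2_tb,
            }
            for r in rows
        ]
    )
    return {
        "table": frame,
        "n_shared_roots": len(rows),
        "high_extremes": [r.cluster for r in rows if r.tb >= high],
        "low_extremes": [r.cluster for r in rows if r.tb <= low],
        "high_threshold": high,
        "low_threshold": low,
    }


# ---------------------------------------------------------------------------
# Amplification ratio
# ---------------------------------------------------------------------------

def amplification_ratio(n_proteins: int, n_map_clusters: int) -> float:
    """Proteins under a root / distinct stable clusters they occupy.

    Reported rounded half-up to 2 decimals, matching the printed precision
    of the published ratio tables.  Errors when no stable cluster holds any
    of the proteins.
    """
    if n_map_clusters < 1:
        raise ValueError("amplification ratio undefined: zero stable clusters")
    if n_proteins < n_map_clusters:
        raise ValueError(
            "fewer proteins than clusters: every stable cluster holds at least one"
        )
    ratio = Decimal(n_proteins) / Decimal(n_map_clusters)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def amplification_table(mapping: MappingResult) -> pd.DataFrame:
    """Per-root paralog counts, distinct stable-cluster counts and their ratio,
    sorted by descending paralog count (the layout of the published table)."""
    per_root: dict = {}
    for a in mapping:
        if not a.is_mapped or a.is_excluded:
            continue
        entry = per_root.setdefault(a.root, {"n_proteins": 0, "clusters": set()})
        entry["n_proteins"] += 1
        entry["clusters"].add(a.cluster)
    rows = [
        {
            "root": root,
            "n_proteins": e["n_proteins"],
            "n_map_clusters": len(e["clusters"]),
            "ratio": amplification_ratio(e["n_proteins"], len(e["clusters"])),
        }
        for root, e in per_root.items()
    ]
    frame = pd.DataFrame(
        rows, columns=["root", "n_proteins", "n_map_clusters", "ratio"]
    )
    return frame.sort_values(
        ["n_proteins", "root"], ascending=[False, True], ignore_index=True
    )
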