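"""Mapping query proteins onto the stable clusters of a frozen merge tree.

A query is eligible for a stable cluster when the mean capped E-value
between the query and the cluster's members falls below ``tau_map``; among
eligible clusters the minimal-sized one wins (ties: lower score, then lower
node id).  The chosen cluster is then lifted to its PL <= 70 ancestor (its
"ProRoot"), which is the family granularity used for annotation and the
cross-species statistics.  Queries never alter the frozen hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster_tree import EXCLUDED, MergeTree, Sentinel, StabilityParams, proroot
from .similarity import E_CAP, ProteinRecord, SimilarityMatrix, surrogate_evalue

#: Returned when no stable cluster is eligible for a query.
UNMAPPED = Sentinel("UNMAPPED")


@dataclass(frozen=True)
class ProteinMapping:
    """Assignment of one query: best stable cluster and its lifted root."""

    protein_id: str
    cluster: object  # node id or UNMAPPED
    score: float
    root: object  # node id, EXCLUDED, or None when unmapped

    @property
    def is_mapped(self) -> bool:
        return self.cluster is not UNMAPPED

    @property
    def is_excluded(self) -> bool:
        return self.root is EXCLUDED

    @property
    def status(self) -> str:
        if not self.is_mapped:
            return "unmapped"
        return "excluded" if self.is_excluded else "mapped"


@dataclass
class MappingResult:
    """Per-protein assignments plus summary counts for one query proteome."""

    assignments: dict  # protein_id -> ProteinMapping, insertion-ordered
    summary: dict

    def __getitem__(self, protein_id: str) -> ProteinMapping:
        return self.assignments[protein_id]

    def __iter__(self):
        return iter(self.assignments.values())

    def __len__(self) -> int:
        return len(self.assignments)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": a.protein_id,
                "status": a.status,
                "map_cluster": a.cluster if a.is_mapped else "UNMAPPED",
                "map_score": a.score,
                "root": (
                    "EXCLUDED"
                    if a.is_excluded
                    else (a.root if a.is_mapped else "NA")
                ),
            }
            for a in self
        ]
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _as_row(query_scores, m_ids: Sequence[str], index: Mapping[str, int], cap: float) -> np.ndarray:
    if isinstance(query_scores, np.ndarray):
        if query_scores.shape != (len(m_ids),):
            raise ValueError(
                f"query score vector of length {query_scores.shape} does not "
                f"match {len(m_ids)} tree proteins"
            )
        return np.minimum(query_scores.astype(float), cap)
    row = np.full(len(m_ids), cap, dtype=float)
    for pid, ev in query_scores.items():
        row[index[pid]] = min(float(ev), cap)
    return row


def map_protein(
    query_scores,
    tree: MergeTree,
    stable_set: set,
    tau_map: float = 1.0,
    prefer: str = "size",
    cap: float = E_CAP,
    _cluster_index: dict | None = None,
):
    """Map one query onto its best stable cluster.

    ``query_scores`` is either a dict ``tree_protein_id -> evalue`` (missing
    pairs read as the cap) or a vector aligned with ``tree.ids``.  Returns
    ``(node_id, score)`` or ``(UNMAPPED, nan)``.  ``prefer`` selects the
    ordering among eligible clusters: ``"size"`` (minimal-sized first, the
    default) or ``"score"`` (best mean E-value first).
    """
    if not stable_set:
        raise ValueError("empty stable cluster set")
    if prefer not in ("size", "score"):
        raise ValueError(f"prefer must be 'size' or 'score', got {prefer!r}")
    index = {pid: i for i, pid in enumerate(tree.ids)}
    row = _as_row(query_scores, tree.ids, index, cap)
    if _cluster_index is None:
        _cluster_index = {
            nid: np.fromiter(
                (index[pid] for pid in tree.node(nid).members), dtype=int
            )
            for nid in sorted(stable_set)
        }
    best = None
    for nid, idx in _cluster_index.items():
        score = float(row[idx].mean())
        if score >= tau_map:
            continue
        key = (
            (len(idx), score, nid) if prefer == "size" else (score, len(idx), nid)
        )
        if best is None or key < best[0]:
            best = (key, nid, score)
    if best is None:
        return UNMAPPED, float("nan")
    return best[1], best[2]


def map_proteome(
    query_rows: Mapping[str, object],
    tree: MergeTree,
    stable_set: set,
    params: StabilityParams | None = None,
    tau_map: float = 1.0,
    prefer: str = "size",
    cap: float = E_CAP,
) -> MappingResult:
    """Map every query of ``query_rows`` (id -> score row) and lift to ProRoots."""
    params = params or StabilityParams()
    index = {pid: i for i, pid in enumerate(tree.ids)}
    cluster_index = {
        nid: np.fromiter((index[pid] for pid in tree.node(nid).members), dtype=int)
        for nid in sorted(stable_set)
    }
    assignments = {}
    for qid, scores in query_rows.items():
        cluster, score = map_protein(
            scores,
            tree,
            stable_set,
            tau_map=tau_map,
            prefer=prefer,
            cap=cap,
            _cluster_index=cluster_index,
        )
        root = (
            proroot(tree, cluster, params.pl_root) if cluster is not UNMAPPED else None
        )
        assignments[qid] = ProteinMapping(qid, cluster, score, root)
    n = len(assignments)
    n_unmapped = sum(1 for a in assignments.values() if not a.is_mapped)
    n_excluded = sum(1 for a in assignments.values() if a.is_excluded)
    n_mapped = n - n_unmapped
    summary = {
        "n_queries": n,
        "n_mapped": n_mapped,
        "n_unmapped": n_unmapped,
        "n_excluded": n_excluded,
        "fraction_mapped": n_mapped / n if n else 0.0,
        "fraction_unmapped": n_unmapped / n if n else 0.0,
        "fraction_excluded": n_excluded / n if n else 0.0,
    }
    return MappingResult(assignments, summary)


# ---------------------------------------------------------------------------
# Query row helpers
# ---------------------------------------------------------------------------

def self_query_rows(m: SimilarityMatrix, ids: Sequence[str] | None = None) -> dict:
    """Score rows for queries that are themselves members of the scored set."""
    return {pid: m.row(pid) for pid in (ids if ids is not None else m.ids)}


def score_query_rows(
    queries: Sequence[ProteinRecord],
    tree_proteome: Sequence[ProteinRecord],
    scorer=None,
    cap: float = E_CAP,
    **scorer_kwargs,
) -> dict:
    """Score external query sequences against the tree proteome.

    Uses the deterministic k-mer surrogate by default; any symmetric
    ``scorer(a, b) -> evalue`` can be substituted.
    """
    if scorer is None:
        def scorer(a, b):  # noqa: ANN001
            return surrogate_evalue(a, b, cap=cap, **scorer_kwargs)
    rows = {}
    for q in queries:
        rows[q.id] = np.array(
            [min(float(scorer(q, t)), cap) for t in tree_proteome], dtype=float
        )
    return rows


# ---------------------------------------------------------------------------
# Venn partition over three species
# ---------------------------------------------------------------------------

def venn_partition(
    mappings: Mapping[str, MappingResult],
    species: Sequence[str],
    allow_any_arity: bool = False,
) -> dict:
    """Partition occupied roots (and proteins) across species co-occupancy regions.

    Root-based view: each root occupied by at least one mapped, non-excluded
    protein is assigned to the region of species present in it.  Protein-based
    view: each protein counts in the region of its root.  Designed for the
    3-way comparison; pass ``allow_any_arity=True`` to generalize.
    """
    species = list(species)
    if len(species) != 3 and not allow_any_arity:
        raise ValueError(
            f"venn_partition expects exactly 3 species, got {len(species)} "
            "(pass allow_any_arity=True to generalize)"
        )
    if set(species) - set(mappings):
        missing = sorted(set(species) - set(mappings))
        raise ValueError(f"no mapping result for species {missing!r}")

    occupancy: dict = {}
    for sp in species:
        for a in mappings[sp]:
            if not a.is_mapped or a.is_excluded:
                continue
            occupancy.setdefault(a.root, {s: 0 for s in species})[sp] += 1

    regions = {}
    for r in range(1, 2 ** len(species)):
        present = tuple(sp for k, sp in enumerate(species) if r >> k & 1)
        regions["&".join(present)] = {
            "roots": 0,
            "proteins": {sp: 0 for sp in present},
        }
    for root, counts in occupancy.items():
        present = tuple(sp for sp in species if counts[sp] > 0)
        region = regions["&".join(present)]
        region["roots"] += 1
        for sp in present:
            region["proteins"][sp] += counts[sp]
    return regions
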