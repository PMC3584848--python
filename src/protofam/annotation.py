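"""Annotation transfer from cluster term statistics.

Each cluster is scored against every annotation term carried by its
members: the Correspondence Score (CS) is the intersection-over-union of
the cluster's member set and the term's carrier set, and the specificity
(purity) is the fraction of cluster members carrying the term.  Per
annotation source, the non-blacklisted term with the highest CS among
those with specificity >= 0.2 becomes part of the cluster's composed
"ProtoName", provided the cluster holds at least 5 proteins.  A mapped
protein inherits the ProtoName terms of its cluster and of every ancestor
up to and including its ProRoot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cluster_tree import ClusterNode, MergeTree, proroot
from .mapping import MappingResult, ProteinMapping

#: Term labels too generic to describe a family; matched case-insensitively
#: as substrings at load time and again at selection time.
DEFAULT_BLACKLIST = ("complete proteome", "taxonomy", "hypothetical protein")

_COLUMNS = ["protein_id", "source", "term_id", "term_label"]


def _blacklisted(label: str, blacklist: Sequence[str]) -> bool:
    low = label.lower()
    return any(b.lower() in low for b in blacklist)


@dataclass
class AnnotationDB:
    """Flat (protein, source, term) triples over an analysis universe."""

    frame: pd.DataFrame
    universe: frozenset

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"annotation table lacks columns {missing}")
        if self.frame.duplicated(["protein_id", "source", "term_id"]).any():
            raise ValueError("duplicate (protein, source, term) triples")
        unknown = set(self.frame["protein_id"]) - set(self.universe)
        if unknown:
            raise ValueError(
                f"annotation rows for proteins outside the universe: {sorted(unknown)[:5]}"
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        universe: Iterable[str],
        blacklist: Sequence[str] = DEFAULT_BLACKLIST,
    ) -> "AnnotationDB":
        frame = pd.DataFrame(list(records) or None, columns=_COLUMNS)
        if not frame.empty:
            keep = ~frame["term_label"].map(
                lambda s: _blacklisted(s, blacklist)
            ).astype(bool)
            frame = frame[keep]
        frame = frame.drop_duplicates(["protein_id", "source", "term_id"])
        return cls(frame.reset_index(drop=True), frozenset(universe))

    @classmethod
    def load(
        cls,
        path,
        universe: Iterable[str],
        blacklist: Sequence[str] = DEFAULT_BLACKLIST,
    ) -> "AnnotationDB":
        """Read a 4-column tab-separated table (``#`` comments allowed)."""
        frame = pd.read_csv(
            path, sep="\t", comment="#", names=_COLUMNS, dtype=str, header=None,
            skip_blank_lines=True,
        )
        return cls.from_records(
            frame.itertuples(index=False, name=None), universe, blacklist
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# " + "\t".join(_COLUMNS) + "\n")
            self.frame.to_csv(fh, sep="\t", index=False, header=False)

    def term_members(self, source: str, term_id: str) -> frozenset:
        sel = self.frame[
            (self.frame["source"] == source) & (self.frame["term_id"] == term_id)
        ]
        return frozenset(sel["protein_id"])

    def terms_touching(self, members: frozenset) -> pd.DataFrame:
        """Distinct (source, term_id, term_label) carried by any of ``members``."""
        sel = self.frame[self.frame["protein_id"].isin(members)]
        return sel[["source", "term_id", "term_label"]].drop_duplicates()

    @property
    def sources(self) -> list[str]:
        return sorted(self.frame["source"].unique())


# ---------------------------------------------------------------------------
# Per-term cluster statistics
# ---------------------------------------------------------------------------

def correspondence_score(cluster_members: frozenset, term_members: frozenset) -> float:
    """Intersection-over-union of a cluster's member set and a term's carriers."""
    if not cluster_members:
        raise ValueError("empty cluster")
    inter = len(cluster_members & term_members)
    union = len(cluster_members | term_members)
    return inter / union


def specificity(cluster_members: frozenset, term_members: frozenset) -> float:
    """Fraction of cluster members carrying the term (cluster purity)."""
    if not cluster_members:
        raise ValueError("empty cluster")
    return len(cluster_members & term_members) / len(cluster_members)


@dataclass(frozen=True)
class ClusterTerm:
    source: str
    term_id: str
    term_label: str
    n_intersect: int
    cs: float
    specificity: float


@dataclass(frozen=True)
class ProtoName:
    """The per-source best terms describing one cluster."""

    node_id: int
    terms: tuple  # ClusterTerm per source, source-sorted

    @property
    def label(self) -> str:
        return "; ".join(t.term_label for t in self.terms)

    def term_keys(self) -> set:
        return {(t.source, t.term_id) for t in self.terms}


def protoname(
    node: ClusterNode,
    db: AnnotationDB,
    min_size: int = 5,
    min_spec: float = 0.2,
    blacklist: Sequence[str] = DEFAULT_BLACKLIST,
) -> ProtoName | None:
    """Select the composed ProtoName of a cluster, or ``None``.

    Clusters below ``min_size`` are never named.  Per source, candidate
    terms must clear the specificity filter and the blacklist before CS
    ranking; ties break on larger intersection, then lexicographic term id.
    """
    members = node.members
    if len(members) < min_size:
        return None
    candidates = db.terms_touching(members)
    best_per_source: dict = {}
    for source, term_id, term_label in candidates.itertuples(index=False, name=None):
        if _blacklisted(term_label, blacklist):
            continue
        carriers = db.term_members(source, term_id)
        spec = specificity(members, carriers)
        if spec < min_spec:
            continue
        cs = correspondence_score(members, carriers)
        entry = ClusterTerm(
            source, term_id, term_label, len(members & carriers), cs, spec
        )
        incumbent = best_per_source.get(source)
        if incumbent is None or (
            (-entry.cs, -entry.n_intersect, entry.term_id)
            < (-incumbent.cs, -incumbent.n_intersect, incumbent.term_id)
        ):
            best_per_source[source] = entry
    if not best_per_source:
        return None
    terms = tuple(best_per_source[s] for s in sorted(best_per_source))
    return ProtoName(node.node_id, terms)


def protonames_for_tree(
    tree: MergeTree,
    db: AnnotationDB,
    node_ids: Iterable[int] | None = None,
    min_size: int = 5,
    min_spec: float = 0.2,
    blacklist: Sequence[str] = DEFAULT_BLACKLIST,
) -> dict:
    """ProtoNames for the requested nodes (all nodes by default); NONEs omitted."""
    out = {}
    for nid in tree.nodes if node_ids is None else node_ids:
        name = protoname(tree.node(nid), db, min_size, min_spec, blacklist)
        if name is not None:
            out[nid] = name
    return out


# ---------------------------------------------------------------------------
# Inference onto mapped proteins
# ---------------------------------------------------------------------------

def infer_protein_annotations(
    assignment: ProteinMapping,
    tree: MergeTree,
    protonames: Mapping[int, ProtoName],
    pl_root: float = 70.0,
) -> set:
    """Terms inherited by one protein: the ProtoNames of its mapped cluster
    and of every ancestor up to and including its ProRoot.

    Unmapped or depth-excluded proteins receive the empty set (their status
    flag lives on the assignment).
    """
    if not assignment.is_mapped or assignment.is_excluded:
        return set()
    chain = [assignment.cluster]
    target = assignment.root
    if target != assignment.cluster:
        for anc in tree.ancestors(assignment.cluster):
            chain.append(anc)
            if anc == target:
                break
    terms: set = set()
    for nid in chain:
        name = protonames.get(nid)
        if name is not None:
            terms |= {(t.source, t.term_id, t.term_label) for t in name.terms}
    # deduplicate by (source, term_id): keep one label per term
    dedup: dict = {}
    for source, term_id, label in sorted(terms):
        dedup.setdefault((source, term_id), (source, term_id, label))
    return set(dedup.values())


def annotation_summary(
    mapping: MappingResult,
    protonames: Mapping[int, ProtoName],
    inferences: Mapping[str, set],
) -> dict:
    """Coverage summary: named-root fraction, annotated-proteome fraction,
    mean terms per named root, and per-source term shares."""
    occupied_roots = {
        a.root for a in mapping if a.is_mapped and not a.is_excluded
    }
    named_roots = {r for r in occupied_roots if r in protonames}
    n_annotated = sum(1 for pid in inferences if inferences[pid])
    n_queries = len(mapping)
    source_counts: dict = {}
    total_terms = 0
    for r in named_roots:
        for t in protonames[r].terms:
            source_counts[t.source] = source_counts.get(t.source, 0) + 1
            total_terms += 1
    per_root_terms = [
        sum(
            len(protonames[nid].terms)
            for nid in ([r] if r in protonames else [])
        )
        for r in occupied_roots
    ]
    return {
        "n_occupied_roots": len(occupied_roots),
        "fraction_roots_named": (
            len(named_roots) / len(occupied_roots) if occupied_roots else 0.0
        ),
        "fraction_proteome_annotated": n_annotated / n_queries if n_queries else 0.0,
        "mean_terms_per_root": (
            sum(per_root_terms) / len(occupied_roots) if occupied_roots else 0.0
        ),
        "source_shares": {
            s: c / total_terms for s, c in sorted(source_counts.items())
        }
        if total_terms
        else {},
    }


def protoname_table(protonames: Mapping[int, ProtoName]) -> pd.DataFrame:
    rows = [
        {
            "node_id": name.node_id,
            "source": t.source,
            "term_id": t.term_id,
            "term_label": t.term_label,
            "n_intersect": t.n_intersect,
            "cs": t.cs,
            "specificity": t.specificity,
        }
        for name in protonames.values()
        for t in name.terms
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "node_id", "source", "term_id", "term_label",
            "n_intersect", "cs", "specificity",
        ],
    ).sort_values(["node_id", "source"], ignore_index=True)
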