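"""Synthetic proteomes with planted family structure and ground truth.

The generator emulates the statistical structure the pipeline assumes:
protein families whose within-family E-values sit many orders of magnitude
below the cap, cap-level values between families and around orphans,
multi-species family occupancy, and one planted annotation term per family
assigned at a controllable purity.

Within a family, E-values follow a star-like divergence model: every family
draws one log10 band inside ``within_log10_range`` and each member carries a
divergence rank, with the pair E-value set by the more divergent member
(an ultrametric matrix).  Families therefore agglomerate as a chain - the
founder pair first, then one member at a time - so that intermediate
sub-family clusters are absorbed after a single step while the completed
family survives the whole cap-level merge phase.  This keeps "stable
cluster" and "planted family" aligned, which is exactly the property the
recovery benchmarks exercise.  Random number streams are per component
(structure, matrix, sequences, annotations, guide cases) so toggling one
output leaves the others unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotation import AnnotationDB
from .paralog_scores import GuideTree, build_guide_tree
from .similarity import E_CAP, E_FLOOR, ProteinRecord, SimilarityMatrix

_AMINO = "ACDEFGHIKLMNPQRSTVWY"
_SOURCES = ("GO", "InterPro", "Pfam", "Keyword")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_families: int = 24
    family_size_range: tuple = (4, 20)
    species: tuple = ("daphnia", "fly", "mouse")
    #: probability that a family contains each species (first species always in)
    species_mix: tuple = (1.0, 0.6, 0.6)
    within_log10_range: tuple = (-60.0, -20.0)
    between_evalue: float = E_CAP
    orphan_fraction: float = 0.02
    annotation_purity: float = 1.0
    n_decoy_terms: int = 5
    decoy_rate: float = 0.02
    unannotated_family_fraction: float = 0.0
    mutation_rate: float = 0.05
    seq_length_range: tuple = (120, 400)

    def __post_init__(self) -> None:
        lo, hi = self.within_log10_range
        if not (lo < hi < np.log10(self.between_evalue)):
            raise ValueError(
                f"within_log10_range {self.within_log10_range} must satisfy "
                f"lo < hi < log10(cap)"
            )
        if not (0 <= self.orphan_fraction < 1):
            raise ValueError("orphan_fraction must be in [0, 1)")
        for p in (self.annotation_purity, self.decoy_rate,
                  self.unannotated_family_fraction, *self.species_mix):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        if len(self.species_mix) != len(self.species):
            raise ValueError("species_mix must match species")
        if self.family_size_range[0] < 2:
            raise ValueError("families need at least 2 members")
        if self.n_families < 1:
            raise ValueError("need at least one family")


@dataclass
class GroundTruth:
    """Planted structure: family membership, species, terms, orphans."""

    families: dict  # family id -> ordered list of protein ids
    family_of: dict  # protein id -> family id
    species_of: dict  # protein id -> species
    orphans: list
    term_of_family: dict = field(default_factory=dict)  # fam -> (source, term_id, label)
    band_order: list = field(default_factory=list)  # family ids by E-value band

    @property
    def proteins(self) -> list:
        return [p for fam in self.families.values() for p in fam] + list(self.orphans)

    def occupancy(self) -> dict:
        """Per-family species counts (the planted Venn ground truth)."""
        out: dict = {}
        for fam, members in self.families.items():
            counts: dict = {}
            for pid in members:
                sp = self.species_of[pid]
                counts[sp] = counts.get(sp, 0) + 1
            out[fam] = counts
        return out

    def partition_labels(self, protein_ids: Sequence[str]) -> list:
        """Family label per protein (orphans get their own singleton labels)."""
        return [self.family_of.get(pid, f"orphan:{pid}") for pid in protein_ids]

    def to_json(self) -> str:
        return json.dumps(
            {
                "families": self.families,
                "family_of": self.family_of,
                "species_of": self.species_of,
                "orphans": self.orphans,
                "term_of_family": {
                    k: list(v) for k, v in self.term_of_family.items()
                },
                "band_order": self.band_order,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        data = json.loads(text)
        return cls(
            families=data["families"],
            family_of=data["family_of"],
            species_of=data["species_of"],
            orphans=data["orphans"],
            term_of_family={
                k: tuple(v) for k, v in data["term_of_family"].items()
            },
            band_order=data.get("band_order", []),
        )


# ---------------------------------------------------------------------------
# Shared structural plan (same for matrix and sequence modes of one seed)
# ---------------------------------------------------------------------------

def _plan(spec: SyntheticSpec, seed: int) -> GroundTruth:
    rng = np.random.default_rng([int(seed), 0])
    lo_s, hi_s = spec.family_size_range
    sizes = rng.integers(lo_s, hi_s + 1, size=spec.n_families)
    families: dict = {}
    family_of: dict = {}
    species_of: dict = {}
    for f, size in enumerate(sizes):
        fam = f"F{f:03d}"
        present = [
            sp
            for sp, p in zip(spec.species, spec.species_mix)
            if rng.random() < p
        ]
        if not present:
            present = [spec.species[0]]
        members = []
        for m in range(size):
            pid = f"{fam}_P{m:02d}"
            members.append(pid)
            family_of[pid] = fam
            species_of[pid] = present[int(rng.integers(len(present)))]
        families[fam] = members
    n_family_proteins = int(sizes.sum())
    n_orphans = int(
        round(
            n_family_proteins * spec.orphan_fraction / (1.0 - spec.orphan_fraction)
        )
    )
    orphans = []
    for i in range(n_orphans):
        pid = f"ORPH{i:03d}"
        orphans.append(pid)
        species_of[pid] = spec.species[int(rng.integers(len(spec.species)))]
    band_order = [f"F{f:03d}" for f in rng.permutation(spec.n_families)]
    return GroundTruth(
        families=families,
        family_of=family_of,
        species_of=species_of,
        orphans=orphans,
        band_order=band_order,
    )


# ---------------------------------------------------------------------------
# Matrix mode
# ---------------------------------------------------------------------------

def gen_similarity(spec: SyntheticSpec, seed: int) -> tuple:
    """Planted-family similarity matrix plus its ground truth.

    Within-family values land in a per-family log10 band with a divergence
    gradient (see the module docstring); between-family and orphan entries
    sit at the cap.  Deterministic for a given seed.
    """
    truth = _plan(spec, seed)
    ids = truth.proteins
    n = len(ids)
    index = {pid: i for i, pid in enumerate(ids)}
    values = np.full((n, n), spec.between_evalue, dtype=float)
    lo, hi = spec.within_log10_range
    width = (hi - lo) / spec.n_families
    for band, fam in enumerate(truth.band_order):
        members = truth.families[fam]
        size = len(members)
        base = lo + band * width
        for j in range(1, size):
            # the pair value is set by the more divergent member
            expo = base + 0.8 * width * j / size
            ev = 10.0 ** expo
            jj = index[members[j]]
            for i in range(j):
                ii = index[members[i]]
                values[ii, jj] = values[jj, ii] = ev
    np.fill_diagonal(values, E_FLOOR)
    m = SimilarityMatrix(ids, values, cap=spec.between_evalue, floor=E_FLOOR)
    return m, truth


# ---------------------------------------------------------------------------
# Sequence mode
# ---------------------------------------------------------------------------

def _random_sequence(rng, length: int) -> str:
    return "".join(
        _AMINO[i] for i in rng.integers(len(_AMINO), size=length)
    )


def _mutate(rng, sequence: str, rate: float) -> str:
    if rate <= 0:
        return sequence
    chars = list(sequence)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        choices = _AMINO.replace(chars[i], "")
        chars[i] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def gen_sequences(spec: SyntheticSpec, seed: int) -> tuple:
    """Planted-family protein sequences plus ground truth.

    One random ancestor per family; members are the ancestor with i.i.d.
    point substitutions at ``mutation_rate``; orphans are fresh random
    sequences.  Shares the structural plan (family sizes, species, bands)
    with :func:`gen_similarity` for the same seed.
    """
    truth = _plan(spec, seed)
    rng = np.random.default_rng([int(seed), 2])
    lo_len, hi_len = spec.seq_length_range
    records = []
    for fam, members in truth.families.items():
        ancestor = _random_sequence(rng, int(rng.integers(lo_len, hi_len + 1)))
        for pid in members:
            records.append(
                ProteinRecord(
                    id=pid,
                    sequence=_mutate(rng, ancestor, spec.mutation_rate),
                    species=truth.species_of[pid],
                )
            )
    for pid in truth.orphans:
        records.append(
            ProteinRecord(
                id=pid,
                sequence=_random_sequence(
                    rng, int(rng.integers(lo_len, hi_len + 1))
                ),
                species=truth.species_of[pid],
            )
        )
    return records, truth


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def gen_annotations(truth: GroundTruth, spec: SyntheticSpec, seed: int) -> AnnotationDB:
    """Planted one-term-per-family annotations at the requested purity.

    Each family's planted term goes to each member with probability
    ``annotation_purity``; ``n_decoy_terms`` decoy terms are scattered
    uniformly at ``decoy_rate``; a fraction of families can be left without
    any planted term.  The planted terms are recorded on ``truth``.
    """
    rng = np.random.default_rng([int(seed), 3])
    universe = truth.proteins
    records = []
    fams = list(truth.families)
    n_unannotated = int(round(spec.unannotated_family_fraction * len(fams)))
    unannotated = set(
        fams[i] for i in rng.permutation(len(fams))[:n_unannotated]
    )
    truth.term_of_family = {}
    for f, fam in enumerate(fams):
        if fam in unannotated:
            continue
        source = _SOURCES[f % len(_SOURCES)]
        term = (source, f"T{f:04d}", f"planted family {fam}")
        truth.term_of_family[fam] = term
        for pid in truth.families[fam]:
            if rng.random() < spec.annotation_purity:
                records.append((pid, *term))
    for d in range(spec.n_decoy_terms):
        source = _SOURCES[d % len(_SOURCES)]
        for pid in universe:
            if rng.random() < spec.decoy_rate:
                records.append((pid, source, f"D{d:04d}", f"decoy term {d}"))
    return AnnotationDB.from_records(records, universe)


# ---------------------------------------------------------------------------
# Guide-tree cases
# ---------------------------------------------------------------------------

def gen_guide_case(
    n_interest: int,
    n_other: int,
    intermix: bool,
    seed: int,
    interest_species: str = "interest",
    other_species: str = "other",
) -> tuple:
    """A guide tree with planted clade structure plus its expected TS.

    With ``intermix=False`` the interest leaves form one planted clade, so
    TS is exactly 1.0.  With ``intermix=True`` the interest leaves are
    scattered so that their LCA is the root: TS is exactly
    ``n_interest / (n_interest + n_other)``, which is bounded above by
    ``n_interest / (n_interest + 1)``.
    """
    if n_interest < 1:
        raise ValueError("need at least one leaf of the species of interest")
    if intermix and n_other < 1:
        raise ValueError("intermixing needs at least one other-species leaf")
    rng = np.random.default_rng([int(seed), 4])
    interest = [f"I{i:02d}" for i in range(n_interest)]
    other = [f"O{i:02d}" for i in range(n_other)]
    if intermix:
        middle = interest[1:-1] + other[:-1] if n_interest > 1 else other[:-1]
        middle = [middle[i] for i in rng.permutation(len(middle))]
        # interest leaves at both extremes of a caterpillar => LCA is the root
        order = (
            [interest[0]] + middle + [other[-1], interest[-1]]
            if n_interest > 1
            else [interest[0]] + middle + [other[-1]]
        )
        nested = order[0]
        for leaf in order[1:-1]:
            nested = (nested, leaf)
        nested = (order[-1], nested) if n_interest > 1 else (nested, order[-1])
        expected = (
            n_interest / (n_interest + n_other) if n_interest > 1 else 1.0
        )
    else:
        def random_clade(leaves):
            if len(leaves) == 1:
                return leaves[0]
            k = 1 + int(rng.integers(len(leaves) - 1))
            return (random_clade(leaves[:k]), random_clade(leaves[k:]))

        interest = [interest[i] for i in rng.permutation(n_interest)]
        nested = random_clade(interest)
        if other:
            other = [other[i] for i in rng.permutation(n_other)]
            nested = (nested, random_clade(other))
        expected = 1.0
    species = {name: interest_species for name in interest}
    species.update({name: other_species for name in other})
    return _tree_from_nesting(nested, species), expected


def _tree_from_nesting(nested, species: Mapping[str, str]) -> GuideTree:
    """Realize a nested-tuple topology as a GuideTree via ultrametric UPGMA."""

    labels: list = []

    def collect(node):
        if isinstance(node, str):
            labels.append(node)
        else:
            for child in node:
                collect(child)

    collect(nested)
    index = {name: i for i, name in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))

    def fill(node) -> tuple:
        """Return (leaf list, height); set distances below this node."""
        if isinstance(node, str):
            return [node], 0.0
        sides = [fill(child) for child in node]
        height = 1.0 + max(h for _, h in sides)
        leaves = []
        for k, (left, _) in enumerate(sides):
            for right, _ in sides[k + 1:]:
                for a in left:
                    for b in right:
                        d[index[a], index[b]] = d[index[b], index[a]] = 2.0 * height
            leaves.extend(left)
        return leaves, height

    fill(nested)
    return build_guide_tree(d, labels, species=species)
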