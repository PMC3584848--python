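"""Capped all-vs-all E-value matrices over a proteome.

The clustering substrate is a symmetric matrix of BLAST-style E-values in
which every pair less significant than a cap (default 100) is stored *at*
the cap, and self-similarity is pinned to a small floor so that log-space
plots never hit zero.  Matrices can be ingested from 3-column score tables
produced by an external aligner, or computed internally with a deterministic
k-mer Jaccard surrogate scorer so that the whole pipeline is testable
without running an aligner.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: E-values less significant than this are stored at the cap.
E_CAP = 100.0
#: Lower bound for any stored E-value; also the pinned self-similarity.
E_FLOOR = 1e-180

#: 20 standard residues plus the ambiguity code X.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein of a proteome: id, sequence, species tag, fragment flag."""

    id: str
    sequence: str
    species: str = "unknown"
    is_fragment: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residues {sorted(bad)!r} "
                "(uppercase 20-letter alphabet plus X expected)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def kmers(self, k: int) -> frozenset:
        """Set of overlapping k-mers; error when the sequence is shorter than k."""
        if self.length < k:
            raise ValueError(
                f"protein {self.id!r}: sequence length {self.length} < k={k}"
            )
        seq = self.sequence
        return frozenset(seq[i : i + k] for i in range(self.length - k + 1))


# ---------------------------------------------------------------------------
# FASTA I/O.  Header layout: >id species=<tag> [fragment=1]
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    """Read a proteome from FASTA, picking species / fragment flags off the header."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok
        )
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                species=fields.get("species", "unknown"),
                is_fragment=fields.get("fragment", "0") == "1",
            )
        )
    return records


def write_fasta(records: Sequence[ProteinRecord], path) -> None:
    seqs = []
    for r in records:
        desc = f"species={r.species}"
        if r.is_fragment:
            desc += " fragment=1"
        seqs.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    SeqIO.write(seqs, str(path), "fasta")


def filter_full_length(proteome: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Drop records flagged as fragments, preserving order.

    Raises ``ValueError`` when nothing survives the filter; logs the number
    of removed records otherwise.
    """
    kept = [r for r in proteome if not r.is_fragment]
    if not kept:
        raise ValueError("no full-length proteins: every record is flagged as a fragment")
    removed = len(proteome) - len(kept)
    if removed:
        log.info("filter_full_length: removed %d fragment(s), kept %d", removed, len(kept))
    return kept


# ---------------------------------------------------------------------------
# The similarity matrix
# ---------------------------------------------------------------------------

class SimilarityMatrix:
    """Symmetric, capped pairwise E-values over an ordered protein id list.

    Invariants: ``evalue(i, j) == evalue(j, i) <= cap``; the diagonal is
    pinned to the floor; pairs never scored read as the cap.
    """

    def __init__(
        self,
        ids: Sequence[str],
        values: np.ndarray,
        cap: float = E_CAP,
        floor: float = E_FLOOR,
        validate: bool = True,
    ) -> None:
        self.ids = list(ids)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate protein ids in similarity matrix")
        self.values = np.asarray(values, dtype=float)
        self.cap = float(cap)
        self.floor = float(floor)
        self._index = {pid: i for i, pid in enumerate(self.ids)}
        if validate:
            self._validate()

    def _validate(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("similarity matrix is not symmetric")
        if np.any(self.values > self.cap):
            raise ValueError(f"similarity matrix holds values above the cap {self.cap}")
        if np.any(self.values < self.floor):
            raise ValueError(f"similarity matrix holds values below the floor {self.floor}")
        if not np.all(np.diag(self.values) == self.floor):
            raise ValueError("diagonal of the similarity matrix must equal the floor")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, protein_id: str) -> int:
        try:
            return self._index[protein_id]
        except KeyError:
            raise KeyError(f"unknown protein id {protein_id!r}") from None

    def evalue(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def row(self, protein_id: str) -> np.ndarray:
        """The query row of a member protein, aligned with ``self.ids``."""
        return self.values[self.index(protein_id)].copy()

    def subset(self, ids: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.index(i) for i in ids]
        return SimilarityMatrix(
            ids, self.values[np.ix_(idx, idx)], cap=self.cap, floor=self.floor
        )


def load_pairwise_scores(
    source,
    ids: Sequence[str],
    cap: float = E_CAP,
    floor: float = E_FLOOR,
) -> SimilarityMatrix:
    """Build a :class:`SimilarityMatrix` from a 3-column score table.

    ``source`` is a path or an iterable of lines ``query<TAB>subject<TAB>evalue``
    (``#`` comments and blank lines allowed).  Values above the cap are
    replaced by the cap; reciprocal directed pairs are symmetrized with the
    minimum (most significant) of the two directions; absent pairs default to
    the cap; the diagonal is pinned to the floor.
    """
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = Path(source).read_text().splitlines()
    else:
        lines = source
    index = {pid: i for i, pid in enumerate(ids)}
    if len(index) != len(ids):
        raise ValueError("duplicate protein ids in declared proteome")
    n = len(ids)
    values = np.full((n, n), cap, dtype=float)
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3:
            raise ValueError(f"malformed score row on line {ln}: {raw!r}")
        q, s, tok = parts
        for pid in (q, s):
            if pid not in index:
                raise ValueError(f"unknown protein id {pid!r} on line {ln}")
        try:
            ev = float(tok)
        except ValueError:
            raise ValueError(f"malformed E-value {tok!r} on line {ln}") from None
        if not math.isfinite(ev) or ev < 0:
            raise ValueError(f"E-value out of range ({tok!r}) on line {ln}")
        ev = min(ev, cap)
        ev = max(ev, floor)
        i, j = index[q], index[s]
        if ev < values[i, j]:
            values[i, j] = ev
            values[j, i] = ev
    np.fill_diagonal(values, floor)
    return SimilarityMatrix(ids, values, cap=cap, floor=floor)


def write_pairwise_scores(m: SimilarityMatrix, path, precision: int | None = 6) -> None:
    """Write the off-diagonal, below-cap entries as a 3-column table.

    ``precision`` is the number of significant digits (scientific notation);
    ``None`` writes the shortest decimal representation that round-trips the
    double exactly.  Cap-level pairs are omitted (they are the default on
    re-loading), so the written table re-loads to the identical matrix.
    """
    with open(path, "w") as fh:
        fh.write("# query\tsubject\tevalue\n")
        for i in range(m.n):
            for j in range(i + 1, m.n):
                v = m.values[i, j]
                if v == m.cap:
                    continue
                txt = repr(float(v)) if precision is None else f"{v:.{precision - 1}e}"
                fh.write(f"{m.ids[i]}\t{m.ids[j]}\t{txt}\n")


# ---------------------------------------------------------------------------
# Deterministic surrogate scorer
# ---------------------------------------------------------------------------

def surrogate_evalue(
    a: ProteinRecord,
    b: ProteinRecord,
    k: int = 3,
    s: float = 40.0,
    cap: float = E_CAP,
    floor: float = E_FLOOR,
) -> float:
    """Deterministic stand-in for an aligner E-value.

    With J the Jaccard index of the two k-mer sets, returns
    ``clamp(10**(2 - s*J), floor, cap)``: unrelated sequences (J=0) land at
    the cap, identical sequences at 1e-38 with the defaults.  Symmetric and
    monotone decreasing in J.
    """
    ka, kb = a.kmers(k), b.kmers(k)
    union = len(ka | kb)
    jaccard = len(ka & kb) / union if union else 0.0
    ev = 10.0 ** (2.0 - s * jaccard)
    return min(max(ev, floor), cap)


def all_vs_all(
    proteome: Sequence[ProteinRecord],
    scorer: Callable[[ProteinRecord, ProteinRecord], float] | None = None,
    cap: float = E_CAP,
    floor: float = E_FLOOR,
    **scorer_kwargs,
) -> SimilarityMatrix:
    """Score every unordered pair of a proteome into a similarity matrix.

    ``scorer`` defaults to :func:`surrogate_evalue`; extra keyword arguments
    are forwarded to it.  A scorer failure is re-raised naming the pair.
    """
    if len(proteome) < 2:
        raise ValueError("all_vs_all needs at least 2 proteins")
    if scorer is None:
        def scorer(a, b):  # noqa: ANN001 - local default
            return surrogate_evalue(a, b, cap=cap, floor=floor, **scorer_kwargs)
    n = len(proteome)
    values = np.full((n, n), floor, dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                ev = float(scorer(proteome[i], proteome[j]))
            except Exception as exc:
                raise RuntimeError(
                    f"scorer failed on pair ({proteome[i].id!r}, {proteome[j].id!r}): {exc}"
                ) from exc
            ev = min(max(ev, floor), cap)
            values[i, j] = values[j, i] = ev
    np.fill_diagonal(values, floor)
    return SimilarityMatrix([p.id for p in proteome], values, cap=cap, floor=floor)
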