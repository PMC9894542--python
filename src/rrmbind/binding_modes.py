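"""Binding-mode similarity, clustering and the contact-anchored RNA MSA.

Two bound RNAs share a binding mode when their nucleotides touch the
same master-alignment columns of the RRM.  The pairwise similarity
score slides one RNA along the other and, for each aligned nucleotide
pair, divides the number of matching contacted columns by the number of
unique contacted columns; the ratios are averaged over the aligned
length.  The best offset defines both the score (0 = unrelated binding
mode, 1 = identical) and, later, the placement of each RNA in the
cluster's RNA multiple alignment.

The largest cluster under this score corresponds to the canonical
binding mode: ssRNA laid across the beta-sheet face, anchored by the
RNP1/RNP2 aromatics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .core import GAP, ComplexEntry, InputError


@dataclass
class RnaContactProfile:
    """Bound RNA truncated to its contacted region, with column sets.

    ``columns[i]`` is the set of master columns contacted by nucleotide
    ``i`` of ``sequence``.  Leading/trailing nucleotides with no contact
    are trimmed (long RNAs in deposited structures can run to thousands
    of nucleotides, of which only a short stretch binds the domain).
    """

    entry_id: str
    sequence: str
    columns: list[frozenset[int]]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.columns):
            raise InputError("sequence/columns length mismatch")
        if not self.sequence:
            raise InputError(f"profile {self.entry_id} has no nucleotides")

    @classmethod
    def from_entry(cls, entry: ComplexEntry) -> "RnaContactProfile":
        contacted = [i for i, cols in entry.contact_map.items() if cols]
        if not contacted:
            raise InputError(f"entry {entry.entry_id} has no contacts")
        lo, hi = min(contacted), max(contacted)
        seq = entry.rna_seq[lo:hi + 1]
        cols = [frozenset(entry.contact_map.get(i, set()))
                for i in range(lo, hi + 1)]
        return cls(entry_id=entry.entry_id, sequence=seq, columns=cols)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PairAlignment:
    """Best sliding alignment of profile B against profile A."""

    offset: int          # B's 5' end sits at coordinate `offset` of A
    score: float
    aligned_length: int  # nucleotide pairs contributing to the score
    pair_ratios: list[tuple[int, int, int, int]] = field(default_factory=list)
    # (index in A, index in B, matching positions, unique positions)


def _score_at_offset(a: RnaContactProfile, b: RnaContactProfile,
                     offset: int) -> PairAlignment | None:
    lo = max(0, offset)
    hi = min(len(a), offset + len(b))
    if hi <= lo:
        return None
    ratios = []
    total = 0.0
    for i in range(lo, hi):
        ca, cb = a.columns[i], b.columns[i - offset]
        union = ca | cb
        if not union:
            continue  # no binding information on either side
        match = len(ca & cb)
        ratios.append((i, i - offset, match, len(union)))
        total += match / len(union)
    if not ratios:
        return None
    return PairAlignment(offset=offset, score=total / len(ratios),
                         aligned_length=len(ratios), pair_ratios=ratios)


def rna_similarity(a: RnaContactProfile, b: RnaContactProfile
                   ) -> PairAlignment:
    """Best-offset binding-mode similarity between two contact profiles.

    Every offset with at least one overlapping nucleotide pair is
    evaluated; the maximum-score alignment is returned.  Ties between
    offsets break toward the smallest absolute offset, then toward the
    negative one.  The score is symmetric in the two profiles.
    """
    best: PairAlignment | None = None
    for offset in range(-(len(b) - 1), len(a)):
        cand = _score_at_offset(a, b, offset)
        if cand is None:
            continue
        if best is None or cand.score > best.score or (
                cand.score == best.score
                and (abs(cand.offset), cand.offset)
                < (abs(best.offset), best.offset)):
            best = cand
    if best is None:
        # profiles exist but share no informative overlap at any offset
        return PairAlignment(offset=0, score=0.0, aligned_length=0)
    return best


# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """Symmetric matrix of best pairwise binding-mode similarities.

    The diagonal is 1 internally (a profile aligned to itself); the CSV
    dialect used for data exchange writes 0 on the diagonal instead, and
    reading converts back.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InputError("matrix shape does not match id count")
        if len(set(self.ids)) != n:
            raise InputError("duplicate entry ids")

    def index(self, entry_id: str) -> int:
        return self.ids.index(entry_id)

    def similarity(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.index(id_a), self.index(id_b)])

    def to_csv(self, path) -> None:
        import pandas as pd

        out = self.values.copy()
        np.fill_diagonal(out, 0.0)  # file-dialect convention
        pd.DataFrame(out, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy(dtype=float)
        np.fill_diagonal(values, 1.0)
        return cls(ids=[str(c) for c in df.columns], values=values)


def build_similarity_matrix(profiles: list[RnaContactProfile]
                            ) -> SimilarityMatrix:
    """All-pairs best similarity scores, computed once and mirrored."""
    if len(profiles) < 2:
        raise InputError("need at least two profiles")
    ids = [p.entry_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate entry ids among profiles")
    n = len(profiles)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = rna_similarity(profiles[i], profiles[j]).score
            m[i, j] = m[j, i] = s
    return SimilarityMatrix(ids=ids, values=m)


def _qualifying_counts(values: np.ndarray, idx: list[int],
                       score_min: float) -> list[int]:
    sub = values[np.ix_(idx, idx)]
    qual = sub >= score_min
    np.fill_diagonal(qual, False)
    return qual.sum(axis=1).tolist()


def extract_primary_cluster(matrix: SimilarityMatrix,
                            score_min: float = 0.25,
                            member_fraction: float = 0.25) -> set[str]:
    """Largest group where every member resembles enough of the others.

    Membership criterion: each member must have similarity >=
    ``score_min`` with at least ``member_fraction`` of the other
    members.  The procedure prunes iteratively: starting from all
    entries, repeatedly drop the entry with the fewest qualifying
    partners (ties drop the lexicographically smallest id) until every
    remaining entry satisfies the criterion.
    """
    if not matrix.ids:
        raise InputError("empty similarity matrix")
    order = sorted(range(len(matrix.ids)), key=lambda i: matrix.ids[i])
    idx = list(order)
    while idx:
        counts = _qualifying_counts(matrix.values, idx, score_min)
        need = member_fraction * (len(idx) - 1)
        failing = [k for k, c in enumerate(counts) if c < need]
        if not failing:
            break
        worst = min(failing, key=lambda k: (counts[k], matrix.ids[idx[k]]))
        idx.pop(worst)
    return {matrix.ids[i] for i in idx}


def extract_clusters(matrix: SimilarityMatrix,
                     score_min: float = 0.25,
                     member_fraction: float = 0.25,
                     min_size: int = 2) -> list[set[str]]:
    """Primary cluster, then repeat on the complement for further modes."""
    remaining = list(matrix.ids)
    clusters = []
    while len(remaining) >= min_size:
        keep = [matrix.index(i) for i in remaining]
        sub = SimilarityMatrix(
            ids=[matrix.ids[i] for i in keep],
            values=matrix.values[np.ix_(keep, keep)].copy())
        cluster = extract_primary_cluster(sub, score_min, member_fraction)
        if len(cluster) < min_size:
            break
        clusters.append(cluster)
        remaining = [i for i in remaining if i not in cluster]
    return clusters


def find_medoid(matrix: SimilarityMatrix, members: set[str]) -> str:
    """Member with the highest total similarity to the other members."""
    members = sorted(members)
    if not members:
        raise InputError("empty member set")
    if any(m not in matrix.ids for m in members):
        raise InputError("member not in matrix")
    idx = [matrix.index(m) for m in members]
    sub = matrix.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, 0.0)
    sums = sub.sum(axis=1)
    return members[int(np.argmax(sums))]  # argmax takes first = lexicographic


# ---------------------------------------------------------------------------
# contact-anchored RNA multiple alignment

@dataclass
class RnaMsa:
    """Cluster RNA alignment anchored on the medoid.

    Each member RNA is placed at its best-scoring offset against the
    medoid profile, then padded with 5'/3' gaps to a common frame.
    ``core_positions`` (filled by :func:`select_core_positions`) are the
    least-gapped frame positions, the only ones used by the scorer;
    they are numbered 1..k in 5'->3' order.
    """

    rows: dict[str, str]
    offsets: dict[str, int]
    medoid: str
    core_positions: list[int] = field(default_factory=list)

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    def gap_fractions(self) -> np.ndarray:
        rows = list(self.rows.values())
        return np.array([sum(r[c] == GAP for r in rows) / len(rows)
                         for c in range(self.width)])

    def nucleotide_at(self, entry_id: str, frame_position: int) -> str | None:
        ch = self.rows[entry_id][frame_position]
        return None if ch == GAP else ch

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, row in self.rows.items():
                fh.write(f">{name}\n{row}\n")


def build_rna_msa(profiles: list[RnaContactProfile], medoid_id: str
                  ) -> RnaMsa:
    """Align every cluster RNA against the medoid and pad to a frame."""
    by_id = {p.entry_id: p for p in profiles}
    if medoid_id not in by_id:
        raise InputError(f"medoid {medoid_id!r} not among profiles")
    medoid = by_id[medoid_id]

    offsets: dict[str, int] = {}
    for p in profiles:
        if p.entry_id == medoid_id:
            offsets[p.entry_id] = 0
            continue
        best = rna_similarity(medoid, p)
        if best.aligned_length == 0 or best.score <= 0.0:
            warnings.warn(
                f"{p.entry_id}: no positive-score alignment against the "
                "medoid; placed at offset 0")
            offsets[p.entry_id] = 0
        else:
            offsets[p.entry_id] = best.offset

    start = min(min(offsets.values()), 0)
    end = max(offsets[p.entry_id] + len(p) for p in profiles)
    width = end - start
    rows = {}
    for p in profiles:
        left = offsets[p.entry_id] - start
        rows[p.entry_id] = (GAP * left + p.sequence
                            + GAP * (width - left - len(p)))
    return RnaMsa(rows=rows, offsets={k: v - start for k, v in
                                      offsets.items()}, medoid=medoid_id)


def select_core_positions(msa: RnaMsa, k: int = 5) -> list[int]:
    """The ``k`` least-gapped frame positions, 5'->3', ties toward 5'."""
    if k > msa.width:
        raise InputError(f"k={k} exceeds frame width {msa.width}")
    frac = msa.gap_fractions()
    ranked = sorted(range(msa.width), key=lambda c: (frac[c], c))
    core = sorted(ranked[:k])
    msa.core_positions = core
    return core


# ---------------------------------------------------------------------------
# superposition sanity check

SUGAR_HEAVY_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O2'", "O3'", "O4'"}


def superpose_rmsd(coords_a: "np.ndarray | list",
                   coords_b: "np.ndarray | list") -> float:
    """RMSD after optimal rigid-body superposition of paired atoms.

    Intended for the sugar heavy atoms of aligned nucleotides from two
    complexes, as a geometric check that a low similarity score can
    still reflect the same binding mode.
    """
    from Bio.SVDSuperimposer import SVDSuperimposer

    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InputError("coordinate arrays must be matched (n, 3)")
    if a.shape[0] < 3:
        raise InputError("need at least 3 atom pairs for superposition")
    sup = SVDSuperimposer()
    sup.set(a, b)
    sup.run()
    return float(sup.get_rms())


def sugar_atom_coords(atoms, nucleotide_numbers: list[int],
                      chain_id: str) -> tuple[np.ndarray, list[str]]:
    """Collect sugar heavy-atom coordinates for the given nucleotides.

    Returns the coordinate array and parallel ``"<nucnum>:<atom>"``
    labels so two structures can be paired atom-by-atom; pairs missing
    on either side should be dropped by the caller.
    """
    coords, labels = [], []
    for a in atoms:
        if (a.chain_id == chain_id and a.residue_number in nucleotide_numbers
                and a.atom_name in SUGAR_HEAVY_ATOMS):
            coords.append(a.coordinates)
            labels.append(f"{a.residue_number}:{a.atom_name}")
    return np.array(coords, dtype=float), labels
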