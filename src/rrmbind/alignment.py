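"""The master RRM alignment: the package's coordinate system.

The RRM fold is a ~90-residue beta1-alpha1-beta2-beta3-alpha2-beta4
sandwich.  A curated multiple sequence alignment of RRM domains, with
every column assigned to a secondary-structure element (or a loop or
terminus), defines the column numbering that contacts, similarity
scores and the trained scorer all refer to.  Structured columns carry
grid labels such as ``β1–1`` (first column of strand beta-1); the RNP2
and RNP1 aromatics sit at β1–3, β3–3 and β3–5.

Loops align poorly, so the alignment is refined by "squeezing": loop
residues are packed flush against their flanking structured elements
with all gaps contiguous in the middle of the loop; N/C-terminal gaps
go to the alignment extremes.  What matters for a loop residue is how
it connects to the fixed elements, not its exact column.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .core import GAP, ComplexEntry, InputError, RrmBindError

ELEMENT_ORDER = ("Nterm", "β1", "loop1", "α1", "loop2", "β2", "loop3",
                 "β3", "loop4", "α2", "loop5", "β4", "Cterm")
CORE_ELEMENTS = ("β1", "α1", "β2", "β3", "α2", "β4")

_ASCII_ALIASES = {
    "beta1": "β1", "beta2": "β2", "beta3": "β3", "beta4": "β4",
    "alpha1": "α1", "alpha2": "α2",
    "b1": "β1", "b2": "β2", "b3": "β3", "b4": "β4",
    "a1": "α1", "a2": "α2",
}


class NotAnRrmError(RrmBindError):
    """Raised when a query sequence cannot be credibly aligned as an RRM."""


def canonical_element(name: str) -> str:
    name = _ASCII_ALIASES.get(name.strip().lower(), name.strip())
    if name not in ELEMENT_ORDER:
        raise InputError(f"unknown secondary-structure element {name!r}")
    return name


def parse_grid_label(label: str) -> tuple[str, int]:
    """Split ``"β1–1"`` (en dash or hyphen; ASCII aliases ok) into parts."""
    norm = label.replace("–", "-")
    elem, _, idx = norm.rpartition("-")
    if not elem or not idx.isdigit():
        raise InputError(f"malformed grid label {label!r}")
    return canonical_element(elem), int(idx)


@dataclass
class MasterAlignment:
    """Column-annotated RRM multiple sequence alignment.

    ``element_spans`` is an ordered list of ``(element, start, end)``
    half-open column ranges that tile ``[0, n_columns)``.
    """

    entries: dict[str, str]
    element_spans: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        self.element_spans = [(canonical_element(e), int(s), int(t))
                              for e, s, t in self.element_spans]
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_columns(self) -> int:
        return self.element_spans[-1][2]

    def validate(self) -> None:
        if not self.entries:
            raise InputError("empty alignment")
        spans = self.element_spans
        if spans[0][1] != 0:
            raise InputError("element spans must start at column 0")
        for (_, _, e1), (_, s2, _) in zip(spans, spans[1:]):
            if e1 != s2:
                raise InputError("element spans must tile without overlap")
        L = self.n_columns
        for name, seq in self.entries.items():
            if len(seq) != L:
                raise InputError(
                    f"row {name!r} has length {len(seq)}, expected {L}")
        for elem, s, t in spans:
            if elem in CORE_ELEMENTS:
                for name, seq in self.entries.items():
                    if GAP in seq[s:t]:
                        raise InputError(
                            f"gap inside core element {elem} in row {name!r}")

    def span_of(self, element: str) -> tuple[int, int]:
        element = canonical_element(element)
        for elem, s, t in self.element_spans:
            if elem == element:
                return s, t
        raise InputError(f"element {element!r} not in alignment")

    def element_of_column(self, column: int) -> str:
        for elem, s, t in self.element_spans:
            if s <= column < t:
                return elem
        raise InputError(f"column {column} out of range")

    def grid_label(self, column: int) -> str:
        """Label of a column: ``"β1–1"`` style, 1-based within its element.

        Structured columns follow the standard grid convention; loop and
        terminal columns get analogous ``loop1–2`` labels (useful for
        diagnostics only).
        """
        for elem, s, t in self.element_spans:
            if s <= column < t:
                return f"{elem}–{column - s + 1}"
        raise InputError(f"column {column} out of range")

    def column_of_label(self, label: str) -> int:
        elem, k = parse_grid_label(label)
        s, t = self.span_of(elem)
        col = s + k - 1
        if not (s <= col < t):
            raise InputError(f"label {label!r} outside its element span")
        return col

    # -- squeezing ---------------------------------------------------------

    def squeeze_gaps(self) -> "MasterAlignment":
        """Pack loop residues against flanking elements, gaps in the middle.

        The first ceil(n/2) residues of a loop anchor to the preceding
        element and the rest to the following one.  N-terminal gaps are
        pushed to the alignment start and C-terminal gaps to the end.
        Ungapped sequences are unchanged; the operation is idempotent.
        """
        new_entries = {}
        for name, seq in self.entries.items():
            parts = []
            for elem, s, t in self.element_spans:
                seg = seq[s:t]
                if len(seg) != t - s:
                    raise InputError("span annotation inconsistent with row")
                if elem in CORE_ELEMENTS:
                    parts.append(seg)
                    continue
                residues = seg.replace(GAP, "")
                gaps = GAP * (len(seg) - len(residues))
                if elem == "Nterm":
                    parts.append(gaps + residues)
                elif elem == "Cterm":
                    parts.append(residues + gaps)
                else:
                    left = residues[:math.ceil(len(residues) / 2)]
                    parts.append(left + gaps + residues[len(left):])
            new_entries[name] = "".join(parts)
        return MasterAlignment(entries=new_entries,
                               element_spans=list(self.element_spans))

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_fasta(cls, fasta_path, spans_path) -> "MasterAlignment":
        """Load from an aligned FASTA plus a YAML/JSON span annotation.

        The span file is a list of ``{element, start, end}`` mappings
        with half-open 0-based column ranges (FASTA itself carries no
        secondary-structure annotation).
        """
        import yaml
        from Bio import SeqIO

        entries = {rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(str(fasta_path), "fasta")}
        with open(spans_path) as fh:
            raw = yaml.safe_load(fh)
        spans = [(d["element"], int(d["start"]), int(d["end"])) for d in raw]
        return cls(entries=entries, element_spans=spans)

    def to_fasta(self, fasta_path, spans_path) -> None:
        import yaml

        with open(fasta_path, "w") as fh:
            for name, seq in self.entries.items():
                fh.write(f">{name}\n{seq}\n")
        with open(spans_path, "w") as fh:
            yaml.safe_dump([{"element": e, "start": s, "end": t}
                            for e, s, t in self.element_spans], fh,
                           allow_unicode=True, sort_keys=False)


@dataclass
class AlignedRRM:
    """A query RRM mapped into master columns.

    ``column_of_residue`` maps 0-based residue indices of the ungapped
    query to master columns; it is strictly increasing and partial
    (residues aligned to insert states have no column).
    """

    entry_id: str
    sequence: str
    n_columns: int
    column_of_residue: dict[int, int]

    def __post_init__(self) -> None:
        cols = [self.column_of_residue[i]
                for i in sorted(self.column_of_residue)]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise InputError("column mapping must be strictly increasing")
        self.residue_of_column = {c: i
                                  for i, c in self.column_of_residue.items()}

    @property
    def gapped(self) -> str:
        row = [GAP] * self.n_columns
        for i, c in self.column_of_residue.items():
            row[c] = self.sequence[i]
        return "".join(row)

    def residue_at_column(self, column: int) -> str | None:
        i = self.residue_of_column.get(column)
        return None if i is None else self.sequence[i]

    @classmethod
    def from_gapped(cls, entry_id: str, gapped: str) -> "AlignedRRM":
        seq, mapping, i = [], {}, 0
        for col, ch in enumerate(gapped):
            if ch != GAP:
                mapping[i] = col
                seq.append(ch)
                i += 1
        return cls(entry_id=entry_id, sequence="".join(seq),
                   n_columns=len(gapped), column_of_residue=mapping)


# ---------------------------------------------------------------------------
# profile-HMM alignment of new sequences into master columns

@lru_cache(maxsize=8)
def _build_hmm(rows: tuple[tuple[str, str], ...]):
    import pyhmmer
    from pyhmmer.easel import Alphabet, TextMSA, TextSequence

    abc = Alphabet.amino()
    msa = TextMSA(name=b"master",
                  sequences=[TextSequence(name=n.encode(), sequence=s)
                             for n, s in rows])
    # every master column becomes a match state, so match state k <-> column k
    msa.reference = "x" * len(rows[0][1])
    builder = pyhmmer.plan7.Builder(abc, architecture="hand", seed=7)
    bg = pyhmmer.plan7.Background(abc)
    hmm, _, _ = builder.build_msa(msa.digitize(abc), bg)
    return abc, bg, hmm


def align_to_master(query: str, master: MasterAlignment,
                    entry_id: str = "query",
                    check_rrm: bool = True) -> AlignedRRM:
    """Align an ungapped amino-acid sequence into master columns.

    A profile HMM is built from the master alignment with a one-to-one
    match-state/column correspondence; the query is then aligned with
    the standard profile alignment algorithm.  Deterministic for a fixed
    master alignment.

    Raises :class:`NotAnRrmError` when the query does not score above
    the profile's reporting floor (``check_rrm=False`` disables the
    check, e.g. for deliberately tiny toy alignments).
    """
    import pyhmmer
    from pyhmmer.easel import TextSequence

    query = query.strip().upper()
    if not query:
        raise InputError("empty query sequence")
    if not (70 <= len(query) <= 120):
        warnings.warn(
            f"query length {len(query)} is unusual for a single RRM "
            "domain (expected roughly 70-120 aa)")

    abc, bg, hmm = _build_hmm(tuple(master.entries.items()))
    dsq = TextSequence(name=entry_id.encode(), sequence=query).digitize(abc)

    if check_rrm:
        pipeline = pyhmmer.plan7.Pipeline(abc, background=bg)
        hits = pipeline.search_hmm(
            hmm, pyhmmer.easel.DigitalSequenceBlock(abc, [dsq]))
        if len(hits) == 0:
            raise NotAnRrmError(
                f"query {entry_id!r} does not align to the RRM profile")

    aln = pyhmmer.hmmer.hmmalign(hmm, [dsq], trim=False)
    text = aln.alignment[0]
    ref = aln.reference  # 'x' for match columns, '.' for inserts

    mapping: dict[int, int] = {}
    residue_i = 0
    column = 0
    for ch, r in zip(text, ref):
        if r == "x":
            if ch != GAP and ch != ".":
                mapping[residue_i] = column
                residue_i += 1
            column += 1
        else:  # insert state: consumes query residues, no master column
            if ch not in (GAP, "."):
                residue_i += 1
    if residue_i != len(query):
        raise RrmBindError("alignment did not consume the full query")
    return AlignedRRM(entry_id=entry_id, sequence=query,
                      n_columns=master.n_columns,
                      column_of_residue=mapping)


# ---------------------------------------------------------------------------
# per-column contact / gap profiles

@dataclass
class ColumnProfile:
    """Percentage of entries contacting RNA / gapped, per master column."""

    contact_percentage: np.ndarray
    gap_percentage: np.ndarray = field(default=None)  # type: ignore[assignment]


def column_profiles(entries: list[ComplexEntry]) -> ColumnProfile:
    """Contact and gap percentages over master columns for bound entries.

    ``contact_percentage[c]`` is the percentage of entries with at least
    one residue-nucleotide contact at column ``c``.
    """
    if not entries:
        raise InputError("no entries")
    L = len(entries[0].aligned_seq or "")
    if L == 0:
        raise InputError("entries must be aligned")
    contact = np.zeros(L)
    gap = np.zeros(L)
    for e in entries:
        if e.aligned_seq is None or len(e.aligned_seq) != L:
            raise InputError(f"entry {e.entry_id} misaligned")
        contacted = set()
        for cols in e.contact_map.values():
            contacted.update(cols)
        if any(c >= L or c < 0 for c in contacted):
            raise InputError(
                f"entry {e.entry_id} has a contact outside the alignment")
        for c in contacted:
            contact[c] += 1
        for c, ch in enumerate(e.aligned_seq):
            if ch == GAP:
                gap[c] += 1
    n = len(entries)
    return ColumnProfile(contact_percentage=100.0 * contact / n,
                         gap_percentage=100.0 * gap / n)


# ---------------------------------------------------------------------------
# fixture-scale redundancy removal

def dedup_sequences(sequences: list[str],
                    identity_threshold: float = 0.99) -> list[str]:
    """Greedy identity-based redundancy removal (longest first).

    A sequence joins an existing representative when the pairwise
    identity (edit-distance based, over the longer length) is at least
    the threshold; otherwise it becomes a new representative.  This is a
    small-scale utility for near-duplicate removal, not a replacement
    for a proper clustering tool at low identity thresholds.
    """
    import edlib

    reps: list[str] = []
    for seq in sorted(sequences, key=lambda s: (-len(s), s)):
        for rep in reps:
            d = edlib.align(seq, rep, task="distance")["editDistance"]
            identity = 1.0 - d / max(len(seq), len(rep))
            if identity >= identity_threshold:
                break
        else:
            reps.append(seq)
    return reps
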