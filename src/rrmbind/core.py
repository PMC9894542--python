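"""Shared domain objects for RRM-RNA complexes.

The central coordinate system of the package is the *master alignment*
column index (see :mod:`rrmbind.alignment`).  A :class:`ComplexEntry`
records everything known about one RRM-RNA complex structure after its
protein sequence has been mapped into master columns: identifiers, the
gapped protein row, the bound RNA, and the contact map linking RNA
nucleotides to the master columns of the residues they touch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
RNA_ALPHABET = "ACGU"
GAP = "-"


class RrmBindError(Exception):
    """Base class for all package errors."""


class InputError(RrmBindError):
    """Invalid user-supplied input (bad sequence, malformed file, ...)."""


@dataclass(frozen=True)
class ContactRecord:
    """One residue-nucleotide contact, in structure-file numbering."""

    pdb_id: str
    protein_chain: str
    residue_number: int
    residue_code: str
    nucleotide_code: str
    nucleotide_number: int
    rna_chain: str

    def key(self) -> tuple:
        return (self.pdb_id, self.protein_chain, self.residue_number,
                self.nucleotide_number, self.rna_chain)


@dataclass(frozen=True)
class DomainRange:
    """Location of one RRM domain in a structure, in three numberings.

    ``pdb_*`` follow the residue numbers of the structure file,
    ``uniprot_*`` the UniProt sequence, and ``mapping_*`` the internal
    numbering of the sequence stored alongside the identifier (which may
    include extra terminal residues).
    """

    uniprot_id: str
    rrm_index: int
    pdb_id: str
    protein_chain: str
    pdb_start: int
    pdb_end: int
    uniprot_start: int
    uniprot_end: int
    mapping_start: int
    mapping_end: int
    rna_chain: str

    def __post_init__(self) -> None:
        for a, b in ((self.pdb_start, self.pdb_end),
                     (self.uniprot_start, self.uniprot_end),
                     (self.mapping_start, self.mapping_end)):
            if a > b:
                raise InputError(f"domain range start {a} > end {b}")

    @property
    def entry_id(self) -> str:
        return "_".join(str(x) for x in (
            self.uniprot_id, self.rrm_index, self.pdb_id, self.protein_chain,
            f"{self.pdb_start}-{self.pdb_end}",
            f"{self.uniprot_start}-{self.uniprot_end}",
            f"{self.mapping_start}-{self.mapping_end}", self.rna_chain))


@dataclass
class ComplexEntry:
    """One RRM-RNA complex mapped into master-alignment coordinates.

    Parameters
    ----------
    entry_id
        Unique identifier (conventionally UniProt id, RRM index, PDB id
        and chains joined by underscores).
    uniprot_id, pdb_id, protein_chain, rna_chain, rrm_index
        Identifiers of the underlying structure.
    aligned_seq
        Gapped protein row over the master columns (length == number of
        master columns) or ``None`` if not yet aligned.
    rna_seq
        The bound RNA sequence, 5'->3'.
    contact_map
        Mapping from 0-based nucleotide index in ``rna_seq`` to the set
        of master columns contacted by that nucleotide.
    contact_records
        Optional raw structure-numbering contacts this entry was built
        from.
    """

    entry_id: str
    uniprot_id: str
    pdb_id: str = ""
    protein_chain: str = ""
    rna_chain: str = ""
    rrm_index: int = 1
    aligned_seq: str | None = None
    rna_seq: str = ""
    contact_map: dict[int, set[int]] = field(default_factory=dict)
    contact_records: list[ContactRecord] = field(default_factory=list)

    def n_contacted_nucleotides(self) -> int:
        """Number of distinct nucleotides with at least one contact."""
        return sum(1 for cols in self.contact_map.values() if cols)

    def residue_at_column(self, column: int) -> str | None:
        """Residue at a master column, or ``None`` for a gap."""
        if self.aligned_seq is None:
            raise InputError(f"entry {self.entry_id} is not aligned")
        ch = self.aligned_seq[column]
        return None if ch == GAP else ch
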