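"""Residue-nucleotide contact extraction and the contact-list text format.

A residue and a nucleotide are in contact when *any* atom of one lies
strictly less than a distance cutoff (default 5.0 A) from any atom of
the other.  That definition keeps hydrogen bonds and electrostatics and
still admits hydrophobic packing at 3.8-5.0 A.

The plain-text contact format is one contact per line::

    <pdb>_<protein chain>, <resnum>_<res code>_<nuc code>_<nucnum>_<RNA chain>

e.g. ``2rs2_A, 21_K_G_4_B`` for lysine 21 of chain A touching guanine 4
of chain B.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import (AA_ALPHABET, RNA_ALPHABET, ComplexEntry, ContactRecord,
                   DomainRange, InputError)

logger = logging.getLogger(__name__)

#: Common modified residues/nucleotides mapped to their parent one-letter
#: code.  Anything not in here and not standard is excluded with a warning.
MODIFIED_PARENT = {
    # protein
    "MSE": "M", "SEP": "S", "TPO": "T", "PTR": "Y", "CSO": "C",
    "MLY": "K", "HYP": "P", "KCX": "K", "CME": "C", "PCA": "E",
    # RNA
    "PSU": "U", "5MC": "C", "5MU": "U", "1MA": "A", "OMG": "G",
    "OMC": "C", "OMU": "U", "2MG": "G", "7MG": "G", "M2G": "G", "4SU": "U",
    # DNA (thymine folded into U; see dna_as_rna flag on parsed chains)
    "DA": "A", "DC": "C", "DG": "G", "DT": "U", "DU": "U", "T": "U",
}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


@dataclass(frozen=True)
class AtomRecord:
    """A single atom with its residue context."""

    chain_id: str
    residue_number: int
    residue_code: str
    atom_name: str
    coordinates: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coordinates)):
            raise InputError(
                f"non-finite coordinates for atom {self.atom_name} "
                f"{self.chain_id}/{self.residue_number}")


def _residue_key(a: AtomRecord) -> tuple[str, int, str]:
    return (a.chain_id, a.residue_number, a.residue_code)


def extract_contacts(protein_atoms: list[AtomRecord],
                     rna_atoms: list[AtomRecord],
                     cutoff: float = 5.0,
                     pdb_id: str = "") -> list[ContactRecord]:
    """All residue-nucleotide pairs with any atom pair strictly < ``cutoff``.

    Each (residue, nucleotide) pair is reported once no matter how many
    of its atom pairs fall inside the cutoff, and the result does not
    depend on atom order.  Records are sorted by (protein chain, residue
    number, RNA chain, nucleotide number).
    """
    if not protein_atoms or not rna_atoms:
        raise InputError("empty atom list")
    if cutoff <= 0:
        raise InputError("cutoff must be positive")

    p_xyz = np.array([a.coordinates for a in protein_atoms], dtype=float)
    r_xyz = np.array([a.coordinates for a in rna_atoms], dtype=float)
    close = cdist(p_xyz, r_xyz) < cutoff  # strict inequality

    pairs: set[tuple] = set()
    for pi, ri in zip(*np.nonzero(close)):
        pa, ra = protein_atoms[pi], rna_atoms[ri]
        pairs.add((_residue_key(pa), _residue_key(ra)))

    records = [
        ContactRecord(pdb_id=pdb_id,
                      protein_chain=pk[0], residue_number=pk[1],
                      residue_code=pk[2], nucleotide_code=rk[2],
                      nucleotide_number=rk[1], rna_chain=rk[0])
        for pk, rk in pairs
    ]
    records.sort(key=lambda c: (c.protein_chain, c.residue_number,
                                c.rna_chain, c.nucleotide_number))
    return records


def filter_complexes_by_bound_length(complexes: list[ComplexEntry],
                                     min_nucleotides: int = 3
                                     ) -> list[ComplexEntry]:
    """Keep complexes recognizing at least ``min_nucleotides`` nucleotides.

    Structures where fewer than three nucleotides are contacted carry
    too little binding-mode information and are discarded by default.
    Input order is preserved.
    """
    return [c for c in complexes
            if c.n_contacted_nucleotides() >= min_nucleotides]


# ---------------------------------------------------------------------------
# contact-list text format

_CONTACT_RE = re.compile(
    r"^\s*(\S+)_(\S+),\s*(-?\d+)_([A-Za-z])_([A-Za-z])_(-?\d+)_(\S+)\s*$")


def parse_contact_line(line: str, line_number: int | None = None
                       ) -> ContactRecord:
    """Parse one contact line; raises :class:`InputError` on bad syntax."""
    m = _CONTACT_RE.match(line)
    if m is None:
        where = f" at line {line_number}" if line_number is not None else ""
        raise InputError(f"malformed contact line{where}: {line!r}")
    pdb_chain_pdb, chain, resnum, rescode, nuccode, nucnum, rna_chain = m.groups()
    return ContactRecord(
        pdb_id=pdb_chain_pdb, protein_chain=chain,
        residue_number=int(resnum), residue_code=rescode.upper(),
        nucleotide_code=nuccode.upper(), nucleotide_number=int(nucnum),
        rna_chain=rna_chain)


def format_contact_line(c: ContactRecord) -> str:
    return (f"{c.pdb_id}_{c.protein_chain}, {c.residue_number}_"
            f"{c.residue_code}_{c.nucleotide_code}_{c.nucleotide_number}_"
            f"{c.rna_chain}")


def read_contact_file(path) -> list[ContactRecord]:
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.strip():
                records.append(parse_contact_line(line, line_number=i))
    return records


def write_contact_file(path, records: list[ContactRecord]) -> None:
    with open(path, "w") as fh:
        for c in records:
            fh.write(format_contact_line(c) + "\n")


# ---------------------------------------------------------------------------
# complex identifier lists ("<UniProt>_<RRM no>_<PDB>_<chain>_<pdb range>_
# <uniprot range>_<mapping range>_<RNA chain>")

def parse_complex_id(text: str) -> DomainRange:
    parts = text.strip().split("_")
    if len(parts) != 8:
        raise InputError(f"expected 8 underscore fields, got {len(parts)}: "
                         f"{text!r}")
    uid, rrm, pdb, chain, pdb_rng, up_rng, map_rng, rna_chain = parts

    def rng(s: str) -> tuple[int, int]:
        a, _, b = s.partition("-")
        return int(a), int(b)

    ps, pe = rng(pdb_rng)
    us, ue = rng(up_rng)
    ms, me = rng(map_rng)
    return DomainRange(uniprot_id=uid, rrm_index=int(rrm), pdb_id=pdb,
                       protein_chain=chain, pdb_start=ps, pdb_end=pe,
                       uniprot_start=us, uniprot_end=ue,
                       mapping_start=ms, mapping_end=me, rna_chain=rna_chain)


# ---------------------------------------------------------------------------
# structure parsing (PDB / mmCIF via gemmi)

def _one_letter(resname: str, is_rna: bool) -> str | None:
    resname = resname.strip().upper()
    if is_rna:
        if resname in RNA_ALPHABET:
            return resname
        mapped = MODIFIED_PARENT.get(resname)
        return mapped if mapped in set(RNA_ALPHABET) else None
    if resname in AA3_TO_1:
        return AA3_TO_1[resname]
    mapped = MODIFIED_PARENT.get(resname)
    return mapped if mapped in set(AA_ALPHABET) else None


def load_structure_atoms(path, protein_chain: str, rna_chain: str
                         ) -> tuple[list[AtomRecord], list[AtomRecord]]:
    """Read a PDB or mmCIF file into protein and RNA atom lists.

    All atoms of each residue are kept (hydrogens included, if present);
    only the first alternate location is used.  Chain identifiers are
    matched case-sensitively.  Thymine and DNA residues are folded into
    the RNA alphabet (T -> U).  Unrecognized residues are skipped with a
    warning.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    out: dict[bool, list[AtomRecord]] = {False: [], True: []}
    wanted = {protein_chain: False, rna_chain: True}
    for chain in model:
        if chain.name not in wanted:
            continue
        is_rna = wanted[chain.name]
        for residue in chain:
            code = _one_letter(residue.name, is_rna)
            if code is None:
                if residue.name not in ("HOH", "H2O"):
                    warnings.warn(
                        f"skipping unrecognized residue {residue.name} in "
                        f"chain {chain.name}")
                continue
            if residue.name in ("DT", "T"):
                logger.info("DNA thymine %s/%d mapped to U",
                            chain.name, residue.seqid.num)
            seen_altloc: set[str] = set()
            for atom in residue:
                if atom.altloc not in ("", "\0"):
                    if atom.name in seen_altloc:
                        continue
                    seen_altloc.add(atom.name)
                out[is_rna].append(AtomRecord(
                    chain_id=chain.name,
                    residue_number=residue.seqid.num,
                    residue_code=code,
                    atom_name=atom.name,
                    coordinates=(atom.pos.x, atom.pos.y, atom.pos.z)))
    return out[False], out[True]


def contacts_from_structure(path, protein_chain: str, rna_chain: str,
                            cutoff: float = 5.0,
                            pdb_id: str | None = None) -> list[ContactRecord]:
    """Convenience wrapper: parse a structure file and extract contacts."""
    import os

    prot, rna = load_structure_atoms(path, protein_chain, rna_chain)
    if pdb_id is None:
        pdb_id = os.path.splitext(os.path.basename(str(path)))[0]
    return extract_contacts(prot, rna, cutoff=cutoff, pdb_id=pdb_id)
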