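"""Synthetic RRM-RNA fixtures with planted, recoverable structure.

The generator emulates the statistical shape of a curated complex
corpus — a column-annotated master alignment, several structures per
protein (to exercise per-protein count normalization), complexes that
share one binding frame (so the similarity score clusters them
together), variable RNA lengths with non-contacting flanks, and planted
(residue, nucleotide) preferences at chosen grid positions — without
any physical realism.  Every draw flows from a single seed, so
identical specs give byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import CORE_ELEMENTS, ELEMENT_ORDER, MasterAlignment
from .contacts import AA1_TO_3, AtomRecord
from .core import AA_ALPHABET, GAP, RNA_ALPHABET, ComplexEntry, InputError

DEFAULT_LAYOUT = (
    ("Nterm", 5), ("β1", 4), ("loop1", 5), ("α1", 12), ("loop2", 4),
    ("β2", 4), ("loop3", 6), ("β3", 5), ("loop4", 4), ("α2", 12),
    ("loop5", 5), ("β4", 4), ("Cterm", 6),
)

#: Which master grid positions each RNA core position touches: the
#: shared binding frame of every generated complex (beta-sheet face,
#: RNP1/RNP2 columns included).
DEFAULT_CONTACT_SCHEME = {
    1: ("β2–3", "loop3–2"),
    2: ("β1–3", "β3–5"),
    3: ("β3–3", "β1–3"),
    4: ("β1–1", "β3–3", "β4–3"),
    5: ("β3–1", "loop5–2"),
}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic cluster."""

    n_uniprot_groups: int = 30
    structures_per_group: tuple[int, int] = (1, 4)
    element_layout: tuple = DEFAULT_LAYOUT
    contact_scheme: dict = field(
        default_factory=lambda: dict(DEFAULT_CONTACT_SCHEME))
    planted_preferences: list[tuple[str, str, str, float]] = field(
        default_factory=list)          # (grid label, residue, nuc, enrich)
    rna_length_range: tuple[int, int] = (3, 11)
    sprinkle_rate: float = 0.05
    interface_palette_size: int = 3
    code_enrichment: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for _, _, _, enrich in self.planted_preferences:
            if enrich < 1:
                raise InputError("enrichment factor must be >= 1")
        if self.code_enrichment is not None and self.code_enrichment < 1:
            raise InputError("code_enrichment must be >= 1")


@dataclass
class FixtureTruth:
    """Ground truth recorded during generation."""

    planted_cells: list[dict]            # column/position/residue/nucleotide
    group_residues: dict[str, str]       # uniprot id -> gapped master row
    entry_spans: dict[str, tuple[int, int]]   # entry -> (first, last) core pos
    scheme_columns: dict[int, frozenset[int]]


def _spans_from_layout(layout) -> list[tuple[str, int, int]]:
    spans, start = [], 0
    names = [e for e, _ in layout]
    if names != list(ELEMENT_ORDER):
        raise InputError("layout must list the 13 elements in fold order")
    for elem, width in layout:
        spans.append((elem, start, start + width))
        start += width
    return spans


def _group_row(rng: np.random.Generator, spans,
               planted_residue_at: dict[int, str]) -> str:
    """One gapped master row, already in squeezed form."""
    aa = list(AA_ALPHABET)
    parts = []
    for elem, s, t in spans:
        width = t - s
        if elem in CORE_ELEMENTS:
            n_gaps = 0
        elif elem in ("Nterm", "Cterm"):
            n_gaps = int(rng.integers(0, 3))
        else:
            n_gaps = int(rng.integers(0, 2))
        n_res = width - n_gaps
        # columns that keep a residue, respecting the squeeze convention
        if elem == "Nterm":
            res_cols = list(range(s + n_gaps, t))
        elif elem == "Cterm":
            res_cols = list(range(s, s + n_res))
        else:
            left = (n_res + 1) // 2
            res_cols = (list(range(s, s + left))
                        + list(range(t - (n_res - left), t)))
        seg = []
        for col in range(s, t):
            if col not in res_cols:
                seg.append(GAP)
            elif col in planted_residue_at:
                seg.append(planted_residue_at[col])
            else:
                seg.append(aa[rng.integers(len(aa))])
        parts.append("".join(seg))
    return "".join(parts)


def generate_cluster(spec: FixtureSpec
                     ) -> tuple[MasterAlignment, list[ComplexEntry],
                                FixtureTruth]:
    """Generate a master alignment and a cluster of synthetic complexes.

    Planted preferences: at the stated grid position, half the protein
    groups carry the planted residue; their structures then draw the
    paired nucleotide with odds ``enrichment`` : 1 : 1 : 1 relative to
    each other nucleotide (``enrichment=1`` is the null).  Groups
    without the planted residue draw uniformly.
    """
    rng = np.random.default_rng(spec.seed)
    spans = _spans_from_layout(spec.element_layout)
    probe = MasterAlignment(entries={"_probe": _probe_row(spans)},
                            element_spans=spans)

    scheme_cols = {pos: frozenset(probe.column_of_label(lbl)
                                  for lbl in labels)
                   for pos, labels in spec.contact_scheme.items()}
    core_pos = sorted(scheme_cols)
    interface_cols = sorted(set().union(*scheme_cols.values()))

    planted = []
    driven: dict[int, list[dict]] = {}
    for label, residue, nucleotide, enrich in spec.planted_preferences:
        col = probe.column_of_label(label)
        pos = next((p for p, cols in scheme_cols.items() if col in cols),
                   None)
        if pos is None:
            raise InputError(
                f"planted position {label} is outside the binding frame")
        if any(c["column"] == col for c in planted):
            raise InputError(f"column {label} already carries a planted "
                             "preference")
        cell = {"column": col, "position": pos, "residue": residue,
                "nucleotide": nucleotide, "enrichment": enrich,
                "label": label}
        planted.append(cell)
        driven.setdefault(pos, []).append(cell)

    # small per-column residue repertoires at the interface: binding
    # positions of real RRMs are conserved, and shared residues across
    # proteins are what makes cross-entry statistics possible
    aa = list(AA_ALPHABET)
    palettes: dict[int, list[str]] = {}
    for col in interface_cols:
        pick = rng.choice(len(aa), size=spec.interface_palette_size,
                          replace=False)
        palettes[col] = [aa[i] for i in pick]
    for cell in planted:
        pal = palettes[cell["column"]]
        if cell["residue"] not in pal:
            pal[0] = cell["residue"]
    planted_cols = {cell["column"]: cell for cell in planted}

    if spec.code_enrichment is not None:
        # a full recognition code: every palette residue at every
        # interface column prefers its own (seeded) nucleotide
        taken = {(c["column"], c["residue"]) for c in planted}
        for pos, cols in sorted(scheme_cols.items()):
            for col in sorted(cols):
                for residue in palettes[col]:
                    if (col, residue) in taken:
                        continue
                    nuc = RNA_ALPHABET[rng.integers(4)]
                    driven.setdefault(pos, []).append({
                        "column": col, "position": pos,
                        "residue": residue, "nucleotide": nuc,
                        "enrichment": spec.code_enrichment,
                        "label": None})

    nucs = list(RNA_ALPHABET)
    rows: dict[str, str] = {}
    entries: list[ComplexEntry] = []
    entry_spans: dict[str, tuple[int, int]] = {}
    lo_s, hi_s = spec.structures_per_group
    for g in range(spec.n_uniprot_groups):
        uid = f"UP{g:03d}"
        fixed_residue_at = {}
        for col in interface_cols:
            pal = palettes[col]
            cell = planted_cols.get(col)
            if cell is not None:
                others = [a for a in pal if a != cell["residue"]]
                fixed_residue_at[col] = (
                    cell["residue"] if rng.random() < 0.5 or not others
                    else others[rng.integers(len(others))])
            else:
                fixed_residue_at[col] = pal[rng.integers(len(pal))]
        row = _group_row(rng, spans, fixed_residue_at)
        rows[uid] = row

        n_struct = int(rng.integers(lo_s, hi_s + 1))
        for s in range(n_struct):
            entry_id = f"{uid}_1_pdb{g:03d}{chr(ord('a') + s)}_A"
            span_len = int(rng.integers(3, len(core_pos) + 1))
            first = int(rng.integers(1, len(core_pos) - span_len + 2))
            positions = list(range(first, first + span_len))

            contacted = []
            for p in positions:
                # active preferences multiply their odds per nucleotide
                w = np.ones(len(nucs))
                for cell in driven.get(p, []):
                    if row[cell["column"]] == cell["residue"]:
                        w *= np.array([cell["enrichment"]
                                       if n == cell["nucleotide"] else 1.0
                                       for n in nucs])
                nuc = nucs[rng.choice(len(nucs), p=w / w.sum())]
                contacted.append(nuc)

            lo_l, hi_l = spec.rna_length_range
            total = int(rng.integers(max(lo_l, span_len), hi_l + 1))
            extra5 = int(rng.integers(0, total - span_len + 1))
            extra3 = total - span_len - extra5
            rna = ("".join(nucs[rng.integers(len(nucs))]
                           for _ in range(extra5))
                   + "".join(contacted)
                   + "".join(nucs[rng.integers(len(nucs))]
                             for _ in range(extra3)))

            contact_map: dict[int, set[int]] = {}
            for k, p in enumerate(positions):
                cols = set(scheme_cols[p])
                if rng.random() < spec.sprinkle_rate:
                    cols.add(interface_cols[
                        rng.integers(len(interface_cols))])
                contact_map[extra5 + k] = cols

            entries.append(ComplexEntry(
                entry_id=entry_id, uniprot_id=uid,
                pdb_id=f"pdb{g:03d}{chr(ord('a') + s)}",
                protein_chain="A", rna_chain="B",
                aligned_seq=row, rna_seq=rna, contact_map=contact_map))
            entry_spans[entry_id] = (first, first + span_len - 1)

    master = MasterAlignment(entries=rows, element_spans=spans)
    truth = FixtureTruth(planted_cells=planted, group_residues=rows,
                         entry_spans=entry_spans,
                         scheme_columns=scheme_cols)
    return master, entries, truth


def _probe_row(spans) -> str:
    return "A" * spans[-1][2]


# ---------------------------------------------------------------------------
# geometric toy structures

@dataclass
class ToyStructureLayout:
    """Which (residue number, nucleotide number) pairs must touch."""

    residues: list[tuple[int, str]]          # (number, one-letter code)
    nucleotides: list[tuple[int, str]]
    contacts: list[tuple[int, int]]          # (residue number, nuc number)
    protein_chain: str = "A"
    rna_chain: str = "B"


def generate_toy_structure(layout: ToyStructureLayout
                           ) -> tuple[list[AtomRecord], list[AtomRecord]]:
    """Atom records realizing a contact layout exactly.

    Every required pair gets a dedicated atom pair at 3.5 A; all other
    residue-nucleotide atom pairs are >= 8 A apart, so a 5 A cutoff
    recovers the layout and nothing else.
    """
    if len(set(layout.contacts)) != len(layout.contacts):
        raise InputError("duplicate contact pair in layout")
    res_numbers = {n for n, _ in layout.residues}
    nuc_numbers = {n for n, _ in layout.nucleotides}
    for rn, nn in layout.contacts:
        if rn not in res_numbers or nn not in nuc_numbers:
            raise InputError(f"contact ({rn}, {nn}) references an unknown "
                             "residue or nucleotide")

    protein, rna = [], []
    for i, (num, code) in enumerate(layout.residues):
        protein.append(AtomRecord(layout.protein_chain, num, code, "CA",
                                  (10.0 * i, 0.0, 0.0)))
    for i, (num, code) in enumerate(layout.nucleotides):
        rna.append(AtomRecord(layout.rna_chain, num, code, "C1'",
                              (10.0 * i, 40.0, 0.0)))
    res_code = dict(layout.residues)
    nuc_code = dict(layout.nucleotides)
    for p, (rn, nn) in enumerate(layout.contacts):
        site = (200.0 + 25.0 * p, 120.0, 0.0)
        protein.append(AtomRecord(layout.protein_chain, rn, res_code[rn],
                                  "CB", site))
        rna.append(AtomRecord(layout.rna_chain, nn, nuc_code[nn], "C2'",
                              (site[0] + 3.5, site[1], site[2])))
    return protein, rna


def write_toy_pdb(path, protein: list[AtomRecord],
                  rna: list[AtomRecord]) -> None:
    """Write toy atom records as a minimal PDB file (via gemmi)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for rec, is_rna in ([(a, False) for a in protein]
                        + [(a, True) for a in rna]):
        chain = chains.get(rec.chain_id)
        if chain is None:
            chain = gemmi.Chain(rec.chain_id)
            chains[rec.chain_id] = chain
        resname = rec.residue_code if is_rna else AA1_TO_3[rec.residue_code]
        res = None
        for existing in chain:
            if existing.seqid.num == rec.residue_number:
                res = existing
                break
        if res is None:
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(rec.residue_number, " ")
            chain.add_residue(res)
            res = chain[-1]
        atom = gemmi.Atom()
        atom.name = rec.atom_name
        atom.pos = gemmi.Position(*rec.coordinates)
        atom.element = gemmi.Element(rec.atom_name[0])
        res.add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
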