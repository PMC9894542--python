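"""The information-theoretic RRM-RNA specificity scorer.

The scorer is trained on a cluster of RRM-RNA complexes sharing one
binding mode.  For each *key interaction* — a (master column j, RNA
core position i) pair contacted in at least a fraction (default 20%) of
the distinct proteins in the cluster — a score is computed for every
(residue r, nucleotide n) combination:

    I(dN_i; R_j) = log( f[N_i,R_j] / f[n-N_i,R_j] )
                 + log( f[n-N_i]   / f[N_i] )

where ``f[N_i,R_j]`` counts nucleotide n at position i contacting
residue r at column j, ``f[n-N_i,R_j]`` counts the *other* nucleotides
contacting that residue there, and ``f[N_i]`` / ``f[n-N_i]`` are the
nucleotide marginals at position i.  This is the GOR information
difference: the residue background cancels between the two terms.
Positive scores mean the contact is seen more often than chance,
negative the opposite, near zero no preference (e.g. the RNP1/RNP2
stacking aromatics).

All counts are UniProt-normalized: a protein with ten deposited
structures showing a contact in eight of them contributes 0.8, not 8,
so heavily studied proteins do not dominate the statistics.

The final binding score of an (RRM sequence, RNA window) pair is the
arithmetic mean of the per-interaction scores; cells never observed in
training are "no data" and are skipped (and counted) rather than
silently scored.

Usage follows the Model/Results convention::

    model = BindingSpecificityModel(entries, rna_msa)
    res = model.fit()
    pred = res.score_pair(aligned_rrm, "UAGUA")
    res.summary()
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import AlignedRRM, MasterAlignment
from .binding_modes import RnaContactProfile, RnaMsa
from .core import AA_ALPHABET, RNA_ALPHABET, ComplexEntry, InputError

NUCS = tuple(RNA_ALPHABET)


@dataclass
class ContactCountTable:
    """UniProt-normalized counts behind one key interaction (j, i).

    ``f_n_r[(n, r)]`` is the normalized count of nucleotide ``n`` at the
    RNA position contacting residue ``r`` at the column; ``f_n[n]`` is
    the normalized marginal count of nucleotide ``n`` at the position.
    """

    column: int
    position: int
    f_n_r: dict[tuple[str, str], float]
    f_n: dict[str, float]

    def f_notn_r(self, n: str, r: str) -> float:
        return sum(v for (n2, r2), v in self.f_n_r.items()
                   if r2 == r and n2 != n)

    def f_notn(self, n: str) -> float:
        return sum(self.f_n.values()) - self.f_n.get(n, 0.0)

    def residues(self) -> list[str]:
        return sorted({r for (_, r) in self.f_n_r})


def information_score(counts: ContactCountTable, residue: str,
                      nucleotide: str, log_base: float | None = None,
                      pseudocount: float = 0.0) -> float | None:
    """Information score for one (residue, nucleotide) cell.

    Returns ``None`` ("no data") when any of the four frequencies is
    zero and no pseudocount is configured.  ``log_base=None`` uses the
    natural logarithm.
    """
    fnr = counts.f_n_r.get((nucleotide, residue), 0.0) + pseudocount
    fnotr = counts.f_notn_r(nucleotide, residue) + pseudocount
    fn = counts.f_n.get(nucleotide, 0.0) + pseudocount
    fnotn = counts.f_notn(nucleotide) + pseudocount
    if min(fnr, fnotr, fn, fnotn) <= 0.0:
        return None
    val = math.log(fnr / fnotr) + math.log(fnotn / fn)
    if log_base is not None:
        val /= math.log(log_base)
    return val


@dataclass
class ScoreTable:
    """Score and observation-count matrices for one key interaction."""

    column: int
    position: int
    label: str
    scores: pd.DataFrame   # residues x ACGU, NaN = no data
    counts: pd.DataFrame   # residues x ACGU, normalized observation counts

    def no_data_cells(self) -> list[tuple[str, str]]:
        out = []
        for r in self.scores.index:
            for n in self.scores.columns:
                if np.isnan(self.scores.at[r, n]):
                    out.append((r, n))
        return out


@dataclass
class BindingPrediction:
    """Score of one RNA window against one RRM sequence."""

    window: str
    start_position: int            # RNA core position of the window's 5' end
    rna_offset: int | None         # 0-based 5' offset in the scanned RNA
    raw_score: float
    breakdown: list[dict]          # per scored interaction
    n_scored: int
    n_skipped: int
    report_offset: float | None = None
    confidence: float | None = None

    @property
    def reported_score(self) -> float:
        if self.report_offset is None:
            return self.raw_score
        return self.raw_score + self.report_offset


@dataclass
class MutationEffect:
    substitution: tuple[int, str, str]   # (0-based index, old, new)
    before: BindingPrediction
    after: BindingPrediction
    deltas: list[dict]
    at_key_column: bool


def parse_substitution(text: str) -> tuple[int, str, str]:
    """Parse ``"E87N"`` into (0-based residue index, old, new)."""
    m = re.fullmatch(r"([A-Za-z])(\d+)([A-Za-z])", text.strip())
    if not m:
        raise InputError(f"malformed substitution {text!r} (expected E87N)")
    old, pos, new = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if new not in AA_ALPHABET:
        raise InputError(f"{new!r} is not an amino acid")
    return pos - 1, old, new


# ---------------------------------------------------------------------------

def _entry_core_view(entry: ComplexEntry, rna_msa: RnaMsa
                     ) -> dict[int, tuple[str, frozenset[int]]]:
    """Map 1-based core position -> (nucleotide, contacted columns)."""
    profile = RnaContactProfile.from_entry(entry)
    offset = rna_msa.offsets[entry.entry_id]
    view = {}
    for rank, frame_pos in enumerate(rna_msa.core_positions, start=1):
        j = frame_pos - offset
        if 0 <= j < len(profile):
            view[rank] = (profile.sequence[j], profile.columns[j])
    return view


class BindingSpecificityModel:
    """Trainable residue-nucleotide preference model for one binding mode.

    Parameters
    ----------
    entries
        Aligned cluster members with contact maps.
    rna_msa
        The cluster's contact-anchored RNA alignment with core positions
        selected.
    master
        Optional master alignment; used only to render grid labels.
    prevalence
        Minimum fraction of distinct UniProt ids that must show a
        contact at a (column, position) pair for it to become a key
        interaction (inclusive, default 0.20).
    log_base
        Base of the logarithm in the information score (``None`` =
        natural log).
    pseudocount
        Additive smoothing for the four frequencies (default 0 = off;
        zero-observation cells are then "no data").
    normalize
        ``"uniprot"`` (default) for per-protein fractional counts, or
        ``"raw"`` for plain structure counts.

    Key interactions are selected once, on the full entry set; ``fit``
    may exclude entries (leave-one-out, case studies) and recomputes
    only the count tables.
    """

    def __init__(self, entries: list[ComplexEntry], rna_msa: RnaMsa,
                 master: MasterAlignment | None = None,
                 prevalence: float = 0.20,
                 log_base: float | None = None,
                 pseudocount: float = 0.0,
                 normalize: str = "uniprot"):
        if not entries:
            raise InputError("empty cluster")
        if not rna_msa.core_positions:
            raise InputError("rna_msa has no core positions selected "
                             "(run select_core_positions first)")
        if normalize not in ("uniprot", "raw"):
            raise InputError(f"unknown normalization {normalize!r}")
        self.entries = list(entries)
        self.rna_msa = rna_msa
        self.master = master
        self.prevalence = prevalence
        self.log_base = log_base
        self.pseudocount = pseudocount
        self.normalize = normalize
        self._views = {e.entry_id: _entry_core_view(e, rna_msa)
                       for e in entries}
        self.key_interactions = self._select_key_interactions()

    # -- training ----------------------------------------------------------

    def _groups(self, exclude: frozenset[str]) -> dict[str, list[ComplexEntry]]:
        groups: dict[str, list[ComplexEntry]] = {}
        for e in self.entries:
            if e.entry_id in exclude:
                continue
            groups.setdefault(e.uniprot_id, []).append(e)
        return groups

    def _select_key_interactions(self) -> list[tuple[int, int]]:
        """(column, core position) pairs contacted by enough proteins."""
        groups = self._groups(frozenset())
        n_uniprot = len(groups)
        seen: dict[tuple[int, int], set[str]] = {}
        for uid, members in groups.items():
            for e in members:
                for pos, (_, cols) in self._views[e.entry_id].items():
                    for col in cols:
                        seen.setdefault((col, pos), set()).add(uid)
        keep = [(col, pos) for (col, pos), uids in seen.items()
                if len(uids) >= self.prevalence * n_uniprot]
        return sorted(keep, key=lambda t: (t[1], t[0]))

    def _count_table(self, column: int, position: int,
                     exclude: frozenset[str]) -> ContactCountTable:
        f_n_r: dict[tuple[str, str], float] = {}
        f_n: dict[str, float] = {}
        for uid, members in self._groups(exclude).items():
            n_struct = len(members)
            cell_hits: dict[tuple[str, str], int] = {}
            nuc_hits: dict[str, int] = {}
            for e in members:
                view = self._views[e.entry_id]
                if position in view:
                    nuc, cols = view[position]
                    nuc_hits[nuc] = nuc_hits.get(nuc, 0) + 1
                    if column in cols:
                        r = e.residue_at_column(column)
                        if r is not None:
                            key = (nuc, r)
                            cell_hits[key] = cell_hits.get(key, 0) + 1
            denom = n_struct if self.normalize == "uniprot" else 1
            for key, c in cell_hits.items():
                f_n_r[key] = f_n_r.get(key, 0.0) + c / denom
            for n, c in nuc_hits.items():
                f_n[n] = f_n.get(n, 0.0) + c / denom
        return ContactCountTable(column=column, position=position,
                                 f_n_r=f_n_r, f_n=f_n)

    def _label(self, column: int, position: int) -> str:
        if self.master is not None:
            return f"{self.master.grid_label(column)}/RNA{position}"
        return f"col{column}/RNA{position}"

    def fit(self, exclude: "frozenset[str] | set[str] | tuple" = ()
            ) -> "BindingSpecificityResults":
        """Build count and score tables, optionally excluding entries."""
        exclude = frozenset(exclude)
        remaining = [e for e in self.entries if e.entry_id not in exclude]
        if not remaining:
            raise InputError("excluding every entry leaves nothing to fit")
        tables = {}
        counts = {}
        for col, pos in self.key_interactions:
            ct = self._count_table(col, pos, exclude)
            counts[(col, pos)] = ct
            residues = ct.residues()
            score = pd.DataFrame(np.nan, index=residues, columns=list(NUCS))
            obs = pd.DataFrame(0.0, index=residues, columns=list(NUCS))
            for r in residues:
                for n in NUCS:
                    obs.at[r, n] = ct.f_n_r.get((n, r), 0.0)
                    val = information_score(ct, r, n, self.log_base,
                                            self.pseudocount)
                    if val is not None:
                        score.at[r, n] = val
            tables[(col, pos)] = ScoreTable(
                column=col, position=pos, label=self._label(col, pos),
                scores=score, counts=obs)
        return BindingSpecificityResults(self, tables, counts, exclude)


class _FrozenModel:
    """Just enough model surface to score from a serialized table set."""

    def __init__(self, key_interactions, core_positions, labels,
                 normalize="uniprot", log_base=None):
        from types import SimpleNamespace

        self.key_interactions = key_interactions
        self.rna_msa = SimpleNamespace(core_positions=core_positions)
        self.normalize = normalize
        self.log_base = log_base
        self.entries: list = []
        self._labels = labels

    def _label(self, column, position):
        return self._labels.get((column, position),
                                f"col{column}/RNA{position}")

    def _groups(self, exclude):
        return {}


class BindingSpecificityResults:
    """Fitted score tables plus prediction and reporting methods."""

    def __init__(self, model: BindingSpecificityModel,
                 tables: dict[tuple[int, int], ScoreTable],
                 counts: dict[tuple[int, int], ContactCountTable],
                 excluded: frozenset[str]):
        self.model = model
        self.tables = tables
        self.counts = counts
        self.excluded = excluded

    @property
    def key_interactions(self) -> list[tuple[int, int]]:
        return self.model.key_interactions

    @property
    def n_core_positions(self) -> int:
        return len(self.model.rna_msa.core_positions)

    def cell_score(self, column: int, position: int, residue: str,
                   nucleotide: str) -> float | None:
        """Score of one cell; ``None`` when the cell has no data."""
        table = self.tables.get((column, position))
        if table is None:
            raise InputError(f"({column}, {position}) is not a key "
                             "interaction")
        if residue not in table.scores.index:
            return None
        val = table.scores.at[residue, nucleotide]
        return None if np.isnan(val) else float(val)

    # -- prediction --------------------------------------------------------

    def _default_start(self, window_len: int) -> int:
        # 3'-anchored: a 5-mer covers positions 1..5, a 3-mer 3..5
        return self.n_core_positions - window_len + 1

    def _score_positions(self, residue_at, nucleotides: dict[int, str],
                         window: str, start: int,
                         rna_offset: int | None = None,
                         report_offset: float | None = None
                         ) -> BindingPrediction:
        breakdown, skipped = [], 0
        for col, pos in self.key_interactions:
            n = nucleotides.get(pos)
            if n is None:
                continue
            r = residue_at(col)
            if r is None:
                skipped += 1
                continue
            val = self.cell_score(col, pos, r, n)
            if val is None:
                skipped += 1
                continue
            breakdown.append({
                "column": col, "position": pos,
                "label": self.model._label(col, pos),
                "residue": r, "nucleotide": n, "score": val,
                "count": float(self.tables[(col, pos)].counts.at[r, n]),
            })
        raw = (sum(b["score"] for b in breakdown) / len(breakdown)
               if breakdown else float("nan"))
        return BindingPrediction(
            window=window, start_position=start, rna_offset=rna_offset,
            raw_score=raw, breakdown=breakdown, n_scored=len(breakdown),
            n_skipped=skipped, report_offset=report_offset)

    def score_pair(self, rrm: "AlignedRRM | ComplexEntry", rna_window: str,
                   start_position: int | None = None,
                   report_offset: float | None = None) -> BindingPrediction:
        """Score a 3-5 nucleotide RNA window against an aligned RRM.

        ``start_position`` places the window's 5' nucleotide on an RNA
        core position (1-based); by default windows are 3'-anchored, so
        a 5-mer occupies positions 1-5 and a 3-mer positions 3-5.
        """
        rna_window = rna_window.strip().upper().replace("T", "U")
        k = self.n_core_positions
        if not (3 <= len(rna_window) <= min(5, k)):
            raise InputError(
                f"window length must be 3-{min(5, k)}, got {len(rna_window)}")
        if any(ch not in RNA_ALPHABET for ch in rna_window):
            raise InputError(f"window {rna_window!r} contains non-ACGU "
                             "characters")
        start = (self._default_start(len(rna_window))
                 if start_position is None else start_position)
        if not (1 <= start and start + len(rna_window) - 1 <= k):
            raise InputError(f"window does not fit core positions at "
                             f"start {start}")
        nucleotides = {start + i: ch for i, ch in enumerate(rna_window)}
        return self._score_positions(rrm.residue_at_column, nucleotides,
                                     rna_window, start,
                                     report_offset=report_offset)

    def scan(self, rrm: "AlignedRRM | ComplexEntry", rna: str,
             window: int = 5,
             report_offset: float | None = None) -> list[BindingPrediction]:
        """Score every 5'->3' sliding window of ``rna``.

        The best window (ties toward 5') is the predicted binding site.
        """
        rna = rna.strip().upper().replace("T", "U")
        if not (3 <= window <= 5):
            raise InputError("window must be 3-5 nucleotides")
        if len(rna) < window:
            raise InputError("RNA shorter than the window")
        out = []
        for off in range(len(rna) - window + 1):
            pred = self.score_pair(rrm, rna[off:off + window],
                                   report_offset=report_offset)
            pred.rna_offset = off
            out.append(pred)
        return out

    @staticmethod
    def best_window(predictions: list[BindingPrediction]) -> BindingPrediction:
        finite = [p for p in predictions if not math.isnan(p.raw_score)]
        if not finite:
            raise InputError("no scorable window")
        return max(finite, key=lambda p: (p.raw_score,
                                          -(p.rna_offset or 0)))

    def mutation_effect(self, rrm: AlignedRRM,
                        substitution: tuple[int, str] | str,
                        rna_window: str,
                        start_position: int | None = None) -> MutationEffect:
        """Effect of a single residue substitution on a window score.

        ``substitution`` is ``(0-based residue index, new residue)`` or
        an ``"E87N"`` string (1-based, old residue checked).
        """
        if isinstance(substitution, str):
            idx, old, new = parse_substitution(substitution)
            if idx >= len(rrm.sequence) or rrm.sequence[idx] != old:
                raise InputError(
                    f"substitution {substitution!r} does not match the "
                    f"sequence (found "
                    f"{rrm.sequence[idx] if idx < len(rrm.sequence) else '?'}"
                    f" at {idx + 1})")
        else:
            idx, new = substitution
            if not (0 <= idx < len(rrm.sequence)):
                raise InputError("substitution index out of range")
            old, new = rrm.sequence[idx], new.upper()
        mutated = AlignedRRM(
            entry_id=f"{rrm.entry_id}_{old}{idx + 1}{new}",
            sequence=rrm.sequence[:idx] + new + rrm.sequence[idx + 1:],
            n_columns=rrm.n_columns,
            column_of_residue=dict(rrm.column_of_residue))
        before = self.score_pair(rrm, rna_window, start_position)
        after = self.score_pair(mutated, rna_window, start_position)
        col = rrm.column_of_residue.get(idx)
        key_cols = {c for c, _ in self.key_interactions}
        at_key = col is not None and col in key_cols
        if not at_key:
            warnings.warn(
                f"substitution {old}{idx + 1}{new} is not at a key-"
                "interaction column; the score is unchanged")
        by_key_b = {(b["column"], b["position"]): b for b in before.breakdown}
        by_key_a = {(a["column"], a["position"]): a for a in after.breakdown}
        deltas = []
        for key in sorted(set(by_key_b) | set(by_key_a),
                          key=lambda t: (t[1], t[0])):
            sb = by_key_b.get(key, {}).get("score")
            sa = by_key_a.get(key, {}).get("score")
            if sb != sa:
                deltas.append({"column": key[0], "position": key[1],
                               "before": sb, "after": sa})
        return MutationEffect(substitution=(idx, old, new), before=before,
                              after=after, deltas=deltas, at_key_column=at_key)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable account of the fitted model."""
        lines = [
            "Binding specificity model (information scores)",
            "=" * 54,
            f"entries in training set : "
            f"{len(self.model.entries) - len(self.excluded)}"
            + (f" (excluded {sorted(self.excluded)})" if self.excluded
               else ""),
            f"distinct proteins       : "
            f"{len(self.model._groups(self.excluded))}",
            f"key interactions        : {len(self.key_interactions)}",
            f"RRM columns involved    : "
            f"{len({c for c, _ in self.key_interactions})}",
            f"RNA core positions      : {self.n_core_positions}",
            f"normalization           : {self.model.normalize}",
            f"log base                : "
            f"{self.model.log_base if self.model.log_base else 'e'}",
            "",
        ]
        for (col, pos) in self.key_interactions:
            t = self.tables[(col, pos)]
            lines.append(f"-- {t.label} (column {col}, RNA position {pos})")
            lines.append(t.scores.round(2).to_string())
            lines.append("")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        doc = {
            "meta": {
                "excluded": sorted(self.excluded),
                "normalize": self.model.normalize,
                "log_base": self.model.log_base,
                "pseudocount": self.model.pseudocount,
                "prevalence": self.model.prevalence,
                "core_positions": self.model.rna_msa.core_positions,
            },
            "interactions": [
                {
                    "column": col, "position": pos,
                    "label": self.tables[(col, pos)].label,
                    "residues": list(self.tables[(col, pos)].scores.index),
                    "scores": [[None if np.isnan(v) else v for v in row]
                               for row in
                               self.tables[(col, pos)].scores.to_numpy()],
                    "counts": self.tables[(col, pos)].counts.to_numpy()
                              .tolist(),
                }
                for col, pos in self.key_interactions
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "BindingSpecificityResults":
        """Reload a serialized model for scoring (no refitting possible)."""
        with open(path) as fh:
            doc = json.load(fh)
        tables: dict[tuple[int, int], ScoreTable] = {}
        labels: dict[tuple[int, int], str] = {}
        for item in doc["interactions"]:
            key = (item["column"], item["position"])
            labels[key] = item["label"]
            scores = pd.DataFrame(
                [[np.nan if v is None else v for v in row]
                 for row in item["scores"]],
                index=item["residues"], columns=list(NUCS))
            counts = pd.DataFrame(item["counts"], index=item["residues"],
                                  columns=list(NUCS))
            tables[key] = ScoreTable(column=key[0], position=key[1],
                                     label=item["label"], scores=scores,
                                     counts=counts)
        frozen = _FrozenModel(
            key_interactions=sorted(tables, key=lambda t: (t[1], t[0])),
            core_positions=doc["meta"]["core_positions"], labels=labels,
            normalize=doc["meta"]["normalize"],
            log_base=doc["meta"]["log_base"])
        return cls(frozen, tables, {},  # counts not serialized
                   frozenset(doc["meta"]["excluded"]))

    def score_table_csv(self, column: int, position: int, path) -> None:
        t = self.tables[(column, position)]
        merged = pd.concat({"score": t.scores, "count": t.counts}, axis=1)
        merged.to_csv(path)

    def plot_score_matrix(self, column: int, position: int, ax=None):
        """Heatmap of one interaction's score matrix."""
        import matplotlib.pyplot as plt

        t = self.tables[(column, position)]
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 0.5 * len(t.scores) + 1))
        data = t.scores.to_numpy(dtype=float)
        im = ax.imshow(data, cmap="RdBu_r", vmin=-2, vmax=2)
        ax.set_xticks(range(len(NUCS)), NUCS)
        ax.set_yticks(range(len(t.scores.index)), t.scores.index)
        ax.set_title(t.label)
        for yi, r in enumerate(t.scores.index):
            for xi, n in enumerate(NUCS):
                v = data[yi, xi]
                if not np.isnan(v):
                    ax.text(xi, yi, f"{v:.2f}", ha="center", va="center",
                            fontsize=7)
        plt.colorbar(im, ax=ax, label="information score")
        return ax
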