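"""Internal validation, score confidence, and RNAcompete comparison.

Internal validation is leave-one-out: each cluster entry is scored
against its own bound RNA with a model refitted without that entry
("actual binding" scores), and against a randomized RNA whose
nucleotides are drawn, per core position, from complexes of *other*
proteins.  The separation between the two score distributions shows the
scorer discriminates binders from plausible non-binders.

The confidence of a prediction is the normalized likelihood ratio of
the score under Gaussian kernel-density estimates of the two
distributions: p_train / (p_train + p_random), in [0, 1].

The reporting offset is the additive constant that best separates the
two distributions on the ROC curve (Youden's J), so that offset-shifted
scores are positive for likely binders.

The RNAcompete path turns experimental position frequency matrices
(7-8 positions x ACGU) into per-5-mer information "bits" values, the
same quantities a sequence logo displays, for comparison with model
scores.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GAP, RNA_ALPHABET, ComplexEntry, InputError
from .model import BindingSpecificityModel, BindingSpecificityResults

NUCS = tuple(RNA_ALPHABET)


# ---------------------------------------------------------------------------
# leave-one-out and randomized scoring

@dataclass
class ValidationRun:
    """Paired actual-binding and randomized scores for a cluster."""

    entry_ids: list[str]
    training_scores: np.ndarray
    randomized_scores: np.ndarray
    seed: int | None = None

    def to_csv(self, path) -> None:
        pd.DataFrame({"entry_id": self.entry_ids,
                      "training_score": self.training_scores,
                      "randomized_score": self.randomized_scores}
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ValidationRun":
        df = pd.read_csv(path)
        return cls(entry_ids=df["entry_id"].tolist(),
                   training_scores=df["training_score"].to_numpy(float),
                   randomized_scores=df["randomized_score"].to_numpy(float))


def _score_own(results: BindingSpecificityResults, entry: ComplexEntry,
               nucleotides: dict[int, str]) -> float:
    pred = results._score_positions(entry.residue_at_column, nucleotides,
                                    window="".join(nucleotides.values()),
                                    start=min(nucleotides) if nucleotides
                                    else 1)
    return pred.raw_score


def _own_nucleotides(model: BindingSpecificityModel, entry_id: str
                     ) -> dict[int, str]:
    return {pos: nuc for pos, (nuc, _) in model._views[entry_id].items()}


def randomize_rna(entry: ComplexEntry, entries: list[ComplexEntry],
                  rna_msa, rng: np.random.Generator) -> dict[int, str]:
    """Randomized core-position nucleotides for one entry.

    For each core position the entry occupies, a nucleotide is drawn
    uniformly from the non-gap nucleotides at that position among
    entries of *different* UniProt ids (falling back, with a warning, to
    any non-gap nucleotide when no other protein covers the position).
    The protein sequence is untouched.
    """
    uniprot_of = {e.entry_id: e.uniprot_id for e in entries}
    out: dict[int, str] = {}
    row = rna_msa.rows[entry.entry_id]
    for rank, frame_pos in enumerate(rna_msa.core_positions, start=1):
        if row[frame_pos] == GAP:
            continue
        other = [rna_msa.rows[eid][frame_pos] for eid in rna_msa.rows
                 if uniprot_of.get(eid) != entry.uniprot_id
                 and rna_msa.rows[eid][frame_pos] != GAP]
        if not other:
            other = [rna_msa.rows[eid][frame_pos] for eid in rna_msa.rows
                     if rna_msa.rows[eid][frame_pos] != GAP]
            warnings.warn(
                f"position {rank}: only entries of the same protein are "
                "non-gap; falling back to all entries")
        out[rank] = other[rng.integers(len(other))]
    return out


def leave_one_out(model: BindingSpecificityModel,
                  seed: int | None = None,
                  randomize: bool = True) -> ValidationRun:
    """Leave-one-out actual-binding scores, plus a randomized set.

    Each entry is scored by a model fitted on the remaining entries, so
    its own contacts never inform its own score.
    """
    if len(model.entries) < 2:
        raise InputError("leave-one-out needs at least two entries")
    rng = np.random.default_rng(seed)
    ids, train, rand = [], [], []
    for entry in model.entries:
        res = model.fit(exclude={entry.entry_id})
        own = _own_nucleotides(model, entry.entry_id)
        ids.append(entry.entry_id)
        train.append(_score_own(res, entry, own))
        if randomize:
            shuffled = randomize_rna(entry, model.entries, model.rna_msa,
                                     rng)
            rand.append(_score_own(res, entry, shuffled))
    return ValidationRun(entry_ids=ids,
                         training_scores=np.asarray(train),
                         randomized_scores=np.asarray(rand) if randomize
                         else np.array([]),
                         seed=seed)


def _finite(scores, label: str) -> np.ndarray:
    """Drop entries that had no scorable interaction (NaN scores)."""
    x = np.asarray(scores, dtype=float)
    bad = ~np.isfinite(x)
    if bad.any():
        warnings.warn(f"{bad.sum()} unscorable {label} entr(ies) dropped")
    return x[~bad]


# ---------------------------------------------------------------------------
# KDE likelihood-ratio confidence

@dataclass
class ConfidenceModel:
    """Normalized KDE likelihood ratio between binder/non-binder scores."""

    kde_train: object
    kde_random: object
    bandwidth: float

    def confidence(self, score) -> np.ndarray | float:
        s = np.atleast_1d(np.asarray(score, dtype=float)).reshape(-1, 1)
        p_t = np.exp(self.kde_train.score_samples(s))
        p_r = np.exp(self.kde_random.score_samples(s))
        conf = p_t / (p_t + p_r)
        return float(conf[0]) if np.isscalar(score) else conf


def _silverman_bandwidth(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def fit_confidence(training_scores, randomized_scores,
                   bandwidth: float | None = None) -> ConfidenceModel:
    """Fit Gaussian KDEs to the two score sets.

    The default bandwidth is the Silverman rule of thumb computed on the
    pooled scores.  All-equal inputs (zero bandwidth) are rejected.
    """
    from sklearn.neighbors import KernelDensity

    t = _finite(training_scores, "training")
    r = _finite(randomized_scores, "randomized")
    if len(t) < 10 or len(r) < 10:
        raise InputError("need at least 10 scores in each set")
    if bandwidth is None:
        bandwidth = _silverman_bandwidth(np.concatenate([t, r]))
    if not bandwidth > 0:
        raise InputError("degenerate (all-equal) scores: zero bandwidth")
    kt = KernelDensity(kernel="gaussian", bandwidth=bandwidth)
    kt.fit(t.reshape(-1, 1))
    kr = KernelDensity(kernel="gaussian", bandwidth=bandwidth)
    kr.fit(r.reshape(-1, 1))
    return ConfidenceModel(kde_train=kt, kde_random=kr, bandwidth=bandwidth)


def roc_offset(training_scores, randomized_scores) -> float:
    """Additive offset that best separates the two score sets.

    The threshold maximizing Youden's J (sensitivity + specificity - 1,
    with training scores as positives) is found by an exhaustive sweep
    over midpoints between adjacent observed values; ties break toward
    the larger threshold, so perfectly separated sets give the midpoint
    of the gap.  The returned offset is the negated threshold: adding it
    makes likely-binder scores positive.
    """
    t = _finite(training_scores, "training")
    r = _finite(randomized_scores, "randomized")
    if len(t) == 0 or len(r) == 0:
        raise InputError("both score sets must be non-empty")
    values = np.unique(np.concatenate([t, r]))
    candidates = [(values[0] - 1.0)]
    candidates += [0.5 * (a + b) for a, b in zip(values, values[1:])]
    candidates.append(values[-1] + 1.0)
    best_thr, best_j = None, -np.inf
    for thr in candidates:
        j = (t >= thr).mean() + (r < thr).mean() - 1.0
        if j > best_j or (j == best_j and thr > best_thr):
            best_thr, best_j = thr, j
    return -best_thr


# ---------------------------------------------------------------------------
# RNAcompete preference matrices -> bits

@dataclass
class PreferencePfm:
    """Position frequency matrix (positions x ACGU) from a binding assay."""

    protein_id: str
    frequencies: pd.DataFrame  # index 1..m, columns A C G U

    def __post_init__(self) -> None:
        f = self.frequencies
        if list(f.columns) != list(NUCS):
            raise InputError("PFM columns must be A, C, G, U")
        arr = f.to_numpy(dtype=float)
        if (arr < 0).any():
            raise InputError("negative frequency in PFM")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
            raise InputError("PFM rows must sum to 1")

    @property
    def n_positions(self) -> int:
        return len(self.frequencies)

    @classmethod
    def from_file(cls, path, protein_id: str | None = None
                  ) -> "PreferencePfm":
        """Read a whitespace-separated PFM text file (Pos A C G U)."""
        df = pd.read_csv(path, sep=r"\s+")
        first = df.columns[0]
        if first.lower() in ("pos", "position", "#"):
            df = df.set_index(first)
        df.columns = [c.upper().replace("T", "U") for c in df.columns]
        df = df[list(NUCS)]
        if protein_id is None:
            import os
            protein_id = os.path.splitext(os.path.basename(str(path)))[0]
        return cls(protein_id=protein_id, frequencies=df)


def pfm_bits(pfm: PreferencePfm) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-position information content and per-letter heights (bits).

    IC(pos) = 2 + sum_n p_n log2 p_n; letter height = p_n * IC, the
    quantities a sequence logo draws (0 log 0 := 0).
    """
    p = pfm.frequencies.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p, where=p > 0), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    heights = pd.DataFrame(p * ic[:, None], index=pfm.frequencies.index,
                           columns=list(NUCS))
    return ic, heights


def all_kmers(k: int = 5) -> list[str]:
    return ["".join(t) for t in itertools.product(NUCS, repeat=k)]


def best_5mer_window(pfm: PreferencePfm, k: int = 5
                     ) -> tuple[int, dict[str, float]]:
    """Most-informative contiguous 5-position window and its 5-mer bits.

    The window maximizing the summed information content is chosen
    (ties toward 5'); the bits value of each of the 1024 possible
    5-mers is the mean letter height of its nucleotides over the window
    positions.
    """
    if pfm.n_positions < k:
        raise InputError(f"PFM has {pfm.n_positions} positions, need >= {k}")
    ic, heights = pfm_bits(pfm)
    sums = [ic[s:s + k].sum() for s in range(pfm.n_positions - k + 1)]
    start = int(np.argmax(sums))  # first max = 5'-most on ties
    h = heights.to_numpy(dtype=float)[start:start + k]
    nuc_idx = {n: i for i, n in enumerate(NUCS)}
    table = {kmer: float(np.mean([h[i, nuc_idx[c]]
                                  for i, c in enumerate(kmer)]))
             for kmer in all_kmers(k)}
    return start, table


# ---------------------------------------------------------------------------
# score-vs-bits comparison

CATEGORIES = ("single RRM", "multiple RRM", "multiple RBP")


@dataclass
class RnaCompeteComparison:
    pairs: pd.DataFrame                 # protein_id, kmer, score, bits
    binned_medians: pd.DataFrame        # category, bin_center, median_bits
    correlations: dict[str, float] = field(default_factory=dict)


def rnacompete_compare(proteins: list[dict], bin_width: float = 0.1,
                       raw_pairs: bool = False) -> RnaCompeteComparison:
    """Pair model scores with assay bits values, per protein category.

    Each input dict carries ``protein_id``, ``category`` (one of
    ``single RRM`` / ``multiple RRM`` / ``multiple RBP``),
    ``domain_scores`` (one 1024-vector per RRM domain, index-aligned
    with the canonical 5-mer order) and ``bits`` (1024-vector).
    Multi-domain proteins contribute the per-5-mer maximum over their
    domains.  Scores are binned at ``bin_width``; the per-category
    Pearson correlation is computed on the binned medians (or on raw
    pairs with ``raw_pairs=True``).
    """
    from scipy.stats import pearsonr

    kmers = all_kmers(5)
    rows = []
    seen_categories = set()
    for p in proteins:
        cat = p["category"]
        if cat not in CATEGORIES:
            warnings.warn(f"unknown category {cat!r} skipped")
            continue
        seen_categories.add(cat)
        scores = np.max(np.asarray(p["domain_scores"], dtype=float), axis=0)
        bits = np.asarray(p["bits"], dtype=float)
        if scores.shape != (len(kmers),) or bits.shape != (len(kmers),):
            raise InputError(
                f"{p['protein_id']}: score/bits vectors must have length "
                f"{len(kmers)}")
        for kmer, s, b in zip(kmers, scores, bits):
            rows.append((p["protein_id"], cat, kmer, s, b))
    for cat in CATEGORIES:
        if cat not in seen_categories:
            warnings.warn(f"category {cat!r} missing from input")
    pairs = pd.DataFrame(rows, columns=["protein_id", "category", "kmer",
                                        "score", "bits"])

    med_rows, correlations = [], {}
    for cat, sub in pairs.groupby("category"):
        if raw_pairs:
            correlations[cat] = float(pearsonr(sub["score"],
                                               sub["bits"])[0])
        bins = np.floor(sub["score"] / bin_width)
        med = sub.groupby(bins)["bits"].median()
        centers = (med.index.to_numpy() + 0.5) * bin_width
        for c, m in zip(centers, med.to_numpy()):
            med_rows.append((cat, c, m))
        if not raw_pairs:
            correlations[cat] = (float(pearsonr(centers,
                                                med.to_numpy())[0])
                                 if len(med) > 1 else float("nan"))
    binned = pd.DataFrame(med_rows,
                          columns=["category", "bin_center", "median_bits"])
    return RnaCompeteComparison(pairs=pairs, binned_medians=binned,
                                correlations=correlations)
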