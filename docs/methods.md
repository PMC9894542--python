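# Methods

This note records the model behind `rrmbind`, the parameters that
matter, the numerical and design choices that were genuinely open, and
what the synthetic fixtures do and do not establish.

## Model

### Contact definition

A residue–nucleotide pair is in contact when *any* atom of one lies
strictly less than 5.0 Å from any atom of the other. The 5 Å any-atom
rule keeps hydrogen bonds and electrostatics while still catching
hydrophobic packing (3.8–5.0 Å). Strictness at the boundary is a
convention; ties at exactly 5.0 Å are excluded. All atoms participate,
hydrogens included when a structure provides them (X-ray entries
usually do not). Only the first alternate location of an atom is used.
Modified residues and nucleotides are mapped to their parent code
through a fixed table (MSE→M, PSU→U, ...); unmappable residues are
skipped with a warning rather than guessed. Thymine and
deoxynucleotides are folded into the RNA alphabet (T→U), since some
RRMs bind ssDNA in the same mode. Complexes contacting fewer than
three distinct nucleotides carry too little binding-mode information
and are dropped.

### Master alignment and grid coordinates

Every protein-side quantity is expressed in the columns of one
secondary-structure-annotated RRM alignment. Columns belong to the
thirteen elements Nterm, β1, loop1, α1, loop2, β2, loop3, β3, loop4,
α2, loop5, β4, Cterm; the six core elements must be gap-free.
Structured columns carry grid labels (`β3–3` = third column of strand
β3); loop columns get analogous labels for diagnostics, an extension
beyond the usual strand/helix labelling.

Loop regions of an input alignment are *squeezed*: within each loop
the first ⌈n/2⌉ residues pack against the preceding element, the rest
against the following one, with all gaps contiguous in the middle;
N-terminal gaps go to the alignment start, C-terminal gaps to the end.
The rationale is that a loop residue is characterized by which fixed
element it hangs off, not by a column assignment inside an
unalignable region. The left-heavy ⌈n/2⌉ split for odd counts is a
tie-break chosen for determinism. Squeezing is idempotent and never
alters an ungapped sequence.

New sequences are mapped into columns with a profile HMM built from
the alignment, with every column annotated as a match state so match
state *k* corresponds exactly to column *k*. Alignment is
deterministic for a fixed master. A search-pipeline score floor
rejects sequences that do not look like RRMs at all instead of
returning a garbage mapping. Limitation: heavily gapped terminal
columns have weak match emissions, so one or two residues at the
extreme termini can fall to flanking insert states and receive no
column; core-element mappings are unaffected.

### Binding-mode similarity and clustering

The bound RNA of each complex is truncated to its contacted region and
represented as the ordered list of master-column sets its nucleotides
touch. Two profiles are compared at every sliding offset with at least
one overlapping nucleotide; an aligned pair contributes
|intersection| / |union| of the two column sets, and the offset score
is the mean over contributing pairs. Pairs in which neither nucleotide
has any contact carry no binding-mode information and are excluded
from both numerator and denominator. The best offset defines the
similarity (in [0, 1]) and, later, the RNA alignment placement. Ties
between offsets break toward the smallest absolute offset, then the
negative one.

The similarity matrix holds the best score for every complex pair
(diagonal 1 internally; the CSV interchange dialect writes 0 on the
diagonal). The primary cluster is the largest set in which every
member has similarity ≥ 0.25 with at least 25 % of the other members.
Since the criterion alone does not determine a procedure, membership
is computed by iterative pruning: repeatedly drop the entry with the
fewest qualifying partners (lexicographic tie-break) until all remain
qualified. The procedure is deterministic and monotone; further
binding modes come from repeating it on the complement.

The cluster medoid — the member with the largest summed similarity to
the others — anchors the RNA multiple alignment: each member RNA is
placed at its best-scoring offset against the medoid and padded with
5'/3' gaps into a common frame (RNA lengths 3–11 are typical). A
member with no positive-scoring offset is placed at offset 0 with a
warning rather than dropped. The *k* = 5 least-gapped frame positions
(ties toward 5') become the scored core, numbered 1–5.

As a geometric sanity check for low-similarity cluster pairs,
`superpose_rmsd` performs a least-squares rigid-body superposition
(Kabsch, via SVD) on the sugar heavy atoms of aligned nucleotides.

### Information score

For a key interaction (column *j*, core position *i*), the score of
residue R with nucleotide N is

    I = log( f(N,R) / f(¬N,R) ) + log( f(¬N) / f(N) )

where f(N,R) counts N at position *i* contacting R at column *j*,
f(¬N,R) the other nucleotides contacting R there, and f(N) / f(¬N)
are the nucleotide marginals at the position. This is the GOR
information difference; the residue background cancels between the
two log terms, which is what makes the score usable with the modest
number of solved complexes. Positive = contact seen more often than
the position's nucleotide composition predicts; ≈0 = no preference
(the RNP1/RNP2 stacking aromatics behave this way, as stacking is not
base-specific).

All counts are UniProt-normalized: each protein contributes, per cell,
the fraction of its structures showing the contact. Duplicating a
protein's structures therefore changes nothing — the property the
normalization exists for. Raw-count mode is available
(`normalize="raw"`) for sensitivity analysis. Key interactions are the
(column, position) pairs contacted by at least 20 % (inclusive) of the
distinct proteins in the cluster; they are selected once, on the full
cluster, and kept fixed during leave-one-out refits, mirroring how
the validation is meant to isolate count evidence rather than the
interaction list.

Numerical choices: the logarithm is natural by default (`log_base`
configurable). The score is undefined if any of the four counts is
zero; such cells are "no data", rendered blank, skipped during
averaging, and reported via `n_skipped` so low-coverage predictions
are visible. An optional additive pseudocount (default off) smooths
all four counts for experimentation. The plug-in log-ratio estimator
has the usual small negative finite-sample bias: on null synthetic
clusters of 50 proteins the mean defined-cell score is ≈ −0.05,
shrinking roughly like 1/n (≈ −0.015 at 100, ≈ −0.007 at 200).

### Prediction

The binding score of an (RRM, RNA window) pair is the arithmetic mean
of the defined cell scores over key interactions covered by the
window; the per-interaction breakdown is always reported. Windows are
3–5 nucleotides; a 5-mer occupies core positions 1–5, and shorter
windows default to 3'-anchored placement (a 3-mer covers positions
3–5, where the central strands read the RNA), overridable via
`start_position` since the mapping of sub-5-mers onto the core is not
canonical. Scanning slides the window 5'→3' and reports every
placement; best-window ties resolve 5'-most. Mutation effects are
computed on the unchanged column mapping with the residue swapped, so
the delta is exactly the difference of the two matrix cells divided by
the number of scored interactions. Scores are relative, not binding
free energies; no thermodynamic calibration is implied.

### Validation, confidence, reporting offset

Leave-one-out: each cluster entry is scored against its own bound RNA
by a model refitted without it. The randomized counterpart keeps the
protein but redraws each occupied core position uniformly from the
non-gap nucleotides of *other* proteins at that position (falling
back, with a warning, to all proteins when no other covers it);
sampling is uniform over qualifying entries, i.e. weighted by natural
multiplicity, with replacement across positions, and fully seeded.
Entries whose leave-out model has no data for any of their cells
produce no score and are dropped from the distributions with a
warning.

Confidence is the normalized likelihood ratio p_train/(p_train +
p_rand) under Gaussian kernel density estimates of the two score sets;
it is bounded in [0, 1] and monotone wherever the density ratio is.
The bandwidth defaults to the Silverman rule of thumb on the pooled
scores (configurable); all-equal score sets are rejected rather than
given a zero bandwidth. The reporting offset is the negated threshold
maximizing Youden's J over an exhaustive sweep of midpoints between
adjacent observed scores (ties toward the larger threshold, so
perfectly separated sets yield the gap midpoint); it is a
presentation device only and is never baked into stored models.

### RNAcompete-style comparison

Experimental preference matrices (7–8 positions × ACGU) are converted
to sequence-logo quantities: IC(pos) = 2 + Σ p log₂ p bits and letter
heights p·IC. The most informative contiguous 5-position window (ties
5'-most) defines a bits value for each of the 1024 5-mers as the mean
letter height of its nucleotides — "mean letter height" rather than
mean IC, because the letter height is the per-letter quantity a logo
draws. Model scores are paired with bits per 5-mer; multi-domain
proteins contribute the per-5-mer maximum over their domains, since
the highest-affinity domain dominates observed preferences. Scores
are binned at 0.1 width and the per-category Pearson correlation is
computed on binned medians (raw-pair mode available), reflecting that
medians, not raw pairs, are the robust summary at this noise level.

## Synthetic fixtures

The generator emulates the statistical structure the method feeds on:
a column-annotated master alignment (default 76 columns); 30 protein
groups by default with 1–4 structures each, a scaled-down proportion
of a realistic canonical-mode corpus (a few hundred complexes over
~70 proteins) — large enough that a ×4 planted preference is
recovered with ≥95 % probability; a shared binding frame (five core
positions, each touching 2–3 interface columns including the RNP
positions) so the similarity score clusters all complexes together;
RNA lengths 3–11 with non-contacting flanks, exercising the 5'/3'
padding; small per-column residue palettes (size 3) at interface
columns, because real binding positions are conserved and shared
residues across proteins are what makes cross-protein statistics
possible; and a low sprinkle rate of random extra contacts so
zero-count "no data" cells occur.

Preferences are planted in two ways. Individual cells (grid label,
residue, nucleotide, enrichment *e*): carrier groups draw the paired
nucleotide with odds *e* : 1 : 1 : 1 per structure; *e* = 1 is the
null. A full recognition code (`code_enrichment`): every palette
residue at every interface column prefers its own seeded nucleotide —
without this, most interactions are pure noise and the leave-one-out
training/randomized distributions rightly do not separate, so the
separation and confidence checks run on coded clusters. Strict
dominance of a planted cell over the alternative nucleotides is an
asymptotic property; at fixture scale it holds in aggregate over
replicates but not in every seed, and is tested accordingly.

What passing fixtures shows — and does not. The fixtures verify the
machinery end to end: contact recovery, clustering, alignment
bookkeeping, count normalization, estimator correctness against exact
oracles, planted-signal recovery, and calibration of the confidence
construction. They are geometric and statistical scaffolds, not
physics: they cannot certify that the 5 Å rule, the 20 % prevalence
threshold or the canonical-mode restriction are biologically optimal,
nor reproduce corpus-level statistics that require the full deposited
structure set.

## Problem sizes

Defaults used by the test suite and acceptance script: 30-group
clusters (≈70–90 complexes) for pipeline runs and leave-one-out
validation, 100 replicates for the recovery rate, 3 × 50-group null
clusters, and 25 randomized toys per oracle check. These sizes give
stable statistics (recovery rates and separations vary by a few
percent across seeds) while a full run completes in seconds.

## Known limitations

- Only the canonical binding mode is modelled; additional clusters are
  extracted as member lists but not scored.
- Scores are relative; no Kd calibration.
- Sub-5-mer window placement is a convention (3'-anchored default).
- Terminal residues can fall outside the column mapping (see above).
- The greedy identity dedup utility is for near-duplicate removal at
  high thresholds; it is not a general low-identity clusterer.
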