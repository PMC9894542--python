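# rrmbind

Statistics-based scoring of RRM–ssRNA binding specificity.

The RNA recognition motif (RRM) is the most common eukaryotic
RNA-binding domain: a ~90-residue β1-α1-β2-β3-α2-β4 fold that binds
single-stranded RNA across its four-stranded β-sheet face, anchored by
stacking aromatics in the conserved RNP1/RNP2 motifs (grid positions
β1–3, β3–3, β3–5). Although the fold is conserved, the sequence of the
binding interface varies enormously, and a single substitution there
can switch the recognized RNA. `rrmbind` derives a residue-level
recognition code for this canonical binding mode from the statistics of
residue–nucleotide contacts in solved RRM–RNA complex structures, and
uses it to score how likely a 3–5 nucleotide ssRNA fragment is to bind
a given RRM sequence — fast, per-contact interpretable, and usable at
genome scale. It is aimed at structural bioinformaticians and protein
engineers triaging RNA targets or interface mutations.

## The method

1. **Contacts.** A residue and a nucleotide interact when any atom pair
   lies < 5 Å apart. Complexes recognizing fewer than 3 nucleotides are
   discarded.
2. **Master alignment.** All RRM sequences live in one
   secondary-structure-annotated multiple alignment whose columns are
   the coordinate system (`β1–1` = first column of strand β1). Loop
   residues are "squeezed" flush against the flanking elements; new
   sequences are mapped in with a profile HMM built from the alignment.
3. **Binding modes.** Two bound RNAs are compared by sliding one along
   the other and scoring, per aligned nucleotide pair, the Jaccard-like
   ratio of shared to total contacted columns, averaged over the
   aligned length:

       S = ( Σᵢ  N_match(i) / N_unique(i) ) / N_aligned  ∈ [0, 1]

   The largest cluster at cutoffs (S ≥ 0.25 with ≥ 25 % of co-members)
   is the canonical binding mode. Cluster RNAs are aligned against the
   cluster medoid with 5'/3' gap padding; the 5 least-gapped positions
   are the scored core.
4. **Scoring.** For each *key interaction* — a (column *j*, RNA
   position *i*) pair contacted by ≥ 20 % of distinct proteins — every
   (residue R, nucleotide N) cell gets a GOR-style information score

       I(ΔN_i; R_j) = log( f(N_i,R_j) / f(¬N_i,R_j) )
                    + log( f(¬N_i) / f(N_i) )

   with UniProt-normalized counts (a protein with 10 structures showing
   a contact in 8 contributes 0.8), so over-studied proteins do not
   dominate. The binding score of an (RRM, RNA window) pair is the mean
   over key interactions; never-observed cells are "no data" and are
   skipped and counted, not silently scored.
5. **Validation and confidence.** Leave-one-out scores of true
   complexes are compared with scores of RNAs randomized from other
   proteins; Gaussian KDEs of the two distributions give a confidence
   `p_bind / (p_bind + p_rand)` in [0, 1], and the ROC-optimal offset
   makes reported scores positive for likely binders.

A seeded synthetic-data generator (`rrmbind.synthetic`) builds master
alignments, complexes and contact maps with planted, recoverable
preferences, so the full pipeline is testable without any downloads.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from rrmbind import (FixtureSpec, PipelineConfig, generate_cluster,
                     run_pipeline)

master, complexes, truth = generate_cluster(FixtureSpec(
    seed=7, n_uniprot_groups=30, code_enrichment=4.0))
result = run_pipeline(complexes, PipelineConfig(seed=7), master=master)

res = result.results
print(f"complexes: {len(complexes)}, primary cluster: "
      f"{len(result.cluster)}, medoid: {result.medoid}")
print(f"key interactions: {len(res.key_interactions)} over "
      f"{len({c for c, _ in res.key_interactions})} RRM columns")

entry = result.entries[0]
pred = res.score_pair(entry, "ACGUA")
print(f"score({entry.entry_id}, ACGUA) = {pred.raw_score:.3f} "
      f"({pred.n_scored} scored, {pred.n_skipped} skipped)")
for b in pred.breakdown[:3]:
    print(f"  {b['label']:>12}  {b['residue']}-{b['nucleotide']}  "
          f"{b['score']:+.2f}  (obs {b['count']:.2f})")

best = res.best_window(res.scan(entry, "GGACGUAGGC", window=5))
print(f"best window: {best.window} at offset {best.rna_offset} "
      f"(raw {best.raw_score:.3f})")

t = result.validation.training_scores
r = result.validation.randomized_scores
print(f"leave-one-out: training mean {t.mean():+.3f}, "
      f"randomized mean {r.mean():+.3f}")
print(f"confidence of best window: "
      f"{result.confidence.confidence(best.raw_score):.2f}")
```

which prints:

```
complexes: 72, primary cluster: 72, medoid: UP003_1_pdb003c_A
key interactions: 11 over 9 RRM columns
score(UP000_1_pdb000a_A, ACGUA) = 0.040 (11 scored, 0 skipped)
     β2–3/RNA1  W-A  +1.12  (obs 6.67)
  loop3–2/RNA1  D-A  -0.26  (obs 3.83)
     β1–3/RNA2  S-C  -1.48  (obs 0.83)
best window: UAGGC at offset 5 (raw 0.387)
leave-one-out: training mean +0.501, randomized mean -0.056
confidence of best window: 0.68
```

Read this as: the 72 synthetic complexes share one binding mode; the
trained model covers 11 key interactions; the per-contact breakdown
shows which residue–nucleotide pairs pull the window score up or down
(`obs` is the protein-normalized observation count behind the cell);
scanning a longer RNA locates the best-scoring 5-mer, and the
leave-one-out separation (+0.50 vs −0.06) is what the confidence of a
prediction is calibrated against.

The same steps are available from the shell:

```
rrmbind fixtures --groups 10 --plant b1-1:K:G:4 --seed 3 -o fx/
rrmbind run fx/complexes.json -o run/
rrmbind score --model run/model.json --master-fasta fx/master.fasta \
    --master-spans fx/master_spans.yaml --rrm-seq <SEQ> --rna ACGUA
```

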