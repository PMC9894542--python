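"""End-to-end orchestration: contacts -> cluster -> RNA MSA -> scorer.

Stages mirror the data flow of the method: filter complexes by bound
length, build contact profiles, compute the all-pairs binding-mode
similarity matrix, extract the primary (canonical-mode) cluster, pick
its medoid, align the cluster RNAs, select the core positions, train
the specificity model, and run the leave-one-out validation with the
KDE confidence model and ROC reporting offset.  Every intermediate is
written in its standard text format, and a fixed config + seed gives
identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import binding_modes as bm
from .config import PipelineConfig
from .contacts import filter_complexes_by_bound_length
from .core import ComplexEntry, RrmBindError
from .model import BindingSpecificityModel, BindingSpecificityResults
from .validation import (ConfidenceModel, ValidationRun, fit_confidence,
                         leave_one_out, roc_offset)

logger = logging.getLogger(__name__)


class StageError(RrmBindError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    entries: list[ComplexEntry]
    matrix: bm.SimilarityMatrix
    cluster: set[str]
    medoid: str
    rna_msa: bm.RnaMsa
    model: BindingSpecificityModel
    results: BindingSpecificityResults
    validation: ValidationRun | None
    confidence: ConfidenceModel | None
    report_offset: float | None


def run_pipeline(entries: list[ComplexEntry], config: PipelineConfig,
                 master=None, outdir: "Path | str | None" = None,
                 validate: bool = True) -> PipelineResult:
    """Run every stage on aligned complexes with contact maps."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        logger.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            raise StageError(name, exc) from exc

    kept = stage("filter", lambda: filter_complexes_by_bound_length(
        entries, config.min_bound_nucleotides))
    if not kept:
        raise StageError("filter", RrmBindError(
            "no complex recognizes enough nucleotides"))

    profiles = stage("profiles", lambda: [
        bm.RnaContactProfile.from_entry(e) for e in kept])
    matrix = stage("similarity",
                   lambda: bm.build_similarity_matrix(profiles))
    if out is not None:
        matrix.to_csv(out / "similarity.csv")

    cluster = stage("cluster", lambda: bm.extract_primary_cluster(
        matrix, config.cluster_score_min, config.cluster_member_fraction))
    if len(cluster) < 2:
        raise StageError("cluster", RrmBindError(
            f"primary cluster has only {len(cluster)} member(s)"))
    if out is not None:
        (out / "cluster0.txt").write_text(
            "\n".join(sorted(cluster)) + "\n")

    medoid = stage("medoid", lambda: bm.find_medoid(matrix, cluster))
    member_profiles = [p for p in profiles if p.entry_id in cluster]
    rna_msa = stage("rnamsa",
                    lambda: bm.build_rna_msa(member_profiles, medoid))
    stage("core", lambda: bm.select_core_positions(
        rna_msa, min(config.n_core_positions, rna_msa.width)))
    if out is not None:
        rna_msa.to_fasta(out / "rna_msa.fasta")

    members = [e for e in kept if e.entry_id in cluster]
    model = stage("train", lambda: BindingSpecificityModel(
        members, rna_msa, master=master, prevalence=config.prevalence,
        log_base=config.log_base, pseudocount=config.pseudocount,
        normalize=config.normalize))
    results = stage("fit", model.fit)
    if out is not None:
        results.to_json(out / "model.json")

    validation = confidence = offset = None
    if validate:
        validation = stage("validate",
                           lambda: leave_one_out(model, seed=config.seed))
        if out is not None:
            validation.to_csv(out / "validation.csv")
        confidence = stage("confidence", lambda: fit_confidence(
            validation.training_scores, validation.randomized_scores,
            bandwidth=config.kde_bandwidth))
        offset = stage("offset", lambda: roc_offset(
            validation.training_scores, validation.randomized_scores))
        if out is not None:
            (out / "confidence.json").write_text(json.dumps({
                "kde_bandwidth": confidence.bandwidth,
                "report_offset": offset,
            }, indent=1))
    return PipelineResult(entries=kept, matrix=matrix, cluster=cluster,
                          medoid=medoid, rna_msa=rna_msa, model=model,
                          results=results, validation=validation,
                          confidence=confidence, report_offset=offset)
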