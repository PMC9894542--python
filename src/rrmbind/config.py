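"""Pipeline configuration with the method's canonical default values."""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .core import InputError


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their defaults.

    contact_cutoff          contact distance in Angstrom (strict <)
    min_bound_nucleotides   complexes contacting fewer are dropped
    cluster_score_min       minimum pairwise similarity inside a cluster
    cluster_member_fraction fraction of co-members that must qualify
    n_core_positions        least-gapped RNA positions used for scoring
    prevalence              UniProt fraction defining key interactions
    log_base                information-score log base (None = natural)
    pseudocount             additive smoothing (0 = zero cells are
                            "no data" and skipped)
    report_offset           presentation offset added to raw scores
                            (None = report raw scores)
    kde_bandwidth           confidence KDE bandwidth (None = rule of
                            thumb)
    seed                    master seed for every random draw
    """

    contact_cutoff: float = 5.0
    min_bound_nucleotides: int = 3
    cluster_score_min: float = 0.25
    cluster_member_fraction: float = 0.25
    n_core_positions: int = 5
    prevalence: float = 0.20
    log_base: float | None = None
    pseudocount: float = 0.0
    normalize: str = "uniprot"
    report_offset: float | None = None
    kde_bandwidth: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise InputError("contact_cutoff must be positive")
        if not (0 <= self.cluster_score_min <= 1
                and 0 <= self.cluster_member_fraction <= 1
                and 0 <= self.prevalence <= 1):
            raise InputError("fractional thresholds must lie in [0, 1]")
        if self.min_bound_nucleotides < 0 or self.n_core_positions < 1:
            raise InputError("counts must be positive")
        if self.pseudocount < 0:
            raise InputError("pseudocount must be >= 0")

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)
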