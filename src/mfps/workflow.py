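"""End-to-end driver: raw aligned FASTA -> labeled training matrix.

Chains the preparation stages, per-genus OTU clustering, taxonomy
labeling and probe-matrix construction so the CLI and tests can run the
whole training pipeline in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment_prep import PrepConfig, QCReport, prepare
from .core import AlignmentSet, TaxonomyLabel
from .otu_cluster import assign_otus_per_genus, label_set
from .probe_matrix import PROBE_LENGTH, TOP_N, ProbeMatrix, build_training_matrix


@dataclass
class PipelineConfig:
    prep: PrepConfig = field(default_factory=PrepConfig)
    otu_threshold: float = 0.01
    probe_length: int = PROBE_LENGTH
    top_n: int | None = TOP_N
    reverse_complement: bool = False


@dataclass
class PipelineResult:
    processed: AlignmentSet  # truncated, QC'd, fully labeled
    otus: dict[str, str]
    matrix: ProbeMatrix
    qc: QCReport


def run_pipeline(
    aln: AlignmentSet,
    taxonomy: dict[str, TaxonomyLabel],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Prepare sequences, cluster OTUs per genus, label, build the matrix."""
    cfg = config or PipelineConfig()
    qc = QCReport()
    processed = prepare(aln, cfg.prep, report=qc)
    otus = assign_otus_per_genus(processed, taxonomy, threshold=cfg.otu_threshold)
    labeled = label_set(processed, taxonomy, otus)
    pm = build_training_matrix(
        labeled,
        probe_length=cfg.probe_length,
        top_n=cfg.top_n,
        reverse_complement=cfg.reverse_complement,
    )
    return PipelineResult(processed=labeled, otus=otus, matrix=pm, qc=qc)
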