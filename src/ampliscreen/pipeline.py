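"""High-level pilot-cohort pipeline: one call from seed to QC'd calls.

Bundles the full study reproduction — reference + paper-scale fixture,
pilot planting, cohort read simulation, genotyping, and run QC — so that
scripts and analyses can reproduce the run from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from ampliscreen.genotype import CallThresholds, RunResult, genotype_run
from ampliscreen.panel import MutationPanel
from ampliscreen.pooling import Amplicon
from ampliscreen.qc import (
    AssayMatrix,
    RecurrentVariantFlag,
    RunMetrics,
    SampleQC,
    UnexpectedPartition,
    compute_assay_matrix,
    coverage_metrics,
    exclude_samples,
    flag_recurrent,
    on_target_fraction,
)
from ampliscreen.simulate import (
    PAPER_SCALE,
    CohortDesign,
    DepthModel,
    ReadSimParams,
    design_pilot_cohort,
    generate_panel_fixture,
    generate_reference,
    simulate_cohort,
)


@dataclass
class PilotRun:
    reference: dict
    panel: MutationPanel
    amplicons: list[Amplicon]
    design: CohortDesign
    manifest: dict
    result: RunResult
    matrix: AssayMatrix
    sample_qc: list[SampleQC]
    included: list[str]
    metrics: RunMetrics
    on_target_pooled: float
    partition: UnexpectedPartition
    recurrent_flags: list[RecurrentVariantFlag]

    @property
    def known_pairs(self) -> set[tuple[str, str]]:
        return set(map(tuple, self.manifest["planting"]["known_het"]))

    def known_het_sensitivity(self) -> tuple[int, int]:
        """(called HET, planted) over the known heterozygote list."""
        lk = self.result.call_lookup()
        planted = self.design.planting.known_het
        called = sum(
            1 for sid, mid in planted
            if (c := lk.get((sid, mid))) is not None and c.genotype == "HET"
        )
        return called, len(planted)


def run_pilot_cohort(
    seed: int,
    workdir: Union[str, Path],
    depth_model: Optional[DepthModel] = None,
    thresholds: Optional[CallThresholds] = None,
    per_base_error: float = 0.001,
    paralog_mode: str = "dilute",
) -> PilotRun:
    """Reproduce the pilot study end to end on the paper-scale fixture.

    FASTQ intermediates are written under ``workdir``; everything else is
    returned in memory.
    """
    depth_model = depth_model or DepthModel()
    thresholds = thresholds or CallThresholds()
    reference = generate_reference(seed)
    panel, amplicons = generate_panel_fixture(reference, PAPER_SCALE, seed)
    design = design_pilot_cohort(panel, amplicons, seed)
    design.paralog_mode = paralog_mode
    read_params = ReadSimParams(per_base_error=per_base_error, seed=seed)
    manifest = simulate_cohort(
        reference, panel, amplicons, design, depth_model, read_params, workdir
    )
    fastqs = {sid: tuple(paths) for sid, paths in manifest["fastqs"].items()}
    known_pairs = set(map(tuple, manifest["planting"]["known_het"]))
    result = genotype_run(fastqs, panel, amplicons, reference, thresholds, known_pairs)
    matrix = compute_assay_matrix(result.pileups, result.targets, result.sample_ids, panel)
    read_counts = {s: v.total_pairs for s, v in result.read_stats.items()}
    sample_qc = exclude_samples(read_counts, matrix)
    included = [q.sample_id for q in sample_qc if not q.excluded]
    metrics = coverage_metrics(matrix, included, dp_threshold=thresholds.min_dp)
    pooled, _per = on_target_fraction(result.read_stats, included)
    partition, flags = flag_recurrent(result.calls, known_pairs, included)
    return PilotRun(
        reference=reference,
        panel=panel,
        amplicons=list(amplicons),
        design=design,
        manifest=manifest,
        result=result,
        matrix=matrix,
        sample_qc=sample_qc,
        included=included,
        metrics=metrics,
        on_target_pooled=pooled,
        partition=partition,
        recurrent_flags=flags,
    )
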