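"""Run-level QC: assay depth matrix, sample exclusion, coverage metrics,
on-target specificity, and recurrent-variant (benign-candidate) flagging.

The central object is the assay matrix — target positions × samples, each
cell the fragment depth (DP) at that position in that sample.  An "assay"
is the determination of one mutation in one sample, so the headline assay
count uses the mutation-count convention (mutations × samples) while the
matrix itself has one row per collapsed position; both accountings are
reported explicitly because they differ whenever positions host two
alleles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ampliscreen.genotype import (
    HET,
    HOM,
    NO_CALL,
    AssayCall,
    PileupResult,
    SampleReadStats,
)
from ampliscreen.panel import MutationPanel, TargetPosition

LOW_READS = "LOW_READS"
MANY_LOW_TARGETS = "MANY_LOW_TARGETS"
NONE = "NONE"


@dataclass
class AssayMatrix:
    """Targets × samples fragment-depth grid with assay accounting."""

    depth: pd.DataFrame  # index=target_id, columns=sample_id, int DP
    n_mutations: int
    accounting: dict = field(default_factory=dict)

    @property
    def n_targets(self) -> int:
        return len(self.depth.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.depth.columns)

    def assay_counts(self, sample_ids: Optional[Sequence[str]] = None) -> dict:
        n_s = len(sample_ids) if sample_ids is not None else len(self.depth.columns)
        return {
            "mutations_x_samples": self.n_mutations * n_s,
            "positions_x_samples": self.n_targets * n_s,
            "n_samples": n_s,
        }


@dataclass(frozen=True)
class SampleQC:
    sample_id: str
    total_reads: int
    n_targets_below_10x: int
    excluded: bool
    reason: str = NONE


@dataclass(frozen=True)
class QcRules:
    low_read_fraction: float = 0.01   # of the median of the other samples
    max_low_targets: int = 40
    low_target_dp: int = 10


@dataclass
class RunMetrics:
    pct_assays_ge_dp: float
    pct_targets_covered_all_samples: float
    pct_targets_avg_ge_high: float
    per_sample_conclusive_pct: dict[str, float]
    min_conclusive_pct: float
    n_assays_total: dict
    dp_threshold: int
    high_depth_threshold: int
    mean_assay_depth: float


@dataclass(frozen=True)
class RecurrentVariantFlag:
    mutation_id: str
    n_samples_called: int
    n_hom: int
    cohort_fraction: float
    flagged_benign_candidate: bool


@dataclass
class UnexpectedPartition:
    """Non-expected calls split into recurrent-attributed vs singletons."""

    recurrent_calls: list[AssayCall]
    singleton_calls: list[AssayCall]

    @property
    def n_total(self) -> int:
        return len(self.recurrent_calls) + len(self.singleton_calls)


def compute_assay_matrix(
    pileups: Mapping[tuple[str, str], PileupResult],
    targets: Sequence[TargetPosition],
    sample_ids: Sequence[str],
    panel: Optional[MutationPanel] = None,
) -> AssayMatrix:
    """Assemble the complete depth matrix (missing pileups count as 0)."""
    data = np.zeros((len(targets), len(sample_ids)), dtype=int)
    for i, t in enumerate(targets):
        for j, sid in enumerate(sample_ids):
            pu = pileups.get((t.target_id, sid))
            if pu is not None:
                data[i, j] = pu.dp
    n_mut = len(panel.small_mutations) if panel is not None else sum(
        len(t.mutation_ids) for t in targets
    )
    depth = pd.DataFrame(data, index=[t.target_id for t in targets], columns=list(sample_ids))
    m = AssayMatrix(depth=depth, n_mutations=n_mut)
    m.accounting = m.assay_counts()
    return m


def exclude_samples(
    read_counts: Mapping[str, int],
    matrix: AssayMatrix,
    rules: QcRules = QcRules(),
) -> list[SampleQC]:
    """Apply the run's sample-exclusion rules.

    LOW_READS: total reads under ``low_read_fraction`` of the median of the
    other samples (median-of-others is a robust stand-in for "less than 1 %
    of reads in each of the other samples").  MANY_LOW_TARGETS: more than
    ``max_low_targets`` targets under ``low_target_dp``.  LOW_READS takes
    precedence when both fire.
    """
    out = []
    samples = list(matrix.sample_ids)
    totals = {sid: int(read_counts.get(sid, 0)) for sid in samples}
    for sid in samples:
        others = [totals[s] for s in samples if s != sid]
        median_others = float(np.median(others)) if others else 0.0
        n_low = int((matrix.depth[sid] < rules.low_target_dp).sum())
        if median_others > 0 and totals[sid] < rules.low_read_fraction * median_others:
            out.append(SampleQC(sid, totals[sid], n_low, True, LOW_READS))
        elif n_low > rules.max_low_targets:
            out.append(SampleQC(sid, totals[sid], n_low, True, MANY_LOW_TARGETS))
        else:
            out.append(SampleQC(sid, totals[sid], n_low, False, NONE))
    return out


def coverage_metrics(
    matrix: AssayMatrix,
    included_samples: Sequence[str],
    dp_threshold: int = 50,
    high_depth_threshold: int = 150,
) -> RunMetrics:
    """Coverage statistics over the included samples.

    Reports the fraction of assays at or above ``dp_threshold``, the
    fraction of targets conclusive in every included sample, the fraction
    of targets whose per-sample average depth reaches
    ``high_depth_threshold``, and per-sample conclusive rates (fraction of
    targets at or above threshold — the complement of a sample's
    inconclusive-test rate).
    """
    sub = matrix.depth[list(included_samples)]
    if sub.size == 0:
        raise ValueError("empty matrix after exclusions")
    cells = sub.to_numpy()
    pct_assays = 100.0 * float((cells >= dp_threshold).mean())
    pct_all = 100.0 * float((cells >= dp_threshold).all(axis=1).mean())
    pct_high = 100.0 * float((cells.mean(axis=1) >= high_depth_threshold).mean())
    per_sample = {
        sid: 100.0 * float((sub[sid] >= dp_threshold).mean()) for sid in included_samples
    }
    accounting = {
        "pre_exclusion": matrix.assay_counts(),
        "post_exclusion": matrix.assay_counts(included_samples),
    }
    return RunMetrics(
        pct_assays_ge_dp=pct_assays,
        pct_targets_covered_all_samples=pct_all,
        pct_targets_avg_ge_high=pct_high,
        per_sample_conclusive_pct=per_sample,
        min_conclusive_pct=min(per_sample.values()),
        n_assays_total=accounting,
        dp_threshold=dp_threshold,
        high_depth_threshold=high_depth_threshold,
        mean_assay_depth=float(cells.mean()),
    )


def on_target_fraction(
    read_stats: Mapping[str, SampleReadStats],
    included_samples: Optional[Sequence[str]] = None,
) -> tuple[float, dict[str, float]]:
    """Fraction of read pairs assigned to expected amplicons, pooled and per sample."""
    samples = list(included_samples) if included_samples is not None else list(read_stats)
    per_sample = {}
    tot_assigned = tot_all = 0
    for sid in samples:
        s = read_stats[sid]
        per_sample[sid] = s.assigned_pairs / s.total_pairs if s.total_pairs else 0.0
        tot_assigned += s.assigned_pairs
        tot_all += s.total_pairs
    pooled = tot_assigned / tot_all if tot_all else 0.0
    return pooled, per_sample


def flag_recurrent(
    calls: Sequence[AssayCall],
    known_pairs: set[tuple[str, str]],
    included_samples: Sequence[str],
    cohort_fraction_threshold: float = 0.10,
) -> tuple[UnexpectedPartition, list[RecurrentVariantFlag]]:
    """Partition unexpected calls and flag benign-polymorphism candidates.

    Unexpected calls are HET/HOM calls at (sample, mutation) pairs not in
    the expected-known list, restricted to included samples.  A variant is
    flagged as a benign candidate when its cohort fraction reaches the
    threshold or it is homozygous in at least two samples — recurrent,
    often-homozygous "pathogenic" panel entries are almost certainly common
    polymorphisms and should be re-evaluated and dropped from future
    panels.
    """
    included = set(included_samples)
    unexpected = [
        c
        for c in calls
        if c.genotype in (HET, HOM)
        and c.sample_id in included
        and c.allele is not None
        and (c.sample_id, c.allele) not in known_pairs
    ]
    by_mut: dict[str, list[AssayCall]] = {}
    for c in unexpected:
        by_mut.setdefault(c.allele, []).append(c)
    flags = []
    recurrent_ids = set()
    for mid, group in sorted(by_mut.items()):
        n_called = len({c.sample_id for c in group})
        n_hom = len({c.sample_id for c in group if c.genotype == HOM})
        frac = n_called / len(included) if included else 0.0
        flagged = frac >= cohort_fraction_threshold or n_hom >= 2
        if flagged:
            recurrent_ids.add(mid)
        flags.append(RecurrentVariantFlag(mid, n_called, n_hom, frac, flagged))
    partition = UnexpectedPartition(
        recurrent_calls=[c for c in unexpected if c.allele in recurrent_ids],
        singleton_calls=[c for c in unexpected if c.allele not in recurrent_ids],
    )
    return partition, flags


# ---------------------------------------------------------------------------
# Report writers

def write_matrix_tsv(matrix: AssayMatrix, path: Union[str, Path]) -> None:
    matrix.depth.to_csv(path, sep="\t", index_label="target_id")


def write_qc_json(
    path: Union[str, Path],
    matrix: AssayMatrix,
    sample_qc: Sequence[SampleQC],
    metrics: RunMetrics,
    on_target_pooled: float,
    flags: Sequence[RecurrentVariantFlag],
    partition: Optional[UnexpectedPartition] = None,
) -> None:
    doc = {
        "assay_accounting": {
            "pre_exclusion": matrix.assay_counts(),
            "post_exclusion": matrix.assay_counts(
                [q.sample_id for q in sample_qc if not q.excluded]
            ),
        },
        "sample_qc": [asdict(q) for q in sample_qc],
        "metrics": asdict(metrics),
        "on_target_fraction": on_target_pooled,
        "recurrent_variant_flags": [asdict(f) for f in flags],
    }
    if partition is not None:
        doc["unexpected_calls"] = {
            "total": partition.n_total,
            "recurrent_attributed": len(partition.recurrent_calls),
            "singletons": len(partition.singleton_calls),
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def write_sample_reports(
    calls: Sequence[AssayCall],
    junction_calls: Sequence,
    panel: MutationPanel,
    targets: Sequence[TargetPosition],
    outdir: Union[str, Path],
    included_samples: Sequence[str],
) -> list[Path]:
    """Final per-sample reports: the mutations identified in each sample."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    by_sample: dict[str, list[AssayCall]] = {}
    for c in calls:
        if c.genotype in (HET, HOM):
            by_sample.setdefault(c.sample_id, []).append(c)
    junc_by_sample: dict[str, list] = {}
    for jc in junction_calls:
        if jc.carrier:
            junc_by_sample.setdefault(jc.sample_id, []).append(jc)
    for sid in included_samples:
        path = outdir / f"report_{sid}.tsv"
        with open(path, "w") as fh:
            fh.write("#sample_id\tgene\tdisorder\tmutation\tlabel\tgenotype\tDP\tAF\tflags\n")
            for c in sorted(by_sample.get(sid, []), key=lambda c: c.allele or ""):
                m = panel[c.allele]
                fh.write(
                    f"{sid}\t{m.gene}\t{m.disorder}\t{c.allele}\t{m.label}\t{c.genotype}\t"
                    f"{c.dp}\t{c.af:.3f}\t{'|'.join(c.flags) or '.'}\n"
                )
            for jc in sorted(junc_by_sample.get(sid, []), key=lambda j: j.mutation_id):
                m = panel[jc.mutation_id]
                fh.write(
                    f"{sid}\t{m.gene}\t{m.disorder}\t{jc.mutation_id}\t{m.label}\tCARRIER\t"
                    f"{jc.supporting_reads}\t.\tJUNCTION\n"
                )
        paths.append(path)
    return paths


def plot_depth_heatmap(matrix: AssayMatrix, path: Union[str, Path], vmax: Optional[float] = None) -> None:
    """Basic log-scale depth heat map, targets ranked by mean depth."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    depth = matrix.depth.loc[matrix.depth.mean(axis=1).sort_values(ascending=False).index]
    fig, ax = plt.subplots(figsize=(8, 10))
    im = ax.imshow(
        np.log10(depth.to_numpy() + 1), aspect="auto", cmap="magma", vmax=vmax, interpolation="nearest"
    )
    ax.set_xlabel("sample")
    ax.set_ylabel("target (ranked by mean depth)")
    fig.colorbar(im, ax=ax, label="log10(DP + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
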