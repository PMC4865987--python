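"""Synthetic study universe: reference, panel/amplicon fixtures, planted
genotypes, and per-sample paired-end amplicon reads.

The generator emulates the structure of a pilot carrier-screening run on a
48-inlet microfluidic chip: a paper-scale panel preset (370 small mutations
in 148 genes with two same-position allele pairs, 345 standard amplicons of
64-200 bp plus one 418 bp outlier and 4 breakpoint-junction amplicons, 48
samples), a pilot planting preset (50 known heterozygotes across 40
samples, two of them on paralog-interference loci; 15 unexpected
singletons; 4 recurrent variants carried by 7, 8, 11 and 23 samples; 5
rearrangement carriers), and a fragment-level read model (negative-binomial
depth per assay, uniform haplotype sampling, substitution errors,
off-target fragments, and even-ratio paralog co-capture).

Fragments are read pairs: depth is counted in fragments throughout.
Read names encode the ground-truth amplicon so callers can be scored
against the manifest without re-reading the FASTQs.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from ampliscreen.panel import (
    MutationClass,
    MutationPanel,
    PanelMutation,
    build_junction_reference,
    collapse_targets,
)
from ampliscreen.pooling import Amplicon
from ampliscreen.seq import gc_fraction, revcomp

# Flank length (bp) on each side of the breakpoint in a junction amplicon's
# mutant-haplotype product; 75+75 guarantees 150 bp reads span the junction.
JUNCTION_PRODUCT_FLANK = 75

_BASES = "ACGT"
_QUAL = "I"  # constant Q40; per-cycle quality profiles are out of scope


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Presets

@dataclass(frozen=True)
class FixturePreset:
    """Structural counts of the synthetic panel/amplicon fixture.

    ``n_mutations`` counts SNV/indel mutations; the ``n_junction_amplicons``
    large rearrangements are additional panel rows with their own junction
    amplicons.  ``n_two_target_amplicons`` standard amplicons cover two
    close targets each, and ``n_dual_covered_targets`` targets are covered
    by two redundant amplicons; together with one outlier amplicon per
    entry of ``outlier_lengths`` these counts must reproduce
    ``n_standard_amplicons`` exactly.
    """

    name: str
    n_mutations: int = 370
    n_same_position_pairs: int = 2
    n_genes: int = 148
    n_standard_amplicons: int = 345
    n_junction_amplicons: int = 4
    n_samples: int = 48
    amplicon_length_range: tuple[int, int] = (64, 200)
    outlier_lengths: tuple[int, ...] = (418,)
    n_two_target_amplicons: int = 46
    n_dual_covered_targets: int = 24
    intra_gene_gap: tuple[int, int] = (600, 2500)
    inter_gene_gap: tuple[int, int] = (6000, 14000)

    @property
    def n_targets(self) -> int:
        return self.n_mutations - self.n_same_position_pairs

    def validate(self) -> None:
        n_single = (
            self.n_targets
            - 2 * self.n_two_target_amplicons
            - len(self.outlier_lengths)
            - self.n_dual_covered_targets
        )
        if n_single < 0:
            raise FixtureError(f"{self.name}: inconsistent structural counts")
        expected = (
            self.n_two_target_amplicons + 2 * self.n_dual_covered_targets + n_single
        )
        if expected != self.n_standard_amplicons:
            raise FixtureError(
                f"{self.name}: structural counts imply {expected} standard amplicons, "
                f"preset declares {self.n_standard_amplicons}"
            )


PAPER_SCALE = FixturePreset(name="paper-scale")

TINY = FixturePreset(
    name="tiny",
    n_mutations=12,
    n_same_position_pairs=1,
    n_genes=5,
    n_standard_amplicons=10,
    n_junction_amplicons=1,
    n_samples=4,
    outlier_lengths=(),
    n_two_target_amplicons=2,
    n_dual_covered_targets=1,
)

PRESETS = {"paper-scale": PAPER_SCALE, "tiny": TINY}


@dataclass(frozen=True)
class DepthModel:
    """Fragment-count model for one (amplicon, sample) cell.

    Counts are NegBin(mean, dispersion) — ``dispersion`` is the gamma shape
    of the mixing distribution, so variance = mean + mean^2/dispersion.
    ``dropout_prob`` optionally zeroes cells at random; engineered QC
    failures are specified per sample in :class:`CohortDesign` instead.
    """

    mean_depth_per_assay: int = 500
    dispersion: float = 8.0
    dropout_prob: float = 0.0
    off_target_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.mean_depth_per_assay <= 0 or self.dispersion <= 0:
            raise FixtureError("depth model mean and dispersion must be positive")
        if not (0 <= self.dropout_prob <= 1 and 0 <= self.off_target_fraction < 1):
            raise FixtureError("depth model fractions out of range")


@dataclass(frozen=True)
class ReadSimParams:
    read_length: int = 150
    paired: bool = True
    per_base_error: float = 0.001
    seed: int = 0


@dataclass(frozen=True)
class RecurrentPlan:
    mutation_id: str
    carrier_samples: tuple[str, ...]
    hom_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not set(self.hom_samples) <= set(self.carrier_samples):
            raise FixtureError(f"{self.mutation_id}: hom samples must be carriers")


@dataclass
class PlantingSpec:
    """Ground-truth genotypes to plant in the cohort."""

    known_het: list[tuple[str, str]] = field(default_factory=list)  # (sample, mutation)
    singletons: list[tuple[str, str]] = field(default_factory=list)
    recurrent: list[RecurrentPlan] = field(default_factory=list)
    paralog_targets: list[str] = field(default_factory=list)
    rearrangement_carriers: list[tuple[str, str]] = field(default_factory=list)

    @property
    def unexpected_singletons(self) -> int:
        return len(self.singletons)

    @property
    def recurrent_variants(self) -> list[tuple[str, int, int]]:
        return [(r.mutation_id, len(r.carrier_samples), len(r.hom_samples)) for r in self.recurrent]

    @property
    def n_unexpected_calls(self) -> int:
        return len(self.singletons) + sum(len(r.carrier_samples) for r in self.recurrent)


@dataclass
class CohortDesign:
    """Everything beyond the planting needed to realize a cohort run."""

    sample_ids: list[str]
    planting: PlantingSpec
    amplicon_efficiency: dict[str, float] = field(default_factory=dict)
    sample_scale: dict[str, float] = field(default_factory=dict)  # starved samples
    killed_amplicons: dict[str, tuple[str, ...]] = field(default_factory=dict)
    paralog_mode: str = "dilute"
    technical_replicates: list[tuple[str, str]] = field(default_factory=list)

    @property
    def qc_failure_samples(self) -> list[str]:
        return sorted(set(self.sample_scale) | set(self.killed_amplicons))


# ---------------------------------------------------------------------------
# Reference genome

def generate_reference(
    seed: int, n_chrom: int = 4, chrom_len: int = 1_200_000, gc: float = 0.41
) -> dict[str, str]:
    """Reproducible random genome with the configured GC content."""
    if chrom_len < 10_000:
        raise FixtureError("chromosomes must be at least 10 kb")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for i in range(n_chrom):
        arr = rng.choice(alphabet, size=chrom_len, p=p)
        genome[f"chr{i + 1}"] = arr.tobytes().decode()
    return genome


# ---------------------------------------------------------------------------
# Panel + amplicon fixture

def _draw_amplicon(
    rng: np.random.Generator,
    chrom: str,
    genome_chrom: str,
    positions: Sequence[int],
    ref_lens: Sequence[int],
    length: int,
    aid: str,
    target_ids: Sequence[str],
    is_outlier: bool = False,
    read_length: int = 150,
) -> Amplicon:
    """Place a product of ``length`` bp containing the given 1-based positions.

    Variant bases stay clear of the 20 bp primer landing sites; for outlier
    products longer than a read, the variant context is kept within the
    first read.
    """
    p_first, p_last = min(positions), max(positions)
    span = p_last - p_first
    max_ref = max(ref_lens)
    lo = 20
    hi = length - 20 - span - max_ref
    if is_outlier:
        hi = min(hi, read_length - 16 - span - max_ref)
    if hi < lo:
        raise FixtureError(f"{aid}: product of {length} bp cannot hold targets")
    offset = int(rng.integers(lo, hi + 1))
    start = p_first - 1 - offset
    end = start + length
    product = genome_chrom[start:end]
    return Amplicon(
        amplicon_id=aid,
        chrom=chrom,
        start=start,
        end=end,
        fwd_primer=product[:20],
        rev_primer=revcomp(product[-20:]),
        gc_fraction=gc_fraction(product),
        target_ids=tuple(target_ids),
        is_length_outlier=is_outlier,
    )


def generate_panel_fixture(
    reference: Mapping[str, str],
    preset: FixturePreset,
    seed: int,
) -> tuple[MutationPanel, list[Amplicon]]:
    """Generate a panel and covering amplicons honouring the preset counts.

    Targets are laid out gene by gene (round-robin over chromosomes) with
    intra-gene spacing short enough to create multiplexing proximity
    conflicts; close-pair targets share one amplicon, dual-covered targets
    get two redundant amplicons, and large rearrangements get junction
    amplicons whose product exists only on the mutant haplotype.
    """
    preset.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    chroms = sorted(reference.keys())
    genome = {c: reference[c] for c in chroms}
    lmin, lmax = preset.amplicon_length_range

    # --- structural plan: site groups -------------------------------------
    n_pairs = preset.n_two_target_amplicons
    n_dual = preset.n_dual_covered_targets
    n_outlier = len(preset.outlier_lengths)
    n_single = preset.n_targets - 2 * n_pairs - n_dual - n_outlier
    groups: list[str] = (
        ["PAIR"] * n_pairs + ["DUAL"] * n_dual + ["OUTLIER"] * n_outlier + ["SINGLE"] * n_single
    )
    rng.shuffle(groups)
    # multi-allelic sites live on SINGLE targets
    single_idx = [i for i, g in enumerate(groups) if g == "SINGLE"]
    multi_idx = set(rng.choice(single_idx, size=preset.n_same_position_pairs, replace=False).tolist())

    # distribute groups over genes, genes round-robin over chromosomes
    n_groups = len(groups)
    base, extra = divmod(n_groups, preset.n_genes)
    gene_sizes = [base + (1 if i < extra else 0) for i in range(preset.n_genes)]
    rng.shuffle(gene_sizes)

    cursors = {c: 1000 for c in chroms}
    targets: list[dict] = []  # planning records
    gi = 0
    group_iter = iter(enumerate(groups))
    outlier_lengths = list(preset.outlier_lengths)
    for gene_no, size in enumerate(gene_sizes):
        gene = f"GENE{gene_no + 1:03d}"
        chrom = chroms[gene_no % len(chroms)]
        cursors[chrom] += int(rng.integers(*preset.inter_gene_gap))
        for _ in range(size):
            idx, kind = next(group_iter)
            pos = cursors[chrom]
            rec = {"kind": kind, "chrom": chrom, "pos": pos, "gene": gene, "multi": idx in multi_idx}
            if kind == "PAIR":
                rec["pos2"] = pos + int(rng.integers(30, 61))
                cursors[chrom] = rec["pos2"]
            targets.append(rec)
            cursors[chrom] += int(rng.integers(*preset.intra_gene_gap))

    # --- mutations ---------------------------------------------------------
    mutations: list[PanelMutation] = []
    genome_blob = "|".join(genome.values())
    mut_no = 0
    forced_tatc = False

    def _context_free(chrom_seq: str, ctx: str) -> bool:
        return ctx not in genome_blob and revcomp(ctx) not in genome_blob

    def _make_mutation(chrom: str, pos: int, gene: str, forbid_classes: set[str] = frozenset()) -> PanelMutation:
        nonlocal mut_no, forced_tatc
        seq = genome[chrom]
        ref_base = seq[pos - 1]
        r = rng.random()
        mclass = "SNV" if r < 0.8 else ("INS" if r < 0.9 else "DEL")
        if mclass in forbid_classes:
            mclass = "SNV"
        mut_no += 1
        mid = f"M{mut_no:03d}"
        disorder = f"disorder{(mut_no * 7) % 120 + 1:03d}"
        if mclass == "SNV":
            alt = _BASES[int(rng.integers(4))]
            while alt == ref_base:
                alt = _BASES[int(rng.integers(4))]
            return PanelMutation(mid, gene, disorder, chrom, pos, ref_base, alt, MutationClass.SNV,
                                 label=f"{gene}:c.{pos}{ref_base}>{alt}")
        if mclass == "INS":
            for _ in range(20):
                if not forced_tatc:
                    ins, forced_tatc = "TATC", True
                else:
                    ins = "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=int(rng.integers(1, 5))))
                alt_ctx = seq[pos - 16 : pos] + ins + seq[pos : pos + 15]
                if _context_free(seq, alt_ctx):
                    return PanelMutation(mid, gene, disorder, chrom, pos, ref_base, ref_base + ins,
                                         MutationClass.INS, label=f"{gene}:c.{pos}ins{ins}")
            raise FixtureError(f"{mid}: could not place unambiguous insertion")
        for k in range(1, 5):
            ref = seq[pos - 1 : pos + k]
            alt_ctx = seq[pos - 16 : pos] + seq[pos + k : pos + k + 15]
            if _context_free(seq, alt_ctx):
                return PanelMutation(mid, gene, disorder, chrom, pos, ref, ref_base,
                                     MutationClass.DEL, label=f"{gene}:c.{pos}del{k}")
        # repeats made every deletion ambiguous here; fall back to an SNV
        alt = _BASES[int(rng.integers(4))]
        while alt == ref_base:
            alt = _BASES[int(rng.integers(4))]
        return PanelMutation(mid, gene, disorder, chrom, pos, ref_base, alt, MutationClass.SNV,
                             label=f"{gene}:c.{pos}{ref_base}>{alt}")

    for rec in targets:
        mut = _make_mutation(rec["chrom"], rec["pos"], rec["gene"])
        rec["mutations"] = [mut]
        mutations.append(mut)
        if rec["kind"] == "PAIR":
            mut2 = _make_mutation(rec["chrom"], rec["pos2"], rec["gene"])
            rec["mutations2"] = [mut2]
            mutations.append(mut2)
        if rec["multi"]:
            # second pathogenic allele of the same nucleotide: SNV partner,
            # or an anchor-sharing insertion (both occur in real panels)
            first = rec["mutations"][0]
            mut_no_local = len(mutations)
            if first.mut_class is MutationClass.SNV and rng.random() < 0.5:
                seq = genome[rec["chrom"]]
                for _ in range(20):
                    ins = "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=int(rng.integers(1, 5))))
                    alt_ctx = seq[rec["pos"] - 16 : rec["pos"]] + ins + seq[rec["pos"] : rec["pos"] + 15]
                    if _context_free(seq, alt_ctx):
                        break
                partner = PanelMutation(
                    f"M{mut_no_local + 1000:03d}", first.gene, first.disorder, first.chrom,
                    first.pos, seq[rec["pos"] - 1], seq[rec["pos"] - 1] + ins, MutationClass.INS,
                    label=f"{first.gene}:c.{first.pos}ins{ins}",
                )
            else:
                seq = genome[rec["chrom"]]
                ref_base = seq[rec["pos"] - 1]
                taken = {first.alt_allele} if first.mut_class is MutationClass.SNV else set()
                alt = next(b for b in _BASES if b != ref_base and b not in taken)
                partner = PanelMutation(
                    f"M{mut_no_local + 1000:03d}", first.gene, first.disorder, first.chrom,
                    first.pos, ref_base, alt, MutationClass.SNV,
                    label=f"{first.gene}:c.{first.pos}{ref_base}>{alt}",
                )
            rec["mutations"].append(partner)
            mutations.append(partner)

    # --- amplicons ---------------------------------------------------------
    amplicons: list[Amplicon] = []
    used_primers: set[str] = set()
    amp_no = 0

    def _add(amp: Amplicon) -> None:
        if amp.fwd_primer in used_primers or amp.rev_primer in used_primers:
            raise FixtureError(f"{amp.amplicon_id}: primer collision")
        used_primers.update((amp.fwd_primer, amp.rev_primer))
        amplicons.append(amp)

    for rec in targets:
        chrom = rec["chrom"]
        seq = genome[chrom]
        tid = f"t_{chrom}_{rec['pos']}"
        ref_lens = [len(m.ref_allele) for m in rec["mutations"]]
        if rec["kind"] == "PAIR":
            tid2 = f"t_{chrom}_{rec['pos2']}"
            span = rec["pos2"] - rec["pos"]
            length = int(rng.integers(span + 45 + max(ref_lens), lmax + 1))
            amp_no += 1
            _add(
                _draw_amplicon(
                    rng, chrom, seq, [rec["pos"], rec["pos2"]],
                    ref_lens + [len(m.ref_allele) for m in rec["mutations2"]],
                    length, f"A{amp_no:03d}", [tid, tid2],
                )
            )
        elif rec["kind"] == "OUTLIER":
            length = outlier_lengths.pop(0)
            amp_no += 1
            _add(_draw_amplicon(rng, chrom, seq, [rec["pos"]], ref_lens, length,
                                f"A{amp_no:03d}", [tid], is_outlier=True))
        else:
            n_amps = 2 if rec["kind"] == "DUAL" else 1
            prev_start = None
            for _ in range(n_amps):
                for _attempt in range(10):
                    length = int(rng.integers(max(lmin, 41 + max(ref_lens)), lmax + 1))
                    amp_no += 1
                    amp = _draw_amplicon(rng, chrom, seq, [rec["pos"]], ref_lens, length,
                                         f"A{amp_no:03d}", [tid])
                    if amp.start != prev_start:
                        break
                    amp_no -= 1
                _add(amp)
                prev_start = amp.start

    # --- large rearrangements + junction amplicons -------------------------
    lr_specs = [("DEL", 5000), ("DEL", 6700), ("INS", 353), ("INS", 1200)]
    for j in range(preset.n_junction_amplicons):
        kind, size = lr_specs[j % len(lr_specs)]
        chrom = chroms[j % len(chroms)]
        seq = genome[chrom]
        anchor = cursors[chrom] + 20_000
        if anchor + size + 2000 > len(seq):
            raise FixtureError("reference too small for rearrangement placement")
        cursors[chrom] = anchor + size + 2000
        mut_no += 1
        mid = f"LR{j + 1}"
        gene = f"GENE{preset.n_genes - j:03d}"
        if kind == "DEL":
            mut = PanelMutation(mid, gene, f"disorder{j + 1:03d}", chrom, anchor, "", "",
                                MutationClass.LARGE_REARRANGEMENT,
                                breakpoints=(anchor, anchor + size - 1),
                                label=f"{gene}:Del{size / 1000:.1f}Kb")
        else:
            rng2 = rng
            ins = "".join(_BASES[int(b)] for b in rng2.integers(0, 4, size=size))
            mut = PanelMutation(mid, gene, f"disorder{j + 1:03d}", chrom, anchor, "", "",
                                MutationClass.LARGE_REARRANGEMENT,
                                breakpoints=(anchor, anchor), inserted_seq=ins,
                                label=f"{gene}:Ins{size}bp")
        mutations.append(mut)
        product = _junction_product(mut, genome)
        b1, b2 = mut.breakpoints
        amp_no += 1
        _add(
            Amplicon(
                amplicon_id=f"J{j + 1}",
                chrom=chrom,
                start=b1 - 1 - JUNCTION_PRODUCT_FLANK,
                end=b2 + JUNCTION_PRODUCT_FLANK,
                fwd_primer=product[:20],
                rev_primer=revcomp(product[-20:]),
                gc_fraction=gc_fraction(product),
                target_ids=(mid,),
                is_junction=True,
            )
        )

    panel = MutationPanel(mutations, version=preset.name, provenance=f"synthetic fixture seed={seed}")
    return panel, amplicons


def _junction_product(mut: PanelMutation, genome: Mapping[str, str]) -> str:
    """Mutant-haplotype PCR product of a junction amplicon."""
    seq = genome[mut.chrom]
    b1, b2 = mut.breakpoints  # type: ignore[misc]
    f = JUNCTION_PRODUCT_FLANK
    if mut.inserted_seq and b1 == b2:
        return seq[b1 - f : b1] + mut.inserted_seq + seq[b1 : b1 + f]
    return seq[b1 - 1 - f : b1 - 1] + seq[b2 : b2 + f]


# ---------------------------------------------------------------------------
# Pilot-cohort design

def design_pilot_cohort(
    panel: MutationPanel,
    amplicons: Sequence[Amplicon],
    seed: int,
    n_samples: int = 48,
    n_known_het: int = 50,
    n_known_samples: int = 40,
    n_paralog: int = 2,
    n_singletons: int = 15,
    recurrent_counts: Sequence[tuple[int, int]] = ((23, 6), (11, 0), (8, 0), (7, 2)),
    n_rearrangement_carriers: int = 5,
    n_weak_amplicons: int = 8,
    weak_efficiency: float = 0.05,
    starved_scales: Sequence[float] = (0.004, 0.0005),
    n_dropout_targets: int = 44,
) -> CohortDesign:
    """Build the pilot-cohort planting and engineered QC failures.

    Mirrors the study conditions: 48 samples of which three fail QC (two
    with starved read counts, one with 44 near-zero targets), 50 known
    heterozygotes across 40 of the remaining samples with two on
    paralog-diluted loci, 15 unexpected singletons, four recurrent variants
    (7/8/11/23 carriers, some homozygous), and 5 rearrangement carriers.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    sample_ids = [f"S{i:02d}" for i in range(1, n_samples + 1)]
    starved = ["S02", "S27"][: len(starved_scales)]
    dropout_sample = "S36"
    qc_fail = set(starved) | {dropout_sample}
    included = [s for s in sample_ids if s not in qc_fail]

    by_mut_amplicons: dict[str, list[Amplicon]] = {}
    targets = collapse_targets(panel)
    target_by_id = {t.target_id: t for t in targets}
    for a in amplicons:
        if a.is_junction:
            continue
        for tid in a.target_ids:
            for mid in target_by_id[tid].mutation_ids:
                by_mut_amplicons.setdefault(mid, []).append(a)

    standard = [a for a in amplicons if not a.is_junction]
    weak_pool = [a for a in standard if not a.is_length_outlier and len(a.target_ids) == 1]
    weak = rng.choice(len(weak_pool), size=min(n_weak_amplicons, len(weak_pool)), replace=False)
    weak_ids = {weak_pool[i].amplicon_id for i in weak}
    efficiency = {aid: weak_efficiency for aid in sorted(weak_ids)}

    def _covered(mid: str) -> bool:
        amps = by_mut_amplicons.get(mid, [])
        return any(a.amplicon_id not in weak_ids for a in amps)

    # plantable mutations: covered, on mutually distinct amplicons, one
    # allele per target (skip multi-allelic partners to keep one variant
    # per amplicon per sample)
    need = n_known_het + n_singletons + len(recurrent_counts)
    taken_amps: set[str] = set()
    taken_targets: set[tuple[str, int]] = set()
    eligible: list[str] = []
    order = [m.mutation_id for m in panel.small_mutations]
    rng.shuffle(order)
    for mid in order:
        if len(eligible) == need:
            break
        m = panel[mid]
        amps = by_mut_amplicons.get(mid, [])
        if not _covered(mid):
            continue
        aids = {a.amplicon_id for a in amps}
        if aids & taken_amps or (m.chrom, m.pos) in taken_targets:
            continue
        taken_amps |= aids
        taken_targets.add((m.chrom, m.pos))
        eligible.append(mid)
    if len(eligible) < need:
        raise FixtureError(f"only {len(eligible)} plantable mutations, need {need}")

    known_muts = eligible[:n_known_het]
    singleton_muts = eligible[n_known_het : n_known_het + n_singletons]
    recurrent_muts = eligible[n_known_het + n_singletons : need]

    # paralog loci among the knowns: prefer single-amplicon SNV targets
    paralog_candidates = [
        mid
        for mid in known_muts
        if len(by_mut_amplicons[mid]) == 1 and panel[mid].mut_class is MutationClass.SNV
    ]
    paralog_targets = paralog_candidates[:n_paralog]
    if len(paralog_targets) < n_paralog:
        raise FixtureError("not enough single-amplicon SNV knowns for paralog planting")

    known_samples = [included[i] for i in rng.choice(len(included), size=n_known_samples, replace=False)]
    known_het: list[tuple[str, str]] = []
    for i, mid in enumerate(known_muts):
        if i < n_known_samples:
            sid = known_samples[i]
        else:
            sid = known_samples[int(rng.integers(n_known_samples))]
        known_het.append((sid, mid))

    singles = [
        (included[int(rng.integers(len(included)))], mid) for mid in singleton_muts
    ]

    recurrent: list[RecurrentPlan] = []
    for mid, (n_car, n_hom) in zip(recurrent_muts, recurrent_counts):
        carriers = sorted(included[i] for i in rng.choice(len(included), size=n_car, replace=False))
        homs = sorted(np.array(carriers)[rng.choice(n_car, size=n_hom, replace=False)].tolist())
        recurrent.append(RecurrentPlan(mid, tuple(carriers), tuple(homs)))

    # carriers over the rearrangements: every junction but the last gets at
    # least one carrier, one mutation absorbs the rest (paper-style: one
    # insertion recurred in three samples, one designed junction saw none)
    lr_muts = [m.mutation_id for m in panel.rearrangements]
    carrier_plan = []
    if lr_muts and n_rearrangement_carriers > 0:
        active = lr_muts[:-1] if len(lr_muts) > 1 else lr_muts
        per_mut = [1] * len(active)
        hub = min(2, len(active) - 1)
        per_mut[hub] += max(0, n_rearrangement_carriers - sum(per_mut))
        while sum(per_mut) > n_rearrangement_carriers:
            per_mut[per_mut.index(max(per_mut))] -= 1
        for mid, count in zip(active, per_mut):
            idx = rng.choice(len(included), size=count, replace=False)
            carrier_plan.extend((included[int(i)], mid) for i in idx)

    # near-zero targets in the dropout sample: kill single-target,
    # singly-covered, planting-free amplicons so exactly those targets drop
    cover_count: dict[str, int] = {}
    for a in standard:
        for tid in a.target_ids:
            cover_count[tid] = cover_count.get(tid, 0) + 1
    killable = [
        a.amplicon_id
        for a in standard
        if len(a.target_ids) == 1
        and cover_count[a.target_ids[0]] == 1
        and a.amplicon_id not in weak_ids
        and a.amplicon_id not in taken_amps
    ]
    n_kill = min(n_dropout_targets, len(killable))
    kill = tuple(sorted(killable[i] for i in rng.choice(len(killable), size=n_kill, replace=False)))

    planting = PlantingSpec(
        known_het=known_het,
        singletons=singles,
        recurrent=recurrent,
        paralog_targets=list(paralog_targets),
        rearrangement_carriers=carrier_plan,
    )
    return CohortDesign(
        sample_ids=sample_ids,
        planting=planting,
        amplicon_efficiency=efficiency,
        sample_scale={s: sc for s, sc in zip(starved, starved_scales)},
        killed_amplicons={dropout_sample: kill},
    )


# ---------------------------------------------------------------------------
# Genotype assignment

GenotypeTable = dict[tuple[str, str], str]  # (sample, mutation) -> HET/HOM


def assign_genotypes(
    panel: MutationPanel,
    planting: PlantingSpec,
    sample_ids: Sequence[str],
    technical_replicates: Sequence[tuple[str, str]] = (),
) -> GenotypeTable:
    """Realize the planting spec as a sample × mutation genotype table.

    Unlisted cells are homozygous reference.  Technical replicates copy the
    source sample's genotypes under a new barcode (sample id); read noise
    stays independent because simulation draws per sample.
    """
    known = set(sample_ids)
    table: GenotypeTable = {}

    def _plant(sid: str, mid: str, gt: str) -> None:
        if sid not in known:
            raise FixtureError(f"planting references unknown sample {sid}")
        if mid not in panel:
            raise FixtureError(f"planting references unknown mutation {mid}")
        table[(sid, mid)] = gt

    for sid, mid in planting.known_het:
        _plant(sid, mid, "HET")
    for sid, mid in planting.singletons:
        _plant(sid, mid, "HET")
    for plan in planting.recurrent:
        for sid in plan.carrier_samples:
            _plant(sid, mid := plan.mutation_id, "HOM" if sid in plan.hom_samples else "HET")
    for sid, mid in planting.rearrangement_carriers:
        _plant(sid, mid, "HET")
    for src, dup in technical_replicates:
        for (sid, mid), gt in list(table.items()):
            if sid == src:
                table[(dup, mid)] = gt
    return table


# ---------------------------------------------------------------------------
# Read simulation

@dataclass
class AmpliconProducts:
    """Pre-built product strings for one amplicon."""

    amplicon: Amplicon
    ref_product: Optional[str]  # None for junction amplicons
    alt_products: dict[str, str]  # mutation_id -> mutant product
    mutation_targets: dict[str, str]  # mutation_id -> target_id


def build_amplicon_products(
    panel: MutationPanel,
    amplicons: Sequence[Amplicon],
    reference: Mapping[str, str],
) -> dict[str, AmpliconProducts]:
    targets = {t.target_id: t for t in collapse_targets(panel)}
    out: dict[str, AmpliconProducts] = {}
    for a in amplicons:
        if a.is_junction:
            mid = a.target_ids[0]
            out[a.amplicon_id] = AmpliconProducts(
                a, None, {mid: _junction_product(panel[mid], reference)}, {mid: mid}
            )
            continue
        seq = reference[a.chrom]
        product = seq[a.start : a.end]
        alts: dict[str, str] = {}
        mts: dict[str, str] = {}
        for tid in a.target_ids:
            for mid in targets[tid].mutation_ids:
                m = panel[mid]
                off = m.pos - 1 - a.start
                alts[mid] = product[:off] + m.alt_allele + product[off + len(m.ref_allele) :]
                mts[mid] = tid
        out[a.amplicon_id] = AmpliconProducts(a, product, alts, mts)
    return out


@dataclass
class SampleSimStats:
    sample_id: str
    fragments_on: int = 0
    fragments_off: int = 0
    per_amplicon: dict[str, int] = field(default_factory=dict)

    @property
    def fragments_total(self) -> int:
        return self.fragments_on + self.fragments_off


def _mutate(seq: str, positions: Iterable[int], rng: np.random.Generator) -> str:
    chars = list(seq)
    for p in positions:
        old = chars[p]
        new = _BASES[int(rng.integers(4))]
        while new == old:
            new = _BASES[int(rng.integers(4))]
        chars[p] = new
    return "".join(chars)


def _emit_group(
    product: str,
    count: int,
    prefix: str,
    serial_start: int,
    read_length: int,
    per_base_error: float,
    rng: np.random.Generator,
    out1: list[str],
    out2: list[str],
) -> int:
    """Append ``count`` read pairs drawn from one product string."""
    if count <= 0:
        return serial_start
    r1 = product[:read_length]
    r2 = revcomp(product)[:read_length]
    l1, l2 = len(r1), len(r2)
    body1 = f"\n{r1}\n+\n{_QUAL * l1}\n"
    body2 = f"\n{r2}\n+\n{_QUAL * l2}\n"
    errors: dict[int, list[int]] = {}
    if per_base_error > 0:
        n_err = rng.binomial(count * (l1 + l2), per_base_error)
        for _ in range(int(n_err)):
            errors.setdefault(int(rng.integers(count)), []).append(int(rng.integers(l1 + l2)))
    for i in range(count):
        name = f"@{prefix}:{serial_start + i}"
        if i in errors:
            p1 = [p for p in errors[i] if p < l1]
            p2 = [p - l1 for p in errors[i] if p >= l1]
            e1 = _mutate(r1, p1, rng) if p1 else r1
            e2 = _mutate(r2, p2, rng) if p2 else r2
            out1.append(f"{name}\n{e1}\n+\n{_QUAL * l1}\n")
            out2.append(f"{name}\n{e2}\n+\n{_QUAL * l2}\n")
        else:
            out1.append(name + body1)
            out2.append(name + body2)
    return serial_start + count


def simulate_sample_reads(
    sample_id: str,
    genotypes: Mapping[str, str],
    products: Mapping[str, AmpliconProducts],
    reference: Mapping[str, str],
    depth_model: DepthModel,
    sim_params: ReadSimParams,
    rng: np.random.Generator,
    out_r1: Union[str, Path],
    out_r2: Union[str, Path],
    paralog_targets: Sequence[str] = (),
    paralog_mode: str = "dilute",
    amplicon_efficiency: Optional[Mapping[str, float]] = None,
    killed_amplicons: Sequence[str] = (),
    scale: float = 1.0,
) -> SampleSimStats:
    """Simulate one sample's paired FASTQ (gzip) from its genotypes.

    Per amplicon the fragment count is NegBin(mean·efficiency·scale,
    dispersion); each fragment is drawn uniformly from the sample's two
    haplotypes, so heterozygous targets yield Binomial(n, 1/2) mutant
    fragments.  Amplicons covering a paralog-interference locus first draw,
    with probability 1/2, from the co-captured paralog haplotype — carrying
    the reference base in ``dilute`` mode (expected het mutant fraction
    0.25) or the mutant base in ``enrich`` mode.  Junction amplicons
    amplify only the mutant haplotype, so they emit reads only in carriers.
    ``off_target_fraction`` of fragments come from random genome positions.
    """
    if paralog_mode not in ("dilute", "enrich"):
        raise FixtureError(f"unknown paralog mode {paralog_mode!r}")
    eff = amplicon_efficiency or {}
    killed = set(killed_amplicons)
    paralog_set = set(paralog_targets)
    k = depth_model.dispersion
    out1: list[str] = []
    out2: list[str] = []
    stats = SampleSimStats(sample_id)
    serial = 0
    rl, pbe = sim_params.read_length, sim_params.per_base_error
    for aid in sorted(products):
        ap = products[aid]
        amp = ap.amplicon
        mean = depth_model.mean_depth_per_assay * eff.get(aid, 1.0) * scale
        if aid in killed:
            mean = 0.0
        carried = [(mid, genotypes.get(mid, "REF")) for mid in ap.alt_products]
        non_ref = [(mid, gt) for mid, gt in carried if gt != "REF"]
        if amp.is_junction:
            if not non_ref:
                continue
            mid, gt = non_ref[0]
            mean *= 0.5 if gt == "HET" else 1.0
        if mean <= 0:
            continue
        n = int(rng.negative_binomial(k, k / (k + mean)))
        if depth_model.dropout_prob > 0 and rng.random() < depth_model.dropout_prob:
            n = int(rng.poisson(1.0))
        if n == 0:
            continue
        if len(non_ref) > 1:
            raise FixtureError(
                f"{sample_id}/{aid}: multiple non-reference mutations per amplicon unsupported"
            )
        prefix = f"{aid}"
        if amp.is_junction:
            mid, _ = non_ref[0]
            serial = _emit_group(ap.alt_products[mid], n, prefix, serial, rl, pbe, rng, out1, out2)
            stats.per_amplicon[aid] = n
            stats.fragments_on += n
            continue
        paralog_here = paralog_set & set(ap.alt_products)
        n_par = int(rng.binomial(n, 0.5)) if paralog_here else 0
        n_locus = n - n_par
        groups: list[tuple[str, int]] = []
        if non_ref:
            mid, gt = non_ref[0]
            if gt == "HET":
                n_alt = int(rng.binomial(n_locus, 0.5))
            else:
                n_alt = n_locus
            groups.append((ap.alt_products[mid], n_alt))
            groups.append((ap.ref_product, n_locus - n_alt))
        else:
            groups.append((ap.ref_product, n_locus))
        if n_par:
            pmid = sorted(paralog_here)[0]
            par_product = ap.ref_product if paralog_mode == "dilute" else ap.alt_products[pmid]
            groups.append((par_product, n_par))
        for product, count in groups:
            serial = _emit_group(product, count, prefix, serial, rl, pbe, rng, out1, out2)
        stats.per_amplicon[aid] = n
        stats.fragments_on += n

    # off-target fragments from random genome positions
    f = depth_model.off_target_fraction
    if f > 0 and stats.fragments_on > 0:
        n_off = int(round(stats.fragments_on * f / (1 - f)))
        chroms = sorted(reference)
        lens = np.array([len(reference[c]) for c in chroms], dtype=float)
        probs = lens / lens.sum()
        for i in range(n_off):
            ci = int(rng.choice(len(chroms), p=probs))
            seq = reference[chroms[ci]]
            flen = int(rng.integers(120, 200))
            start = int(rng.integers(0, len(seq) - flen))
            frag = seq[start : start + flen]
            r1 = frag[:rl]
            r2 = revcomp(frag)[:rl]
            name = f"@OFF:{serial}"
            serial += 1
            out1.append(f"{name}\n{r1}\n+\n{_QUAL * len(r1)}\n")
            out2.append(f"{name}\n{r2}\n+\n{_QUAL * len(r2)}\n")
        stats.fragments_off = n_off

    # fixed mtime keeps seeded reruns byte-identical
    with gzip.GzipFile(out_r1, "wb", compresslevel=1, mtime=0) as fh:
        fh.write("".join(out1).encode())
    with gzip.GzipFile(out_r2, "wb", compresslevel=1, mtime=0) as fh:
        fh.write("".join(out2).encode())
    return stats


def simulate_cohort(
    reference: Mapping[str, str],
    panel: MutationPanel,
    amplicons: Sequence[Amplicon],
    design: CohortDesign,
    depth_model: DepthModel,
    sim_params: ReadSimParams,
    outdir: Union[str, Path],
) -> dict:
    """Simulate every sample and write FASTQs plus a ground-truth manifest.

    The manifest records the full planting (sufficient to score any caller
    without re-reading the FASTQs), the engineered QC failures, and
    per-sample fragment accounting.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = assign_genotypes(panel, design.planting, design.sample_ids, design.technical_replicates)
    products = build_amplicon_products(panel, amplicons, reference)
    ss = np.random.SeedSequence(entropy=sim_params.seed, spawn_key=(3,))
    child_seeds = ss.spawn(len(design.sample_ids))
    fastqs: dict[str, tuple[str, str]] = {}
    per_sample: dict[str, dict] = {}
    for sid, child in zip(design.sample_ids, child_seeds):
        rng = np.random.default_rng(child)
        r1 = outdir / f"{sid}_R1.fastq.gz"
        r2 = outdir / f"{sid}_R2.fastq.gz"
        genotypes = {mid: gt for (s, mid), gt in table.items() if s == sid}
        stats = simulate_sample_reads(
            sid,
            genotypes,
            products,
            reference,
            depth_model,
            sim_params,
            rng,
            r1,
            r2,
            paralog_targets=design.planting.paralog_targets,
            paralog_mode=design.paralog_mode,
            amplicon_efficiency=design.amplicon_efficiency,
            killed_amplicons=design.killed_amplicons.get(sid, ()),
            scale=design.sample_scale.get(sid, 1.0),
        )
        fastqs[sid] = (str(r1), str(r2))
        per_sample[sid] = {
            "fragments_on": stats.fragments_on,
            "fragments_off": stats.fragments_off,
            "fragments_total": stats.fragments_total,
        }
    planting = design.planting
    manifest = {
        "seed": sim_params.seed,
        "samples": list(design.sample_ids),
        "fastqs": fastqs,
        "genotypes": {f"{s}:{m}": gt for (s, m), gt in sorted(table.items())},
        "planting": {
            "known_het": [list(p) for p in planting.known_het],
            "singletons": [list(p) for p in planting.singletons],
            "recurrent": [
                {
                    "mutation_id": r.mutation_id,
                    "carrier_samples": list(r.carrier_samples),
                    "hom_samples": list(r.hom_samples),
                }
                for r in planting.recurrent
            ],
            "paralog_targets": list(planting.paralog_targets),
            "rearrangement_carriers": [list(p) for p in planting.rearrangement_carriers],
        },
        "qc_design": {
            "starved_samples": {s: sc for s, sc in design.sample_scale.items()},
            "killed_amplicons": {s: list(v) for s, v in design.killed_amplicons.items()},
            "weak_amplicons": dict(design.amplicon_efficiency),
        },
        "paralog_mode": design.paralog_mode,
        "depth_model": asdict(depth_model),
        "read_params": asdict(sim_params),
        "per_sample": per_sample,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
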