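"""Primer-anchored read assignment, haplotype-vote pileups, and
threshold-based genotype calling.

Instead of whole-genome alignment, reads are assigned to the amplicon whose
primer they begin with (≤1 mismatch); this is exact for amplicon data and
keeps the pipeline deterministic.  Allele counting is a haplotype vote: for
every member mutation of a target the ±``window`` bp reference and mutant
context strings are built, and each assigned fragment votes for the context
it contains exactly — indels included, via the same mechanism over the
adjacent interval.  Calls follow fixed thresholds: depth below ``min_dp``
is NO_CALL; a mutant allele fraction within [0.30, 0.70] (inclusive) is a
heterozygote; at or above ``hom_af_min`` a homozygote.  A fraction in
[0.15, 0.30) — the signature of an allele diluted by paralog co-capture —
is reported as REF flagged LOW_AF_SUSPECT rather than silently dropped,
and (0.70, 0.85) as REF flagged AF_BAND_GAP.  Large rearrangements are
detected by exact junction core-k-mer matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import zip_longest
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pysam

from ampliscreen.panel import (
    JunctionReference,
    MutationPanel,
    TargetPosition,
    build_junction_reference,
    collapse_targets,
)
from ampliscreen.pooling import Amplicon
from ampliscreen.seq import revcomp

log = logging.getLogger(__name__)

OFF_TARGET = "OFF_TARGET"
AMBIGUOUS = "AMBIGUOUS"

NO_CALL = "NO_CALL"
REF = "REF"
HET = "HET"
HOM = "HOM"

LOW_DP = "LOW_DP"
LOW_AF_SUSPECT = "LOW_AF_SUSPECT"
AF_BAND_GAP = "AF_BAND_GAP"
VALIDATION_REQUIRED = "VALIDATION_REQUIRED"


class FastqFormatError(ValueError):
    pass


@dataclass(frozen=True)
class CallThresholds:
    min_dp: int = 50
    het_af_low: float = 0.30
    het_af_high: float = 0.70
    hom_af_min: float = 0.85
    suspect_af_low: float = 0.15
    min_junction_support: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.suspect_af_low < self.het_af_low < self.het_af_high < self.hom_af_min <= 1):
            raise ValueError("thresholds must satisfy 0 < suspect < het_low < het_high < hom <= 1")
        if self.min_dp < 1 or self.min_junction_support < 1:
            raise ValueError("depth thresholds must be positive")


@dataclass(frozen=True)
class ReadAssignment:
    pair_id: str
    amplicon_id: Optional[str]  # None for off-target
    orientation: str = "fwd"    # fwd: R1 carries the forward primer
    reason: str = ""            # OFF_TARGET / AMBIGUOUS for unassigned


@dataclass
class PileupResult:
    """Per (target, sample) fragment-depth and allele counts.

    ``DP = ref_count + sum(alt_counts) + other_count``; AF is per member
    allele, alt/DP.
    """

    target_id: str
    sample_id: str
    dp: int
    ref_count: int
    alt_counts: dict[str, int]  # mutation_id -> count
    other_count: int
    uncaptured: bool = False

    def af(self, mutation_id: str) -> float:
        if self.dp == 0:
            return 0.0
        return self.alt_counts.get(mutation_id, 0) / self.dp


@dataclass(frozen=True)
class AssayCall:
    target_id: str
    sample_id: str
    genotype: str
    allele: Optional[str]  # member mutation id; None for NO_CALL
    dp: int
    af: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class JunctionCall:
    mutation_id: str
    sample_id: str
    supporting_reads: int
    carrier: bool


# ---------------------------------------------------------------------------
# Primer index + read assignment

class PrimerIndex:
    """Exact/1-mismatch lookup of read prefixes against amplicon primers."""

    def __init__(self, amplicons: Sequence[Amplicon]):
        self.fwd: dict[str, str] = {}
        self.rev: dict[str, str] = {}
        lengths = set()
        for a in amplicons:
            for primer, table in ((a.fwd_primer, self.fwd), (a.rev_primer, self.rev)):
                if primer in table and table[primer] != a.amplicon_id:
                    raise ValueError(f"primer shared by {table[primer]} and {a.amplicon_id}")
                table[primer] = a.amplicon_id
                lengths.add(len(primer))
        self.lengths = sorted(lengths)

    def _exact(self, p1: str, p2: str) -> tuple[set, set]:
        """Candidate amplicons for (R1 leads fwd) and (R1 leads rev)."""
        fwd_frame = set()
        rev_frame = set()
        a = self.fwd.get(p1)
        if a:
            fwd_frame.add(a)
        a = self.rev.get(p2)
        if a:
            fwd_frame.add(a)
        a = self.fwd.get(p2)
        if a:
            rev_frame.add(a)
        a = self.rev.get(p1)
        if a:
            rev_frame.add(a)
        return fwd_frame, rev_frame

    @staticmethod
    def _variants(prefix: str) -> Iterator[str]:
        for i, c in enumerate(prefix):
            for b in "ACGT":
                if b != c:
                    yield prefix[:i] + b + prefix[i + 1 :]

    def assign(self, r1: str, r2: str) -> tuple[Optional[str], str, str]:
        """Return (amplicon_id, orientation, reason)."""
        for L in self.lengths:
            p1, p2 = r1[:L], r2[:L]
            fwd_frame, rev_frame = self._exact(p1, p2)
            cands = fwd_frame | rev_frame
            if len(cands) == 1:
                aid = next(iter(cands))
                return aid, "fwd" if aid in fwd_frame else "rev", ""
            if len(cands) > 1:
                return None, "", AMBIGUOUS
        # fall back to 1-mismatch matching on both prefixes
        for L in self.lengths:
            p1, p2 = r1[:L], r2[:L]
            fwd_frame: set = set()
            rev_frame: set = set()
            for v in self._variants(p1):
                a = self.fwd.get(v)
                if a:
                    fwd_frame.add(a)
                a = self.rev.get(v)
                if a:
                    rev_frame.add(a)
            for v in self._variants(p2):
                a = self.rev.get(v)
                if a:
                    fwd_frame.add(a)
                a = self.fwd.get(v)
                if a:
                    rev_frame.add(a)
            cands = fwd_frame | rev_frame
            if len(cands) == 1:
                aid = next(iter(cands))
                return aid, "fwd" if aid in fwd_frame else "rev", ""
            if len(cands) > 1:
                return None, "", AMBIGUOUS
        return None, "", OFF_TARGET


def iter_read_pairs(
    fastq_r1: Union[str, Path], fastq_r2: Union[str, Path]
) -> Iterator[tuple[str, str, str]]:
    """Yield (name, seq1, seq2); raises on truncated/odd-length files."""
    try:
        with pysam.FastxFile(str(fastq_r1)) as f1, pysam.FastxFile(str(fastq_r2)) as f2:
            for e1, e2 in zip_longest(f1, f2):
                if e1 is None or e2 is None:
                    raise FastqFormatError(
                        f"paired FASTQs {fastq_r1}/{fastq_r2} have unequal read counts"
                    )
                yield e1.name, e1.sequence.upper(), e2.sequence.upper()
    except OSError as exc:
        raise FastqFormatError(f"cannot parse FASTQ pair {fastq_r1}/{fastq_r2}: {exc}") from exc


def assign_reads(
    fastq_r1: Union[str, Path],
    fastq_r2: Union[str, Path],
    amplicons: Sequence[Amplicon],
) -> list[ReadAssignment]:
    """Assign every read pair to at most one amplicon by primer prefix."""
    index = PrimerIndex(amplicons)
    out = []
    for name, s1, s2 in iter_read_pairs(fastq_r1, fastq_r2):
        aid, orient, reason = index.assign(s1, s2)
        out.append(ReadAssignment(name, aid, orient or "fwd", reason))
    return out


# ---------------------------------------------------------------------------
# Haplotype-vote pileup

@dataclass(frozen=True)
class _TargetContexts:
    target_id: str
    ref_ctx: str
    alt_ctx: tuple[tuple[str, str], ...]  # (mutation_id, context)


def build_target_contexts(
    panel: MutationPanel,
    amplicons: Sequence[Amplicon],
    reference: Mapping[str, str],
    window: int = 15,
) -> dict[str, tuple[_TargetContexts, ...]]:
    """Per-amplicon vote contexts for every covered target.

    The reference context spans the longest member ref allele plus
    ``window`` bp on each side; each mutant context applies one member
    allele to the same interval.  Context flanks may overlap primer landing
    sites (primer sequence equals the reference there), but variant bases
    themselves never do.
    """
    targets = {t.target_id: t for t in collapse_targets(panel)}
    out: dict[str, tuple[_TargetContexts, ...]] = {}
    for a in amplicons:
        if a.is_junction:
            out[a.amplicon_id] = ()
            continue
        seq = reference[a.chrom]
        ctxs = []
        for tid in a.target_ids:
            t = targets[tid]
            muts = [panel[mid] for mid in t.mutation_ids]
            max_ref = max(len(m.ref_allele) for m in muts)
            p0 = t.pos - 1
            ref_ctx = seq[p0 - window : p0 + max_ref + window]
            alts = []
            for m in muts:
                alt_ctx = (
                    seq[p0 - window : p0]
                    + m.alt_allele
                    + seq[p0 + len(m.ref_allele) : p0 + len(m.ref_allele) + window]
                )
                alts.append((m.mutation_id, alt_ctx))
            ctxs.append(_TargetContexts(tid, ref_ctx, tuple(alts)))
        out[a.amplicon_id] = tuple(ctxs)
    return out


class PileupAccumulator:
    """Streaming per-(target, sample) vote counts for one sample."""

    def __init__(self, contexts: Mapping[str, tuple[_TargetContexts, ...]]):
        self.contexts = contexts
        # target_id -> [ref, other, {mid: alt}]
        self.counts: dict[str, list] = {}

    def add_pair(self, amplicon_id: str, frame1: str, frame2: str) -> None:
        for tc in self.contexts.get(amplicon_id, ()):
            rec = self.counts.get(tc.target_id)
            if rec is None:
                rec = self.counts[tc.target_id] = [0, 0, {mid: 0 for mid, _ in tc.alt_ctx}]
            for mid, ctx in tc.alt_ctx:
                if ctx in frame1 or ctx in frame2:
                    rec[2][mid] += 1
                    break
            else:
                if tc.ref_ctx in frame1 or tc.ref_ctx in frame2:
                    rec[0] += 1
                else:
                    rec[1] += 1

    def result(self, target: TargetPosition, sample_id: str) -> PileupResult:
        rec = self.counts.get(target.target_id)
        if rec is None:
            return PileupResult(
                target.target_id, sample_id, 0, 0, {m: 0 for m in target.mutation_ids}, 0
            )
        ref, other, alts = rec
        dp = ref + other + sum(alts.values())
        return PileupResult(target.target_id, sample_id, dp, ref, dict(alts), other)


def pileup_target(
    assigned_pairs: Iterable[tuple[str, str, str, str]],
    target: TargetPosition,
    panel: MutationPanel,
    reference: Mapping[str, str],
    amplicons: Sequence[Amplicon],
    sample_id: str = "sample",
    window: int = 15,
) -> PileupResult:
    """Count haplotype votes for one target from assigned read pairs.

    ``assigned_pairs`` holds (amplicon_id, orientation, r1, r2) tuples as
    produced by read assignment.  If no amplicon covers the target the
    result is a structured "uncaptured" pileup with DP 0.
    """
    covering = [a for a in amplicons if target.target_id in a.target_ids and not a.is_junction]
    if not covering:
        return PileupResult(
            target.target_id, sample_id, 0, 0, {m: 0 for m in target.mutation_ids}, 0,
            uncaptured=True,
        )
    contexts = build_target_contexts(panel, covering, reference, window)
    acc = PileupAccumulator(contexts)
    cover_ids = {a.amplicon_id for a in covering}
    for aid, orient, r1, r2 in assigned_pairs:
        if aid not in cover_ids:
            continue
        if orient == "rev":
            r1, r2 = r2, r1
        acc.add_pair(aid, r1, revcomp(r2))
    return acc.result(target, sample_id)


# ---------------------------------------------------------------------------
# Calling

def call_genotype(
    pileup: PileupResult,
    thresholds: CallThresholds = CallThresholds(),
) -> list[AssayCall]:
    """Apply DP/AF thresholds to one pileup; one call per member allele.

    Multi-allelic targets are called per allele; two alleles can both reach
    the heterozygote band (compound call) and each is reported.
    """
    t = thresholds
    if pileup.dp < t.min_dp:
        return [
            AssayCall(
                pileup.target_id, pileup.sample_id, NO_CALL, None, pileup.dp,
                0.0, (LOW_DP,),
            )
        ]
    calls = []
    for mid in pileup.alt_counts:
        af = pileup.af(mid)
        flags: tuple[str, ...] = ()
        if t.het_af_low <= af <= t.het_af_high:
            gt = HET
        elif af >= t.hom_af_min:
            gt = HOM
        else:
            gt = REF
            if t.suspect_af_low <= af < t.het_af_low:
                flags = (LOW_AF_SUSPECT,)
            elif t.het_af_high < af < t.hom_af_min:
                flags = (AF_BAND_GAP,)
        calls.append(
            AssayCall(pileup.target_id, pileup.sample_id, gt, mid, pileup.dp, af, flags)
        )
    return calls


def detect_junction(
    reads: Iterable[str],
    junction_ref: JunctionReference,
    min_support: int = 10,
    sample_id: str = "sample",
) -> JunctionCall:
    """Count reads containing the junction core k-mer (either strand)."""
    core = junction_ref.core_kmer
    core_rc = revcomp(core)
    support = sum(1 for r in reads if core in r or core_rc in r)
    return JunctionCall(junction_ref.mutation_id, sample_id, support, support >= min_support)


# ---------------------------------------------------------------------------
# Whole-run orchestration

@dataclass
class SampleReadStats:
    total_pairs: int = 0
    assigned_pairs: int = 0
    off_target_pairs: int = 0
    ambiguous_pairs: int = 0


@dataclass
class RunResult:
    calls: list[AssayCall]
    junction_calls: list[JunctionCall]
    pileups: dict[tuple[str, str], PileupResult]  # (target_id, sample_id)
    read_stats: dict[str, SampleReadStats]
    targets: list[TargetPosition]
    sample_ids: list[str]
    vcf_path: Optional[str] = None

    def call_lookup(self) -> dict[tuple[str, str], AssayCall]:
        """(sample_id, mutation_id) -> call, for calls with an allele."""
        return {(c.sample_id, c.allele): c for c in self.calls if c.allele is not None}


def genotype_run(
    sample_fastqs: Mapping[str, tuple[Union[str, Path], Union[str, Path]]],
    panel: MutationPanel,
    amplicons: Sequence[Amplicon],
    reference: Mapping[str, str],
    thresholds: CallThresholds = CallThresholds(),
    known_pairs: Optional[set[tuple[str, str]]] = None,
    outdir: Optional[Union[str, Path]] = None,
    window: int = 15,
) -> RunResult:
    """Genotype every sample: assign, pile up, call, detect junctions.

    ``known_pairs`` is the expected-known (sample, mutation) list; non-REF
    calls outside it are flagged VALIDATION_REQUIRED, mirroring the rule
    that unexpected mutations require orthogonal confirmation.  Writes a
    multi-sample VCF and a per-sample calls TSV when ``outdir`` is given.
    """
    targets = collapse_targets(panel)
    contexts = build_target_contexts(panel, amplicons, reference, window)
    index = PrimerIndex(amplicons)
    junction_refs = [build_junction_reference(m, reference) for m in panel.rearrangements]
    junction_by_amp: dict[str, JunctionReference] = {}
    for a in amplicons:
        if a.is_junction:
            for jr in junction_refs:
                if jr.mutation_id == a.target_ids[0]:
                    junction_by_amp[a.amplicon_id] = jr

    calls: list[AssayCall] = []
    junction_calls: list[JunctionCall] = []
    pileups: dict[tuple[str, str], PileupResult] = {}
    read_stats: dict[str, SampleReadStats] = {}
    sample_ids = list(sample_fastqs)

    for sid in sample_ids:
        r1_path, r2_path = sample_fastqs[sid]
        acc = PileupAccumulator(contexts)
        junc_support = {jr.mutation_id: 0 for jr in junction_refs}
        junc_kmers = {
            aid: (jr.core_kmer, revcomp(jr.core_kmer)) for aid, jr in junction_by_amp.items()
        }
        stats = SampleReadStats()
        for _name, s1, s2 in iter_read_pairs(r1_path, r2_path):
            stats.total_pairs += 1
            aid, orient, reason = index.assign(s1, s2)
            if aid is None:
                if reason == AMBIGUOUS:
                    stats.ambiguous_pairs += 1
                else:
                    stats.off_target_pairs += 1
                continue
            stats.assigned_pairs += 1
            if orient == "rev":
                s1, s2 = s2, s1
            f2 = revcomp(s2)
            if aid in junc_kmers:
                core, core_rc = junc_kmers[aid]
                if core in s1 or core in f2 or core_rc in s1 or core_rc in f2:
                    junc_support[junction_by_amp[aid].mutation_id] += 1
                continue
            acc.add_pair(aid, s1, f2)
        read_stats[sid] = stats
        for t in targets:
            pu = acc.result(t, sid)
            pileups[(t.target_id, sid)] = pu
            calls.extend(call_genotype(pu, thresholds))
        for jr in junction_refs:
            support = junc_support[jr.mutation_id]
            junction_calls.append(
                JunctionCall(jr.mutation_id, sid, support, support >= thresholds.min_junction_support)
            )

    if known_pairs is not None:
        calls = [
            _flag_unexpected(c, known_pairs) for c in calls
        ]

    result = RunResult(calls, junction_calls, pileups, read_stats, targets, sample_ids)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.vcf_path = str(outdir / "calls.vcf")
        write_vcf(result, panel, reference, result.vcf_path)
        write_calls_tsv(result, outdir / "calls.tsv")
    return result


def _flag_unexpected(call: AssayCall, known_pairs: set[tuple[str, str]]) -> AssayCall:
    if call.genotype in (HET, HOM) and (call.sample_id, call.allele) not in known_pairs:
        return AssayCall(
            call.target_id, call.sample_id, call.genotype, call.allele, call.dp, call.af,
            call.flags + (VALIDATION_REQUIRED,),
        )
    return call


# ---------------------------------------------------------------------------
# Output writers

def write_calls_tsv(result: RunResult, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("#sample_id\ttarget_id\tallele\tgenotype\tDP\tAF\tflags\n")
        for c in sorted(result.calls, key=lambda c: (c.sample_id, c.target_id, c.allele or "")):
            fh.write(
                f"{c.sample_id}\t{c.target_id}\t{c.allele or '.'}\t{c.genotype}\t"
                f"{c.dp}\t{c.af:.4f}\t{'|'.join(c.flags) or '.'}\n"
            )


def load_calls_tsv(path: Union[str, Path]) -> list[AssayCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            calls.append(
                AssayCall(
                    target_id=f[1],
                    sample_id=f[0],
                    genotype=f[3],
                    allele=None if f[2] == "." else f[2],
                    dp=int(f[4]),
                    af=float(f[5]),
                    flags=tuple(f[6].split("|")) if f[6] != "." else (),
                )
            )
    return calls


def write_vcf(
    result: RunResult, panel: MutationPanel, reference: Mapping[str, str], path: Union[str, Path]
) -> None:
    """Multi-sample VCFv4.2 with one record per variant called in >=1 sample.

    FORMAT carries GT, DP (fragment depth), AF (mutant fraction) and FL
    (pipe-joined flags).  Junction calls are reported in the TSV/JSON
    outputs, not the VCF.
    """
    header = pysam.VariantHeader()
    for chrom in sorted(reference):
        header.contigs.add(chrom, length=len(reference[chrom]))
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("DISORDER", 1, "String", "Associated disorder")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Fragment depth at the target")
    header.formats.add("AF", 1, "Float", "Mutant allele fraction")
    header.formats.add("FL", 1, "String", "Call flags, pipe-joined")
    for sid in result.sample_ids:
        header.add_sample(sid)

    by_allele: dict[str, dict[str, AssayCall]] = {}
    for c in result.calls:
        if c.allele is not None:
            by_allele.setdefault(c.allele, {})[c.sample_id] = c
    called = [
        mid
        for mid, per_sample in by_allele.items()
        if any(c.genotype in (HET, HOM) for c in per_sample.values())
    ]
    order = {m.mutation_id: i for i, m in enumerate(panel)}
    called.sort(key=lambda mid: order[mid])

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for mid in called:
            m = panel[mid]
            rec = vcf.new_record(
                contig=m.chrom,
                start=m.pos - 1,
                alleles=(m.ref_allele, m.alt_allele),
                id=mid,
            )
            rec.info["GENE"] = m.gene
            rec.info["DISORDER"] = m.disorder
            per_sample = by_allele[mid]
            for sid in result.sample_ids:
                c = per_sample.get(sid)
                fmt = rec.samples[sid]
                if c is None or c.genotype == NO_CALL:
                    fmt["GT"] = (None, None)
                    if c is not None:
                        fmt["DP"] = c.dp
                        fmt["FL"] = "|".join(c.flags) or "."
                    continue
                fmt["GT"] = {REF: (0, 0), HET: (0, 1), HOM: (1, 1)}[c.genotype]
                fmt["DP"] = c.dp
                fmt["AF"] = round(c.af, 4)
                fmt["FL"] = "|".join(c.flags) or "."
            vcf.write(rec)
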