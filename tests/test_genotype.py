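"""Genotyper: primer assignment, haplotype-vote pileup, threshold calls,
junction detection, VCF output."""

import gzip
import math

import numpy as np
import pysam
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ampliscreen.genotype import (
    AF_BAND_GAP,
    AMBIGUOUS,
    HET,
    HOM,
    LOW_AF_SUSPECT,
    LOW_DP,
    NO_CALL,
    REF,
    CallThresholds,
    JunctionCall,
    PileupResult,
    PrimerIndex,
    assign_reads,
    call_genotype,
    detect_junction,
    genotype_run,
    pileup_target,
)
from ampliscreen.panel import (
    MutationClass,
    MutationPanel,
    PanelMutation,
    build_junction_reference,
    collapse_targets,
)
from ampliscreen.pooling import Amplicon
from ampliscreen.seq import gc_fraction, revcomp
from ampliscreen.simulate import (
    DepthModel,
    ReadSimParams,
    build_amplicon_products,
    simulate_sample_reads,
)

THRESH = CallThresholds()


# ---------------------------------------------------------------------------
# A hand-built micro universe: one 120 bp amplicon around one SNV and one
# 4 bp insertion on a second amplicon — small enough for exhaustive oracles.

@pytest.fixture(scope="module")
def micro():
    rng = np.random.default_rng(123)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=30_000))
    reference = {"chrM": seq}
    pos_snv, pos_ins = 5001, 12_001
    snv = PanelMutation("SNV1", "GENEA", "dA", "chrM", pos_snv, seq[pos_snv - 1],
                        ("A" if seq[pos_snv - 1] != "A" else "C"), MutationClass.SNV)
    anchor = seq[pos_ins - 1]
    ins = PanelMutation("INS1", "GENEB", "dB", "chrM", pos_ins, anchor, anchor + "TATC",
                        MutationClass.INS)
    panel = MutationPanel([snv, ins])

    def make_amp(aid, pos, length, tid):
        start = pos - 1 - 50
        product = seq[start : start + length]
        return Amplicon(aid, "chrM", start, start + length, product[:20],
                        revcomp(product[-20:]), gc_fraction(product), (tid,))

    amp_snv = make_amp("AMP1", pos_snv, 120, f"t_chrM_{pos_snv}")
    amp_ins = make_amp("AMP2", pos_ins, 130, f"t_chrM_{pos_ins}")
    return reference, panel, [amp_snv, amp_ins]


def _simulate(micro, genotypes, tmp_path, seed=1, mean=150, error=0.0, off=0.0):
    reference, panel, amplicons = micro
    products = build_amplicon_products(panel, amplicons, reference)
    rng = np.random.default_rng(seed)
    r1, r2 = tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz"
    simulate_sample_reads(
        "SX", genotypes, products, reference,
        DepthModel(mean_depth_per_assay=mean, off_target_fraction=off),
        ReadSimParams(per_base_error=error, seed=seed), rng, r1, r2,
    )
    return r1, r2


class TestAssignReads:
    def test_error_free_pairs_go_to_their_ground_truth_amplicon(self, micro, tmp_path):
        _, panel, amplicons = micro
        r1, r2 = _simulate(micro, {}, tmp_path)
        for a in assign_reads(r1, r2, amplicons):
            truth = a.pair_id.split(":")[0]
            assert a.amplicon_id == truth

    def test_random_sequence_pair_is_off_target(self, micro):
        _, _, amplicons = micro
        index = PrimerIndex(amplicons)
        rng = np.random.default_rng(0)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, size=150))
        aid, _, reason = index.assign(junk, revcomp(junk))
        assert aid is None and reason == "OFF_TARGET"

    def test_single_primer_mismatch_is_tolerated_two_are_not(self, micro):
        _, _, amplicons = micro
        a = amplicons[0]
        index = PrimerIndex(amplicons)
        good = a.fwd_primer + "A" * 100
        one_mm = ("T" if a.fwd_primer[5] != "T" else "G")
        r1_1mm = a.fwd_primer[:5] + one_mm + a.fwd_primer[6:] + "A" * 100
        junk_mate = "C" * 120
        assert index.assign(good, junk_mate)[0] == a.amplicon_id
        assert index.assign(r1_1mm, junk_mate)[0] == a.amplicon_id
        two = list(r1_1mm)
        two[10] = "A" if two[10] != "A" else "C"
        assert index.assign("".join(two), junk_mate)[0] is None

    def test_conflicting_primer_evidence_is_ambiguous(self, micro):
        _, _, amplicons = micro
        index = PrimerIndex(amplicons)
        r1 = amplicons[0].fwd_primer + "A" * 100
        r2 = amplicons[1].fwd_primer + "A" * 100
        aid, _, reason = index.assign(r1, r2)
        assert aid is None and reason == AMBIGUOUS

    def test_assignment_accuracy_on_noisy_reads(self, micro, tmp_path):
        """At 0.1 % per-base error and 5 % off-target, >=99 % of pairs match
        the read-name ground truth."""
        _, _, amplicons = micro
        r1, r2 = _simulate(micro, {}, tmp_path, mean=6000, error=0.001, off=0.05)
        assignments = assign_reads(r1, r2, amplicons)
        correct = total = 0
        for a in assignments:
            truth = a.pair_id.split(":")[0]
            total += 1
            got = a.amplicon_id if a.amplicon_id else "OFF"
            correct += got == truth
        assert total >= 10_000
        assert correct / total >= 0.99


class TestPileup:
    def _pileup(self, micro, tmp_path, genotypes, mid, seed=1, error=0.0):
        reference, panel, amplicons = micro
        r1, r2 = _simulate(micro, genotypes, tmp_path, seed=seed, error=error)
        assignments = assign_reads(r1, r2, amplicons)
        pairs = []
        reads1, reads2 = [], []
        with pysam.FastxFile(str(r1)) as f1, pysam.FastxFile(str(r2)) as f2:
            for e1, e2 in zip(f1, f2):
                reads1.append(e1.sequence)
                reads2.append(e2.sequence)
        for a, s1, s2 in zip(assignments, reads1, reads2):
            if a.amplicon_id:
                pairs.append((a.amplicon_id, a.orientation, s1, s2))
        target = next(t for t in collapse_targets(panel) if mid in t.mutation_ids)
        return pairs, pileup_target(pairs, target, panel, reference, amplicons)

    def test_conservation_and_error_free_purity(self, micro, tmp_path):
        pairs, pu = self._pileup(micro, tmp_path, {"SNV1": "HET"}, "SNV1")
        assert pu.ref_count + sum(pu.alt_counts.values()) + pu.other_count == pu.dp
        assert pu.other_count == 0
        assert pu.dp > 50

    def test_insertion_alt_votes_come_from_tatc_context(self, micro, tmp_path):
        """4 bp insertion het: alt votes equal the reads carrying the
        inserted TATC context."""
        reference, panel, amplicons = micro
        pairs, pu = self._pileup(micro, tmp_path, {"INS1": "HET"}, "INS1")
        m = panel["INS1"]
        seq = reference["chrM"]
        p0 = m.pos - 1
        alt_ctx = seq[p0 - 15 : p0] + m.alt_allele + seq[p0 + 1 : p0 + 16]
        n_ctx = sum(
            1 for aid, orient, s1, s2 in pairs
            if aid == "AMP2" and (alt_ctx in s1 or alt_ctx in revcomp(s2))
        )
        assert pu.alt_counts["INS1"] == n_ctx > 0

    def test_counts_match_full_haplotype_string_oracle(self, micro, tmp_path):
        """Brute-force oracle: a fragment votes by exact substring matching
        of its forward-frame reads against the complete ref and mutant
        product sequences."""
        reference, panel, amplicons = micro
        products = build_amplicon_products(panel, amplicons, reference)
        pairs, pu = self._pileup(micro, tmp_path, {"SNV1": "HET"}, "SNV1", seed=9)
        ref_p = products["AMP1"].ref_product
        alt_p = products["AMP1"].alt_products["SNV1"]
        o_ref = o_alt = 0
        for aid, orient, s1, s2 in pairs:
            if aid != "AMP1":
                continue
            f2 = revcomp(s2)
            in_ref = s1 in ref_p and f2 in ref_p
            in_alt = s1 in alt_p and f2 in alt_p
            assert in_ref != in_alt  # error-free reads match exactly one haplotype
            o_ref += in_ref
            o_alt += in_alt
        assert pu.ref_count == o_ref
        assert pu.alt_counts["SNV1"] == o_alt

    def test_uncaptured_target_reports_structured_zero_depth(self, micro):
        reference, panel, amplicons = micro
        target = next(t for t in collapse_targets(panel) if "SNV1" in t.mutation_ids)
        pu = pileup_target([], target, panel, reference, [amplicons[1]])
        assert pu.uncaptured and pu.dp == 0


class TestCallGenotype:
    def _pu(self, dp, alt, mid="M1"):
        return PileupResult("t1", "S1", dp, dp - alt, {mid: alt}, 0)

    @pytest.mark.parametrize(
        "dp, alt, expected_gt, expected_flags",
        [
            (519, 254, HET, ()),              # AF 0.49 — the typical het
            (500, 130, REF, (LOW_AF_SUSPECT,)),  # AF 0.26 — paralog-diluted false negative
            (49, 25, NO_CALL, (LOW_DP,)),     # just under the depth floor
            (50, 15, HET, ()),                # DP 50, AF 0.30 — inclusive boundaries
            (100, 70, HET, ()),               # AF 0.70 still het
            (100, 80, REF, (AF_BAND_GAP,)),   # indeterminate-zygosity band
            (100, 85, HOM, ()),
            (100, 5, REF, ()),
        ],
    )
    def test_threshold_bands(self, dp, alt, expected_gt, expected_flags):
        calls = call_genotype(self._pu(dp, alt), THRESH)
        assert len(calls) == 1
        assert calls[0].genotype == expected_gt
        assert calls[0].flags == expected_flags

    def test_multi_allelic_compound_het_reports_both_alleles(self):
        pu = PileupResult("t1", "S1", 200, 60, {"Ma": 70, "Mb": 70}, 0)
        calls = {c.allele: c.genotype for c in call_genotype(pu, THRESH)}
        assert calls == {"Ma": HET, "Mb": HET}

    @given(dp=st.integers(50, 2000), seed=st.integers(0, 10_000))
    def test_call_never_regresses_as_alt_count_grows(self, dp, seed):
        """At fixed DP, raising the mutant count walks monotonically through
        REF -> HET -> (gap) -> HOM, never back to REF from HET within the band."""
        rank = {REF: 0, HET: 1, HOM: 2}
        prev_af = -1.0
        seen_het = False
        for alt in range(0, dp + 1, max(1, dp // 37)):
            (call,) = call_genotype(self._pu(dp, alt), THRESH)
            af = alt / dp
            if THRESH.het_af_low <= af <= THRESH.het_af_high:
                assert call.genotype == HET
                seen_het = True
            if seen_het and af <= THRESH.het_af_high:
                assert call.genotype != REF or af < THRESH.het_af_low
            prev_af = af


class TestJunction:
    def test_supporting_reads_counted_on_both_strands(self, tiny_fixture, tiny_reference):
        panel, _ = tiny_fixture
        jr = build_junction_reference(panel.rearrangements[0], tiny_reference)
        fwd = "A" * 20 + jr.core_kmer + "T" * 20
        rev = revcomp(fwd)
        noise = "ACGT" * 40
        call = detect_junction([fwd, rev, noise, noise], jr, min_support=2, sample_id="S1")
        assert call.supporting_reads == 2
        assert call.carrier

    def test_below_min_support_is_not_a_carrier(self, tiny_fixture, tiny_reference):
        panel, _ = tiny_fixture
        jr = build_junction_reference(panel.rearrangements[0], tiny_reference)
        read = "A" * 20 + jr.core_kmer
        call = detect_junction([read] * 9, jr, min_support=10)
        assert not call.carrier


class TestGenotypeRun:
    def test_run_calls_planted_variants_and_writes_valid_vcf(self, micro, tmp_path):
        reference, panel, amplicons = micro
        d1 = tmp_path / "s1"
        d2 = tmp_path / "s2"
        d1.mkdir(), d2.mkdir()
        r1a, r2a = _simulate(micro, {"SNV1": "HET", "INS1": "HOM"}, d1, seed=3, error=0.001)
        r1b, r2b = _simulate(micro, {}, d2, seed=4, error=0.001)
        result = genotype_run(
            {"S1": (r1a, r2a), "S2": (r1b, r2b)},
            panel, amplicons, reference, THRESH,
            known_pairs={("S1", "SNV1")},
            outdir=tmp_path / "out",
        )
        lk = result.call_lookup()
        assert lk[("S1", "SNV1")].genotype == HET
        assert lk[("S1", "INS1")].genotype == HOM
        assert lk[("S2", "SNV1")].genotype == REF
        # unexpected HOM is flagged for validation, the expected het is not
        assert "VALIDATION_REQUIRED" in lk[("S1", "INS1")].flags
        assert "VALIDATION_REQUIRED" not in lk[("S1", "SNV1")].flags
        with pysam.VariantFile(result.vcf_path) as vcf:
            recs = list(vcf)
        assert {r.id for r in recs} == {"SNV1", "INS1"}
        snv = next(r for r in recs if r.id == "SNV1")
        assert snv.samples["S1"]["GT"] == (0, 1)
        assert snv.samples["S2"]["GT"] == (0, 0)

    def test_empty_fastq_sample_yields_all_no_call(self, micro, tmp_path):
        reference, panel, amplicons = micro
        for name in ("e_R1.fastq.gz", "e_R2.fastq.gz"):
            with gzip.open(tmp_path / name, "wt") as fh:
                pass
        result = genotype_run(
            {"S0": (tmp_path / "e_R1.fastq.gz", tmp_path / "e_R2.fastq.gz")},
            panel, amplicons, reference, THRESH,
        )
        assert all(c.genotype == NO_CALL for c in result.calls)

    def test_technical_replicates_agree_on_well_covered_calls(self, micro, tmp_path):
        """Same genotypes, independent read noise: concordant calls at DP>=50."""
        reference, panel, amplicons = micro
        d1, d2 = tmp_path / "a", tmp_path / "b"
        d1.mkdir(), d2.mkdir()
        gt = {"SNV1": "HET"}
        r1a, r2a = _simulate(micro, gt, d1, seed=5, error=0.001)
        r1b, r2b = _simulate(micro, gt, d2, seed=6, error=0.001)
        result = genotype_run(
            {"R1": (r1a, r2a), "R2": (r1b, r2b)}, panel, amplicons, reference, THRESH
        )
        lk = result.call_lookup()
        for mid in ("SNV1", "INS1"):
            c1, c2 = lk[("R1", mid)], lk[("R2", mid)]
            if c1.dp >= THRESH.min_dp and c2.dp >= THRESH.min_dp:
                assert c1.genotype == c2.genotype
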