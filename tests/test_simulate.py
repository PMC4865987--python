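"""Read simulator: reference, fixture structure, planting, read models."""

import gzip
import math

import numpy as np
import pytest

from ampliscreen.panel import collapse_targets
from ampliscreen.simulate import (
    PAPER_SCALE,
    TINY,
    CohortDesign,
    DepthModel,
    FixtureError,
    PlantingSpec,
    ReadSimParams,
    assign_genotypes,
    build_amplicon_products,
    design_pilot_cohort,
    generate_panel_fixture,
    generate_reference,
    simulate_cohort,
    simulate_sample_reads,
)


class TestReference:
    def test_same_seed_reproduces_identical_genome(self):
        a = generate_reference(3, n_chrom=1, chrom_len=20_000)
        b = generate_reference(3, n_chrom=1, chrom_len=20_000)
        c = generate_reference(4, n_chrom=1, chrom_len=20_000)
        assert a == b
        assert a != c

    def test_base_composition_matches_configured_gc(self):
        genome = generate_reference(3, n_chrom=1, chrom_len=200_000, gc=0.41)
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.41) < 0.02

    def test_too_short_chromosomes_rejected(self):
        with pytest.raises(FixtureError):
            generate_reference(3, chrom_len=5000)


class TestFixtureStructure:
    def test_paper_scale_counts(self, paper_fixture):
        panel, amplicons = paper_fixture
        assert len(panel.small_mutations) == 370
        assert len(panel.rearrangements) == 4
        assert len(collapse_targets(panel)) == 368
        standard = [a for a in amplicons if not a.is_junction and not a.is_length_outlier]
        assert len(standard) == 345
        assert sum(a.is_length_outlier for a in amplicons) == 1
        assert sum(a.is_junction for a in amplicons) == 4

    def test_exactly_two_multi_allelic_targets(self, paper_fixture):
        panel, _ = paper_fixture
        multi = [t for t in collapse_targets(panel) if len(t.mutation_ids) > 1]
        assert len(multi) == 2
        assert all(len(t.mutation_ids) == 2 for t in multi)

    def test_amplicon_lengths_within_range_except_declared_outliers(self, paper_fixture):
        _, amplicons = paper_fixture
        for a in amplicons:
            if a.is_junction:
                continue
            if a.is_length_outlier:
                assert a.length == 418
            else:
                assert 64 <= a.length <= 200

    def test_primers_are_product_prefixes(self, paper_fixture, paper_reference):
        from ampliscreen.seq import revcomp

        _, amplicons = paper_fixture
        for a in amplicons:
            if a.is_junction:
                continue
            product = paper_reference[a.chrom][a.start : a.end]
            assert product.startswith(a.fwd_primer)
            assert revcomp(product).startswith(a.rev_primer)

    def test_every_target_position_inside_its_amplicons(self, paper_fixture):
        panel, amplicons = paper_fixture
        pos_by_tid = {t.target_id: (t.chrom, t.pos) for t in collapse_targets(panel)}
        covered = set()
        for a in amplicons:
            if a.is_junction:
                continue
            for tid in a.target_ids:
                chrom, pos = pos_by_tid[tid]
                assert chrom == a.chrom
                assert a.start <= pos - 1 < a.end
                covered.add(tid)
        assert covered == set(pos_by_tid)

    def test_zero_pair_preset_gives_identity_target_count(self, tiny_reference):
        preset = TINY.__class__(**{**TINY.__dict__, "n_same_position_pairs": 0,
                                   "n_mutations": 11, "name": "tiny0"})
        panel, _ = generate_panel_fixture(tiny_reference, preset, 2)
        assert len(collapse_targets(panel)) == len(panel.small_mutations)


class TestPilotDesign:
    def test_planting_realizes_study_counts(self, paper_fixture):
        panel, amplicons = paper_fixture
        design = design_pilot_cohort(panel, amplicons, 9)
        p = design.planting
        assert len(p.known_het) == 50
        assert len({s for s, _ in p.known_het}) == 40
        assert p.unexpected_singletons == 15
        assert sorted(n for _, n, _ in p.recurrent_variants) == [7, 8, 11, 23]
        assert p.n_unexpected_calls == 64
        assert len(p.paralog_targets) == 2
        assert len(p.rearrangement_carriers) == 5
        assert len(design.killed_amplicons["S36"]) == 44
        # planting never touches the engineered-failure samples
        planted_samples = {s for s, _ in p.known_het} | {s for s, _ in p.singletons}
        for r in p.recurrent:
            planted_samples |= set(r.carrier_samples)
        assert planted_samples.isdisjoint({"S02", "S27", "S36"})

    def test_genotype_table_recount_matches_spec(self, paper_fixture):
        panel, amplicons = paper_fixture
        design = design_pilot_cohort(panel, amplicons, 9)
        table = assign_genotypes(panel, design.planting, design.sample_ids)
        n_het = sum(1 for gt in table.values() if gt == "HET")
        n_hom = sum(1 for gt in table.values() if gt == "HOM")
        p = design.planting
        expected_hom = sum(len(r.hom_samples) for r in p.recurrent)
        expected_het = (
            len(p.known_het) + len(p.singletons) + len(p.rearrangement_carriers)
            + sum(len(r.carrier_samples) for r in p.recurrent) - expected_hom
        )
        assert (n_het, n_hom) == (expected_het, expected_hom)

    def test_empty_spec_gives_all_ref_table(self, paper_fixture):
        panel, _ = paper_fixture
        assert assign_genotypes(panel, PlantingSpec(), ["S01"]) == {}

    def test_unknown_mutation_in_spec_rejected(self, paper_fixture):
        panel, _ = paper_fixture
        spec = PlantingSpec(known_het=[("S01", "NOPE")])
        with pytest.raises(FixtureError, match="NOPE"):
            assign_genotypes(panel, spec, ["S01"])

    def test_technical_replicates_share_genotypes(self, paper_fixture):
        panel, amplicons = paper_fixture
        design = design_pilot_cohort(panel, amplicons, 9)
        sid, mid = design.planting.known_het[0]
        table = assign_genotypes(
            panel, design.planting, design.sample_ids + ["S49"],
            technical_replicates=[(sid, "S49")],
        )
        assert table[("S49", mid)] == table[(sid, mid)] == "HET"


def _simulate_one(panel, amplicons, reference, genotypes, seed, tmp_path, *,
                  mean=1000, error=0.0, off_target=0.0, paralog=(), mode="dilute"):
    products = build_amplicon_products(panel, amplicons, reference)
    rng = np.random.default_rng(seed)
    r1, r2 = tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz"
    stats = simulate_sample_reads(
        "SX", genotypes, products, reference,
        DepthModel(mean_depth_per_assay=mean, off_target_fraction=off_target),
        ReadSimParams(per_base_error=error, seed=seed),
        rng, r1, r2, paralog_targets=paralog, paralog_mode=mode,
    )
    return stats, r1, r2


def _mutant_fraction(panel, reference, amplicons, mid, r1_path):
    """Count alt- vs ref-context reads straight off the FASTQ."""
    m = panel[mid]
    seq = reference[m.chrom]
    p0 = m.pos - 1
    ref_ctx = seq[p0 - 15 : p0 + len(m.ref_allele) + 15]
    alt_ctx = seq[p0 - 15 : p0] + m.alt_allele + seq[p0 + len(m.ref_allele) : p0 + len(m.ref_allele) + 15]
    n_ref = n_alt = 0
    with gzip.open(r1_path, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 != 1:
                continue
            if alt_ctx in line:
                n_alt += 1
            elif ref_ctx in line:
                n_ref += 1
    return n_ref, n_alt


class TestReadModels:
    def test_het_allele_fraction_follows_binomial_law(self, tiny_fixture, tiny_reference, tmp_path):
        """Error-free het at depth 1000: mutant fraction within 3 binomial SE of 1/2."""
        panel, amplicons = tiny_fixture
        mid = panel.small_mutations[0].mutation_id
        stats, r1, _ = _simulate_one(panel, amplicons, tiny_reference, {mid: "HET"}, 21, tmp_path)
        n_ref, n_alt = _mutant_fraction(panel, tiny_reference, amplicons, mid, r1)
        n = n_ref + n_alt
        assert n > 500
        se = math.sqrt(0.25 / n)
        assert abs(n_alt / n - 0.5) < 3 * se

    def test_hom_target_is_pure_mutant_without_errors(self, tiny_fixture, tiny_reference, tmp_path):
        panel, amplicons = tiny_fixture
        mid = panel.small_mutations[0].mutation_id
        _, r1, _ = _simulate_one(panel, amplicons, tiny_reference, {mid: "HOM"}, 22, tmp_path)
        n_ref, n_alt = _mutant_fraction(panel, tiny_reference, amplicons, mid, r1)
        assert n_ref == 0 and n_alt > 0

    @pytest.mark.parametrize("mode, expected", [("dilute", 0.25), ("enrich", 0.75)])
    def test_paralog_co_capture_shifts_het_fraction(self, tiny_fixture, tiny_reference, tmp_path, mode, expected):
        """Even-ratio paralog capture: the paralog haplotype contributes the
        reference base (dilute, E[AF]=0.25) or the mutant base (enrich)."""
        panel, amplicons = tiny_fixture
        mid = next(m.mutation_id for m in panel.small_mutations if m.mut_class.value == "SNV")
        stats, r1, _ = _simulate_one(
            panel, amplicons, tiny_reference, {mid: "HET"}, 23, tmp_path,
            paralog=(mid,), mode=mode,
        )
        n_ref, n_alt = _mutant_fraction(panel, tiny_reference, amplicons, mid, r1)
        n = n_ref + n_alt
        se = math.sqrt(expected * (1 - expected) / n)
        assert n > 500
        assert abs(n_alt / n - expected) < 3 * se

    def test_junction_reads_only_in_carriers(self, tiny_fixture, tiny_reference, tmp_path):
        from ampliscreen.panel import build_junction_reference

        panel, amplicons = tiny_fixture
        lr = panel.rearrangements[0]
        jr = build_junction_reference(lr, tiny_reference)
        carrier_dir = tmp_path / "carrier"
        ref_dir = tmp_path / "ref"
        carrier_dir.mkdir(), ref_dir.mkdir()
        _, r1c, _ = _simulate_one(panel, amplicons, tiny_reference, {lr.mutation_id: "HET"}, 24, carrier_dir, mean=300)
        _, r1n, _ = _simulate_one(panel, amplicons, tiny_reference, {}, 24, ref_dir, mean=300)
        def count(path):
            with gzip.open(path, "rt") as fh:
                return sum(jr.core_kmer in line for i, line in enumerate(fh) if i % 4 == 1)
        assert count(r1c) > 50
        assert count(r1n) == 0

    def test_read_accounting_matches_fastq_lines(self, tiny_fixture, tiny_reference, tmp_path):
        panel, amplicons = tiny_fixture
        stats, r1, r2 = _simulate_one(panel, amplicons, tiny_reference, {}, 25, tmp_path,
                                      mean=200, error=0.001, off_target=0.05)
        with gzip.open(r1, "rt") as fh:
            n_pairs = sum(1 for _ in fh) // 4
        assert stats.fragments_on + stats.fragments_off == n_pairs
        frac = stats.fragments_off / n_pairs
        assert abs(frac - 0.05) < 0.01


class TestCohort:
    def test_cohort_is_byte_deterministic_and_manifest_recounts(self, tiny_fixture, tiny_reference, tmp_path):
        panel, amplicons = tiny_fixture
        sample_ids = ["S01", "S02", "S03"]
        mids = [m.mutation_id for m in panel.small_mutations[:3]]
        planting = PlantingSpec(
            known_het=[("S01", mids[0])],
            singletons=[("S02", mids[1])],
            rearrangement_carriers=[("S03", panel.rearrangements[0].mutation_id)],
        )
        design = CohortDesign(sample_ids=sample_ids, planting=planting)
        dm = DepthModel(mean_depth_per_assay=120)
        sp = ReadSimParams(seed=31)
        m1 = simulate_cohort(tiny_reference, panel, amplicons, design, dm, sp, tmp_path / "a")
        m2 = simulate_cohort(tiny_reference, panel, amplicons, design, dm, sp, tmp_path / "b")
        for sid in sample_ids:
            a1 = (tmp_path / "a" / f"{sid}_R1.fastq.gz").read_bytes()
            b1 = (tmp_path / "b" / f"{sid}_R1.fastq.gz").read_bytes()
            assert a1 == b1
        assert m1["genotypes"] == m2["genotypes"]
        assert m1["genotypes"] == {
            f"S01:{mids[0]}": "HET",
            f"S02:{mids[1]}": "HET",
            f"S03:{panel.rearrangements[0].mutation_id}": "HET",
        }
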