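import math

import numpy as np
import pytest

from xsanno.fixtures import plant_paralog
from xsanno.localalign import (
    LocalAlignmentHit,
    PidPlThresholds,
    choose_thresholds,
    collect_evidence,
    compute_pid,
    compute_pl,
    inter_species_filter,
    intra_species_filter,
    la_filter,
    local_align,
)
from xsanno.model import GenomicInterval, SequenceStore


def make_hit(matches, mismatches, q_gaps=(0, 0), t_gaps=(0, 0),
             q_start=0, q_end=None, t_len=None):
    q_end = q_end if q_end is not None else matches + mismatches
    t_len = t_len if t_len is not None else matches + mismatches
    return LocalAlignmentHit(
        matches=matches, mismatches=mismatches,
        q_gap_count=q_gaps[0], q_gap_bases=q_gaps[1],
        t_gap_count=t_gaps[0], t_gap_bases=t_gaps[1],
        q_start=q_start, q_end=q_end,
        target=GenomicInterval("chr1", 1000, 1000 + t_len),
        strand="+",
    )


def oracle_pid(matches, mismatches, q_gap_count, t_gap_count, q_ali, t_ali):
    """Plug-in milliBad arithmetic, written independently of the implementation."""
    size_dif = abs(q_ali - t_ali)
    milli_bad = 1000 * (
        mismatches + q_gap_count + t_gap_count + round(3 * math.log(1 + size_dif))
    ) / (matches + mismatches)
    return (1000 - milli_bad) / 1000


class TestPid:
    def test_simple_mismatches(self):
        hit = make_hit(97, 3)
        assert compute_pid(hit) == pytest.approx(0.970)

    def test_perfect(self):
        assert compute_pid(make_hit(150, 0)) == 1.0

    def test_gapped(self):
        # 95 matches, one query gap of 5: qAli=100, tAli=95
        hit = make_hit(95, 0, q_gaps=(1, 5), q_end=100, t_len=95)
        expected = oracle_pid(95, 0, 1, 0, 100, 95)
        assert compute_pid(hit) == pytest.approx(expected)
        assert compute_pid(hit) == pytest.approx(0.9368, abs=1e-3)

    def test_zero_aligned_undefined(self):
        with pytest.raises(ValueError):
            compute_pid(make_hit(0, 0, q_end=1, t_len=1))


class TestPl:
    def test_cases(self):
        assert compute_pl(make_hit(100, 0), 100) == 1.0
        assert compute_pl(make_hit(90, 0, q_start=10, q_end=100), 100) == 0.90
        with pytest.raises(ValueError):
            compute_pl(make_hit(10, 0), 0)


class TestLocalAlign:
    def test_exact_substring_found(self, toy_genome):
        query = toy_genome["chr1"][200:320]
        hits = local_align(query, toy_genome)
        assert any(
            h.matches == 120 and h.mismatches == 0
            and h.target == GenomicInterval("chr1", 200, 320)
            for h in hits
        )

    def test_planted_copy_yields_two_hits(self, toy_genome):
        query = toy_genome["chr1"][100, None] if False else toy_genome["chr1"][100:250]
        genome2, copy_iv = plant_paralog(toy_genome, query, identity=0.97, chrom="chr1", seed=4)
        hits = local_align(query, genome2)
        loci = {(h.target.start, h.target.end) for h in hits}
        assert (100, 250) in loci
        assert any(abs(s - copy_iv.start) < 5 for s, _ in loci if s >= copy_iv.start - 5)
        assert len(hits) >= 2

    def test_reverse_complement_hit(self, toy_genome):
        from xsanno.model import reverse_complement

        query = reverse_complement(toy_genome["chr1"][300:420])
        hits = local_align(query, toy_genome)
        assert any(
            h.strand == "-" and h.target == GenomicInterval("chr1", 300, 420)
            for h in hits
        )

    def test_random_query_absent(self, toy_genome):
        rng = np.random.default_rng(123)
        query = "".join("ACGT"[i] for i in rng.integers(0, 4, size=150))
        # exhaustive check that the query truly is absent
        assert query not in toy_genome["chr1"]
        hits = local_align(query, toy_genome, min_pid=0.9)
        assert all(compute_pl(h, 150) < 0.5 for h in hits)

    def test_short_query_empty(self, toy_genome):
        assert local_align("ACGTACGT", toy_genome, min_seed=20) == []

    def test_pid_pl_match_brute_force_on_fixture_hits(self, small_bundle):
        """PID/PL from hit fields equal an independent recomputation."""
        genome = small_bundle.genome_sp1
        for _key, iv in list(small_bundle.annotation.exon_items())[:20]:
            seq = genome.fetch(iv)
            for h in local_align(seq, genome):
                q_ali = h.q_end - h.q_start
                assert compute_pid(h) == pytest.approx(
                    oracle_pid(h.matches, h.mismatches, h.q_gap_count,
                               h.t_gap_count, q_ali, h.target.length)
                )
                assert compute_pl(h, len(seq)) == pytest.approx(q_ali / len(seq))


WGA_LOC = GenomicInterval("chr1", 1000, 1100)
THR = PidPlThresholds()


class TestInterFilter:
    def test_single_hit_at_wga_locus_kept(self):
        keep, reason = inter_species_filter([make_hit(99, 1)], 100, WGA_LOC, THR)
        assert keep and reason == "kept"

    def test_conserved_paralog_drops(self):
        other = make_hit(98, 2)
        other = LocalAlignmentHit(**{**other.__dict__, "target": GenomicInterval("chr1", 5000, 5100)})
        keep, reason = inter_species_filter([make_hit(99, 1), other], 100, WGA_LOC, THR)
        assert not keep and reason == "multiple_qualifying"

    def test_wrong_chromosome_location_mismatch(self):
        hit = make_hit(99, 1)
        hit = LocalAlignmentHit(**{**hit.__dict__, "target": GenomicInterval("chr9", 1000, 1100)})
        keep, reason = inter_species_filter([hit], 100, WGA_LOC, THR)
        assert not keep and reason == "location_mismatch"

    def test_no_qualifying(self):
        keep, reason = inter_species_filter([make_hit(80, 20)], 100, WGA_LOC, THR)
        assert not keep and reason == "none_qualifying"


class TestIntraFilter:
    def test_self_hit_only_kept(self):
        keep, _ = intra_species_filter([make_hit(100, 0)], 100, THR)
        assert keep

    def test_high_identity_duplicate_drops(self):
        keep, reason = intra_species_filter(
            [make_hit(100, 0), make_hit(99, 1)], 100, THR
        )
        assert not keep and reason == "intra_paralog"

    def test_low_identity_duplicate_kept(self):
        # 90% identity is below the intra PID threshold of 0.97
        keep, _ = intra_species_filter([make_hit(100, 0), make_hit(90, 10)], 100, THR)
        assert keep


class TestStageProperties:
    def test_output_subset_and_length_non_increasing(self, small_bundle):
        from xsanno.liftover import reciprocal_convert

        ann2, ann1, _ = reciprocal_convert(
            small_bundle.annotation, small_bundle.chain_fwd,
            small_bundle.chain_back, 0.913,
        )
        out1, out2, reasons = la_filter(
            ann1, ann2, small_bundle.genome_sp1, small_bundle.genome_sp2
        )
        assert set(out1.exon_map()) <= set(ann1.exon_map())
        assert set(out1.exon_map()) == set(out2.exon_map())
        lengths_in = ann1.exonic_lengths()
        for gid, L in out1.exonic_lengths().items():
            assert L <= lengths_in[gid]

    def test_threshold_monotonicity(self, small_bundle):
        """Raising thresholds never increases retained exons."""
        from xsanno.liftover import reciprocal_convert

        ann2, ann1, _ = reciprocal_convert(
            small_bundle.annotation, small_bundle.chain_fwd,
            small_bundle.chain_back, 0.913,
        )
        evidence = collect_evidence(
            ann1, ann2, small_bundle.genome_sp1, small_bundle.genome_sp2
        )
        kept = []
        for pid in (0.90, 0.95, 0.99):
            thr = PidPlThresholds(inter_pid=pid, inter_pl=pid)
            o1, _, _ = la_filter(
                ann1, ann2, small_bundle.genome_sp1, small_bundle.genome_sp2,
                thr, evidence=evidence,
            )
            kept.append(o1.counts()[2])
        assert kept == sorted(kept, reverse=True)

    def test_planted_high_identity_paralog_genes_removed(self):
        """Copies comfortably above the intra threshold are always caught."""
        from xsanno.fixtures import FixtureConfig, generate_pair
        from xsanno.liftover import reciprocal_convert

        b = generate_pair(
            FixtureConfig(n_genes=12, n_paralog_sp1=2, n_paralog_sp2=2,
                          paralog_identity=(0.995, 1.0), seed=31)
        )
        ann2, ann1, _ = reciprocal_convert(b.annotation, b.chain_fwd, b.chain_back, 0.913)
        out1, _, _ = la_filter(ann1, ann2, b.genome_sp1, b.genome_sp2)
        for cls in ("paralog_sp1", "paralog_sp2"):
            for gid in b.truth.genes_of_class(cls):
                assert gid not in out1.gene_ids()


class TestChooseThresholds:
    def test_tie_returns_strictest(self, identity_bundle):
        from xsanno.liftover import reciprocal_convert

        ann2, ann1, _ = reciprocal_convert(
            identity_bundle.annotation, identity_bundle.chain_fwd,
            identity_bundle.chain_back, 0.98,
        )
        evidence = collect_evidence(
            ann1, ann2, identity_bundle.genome_sp1, identity_bundle.genome_sp2
        )
        thr = choose_thresholds(evidence, inter_grid=(0.9, 0.95), intra_grid=(0.9, 0.95))
        assert (thr.inter_pid, thr.inter_pl) == (0.95, 0.95)
        assert (thr.intra_pid, thr.intra_pl) == (0.95, 0.95)

    def test_maximizes_retention(self, small_bundle):
        from xsanno.liftover import reciprocal_convert

        ann2, ann1, _ = reciprocal_convert(
            small_bundle.annotation, small_bundle.chain_fwd,
            small_bundle.chain_back, 0.913,
        )
        evidence = collect_evidence(
            ann1, ann2, small_bundle.genome_sp1, small_bundle.genome_sp2
        )
        thr = choose_thresholds(evidence, inter_grid=(0.90, 0.99), intra_grid=(0.97,))
        # count retained at each inter grid point with the filter itself
        def retained(pid):
            t = PidPlThresholds(inter_pid=pid, inter_pl=pid)
            return sum(
                1 for ev in evidence.values()
                if inter_species_filter(ev.inter_hits, ev.query_len_sp1,
                                        ev.wga_location, t)[0]
            )
        best = max((0.90, 0.99), key=lambda p: (retained(p), p))
        assert (thr.inter_pid, thr.inter_pl)[0] == best

    def test_empty_evidence_raises(self):
        with pytest.raises(ValueError):
            choose_thresholds({})
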