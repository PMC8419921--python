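"""Back-splice caller: candidate rules, junction refinement, filters."""

import itertools
import random

import numpy as np
import pytest

from circnet import circcall as cc
from circnet import synthdata as s
from circnet.splice import SpliceSiteModel
from circnet.utils import random_dna, revcomp


def seg(chrom="chr1", start=0, end=100, strand="+", qs=0, qe=75):
    return cc.SplitSegment(chrom=chrom, start=start, end=end, strand=strand,
                           query_start=qs, query_end=qe)


class TestCandidateRules:
    def test_reversed_pair_yields_candidate(self):
        aln = cc.SplitAlignment("r1", [seg(start=5000, end=5075, qs=0, qe=75),
                                       seg(start=100, end=175, qs=75, qe=150)])
        cands, rej, _ = cc.find_chimeric_candidates([aln])
        assert len(cands) == 1 and not rej
        c = cands[0]
        assert (c.donor_break, c.acceptor_break) == (5075, 100)

    @pytest.mark.parametrize("mutate,reason", [
        (dict(chrom="chr2"), "different_chromosome"),
        (dict(strand="-"), "opposite_strand"),
        (dict(start=9000, end=9075), "same_order"),
        (dict(start=2_000_000, end=2_000_075), "separation_gt_max"),
    ])
    def test_single_rule_violations_tallied(self, mutate, reason):
        first = seg(start=5000, end=5075, qs=0, qe=75)
        second = seg(start=100, end=175, qs=75, qe=150)
        if "start" in mutate and mutate["start"] == 2_000_000:
            first = seg(start=mutate["start"], end=mutate["end"],
                        qs=0, qe=75)
        else:
            second = seg(**{**dict(start=100, end=175, qs=75, qe=150),
                            **mutate})
        aln = cc.SplitAlignment("r1", [first, second])
        cands, rej, tallies = cc.find_chimeric_candidates([aln])
        assert not cands
        assert rej[0]["reason"] == reason
        assert tallies[reason] == 1

    def test_minus_strand_head_to_tail(self):
        # on the minus strand the earlier read part maps upstream
        aln = cc.SplitAlignment("r1", [
            seg(start=100, end=175, strand="-", qs=0, qe=75),
            seg(start=5000, end=5075, strand="-", qs=75, qe=150)])
        cands, _, _ = cc.find_chimeric_candidates([aln])
        assert len(cands) == 1
        assert (cands[0].donor_break, cands[0].acceptor_break) == (100, 5075)

    def test_malformed_segment_skipped_and_logged(self):
        aln = cc.SplitAlignment("bad", [seg(start=500, end=400)])
        cands, rej, tallies = cc.find_chimeric_candidates([aln])
        assert not cands
        assert rej == [{"stage": "candidate", "key": "bad",
                        "reason": "malformed_segment"}]

    def test_reads_merge_within_tolerance(self):
        alns = [cc.SplitAlignment(f"r{i}", [
            seg(start=5000 + i, end=5075 + i, qs=0, qe=75),
            seg(start=100 + i, end=175 + i, qs=75, qe=150)])
            for i in range(3)]
        cands, _, _ = cc.find_chimeric_candidates(alns, merge_tol=5)
        assert len(cands) == 1
        assert cands[0].supporting_read_ids == {"r0", "r1", "r2"}


def _random_alignments(rng, n_reads):
    alns = []
    for i in range(n_reads):
        n_seg = int(rng.integers(1, 4))
        q = sorted(rng.choice(np.arange(10, 140), size=2 * n_seg,
                              replace=False))
        segs = []
        for j in range(n_seg):
            start = int(rng.integers(0, 2_100_000))
            segs.append(cc.SplitSegment(
                chrom=f"chr{int(rng.integers(1, 3))}", start=start,
                end=start + int(rng.integers(20, 120)),
                strand="+-"[int(rng.integers(2))],
                query_start=int(q[2 * j]), query_end=int(q[2 * j + 1])))
        alns.append(cc.SplitAlignment(f"r{i}", segs))
    return alns


def _brute_force(alignments, max_sep=1_000_000):
    """Independent all-segment-pairs oracle for candidate detection."""
    juncs = {}
    for aln in alignments:
        segs = sorted(aln.segments, key=lambda x: x.query_start)
        for a, b in itertools.combinations(segs, 2):
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            if a.strand == "+" and a.start > b.start:
                donor, acceptor = a.end, b.start
                span = donor - acceptor
            elif a.strand == "-" and a.end < b.end:
                donor, acceptor = a.start, b.end
                span = acceptor - donor
            else:
                continue
            if 0 < span <= max_sep:
                juncs.setdefault((a.chrom, a.strand, donor, acceptor),
                                 set()).add(aln.read_id)
    return juncs


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(5))
    def test_candidates_equal_brute_force(self, trial):
        rng = np.random.default_rng(100 + trial)
        alns = _random_alignments(rng, 400)
        cands, _, _ = cc.find_chimeric_candidates(alns, merge_tol=0)
        got = {(c.chrom, c.strand, c.donor_break, c.acceptor_break):
               c.supporting_read_ids for c in cands}
        assert got == _brute_force(alns)

    def test_permutation_invariance(self, scene):
        alns = cc.alignments_from_sim(scene.reads)
        shuffled = list(alns)
        random.Random(3).shuffle(shuffled)
        c1, _, _ = cc.find_chimeric_candidates(alns)
        c2, _, _ = cc.find_chimeric_candidates(shuffled)
        key = lambda c: (c.chrom, c.strand, c.donor_break, c.acceptor_break)
        assert sorted(map(key, c1)) == sorted(map(key, c2))
        calls1, _ = cc.call_circrnas(c1, scene.genome)
        calls2, _ = cc.call_circrnas(c2, scene.genome)
        assert [(c.chrom, c.start, c.end, c.strand, c.junction_read_count,
                 c.splicing_score) for c in calls1] == \
               [(c.chrom, c.start, c.end, c.strand, c.junction_read_count,
                 c.splicing_score) for c in calls2]


class TestJunctionSelection:
    def test_planted_consensus_recovered_exactly(self, scene, splice_model):
        circ = scene.truth.callable_circs()[0]
        cand = cc.BackspliceCandidate(
            chrom=circ.chrom, strand=circ.strand,
            donor_break=circ.donor_pos + 3, acceptor_break=circ.acceptor_pos - 2,
            supporting_read_ids={"x"})
        d, a, score = cc.select_junction(cand, scene.genome, splice_model,
                                         search_radius=5)
        assert (d, a) == (circ.donor_pos, circ.acceptor_pos)
        assert score == pytest.approx(20.0, abs=1e-6)

    def test_tie_break_prefers_breakpoint_proximity_then_coordinate(
            self, splice_model):
        """Two identical consensus donor/acceptor pairs: enumerate all scored
        pairs and check the documented ordering picks the winner."""
        don = splice_model.consensus_donor()
        acc = splice_model.consensus_acceptor()
        rng = np.random.default_rng(0)
        # exact duplicate consensus acceptors at 100/130 and donors at 520/550
        seq = list(random_dna(rng, 800))
        for pos in (100, 130):
            seq[pos - 20:pos + 3] = acc
        for pos in (520, 550):
            seq[pos - 3:pos + 6] = don
        genome = s.GenomeModel(chromosomes={"t": "".join(seq)}, genes=[])
        cand = cc.BackspliceCandidate(chrom="t", strand="+",
                                      donor_break=548, acceptor_break=128,
                                      supporting_read_ids={"x"})
        d, a, score = cc.select_junction(cand, genome, splice_model,
                                         search_radius=30)
        # oracle: enumerate every pair, apply (score, -dist, -a, -d) ordering
        best = None
        for dd in range(518, 579):
            for aa in range(98, 159):
                tot = splice_model.donor_score(genome.chromosomes["t"], dd, "+") \
                    + splice_model.acceptor_score(genome.chromosomes["t"], aa, "+")
                key = (tot, -(abs(dd - 548) + abs(aa - 128)), -aa, -dd)
                if best is None or key > best[0]:
                    best = (key, dd, aa)
        assert (d, a) == (best[1], best[2])
        # all four consensus pairs tie on score; proximity decides
        assert (d, a) == (550, 130)

    def test_random_sequence_scores_below_threshold(self, splice_model):
        """Null scale: best pair in 1000 random windows stays below 10."""
        rng = np.random.default_rng(42)
        scores = []
        for _ in range(1000):
            genome = s.GenomeModel(
                chromosomes={"r": random_dna(rng, 120)}, genes=[])
            cand = cc.BackspliceCandidate(chrom="r", strand="+",
                                          donor_break=90, acceptor_break=30,
                                          supporting_read_ids={"x"})
            _, _, score = cc.select_junction(cand, genome, splice_model,
                                             search_radius=5)
            scores.append(score)
        assert max(scores) < 10.0

    def test_edge_truncation_warns_and_survives(self, splice_model):
        rng = np.random.default_rng(1)
        genome = s.GenomeModel(chromosomes={"t": random_dna(rng, 60)},
                               genes=[])
        cand = cc.BackspliceCandidate(chrom="t", strand="+", donor_break=55,
                                      acceptor_break=5,
                                      supporting_read_ids={"x"})
        d, a, score = cc.select_junction(cand, genome, splice_model,
                                         search_radius=10)
        assert score < 10.0  # unscorable/truncated region cannot pass


class TestCallFilters:
    def test_boundary_semantics(self):
        assert cc.passes_filters(2, 10.0)
        assert not cc.passes_filters(1, 20.0)
        assert not cc.passes_filters(10, 9.99)
        assert cc.passes_filters(3, 10.000001)

    def test_filter_soundness_and_relaxation_superset(self, scene):
        alns = cc.alignments_from_sim(scene.reads)
        cands, _, _ = cc.find_chimeric_candidates(alns)
        strict, _ = cc.call_circrnas(cands, scene.genome)
        relaxed, _ = cc.call_circrnas(cands, scene.genome, min_reads=1,
                                      min_score=-1e9)
        assert all(c.junction_read_count >= 2 and c.splicing_score >= 10
                   for c in strict)
        strict_keys = {(c.chrom, c.start, c.end, c.strand) for c in strict}
        relaxed_keys = {(c.chrom, c.start, c.end, c.strand) for c in relaxed}
        assert strict_keys <= relaxed_keys
        assert len(relaxed) > len(strict)

    def test_strand_symmetry(self, scene):
        """Reverse-complementing the genome and flipping strands mirrors all
        calls with identical scores."""
        alns = cc.alignments_from_sim(scene.reads)
        cands, _, _ = cc.find_chimeric_candidates(alns)
        calls, _ = cc.call_circrnas(cands, scene.genome)

        mirrored_chroms = {n: revcomp(seq)
                           for n, seq in scene.genome.chromosomes.items()}
        mirror = s.GenomeModel(chromosomes=mirrored_chroms, genes=[])
        lengths = {n: len(seq) for n, seq in mirrored_chroms.items()}
        flipped = []
        for aln in alns:
            segs = [cc.SplitSegment(
                chrom=g.chrom, start=lengths[g.chrom] - g.end,
                end=lengths[g.chrom] - g.start,
                strand="-" if g.strand == "+" else "+",
                query_start=g.query_start, query_end=g.query_end)
                for g in aln.segments]
            flipped.append(cc.SplitAlignment(aln.read_id, segs))
        cands_m, _, _ = cc.find_chimeric_candidates(flipped)
        calls_m, _ = cc.call_circrnas(cands_m, mirror)
        orig = sorted((c.chrom, c.start, c.end, c.strand,
                       round(c.splicing_score, 9)) for c in calls)
        mirrored = sorted((c.chrom, lengths[c.chrom] - c.end,
                           lengths[c.chrom] - c.start,
                           "-" if c.strand == "+" else "+",
                           round(c.splicing_score, 9)) for c in calls_m)
        assert orig == mirrored


class TestSamRoundTrip:
    def test_sam_parse_recovers_segments(self, small_scene, tmp_path):
        sam = tmp_path / "reads.sam"
        s.write_sam(small_scene.genome, small_scene.reads, sam)
        parsed = {a.read_id: a for a in cc.read_sam(sam)}
        for read in small_scene.reads:
            got = parsed[read.qname]
            want = sorted((c, st, e, strand, qs, qe)
                          for c, st, e, strand, qs, qe in read.segments)
            have = sorted((g.chrom, g.start, g.end, g.strand,
                           g.query_start, g.query_end)
                          for g in got.segments)
            assert have == want, read.qname

    def test_bed_output_columns(self, small_scene, tmp_path):
        alns = cc.alignments_from_sim(small_scene.reads)
        cands, _, _ = cc.find_chimeric_candidates(alns)
        calls, _ = cc.call_circrnas(cands, small_scene.genome)
        bed = tmp_path / "calls.bed"
        cc.write_bed(calls, bed)
        lines = [l.split("\t") for l in bed.read_text().splitlines()]
        assert all(len(l) == 8 for l in lines)
        assert [l[3] for l in lines] == [c.circ_id for c in calls]
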