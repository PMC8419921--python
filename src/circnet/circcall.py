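"""Back-splice circRNA identification from chimeric split alignments.

A read supports a head-to-tail (back-splice) junction when two of its
partial alignments map (i) to the same chromosome no more than 1 Mb
apart, (ii) on the same strand, (iii) with genomic order reversed
relative to read order. Supporting reads are aggregated into candidates,
the exact junction is refined by picking the donor/acceptor pair with the
highest combined splice-strength score near the segment breakpoints, and
a circRNA is reported when the junction is supported by at least two
reads with a splicing score of at least 10.

"Reverse order" is strand-aware: on the plus strand the earlier read part
maps downstream of the later part; on the minus strand the relation is
mirrored, because alignment coordinates are reported on the forward
genome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .splice import SpliceSiteModel

MAX_SEPARATION = 1_000_000


@dataclass(frozen=True)
class SplitSegment:
    chrom: str
    start: int
    end: int
    strand: str
    query_start: int
    query_end: int


@dataclass
class SplitAlignment:
    """One read's partial alignments, sorted by position within the read."""

    read_id: str
    segments: list

    def __post_init__(self):
        self.segments = sorted(self.segments, key=lambda s: s.query_start)


@dataclass
class BackspliceCandidate:
    chrom: str
    strand: str
    donor_break: int        # breakpoint implied by the donor-side segments
    acceptor_break: int
    supporting_read_ids: set = field(default_factory=set)


@dataclass
class CircCall:
    circ_id: str
    chrom: str
    start: int              # acceptor side for '+', donor side for '-'
    end: int
    strand: str
    junction_read_count: int
    splicing_score: float
    donor_pos: int = 0
    acceptor_pos: int = 0


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

def read_sam(path) -> list:
    """Parse SAM/BAM into SplitAlignments (primary + supplementary records).

    Query coordinates are reported in original read orientation; soft and
    hard clips delimit the aligned part of the read.
    """
    import pysam

    by_read: dict = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            length = rec.infer_read_length()
            qs, qe = rec.query_alignment_start, rec.query_alignment_end
            # soft-clip offsets are relative to the stored (possibly
            # reverse-complemented) sequence; flip back to read orientation
            if rec.cigartuples and rec.cigartuples[0][0] == 5:
                qs += rec.cigartuples[0][1]
                qe += rec.cigartuples[0][1]
            if rec.is_reverse:
                qs, qe = length - qe, length - qs
            seg = SplitSegment(chrom=rec.reference_name,
                               start=rec.reference_start,
                               end=rec.reference_end,
                               strand="-" if rec.is_reverse else "+",
                               query_start=qs, query_end=qe)
            by_read.setdefault(rec.query_name, []).append(seg)
    return [SplitAlignment(read_id=rid, segments=segs)
            for rid, segs in by_read.items()]


def alignments_from_sim(sim_reads) -> list:
    """Convert synthetic SimRead records to SplitAlignments."""
    out = []
    for read in sim_reads:
        segs = [SplitSegment(chrom=c, start=s, end=e, strand=st,
                             query_start=qs, query_end=qe)
                for c, s, e, st, qs, qe in read.segments]
        out.append(SplitAlignment(read_id=read.qname, segments=segs))
    return out


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------

def classify_pair(seg_a: SplitSegment, seg_b: SplitSegment,
                  max_sep: int = MAX_SEPARATION):
    """Apply the three candidate rules to a query-ordered segment pair.

    Returns ``(junction, None)`` with ``junction = (chrom, strand,
    donor_break, acceptor_break)`` when the pair supports a head-to-tail
    junction, else ``(None, reason)`` naming the first violated rule.
    """
    if seg_a.chrom != seg_b.chrom:
        return None, "different_chromosome"
    if seg_a.strand != seg_b.strand:
        return None, "opposite_strand"
    if seg_a.strand == "+":
        if seg_a.start <= seg_b.start:
            return None, "same_order"
        donor, acceptor = seg_a.end, seg_b.start
        span = donor - acceptor
    else:
        # mirror image of the plus-strand rule: compare segment ends
        if seg_a.end >= seg_b.end:
            return None, "same_order"
        donor, acceptor = seg_a.start, seg_b.end
        span = acceptor - donor
    if span > max_sep:
        return None, "separation_gt_max"
    if span <= 0:
        return None, "same_order"
    return (seg_a.chrom, seg_a.strand, donor, acceptor), None


def find_chimeric_candidates(alignments, max_sep: int = MAX_SEPARATION,
                             merge_tol: int = 5):
    """Aggregate head-to-tail junction evidence into candidates.

    A read contributes when some query-ordered segment pair passes all
    three rules; junctions whose implied breakpoints differ by at most
    ``merge_tol`` nt are merged. Returns ``(candidates, rejections,
    tallies)`` where rejections lists per-read records for multi-segment
    reads that supported no junction.
    """
    junctions = []   # (chrom, strand, donor, acceptor, read_id)
    rejections = []
    tallies: Counter = Counter()
    for aln in alignments:
        bad = [s for s in aln.segments if s.end <= s.start
               or s.query_end <= s.query_start]
        if bad:
            rejections.append({"stage": "candidate", "key": aln.read_id,
                               "reason": "malformed_segment"})
            tallies["malformed_segment"] += 1
            continue
        if len(aln.segments) < 2:
            tallies["single_segment"] += 1
            continue
        hits, best_reason, best_depth = [], None, -1
        rule_order = ["different_chromosome", "opposite_strand",
                      "same_order", "separation_gt_max"]
        for i in range(len(aln.segments)):
            for j in range(i + 1, len(aln.segments)):
                junction, reason = classify_pair(aln.segments[i],
                                                 aln.segments[j], max_sep)
                if junction is not None:
                    hits.append(junction)
                else:
                    depth = rule_order.index(reason)
                    if depth > best_depth:
                        best_depth, best_reason = depth, reason
        if hits:
            for chrom, strand, donor, acceptor in hits:
                junctions.append((chrom, strand, donor, acceptor, aln.read_id))
        else:
            rejections.append({"stage": "candidate", "key": aln.read_id,
                               "reason": best_reason})
            tallies[best_reason] += 1

    junctions.sort()
    clusters: dict = {}
    order: list = []
    for chrom, strand, donor, acceptor, read_id in junctions:
        key = None
        for existing in order:
            echrom, estrand, edonor, eacceptor = existing
            if (echrom == chrom and estrand == strand
                    and abs(edonor - donor) <= merge_tol
                    and abs(eacceptor - acceptor) <= merge_tol):
                key = existing
                break
        if key is None:
            key = (chrom, strand, donor, acceptor)
            order.append(key)
            clusters[key] = BackspliceCandidate(
                chrom=chrom, strand=strand, donor_break=donor,
                acceptor_break=acceptor)
        clusters[key].supporting_read_ids.add(read_id)
    candidates = [clusters[k] for k in order]
    return candidates, rejections, tallies


# ---------------------------------------------------------------------------
# junction refinement and calling
# ---------------------------------------------------------------------------

def select_junction(candidate: BackspliceCandidate, genome,
                    model: SpliceSiteModel, search_radius: int = 10):
    """Pick the (donor, acceptor) pair with the highest splicing score.

    Scans positions within ``search_radius`` nt of the segment
    breakpoints, strand-aware. Ties go to the pair closest to the
    breakpoints, then to the smaller genomic coordinates. Returns
    ``(donor_pos, acceptor_pos, score)``; score is ``-inf`` when no
    position is scorable (window off the chromosome end).
    """
    seq = genome.chromosomes[candidate.chrom]
    strand = candidate.strand
    offs = range(-search_radius, search_radius + 1)
    donor_scores = {candidate.donor_break + o:
                    model.donor_score(seq, candidate.donor_break + o, strand)
                    for o in offs}
    acceptor_scores = {candidate.acceptor_break + o:
                       model.acceptor_score(seq, candidate.acceptor_break + o,
                                            strand)
                       for o in offs}
    best = None
    for d, ds in donor_scores.items():
        for a, as_ in acceptor_scores.items():
            start, end = (a, d) if strand == "+" else (d, a)
            if not 0 < end - start:
                continue
            total = ds + as_
            dist = abs(d - candidate.donor_break) + abs(a - candidate.acceptor_break)
            key = (total, -dist, -a, -d)
            if best is None or key > best[0]:
                best = (key, d, a, total)
    if best is None:
        return candidate.donor_break, candidate.acceptor_break, float("-inf")
    return best[1], best[2], best[3]


def passes_filters(junction_read_count: int, splicing_score: float,
                   min_reads: int = 2, min_score: float = 10.0) -> bool:
    """Inclusive thresholds: exactly 2 reads and score exactly 10.0 pass."""
    return junction_read_count >= min_reads and splicing_score >= min_score


def call_circrnas(candidates, genome, model: SpliceSiteModel | None = None,
                  min_reads: int = 2, min_score: float = 10.0,
                  max_sep: int = MAX_SEPARATION, search_radius: int = 10):
    """Score candidates and emit filtered, coordinate-sorted circRNA calls.

    Returns ``(calls, rejections)``; rejections record candidates failing
    the read-count or score filter.
    """
    model = model or SpliceSiteModel.load()
    calls, rejections = [], []
    ordered = sorted(candidates, key=lambda c: (c.chrom, c.strand,
                                                c.acceptor_break, c.donor_break))
    for cand in ordered:
        donor, acceptor, score = select_junction(cand, genome, model,
                                                 search_radius)
        start, end = (acceptor, donor) if cand.strand == "+" else (donor, acceptor)
        n_reads = len(cand.supporting_read_ids)
        key = f"{cand.chrom}:{start}-{end}:{cand.strand}"
        if not 0 < end - start <= max_sep:
            rejections.append({"stage": "filter", "key": key,
                               "reason": "separation_gt_max"})
            continue
        if n_reads < min_reads:
            rejections.append({"stage": "filter", "key": key,
                               "reason": "too_few_reads"})
            continue
        if not score >= min_score:
            rejections.append({"stage": "filter", "key": key,
                               "reason": "score_below_min"})
            continue
        calls.append(CircCall(
            circ_id=f"bsj_{cand.chrom}_{start}_{end}_{cand.strand}",
            chrom=cand.chrom, start=start, end=end, strand=cand.strand,
            junction_read_count=n_reads, splicing_score=score,
            donor_pos=donor, acceptor_pos=acceptor))
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand))
    return calls, rejections


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_bed(calls, path, header_comments=None) -> None:
    """BED6+2: chrom, start, end, id, junction reads, strand, score, reads."""
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.circ_id}\t"
                     f"{c.junction_read_count}\t{c.strand}\t"
                     f"{c.splicing_score:.4f}\t{c.junction_read_count}\n")


def write_rejections(rejections, path) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tkey\treason\n")
        for r in rejections:
            fh.write(f"{r['stage']}\t{r['key']}\t{r['reason']}\n")
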