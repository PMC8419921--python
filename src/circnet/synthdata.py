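"""Synthetic data with planted ground truth.

This module is the statistical stand-in for an undeposited two-group
(pre/post interferon-α) PBMC RNA-seq cohort. It generates:

* a toy multi-chromosome genome with annotated multi-exon genes whose
  internal exon boundaries carry canonical GT..AG splice motifs;
* planted back-splice junctions (circRNAs) plus decoys, each decoy
  violating exactly one of the caller's candidate/filter rules;
* 150 bp split-read evidence for every planted junction, serialized as
  SAM with primary + supplementary records sharing a QNAME;
* two-group expression matrices per RNA class (mRNA, lncRNA, miRNA,
  circRNA) with planted fold changes and planted ceRNA triplets whose
  ceRNA/mRNA members co-vary through a shared latent factor;
* miRNA seed-match target tables and small GMT annotation sets.

Every output is deterministic for a fixed seed, and a truth table records
what was planted so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import splice as _splice
from .utils import BASES, comp, derive_seed, random_dna, revcomp

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA", "circRNA")

DECOY_REASONS = (
    "different_chromosome",
    "separation_gt_max",
    "opposite_strand",
    "same_order",
    "too_few_reads",
    "score_below_min",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: list  # sorted, non-overlapping [(start, end), ...] 0-based half-open
    rna_class: str

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GenomeModel:
    """Chromosome sequences plus gene annotation."""

    chromosomes: dict          # name -> sequence (A/C/G/T)
    genes: list                # list[Gene]

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def genes_of_class(self, rna_class: str) -> list:
        return [g for g in self.genes if g.rna_class == rna_class]

    # -- sequence access ----------------------------------------------------
    def transcript_seq(self, gene: Gene) -> str:
        seq = self.chromosomes[gene.chrom]
        parts = [seq[s:e] for s, e in gene.exons]
        if gene.strand == "+":
            return "".join(parts)
        return revcomp("".join(parts))

    def transcript_to_genome(self, gene: Gene, t_idx: int) -> int:
        """Map a transcript coordinate to its genomic position."""
        exons = gene.exons if gene.strand == "+" else list(reversed(gene.exons))
        off = t_idx
        for s, e in exons:
            if off < e - s:
                return s + off if gene.strand == "+" else e - 1 - off
            off -= e - s
        raise IndexError(t_idx)

    def interval_seq(self, chrom: str, start: int, end: int, strand: str) -> str:
        seq = self.chromosomes[chrom][start:end]
        return seq if strand == "+" else revcomp(seq)

    def edit(self, chrom: str, pos: int, base: str) -> None:
        s = self.chromosomes[chrom]
        self.chromosomes[chrom] = s[:pos] + base + s[pos + 1:]

    def splice_in(self, chrom: str, pos: int, insert: str) -> None:
        s = self.chromosomes[chrom]
        self.chromosomes[chrom] = s[:pos] + insert + s[pos + len(insert):]

    # -- I/O -----------------------------------------------------------------
    def write_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name in self.chromosomes:
                fh.write(f">{name}\n")
                seq = self.chromosomes[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def write_annotation(self, path) -> None:
        """GTF-like exon table; 1-based inclusive start/end as in GTF."""
        with open(path, "w") as fh:
            fh.write("chrom\tsource\tfeature\tstart\tend\tstrand\tgene_id\trna_class\n")
            for g in self.genes:
                for s, e in g.exons:
                    fh.write(f"{g.chrom}\tcircnet\texon\t{s + 1}\t{e}\t"
                             f"{g.strand}\t{g.gene_id}\t{g.rna_class}\n")

    @classmethod
    def from_files(cls, fasta_path, annotation_path) -> "GenomeModel":
        from Bio import SeqIO
        chroms = {rec.id: str(rec.seq).upper()
                  for rec in SeqIO.parse(str(fasta_path), "fasta")}
        ann = pd.read_csv(annotation_path, sep="\t")
        genes = []
        for gid, grp in ann.groupby("gene_id", sort=False):
            exons = sorted((int(r.start) - 1, int(r.end)) for r in grp.itertuples())
            genes.append(Gene(gene_id=gid, chrom=grp.iloc[0]["chrom"],
                              strand=grp.iloc[0]["strand"], exons=exons,
                              rna_class=grp.iloc[0]["rna_class"]))
        return cls(chromosomes=chroms, genes=genes)

    # -- invariants ----------------------------------------------------------
    def validate(self, model: "_splice.SpliceSiteModel | None" = None) -> None:
        for name, seq in self.chromosomes.items():
            if set(seq) - set(BASES):
                raise ValueError(f"chromosome {name} contains non-ACGT symbols")
        for g in self.genes:
            clen = len(self.chromosomes[g.chrom])
            prev_end = -1
            for s, e in g.exons:
                if not (0 <= s < e <= clen):
                    raise ValueError(f"{g.gene_id} exon ({s},{e}) outside {g.chrom}")
                if s < prev_end:
                    raise ValueError(f"{g.gene_id} exons overlap or unsorted")
                prev_end = e
            for d, a in _internal_boundaries(g):
                seq = self.chromosomes[g.chrom]
                if d is not None:
                    dinuc = (seq[d:d + 2] if g.strand == "+"
                             else revcomp(seq[d - 2:d]))
                    if dinuc != "GT":
                        raise ValueError(f"{g.gene_id}: donor at {d} lacks GT")
                if a is not None:
                    dinuc = (seq[a - 2:a] if g.strand == "+"
                             else revcomp(seq[a:a + 2]))
                    if dinuc != "AG":
                        raise ValueError(f"{g.gene_id}: acceptor at {a} lacks AG")


def _internal_boundaries(gene: Gene):
    """Yield (donor_pos, acceptor_pos) pairs for each internal exon boundary.

    donor_pos is the exon boundary where the downstream intron starts,
    acceptor_pos the boundary where an intron ends, both in genomic
    coordinates on the annotated strand.
    """
    k = len(gene.exons)
    out = []
    for i in range(k - 1):
        s_next = gene.exons[i + 1][0]
        e_this = gene.exons[i][1]
        if gene.strand == "+":
            out.append((e_this, s_next))      # donor at exon end, acceptor at next start
        else:
            out.append((s_next, e_this))      # donor at next exon's genomic start
    return out


@dataclass
class PlantedCirc:
    """A planted back-splice junction (or a decoy read pattern)."""

    circ_id: str
    chrom: str
    start: int                 # lower genomic coordinate of the junction span
    end: int                   # upper genomic coordinate
    strand: str
    donor_pos: int
    acceptor_pos: int
    depth: int                 # junction-spanning reads emitted
    callable: bool
    reason: str | None = None  # decoy rejection reason, None for true plantings
    gene_id: str | None = None
    overhangs: list = field(default_factory=list)   # per read (left, right) nt
    sub_overhang: list = field(default_factory=list)  # per read bool
    # read anchors: (chrom, pos, strand, side) for the donor-side and
    # acceptor-side read parts; decoys override the canonical geometry
    anchor1: tuple | None = None
    anchor2: tuple | None = None

    def __post_init__(self):
        if self.anchor1 is None:
            if self.strand == "+":
                self.anchor1 = (self.chrom, self.donor_pos, "+", "end")
                self.anchor2 = (self.chrom, self.acceptor_pos, "+", "start")
            else:
                self.anchor1 = (self.chrom, self.donor_pos, "-", "start")
                self.anchor2 = (self.chrom, self.acceptor_pos, "-", "end")


@dataclass
class TruthTable:
    """Everything that was planted, for exact downstream scoring."""

    circs: list = field(default_factory=list)       # list[PlantedCirc]
    de: pd.DataFrame = field(default_factory=pd.DataFrame)
    triplets: pd.DataFrame = field(default_factory=pd.DataFrame)
    sites: pd.DataFrame = field(default_factory=pd.DataFrame)
    reads: pd.DataFrame = field(default_factory=pd.DataFrame)
    mirna_seqs: dict = field(default_factory=dict)

    def callable_circs(self) -> list:
        return [c for c in self.circs if c.callable]

    def decoys(self) -> list:
        return [c for c in self.circs if not c.callable]

    @classmethod
    def null(cls, n_features: dict) -> "TruthTable":
        """A truth table of pure null features (no planted DE, no triplets)."""
        rows = [{"feature_id": f"{cl}_{i:04d}", "rna_class": cl, "true_log2fc": 0.0}
                for cl, n in n_features.items() for i in range(n)]
        return cls(de=pd.DataFrame(rows))

    def write(self, outdir) -> None:
        import pathlib
        outdir = pathlib.Path(outdir)
        circ_rows = [{k: v for k, v in dataclasses.asdict(c).items()
                      if k not in ("overhangs", "sub_overhang", "anchor1", "anchor2")}
                     for c in self.circs]
        pd.DataFrame(circ_rows).to_csv(outdir / "truth_circs.tsv", sep="\t", index=False)
        for name in ("de", "triplets", "sites", "reads"):
            df = getattr(self, name)
            if len(df):
                df.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """Study-condition defaults for the synthetic cohort.

    The cohort mirrors a 9-patients-per-arm paired design (pre-IFN group A,
    post-IFN group B) profiled on 150 bp paired-end reads; genome and
    feature counts are a desk-scale reduction of a transcriptome.
    """

    # genome
    n_chroms: int = 2
    chrom_len: int = 100_000
    include_long_chrom: bool = True        # hosts the >1 Mb-separation decoy
    long_chrom_len: int = 1_050_000
    n_mrna: int = 40
    n_lncrna: int = 14
    n_mirna: int = 16
    exon_count_range: tuple = (3, 5)
    exon_len_range: tuple = (120, 250)
    intron_len_range: tuple = (60, 120)
    gene_gap_range: tuple = (200, 400)
    mirna_len: int = 22
    margin: int = 500
    # circRNAs & reads
    n_true_circs: int = 50
    n_decoys: int = 20
    n_circ_free_mrna: int = 12     # mRNA genes kept free of circRNAs (triplet hosts)
    depth_range: tuple = (10, 20)
    read_len: int = 150
    sim_min_overhang: int = 20             # simulated overhangs stay clear of the 6 nt rule
    n_sub_overhang_per_circ: int = 0
    n_background_reads: int = 200
    decoy_depth: int = 2
    # expression
    n_per_group: int = 9
    noise_sd: float = 0.25
    group_jitter_sd: float = 0.4
    de_log2fc: float = 3.0
    mu_log2_range: tuple = (5.0, 12.0)
    count_model: str = "lognormal"         # or "negbin"
    negbin_dispersion: float = 10.0
    n_de: dict = field(default_factory=lambda: {
        "mRNA": (12, 8), "lncRNA": (5, 3), "miRNA": (7, 7), "circRNA": (8, 6)})
    n_triplets: dict = field(default_factory=lambda: {
        "circRNA": (2, 2), "lncRNA": (2, 2)})   # (up, down) per ceRNA class
    n_decoy_triplets: int = 3


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def generate_genome(config: SynthConfig, seed: int) -> GenomeModel:
    """Build the toy genome: random sequence, placed genes, splice motifs."""
    rng = np.random.default_rng(derive_seed(seed, "genome"))
    sm = _splice.SpliceSiteModel.load()
    don_cons = sm.consensus_donor()
    acc_cons = sm.consensus_acceptor()

    names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    arrays = {n: rng.integers(0, 4, size=config.chrom_len).astype(np.int8)
              for n in names}
    if config.include_long_chrom:
        arrays["chrL"] = rng.integers(0, 4, size=config.long_chrom_len).astype(np.int8)

    specs = ([("mRNA", i) for i in range(config.n_mrna)]
             + [("lncRNA", i) for i in range(config.n_lncrna)]
             + [("miRNA", i) for i in range(config.n_mirna)])
    order = rng.permutation(len(specs))

    cursors = {n: config.margin for n in names}
    genes = []
    for idx in order:
        rna_class, i = specs[idx]
        gene_id = {"mRNA": "gene", "lncRNA": "lnc", "miRNA": "mir"}[rna_class] + f"{i:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if rna_class == "miRNA":
            exon_lens = [config.mirna_len]
            intron_lens = []
        else:
            k = int(rng.integers(config.exon_count_range[0],
                                 config.exon_count_range[1] + 1))
            exon_lens = [int(rng.integers(*config.exon_len_range)) for _ in range(k)]
            intron_lens = [int(rng.integers(*config.intron_len_range))
                           for _ in range(k - 1)]
        span = sum(exon_lens) + sum(intron_lens)
        chrom = None
        for n in names:
            if cursors[n] + span <= len(arrays[n]) - config.margin:
                chrom = n
                break
        if chrom is None:
            tight = min(names, key=lambda n: len(arrays[n]) - cursors[n])
            raise ValueError(
                f"chromosome {tight} too short to host gene {gene_id} "
                f"(need {span} nt, {len(arrays[tight]) - cursors[tight]} left)")
        pos = cursors[chrom]
        exons = []
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if j < len(intron_lens):
                pos += intron_lens[j]
        cursors[chrom] = pos + int(rng.integers(*config.gene_gap_range))
        genes.append(Gene(gene_id=gene_id, chrom=chrom, strand=strand,
                          exons=exons, rna_class=rna_class))

    base_codes = {b: i for i, b in enumerate(BASES)}

    def write_motif(chrom, start, motif):
        arrays[chrom][start:start + len(motif)] = [base_codes[b] for b in motif]

    for g in genes:
        for d, a in _internal_boundaries(g):
            if g.strand == "+":
                write_motif(g.chrom, d - 3, don_cons)
                write_motif(g.chrom, a - 20, acc_cons)
            else:
                write_motif(g.chrom, d - 6, revcomp(don_cons))
                write_motif(g.chrom, a - 3, revcomp(acc_cons))

    lut = np.array(list(BASES))
    chroms = {n: "".join(lut[arr]) for n, arr in arrays.items()}
    genes.sort(key=lambda g: (g.chrom, g.start))
    return GenomeModel(chromosomes=chroms, genes=genes)


# ---------------------------------------------------------------------------
# circRNA planting
# ---------------------------------------------------------------------------

def _circ_free_mrna_ids(genome: GenomeModel, n: int) -> set:
    """The first n mRNA gene ids (by id) are reserved as circRNA-free."""
    ids = sorted(g.gene_id for g in genome.genes_of_class("mRNA"))
    return set(ids[:n])


def _circ_slots(genome: GenomeModel, min_span: int, excluded_genes=()):
    """Enumerate (gene, donor_pos, acceptor_pos, start, end) exon-pair slots."""
    slots = []
    for g in genome.genes:
        if g.rna_class == "miRNA" or len(g.exons) < 3 \
                or g.gene_id in excluded_genes:
            continue
        k = len(g.exons)
        if g.strand == "+":
            # acceptor at start of exon i (i>=2), donor at end of exon j (j<=k-1)
            for i in range(1, k - 1):
                for j in range(i, k - 1):
                    acc = g.exons[i][0]
                    don = g.exons[j][1]
                    if don - acc >= min_span:
                        slots.append((g, don, acc, acc, don))
        else:
            # donor at genomic start of exon p (p>=2), acceptor at end of exon q (q<=k-1)
            for p in range(1, k - 1):
                for q in range(p, k - 1):
                    don = g.exons[p][0]
                    acc = g.exons[q][1]
                    if acc - don >= min_span:
                        slots.append((g, don, acc, don, acc))
    return slots


def plant_circrnas(genome: GenomeModel, n_true: int, n_decoys: int, seed: int,
                   config: SynthConfig | None = None) -> tuple:
    """Plant callable circRNAs at exon-pair slots plus rule-violating decoys.

    Every true planting satisfies all candidate rules (same chromosome,
    span <= 1 Mb, same strand, reversed order) with consensus motifs at the
    chosen donor/acceptor; each decoy violates exactly the recorded rule.
    Returns (plantings, truth_table).
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(derive_seed(seed, "plant"))
    sm = _splice.SpliceSiteModel.load()
    reserved = _circ_free_mrna_ids(genome, config.n_circ_free_mrna)
    slots = _circ_slots(genome, min_span=config.read_len + 20,
                        excluded_genes=reserved)
    reasons = [DECOY_REASONS[i % len(DECOY_REASONS)] for i in range(n_decoys)]
    n_slot_needed = n_true + reasons.count("too_few_reads")
    if n_slot_needed > len(slots):
        raise ValueError(f"insufficient exon pairs: need {n_slot_needed}, "
                         f"have {len(slots)}")
    order = rng.permutation(len(slots))
    picked, used = [], set()
    for idx in order:
        g, don, acc, start, end = slots[idx]
        if (g.chrom, don, acc) in used:
            continue
        used.add((g.chrom, don, acc))
        picked.append(slots[idx])
        if len(picked) == n_slot_needed:
            break
    if len(picked) < n_slot_needed:
        raise ValueError("insufficient distinct exon-pair slots")

    def draw_overhangs(depth, n_sub):
        lo = config.sim_min_overhang
        hi = config.read_len - config.sim_min_overhang
        left = rng.integers(lo, hi + 1, size=depth).tolist()
        sub = [False] * depth
        for t in range(min(n_sub, depth)):
            left[t] = 5
            sub[t] = True
        return [(int(l), config.read_len - int(l)) for l in left], sub

    plantings = []
    for i in range(n_true):
        g, don, acc, start, end = picked[i]
        depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
        ov, sub = draw_overhangs(depth, config.n_sub_overhang_per_circ)
        plantings.append(PlantedCirc(
            circ_id=f"circ{i:03d}", chrom=g.chrom, start=start, end=end,
            strand=g.strand, donor_pos=don, acceptor_pos=acc, depth=depth,
            callable=True, gene_id=g.gene_id, overhangs=ov, sub_overhang=sub))

    # intergenic playground for motif-free decoys: the unused tail of each chrom
    def free_region(chrom):
        g_end = max([g.end for g in genome.genes if g.chrom == chrom] + [config.margin])
        return g_end + 1000, len(genome.chromosomes[chrom]) - config.margin

    slot_cursor = n_true
    for i, reason in enumerate(reasons):
        did = f"decoy{i:02d}"
        depth = config.decoy_depth
        ov, sub = draw_overhangs(depth, 0)
        if reason == "too_few_reads":
            g, don, acc, start, end = picked[slot_cursor]
            slot_cursor += 1
            ov, sub = draw_overhangs(1, 0)
            plantings.append(PlantedCirc(
                circ_id=did, chrom=g.chrom, start=start, end=end,
                strand=g.strand, donor_pos=don, acceptor_pos=acc, depth=1,
                callable=False, reason=reason, gene_id=g.gene_id,
                overhangs=ov, sub_overhang=sub))
            continue
        if reason == "separation_gt_max":
            if "chrL" not in genome.chromosomes:
                raise ValueError("separation_gt_max decoy needs the long "
                                 "auxiliary chromosome (include_long_chrom)")
            acc = int(rng.integers(2000, 10_000))
            don = acc + 1_000_001 + int(rng.integers(0, 20_000))
            plantings.append(PlantedCirc(
                circ_id=did, chrom="chrL", start=acc, end=don, strand="+",
                donor_pos=don, acceptor_pos=acc, depth=depth, callable=False,
                reason=reason, overhangs=ov, sub_overhang=sub))
            continue
        chrom = f"chr{1 + i % config.n_chroms}"
        lo, hi = free_region(chrom)
        if reason == "score_below_min":
            # motif-free junction: rejection-sample until the best scoring
            # pair in the caller's search window sits safely below threshold
            for _ in range(100):
                acc = int(rng.integers(lo, hi - 10_000))
                don = acc + int(rng.integers(2000, 8000))
                seq = genome.chromosomes[chrom]
                best = max(sm.donor_score(seq, don + o, "+") for o in range(-12, 13)) \
                    + max(sm.acceptor_score(seq, acc + o, "+") for o in range(-12, 13))
                if best < 8.0:
                    break
            plantings.append(PlantedCirc(
                circ_id=did, chrom=chrom, start=acc, end=don, strand="+",
                donor_pos=don, acceptor_pos=acc, depth=depth, callable=False,
                reason=reason, overhangs=ov, sub_overhang=sub))
            continue
        acc = int(rng.integers(lo, hi - 10_000))
        don = acc + int(rng.integers(2000, 8000))
        if reason == "different_chromosome":
            other = f"chr{1 + (i + 1) % config.n_chroms}"
            lo2, hi2 = free_region(other)
            acc2 = int(rng.integers(lo2, hi2 - 1000))
            plantings.append(PlantedCirc(
                circ_id=did, chrom=chrom, start=acc2, end=don, strand="+",
                donor_pos=don, acceptor_pos=acc2, depth=depth, callable=False,
                reason=reason, overhangs=ov, sub_overhang=sub,
                anchor1=(chrom, don, "+", "end"),
                anchor2=(other, acc2, "+", "start")))
        elif reason == "opposite_strand":
            plantings.append(PlantedCirc(
                circ_id=did, chrom=chrom, start=acc, end=don, strand="+",
                donor_pos=don, acceptor_pos=acc, depth=depth, callable=False,
                reason=reason, overhangs=ov, sub_overhang=sub,
                anchor1=(chrom, don, "+", "end"),
                anchor2=(chrom, acc, "-", "start")))
        elif reason == "same_order":
            plantings.append(PlantedCirc(
                circ_id=did, chrom=chrom, start=acc, end=don, strand="+",
                donor_pos=don, acceptor_pos=acc, depth=depth, callable=False,
                reason=reason, overhangs=ov, sub_overhang=sub,
                anchor1=(chrom, acc, "+", "start"),
                anchor2=(chrom, don, "+", "start")))
        else:  # pragma: no cover - exhaustive
            raise AssertionError(reason)

    truth = TruthTable(circs=plantings)
    return plantings, truth


# ---------------------------------------------------------------------------
# split-read simulation and SAM output
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    qname: str
    seq: str
    # segments: (chrom, start, end, strand, query_start, query_end)
    segments: list


def _part(genome: GenomeModel, anchor, length: int):
    chrom, pos, strand, side = anchor
    if side == "end":
        start, end = pos - length, pos
    else:
        start, end = pos, pos + length
    seq = genome.chromosomes[chrom][start:end]
    if strand == "-":
        seq = revcomp(seq)
    return seq, (chrom, start, end, strand)


def simulate_split_alignments(genome: GenomeModel, plantings: list,
                              read_len: int = 150, seed: int = 0,
                              n_background: int = 200,
                              min_overhang: int = 1,
                              sam_path=None,
                              truth: TruthTable | None = None):
    """Emit junction-spanning split reads plus linear background reads.

    Each junction read is two partial alignments of one read; the left
    overhang per read comes from the planting's overhang profile. Returns
    ``list[SimRead]``; writes SAM when ``sam_path`` is given and records a
    per-read truth table on ``truth`` when supplied.
    """
    rng = np.random.default_rng(derive_seed(seed, "reads"))
    reads, truth_rows = [], []
    for circ in plantings:
        for k, (left, right) in enumerate(circ.overhangs):
            if left <= 0 or right <= 0 or left + right != read_len:
                raise ValueError(
                    f"{circ.circ_id}: overhang profile ({left},{right}) "
                    f"incompatible with read length {read_len}")
            seq1, seg1 = _part(genome, circ.anchor1, left)
            seq2, seg2 = _part(genome, circ.anchor2, right)
            qname = f"{circ.circ_id}:junc:{k:03d}"
            reads.append(SimRead(qname=qname, seq=seq1 + seq2,
                                 segments=[seg1 + (0, left),
                                           seg2 + (left, read_len)]))
            truth_rows.append({"qname": qname, "circ_id": circ.circ_id,
                               "left_overhang": left, "right_overhang": right,
                               "sub_overhang": bool(circ.sub_overhang[k])})
    regular = [n for n in genome.chromosomes if n != "chrL"]
    for k in range(n_background):
        chrom = regular[int(rng.integers(len(regular)))]
        clen = len(genome.chromosomes[chrom])
        pos = int(rng.integers(0, clen - read_len))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = genome.chromosomes[chrom][pos:pos + read_len]
        if strand == "-":
            seq = revcomp(seq)
        reads.append(SimRead(qname=f"bg:{k:04d}", seq=seq,
                             segments=[(chrom, pos, pos + read_len, strand,
                                        0, read_len)]))
    if truth is not None:
        truth.reads = pd.DataFrame(truth_rows)
    if sam_path is not None:
        write_sam(genome, reads, sam_path)
    return reads


def write_sam(genome: GenomeModel, reads: list, path) -> None:
    """Serialize simulated reads as SAM (primary + supplementary records)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in genome.chromosomes.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for read in reads:
            L = len(read.seq)
            for j, (chrom, start, end, strand, qs, qe) in enumerate(read.segments):
                flag = 0
                if strand == "-":
                    flag |= 16
                if j > 0:
                    flag |= 2048
                if strand == "+":
                    cigar = ""
                    if qs:
                        cigar += f"{qs}S"
                    cigar += f"{qe - qs}M"
                    if L - qe:
                        cigar += f"{L - qe}S"
                    seq_out = read.seq
                else:
                    cigar = ""
                    if L - qe:
                        cigar += f"{L - qe}S"
                    cigar += f"{qe - qs}M"
                    if qs:
                        cigar += f"{qs}S"
                    seq_out = revcomp(read.seq)
                qual = "?" * L  # constant Q30
                fh.write(f"{read.qname}\t{flag}\t{chrom}\t{start + 1}\t60\t"
                         f"{cigar}\t*\t0\t0\t{seq_out}\t{qual}\n")


# ---------------------------------------------------------------------------
# regulatory truth: DE statuses, triplets, seed sites
# ---------------------------------------------------------------------------

def plant_regulatory_truth(genome: GenomeModel, truth: TruthTable,
                           config: SynthConfig, seed: int) -> TruthTable:
    """Assign planted DE, choose ceRNA triplets, and plant seed-match sites.

    Mutates the genome so that each planted triplet's miRNA has an 8mer
    site in both its ceRNA and its mRNA, then scrubs accidental seed-core
    matches elsewhere so the target tables contain exactly the planted
    interactions. Fills ``truth.de``, ``truth.triplets``, ``truth.sites``
    and ``truth.mirna_seqs``.
    """
    rng = np.random.default_rng(derive_seed(seed, "regulatory"))
    L = config.de_log2fc

    pools = {
        "mRNA": [g.gene_id for g in genome.genes_of_class("mRNA")],
        "lncRNA": [g.gene_id for g in genome.genes_of_class("lncRNA")],
        "miRNA": [g.gene_id for g in genome.genes_of_class("miRNA")],
        "circRNA": [c.circ_id for c in truth.callable_circs()],
    }

    # --- distinct miRNA sequences with non-overlapping seed cores ----------
    mirna_genes = genome.genes_of_class("miRNA")
    mirna_seqs = {}
    for g in mirna_genes:
        for _ in range(200):
            seq = random_dna(rng, config.mirna_len)
            core = revcomp(seq[1:7])
            site8 = revcomp(seq[1:8]) + "A"
            clash = False
            for other_seq in mirna_seqs.values():
                ocore = revcomp(other_seq[1:7])
                osite = revcomp(other_seq[1:8]) + "A"
                if ocore in site8 or core in osite or ocore == core:
                    clash = True
                    break
            if not clash:
                break
        mirna_seqs[g.gene_id] = seq
        s, e = g.exons[0]
        genome.splice_in(g.chrom, s, seq if g.strand == "+" else revcomp(seq))
    truth.mirna_seqs = mirna_seqs

    # --- triplet members first (forced statuses), then random DE fill ------
    # Triplet mRNAs come from circRNA-free genes so that, after scrubbing,
    # their only seed site is their own triplet's; this makes the planted
    # triplet set exactly recoverable in the noiseless limit.
    circ_free = sorted(_circ_free_mrna_ids(genome, config.n_circ_free_mrna))
    forced: dict = {}
    used: set = set()

    def pick(pool, what):
        cands = [f for f in pool if f not in used]
        if not cands:
            raise ValueError(f"no spare feature for triplet {what}")
        f = cands[int(rng.integers(len(cands)))]
        used.add(f)
        return f

    trip_rows = []
    tid = 0
    # deterministic-part correlation between DE features with independent
    # latent factors (see simulate_expression); recorded for decoy audit
    sigma2 = config.group_jitter_sd ** 2
    r_indep = 0.25 / (0.25 + sigma2)
    for cerna_class, (n_up_t, n_down_t) in config.n_triplets.items():
        for direction, n in (("up", n_up_t), ("down", n_down_t)):
            opp = "down" if direction == "up" else "up"
            for _ in range(n):
                cerna = pick(pools[cerna_class], "ceRNA")
                mirna = pick(pools["miRNA"], "miRNA")
                mrna = pick(circ_free, "mRNA")
                forced[cerna] = direction
                forced[mirna] = opp
                forced[mrna] = direction
                trip_rows.append({
                    "triplet_id": f"trip{tid:02d}", "cerna_id": cerna,
                    "cerna_class": cerna_class, "mirna_id": mirna,
                    "mrna_id": mrna, "direction": direction,
                    "is_decoy": False, "decoy_reason": "", "true_r": 1.0})
                tid += 1

    decoy_reasons = ["mrna_ns", "no_seed_in_cerna", "mirna_same_direction"]
    for i in range(config.n_decoy_triplets):
        reason = decoy_reasons[i % len(decoy_reasons)]
        cerna_class = ["circRNA", "lncRNA"][i % 2]
        cerna = pick(pools[cerna_class], "decoy ceRNA")
        mirna = pick(pools["miRNA"], "decoy miRNA")
        mrna = pick(circ_free, "decoy mRNA")
        forced[cerna] = "up"
        forced[mirna] = "up" if reason == "mirna_same_direction" else "down"
        forced[mrna] = "ns" if reason == "mrna_ns" else "up"
        trip_rows.append({
            "triplet_id": f"trip{tid:02d}", "cerna_id": cerna,
            "cerna_class": cerna_class, "mirna_id": mirna, "mrna_id": mrna,
            "direction": "up", "is_decoy": True, "decoy_reason": reason,
            "true_r": 0.0 if reason == "mrna_ns" else round(r_indep, 6)})
        tid += 1
    truth.triplets = pd.DataFrame(trip_rows)

    de_rows, status = [], {}
    for cl in RNA_CLASSES:
        ids = list(pools[cl])
        n_up, n_down = config.n_de.get(cl, (0, 0))
        have_up = sum(1 for f in ids if forced.get(f) == "up")
        have_down = sum(1 for f in ids if forced.get(f) == "down")
        free_ids = [f for f in ids if f not in forced]
        need = max(0, n_up - have_up) + max(0, n_down - have_down)
        if need > len(free_ids):
            raise ValueError(f"not enough {cl} features for requested DE counts")
        chosen = rng.choice(len(free_ids), size=need, replace=False)
        up = {free_ids[i] for i in chosen[:max(0, n_up - have_up)]}
        down = {free_ids[i] for i in chosen[max(0, n_up - have_up):]}
        for fid in ids:
            st = forced.get(fid) or ("up" if fid in up else
                                     ("down" if fid in down else "ns"))
            lfc = L if st == "up" else (-L if st == "down" else 0.0)
            de_rows.append({"feature_id": fid, "rna_class": cl,
                            "true_log2fc": lfc})
            status[fid] = st
    truth.de = pd.DataFrame(de_rows)

    # --- plant 8mer sites ---------------------------------------------------
    protected = {n: np.zeros(len(s), dtype=bool)
                 for n, s in genome.chromosomes.items()}
    for g in genome.genes:
        for d, a in _internal_boundaries(g):
            if g.strand == "+":
                protected[g.chrom][d - 3:d + 6] = True
                protected[g.chrom][a - 20:a + 3] = True
            else:
                protected[g.chrom][d - 6:d + 3] = True
                protected[g.chrom][a - 3:a + 20] = True

    circs_by_id = {c.circ_id: c for c in truth.callable_circs()}

    def plant_site(mirna_id, target_id, target_class):
        site = revcomp(mirna_seqs[mirna_id][1:8]) + "A"
        if target_class == "circRNA":
            circ = circs_by_id[target_id]
            host = genome.gene(circ.gene_id)
            exons = [(s, e) for s, e in host.exons
                     if s >= circ.start and e <= circ.end
                     and e - s >= len(site) + 56]
            if not exons:
                raise ValueError(f"no exon inside {target_id} can host a site")
            s, e = exons[int(rng.integers(len(exons)))]
            gpos = int(rng.integers(s + 26, e - 26 - len(site)))
            gseq = site if host.strand == "+" else revcomp(site)
            genome.splice_in(circ.chrom, gpos, gseq)
            protected[circ.chrom][gpos:gpos + len(site)] = True
            tseq = circ_sequence(genome, circ, circs_by_id)
            tpos = tseq.find(site)
        else:
            gene = genome.gene(target_id)
            exons = [(s, e) for s, e in gene.exons if e - s >= len(site) + 56]
            s, e = exons[int(rng.integers(len(exons)))]
            off = int(rng.integers(s + 26, e - 26 - len(site)))
            gseq = site if gene.strand == "+" else revcomp(site)
            genome.splice_in(gene.chrom, off, gseq)
            protected[gene.chrom][off:off + len(site)] = True
            tseq = genome.transcript_seq(gene)
            tpos = tseq.find(site)
        return tpos

    site_rows = []
    for r in truth.triplets.itertuples():
        targets = [(r.mrna_id, "mRNA")]
        if r.decoy_reason != "no_seed_in_cerna":
            targets.append((r.cerna_id, r.cerna_class))
        for target_id, target_class in targets:
            tpos = plant_site(r.mirna_id, target_id, target_class)
            site_rows.append({"mirna_id": r.mirna_id, "target_id": target_id,
                              "target_class": target_class, "t_pos": tpos,
                              "triplet_id": r.triplet_id})
    truth.sites = pd.DataFrame(site_rows)

    _scrub_accidental_sites(genome, truth, protected, rng)
    return truth


def circ_sequence(genome: GenomeModel, circ, circs_by_id=None) -> str:
    """Strand-oriented genomic sequence spanned by a back-splice junction."""
    return genome.interval_seq(circ.chrom, circ.start, circ.end, circ.strand)


def _target_sequences(genome: GenomeModel, truth: TruthTable) -> dict:
    """id -> (sequence, class, genomic position mapper) for all scan targets."""
    out = {}
    for g in genome.genes:
        if g.rna_class in ("mRNA", "lncRNA"):
            out[g.gene_id] = (genome.transcript_seq(g), g.rna_class,
                              lambda i, g=g: genome.transcript_to_genome(g, i),
                              g.chrom)
    for c in truth.callable_circs():
        if c.strand == "+":
            mapper = (lambda i, c=c: c.start + i)
        else:
            mapper = (lambda i, c=c: c.end - 1 - i)
        out[c.circ_id] = (circ_sequence(genome, c), "circRNA", mapper, c.chrom)
    return out


def _scrub_accidental_sites(genome, truth, protected, rng, max_passes=40):
    """Mutate away chance seed-core matches so target tables equal the plan.

    Point mutations preserve coordinates, so all occurrences found in one
    pass can be patched before re-scanning; the re-scan catches any core a
    mutation happened to create.
    """
    planted = {(r.mirna_id, r.target_id): r.t_pos + 1  # core offset within the 8mer
               for r in truth.sites.itertuples()}
    for _ in range(max_passes):
        dirty = False
        targets = _target_sequences(genome, truth)
        mutated = {n: set() for n in genome.chromosomes}
        for mid, mseq in truth.mirna_seqs.items():
            core = revcomp(mseq[1:7])
            for tid, (tseq, _tclass, mapper, chrom) in targets.items():
                idx = tseq.find(core)
                while idx != -1:
                    if planted.get((mid, tid)) != idx:
                        gpos = [mapper(i) for i in range(idx, idx + 6)]
                        free = [p for p in gpos if not protected[chrom][p]
                                and p not in mutated[chrom]]
                        if free:
                            p = free[int(rng.integers(len(free)))]
                            old = genome.chromosomes[chrom][p]
                            alts = [b for b in BASES if b != old]
                            genome.edit(chrom, p, alts[int(rng.integers(3))])
                            mutated[chrom].add(p)
                            dirty = True
                    idx = tseq.find(core, idx + 1)
        if not dirty:
            return
    import warnings
    warnings.warn("seed-site scrubbing did not fully converge")


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(truth: TruthTable, n_per_group: int = 9,
                        noise_sd: float = 0.25, seed: int = 0,
                        config: SynthConfig | None = None) -> dict:
    """Two-group abundance matrices per RNA class with planted structure.

    Feature abundances are log-normal: log2 values are a per-feature
    baseline plus ``true_log2fc * group`` plus, for triplet members, the
    planted fold change times a per-triplet latent sample factor (exactly
    mean-centred within each group, so group-mean log2 ratios equal the
    planted fold change before noise), plus N(0, noise_sd) noise.
    Returns ``{rna_class: ExpressionMatrix}``.
    """
    from .quantify import ExpressionMatrix

    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_per_group < 3:
        raise ValueError("need at least 3 samples per group")
    config = config or SynthConfig()
    if truth.de.empty:
        raise ValueError("truth table has no features; plant regulatory truth "
                         "or use TruthTable.null()")
    rng = np.random.default_rng(derive_seed(seed, "expression"))

    samples = [f"A{i + 1}" for i in range(n_per_group)] + \
              [f"B{i + 1}" for i in range(n_per_group)]
    gvec = np.array([0.0] * n_per_group + [1.0] * n_per_group)
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group,
                       index=samples, name="group")

    # latent per-sample factor: shared exactly within a planted triplet,
    # independent across all other DE features. Group B reuses group A's
    # centred values in permuted order, so both groups carry the same
    # multiset and the group-mean ratio equals the planted fold change
    # exactly in the noiseless limit. Sharing drives within-triplet
    # correlation to 1 at zero noise while unrelated DE pairs stay well
    # below the r > 0.9 gate.
    def draw_jitter():
        j = rng.normal(0.0, config.group_jitter_sd, size=n_per_group)
        j -= j.mean()
        return np.concatenate([j, rng.permutation(j)])

    jitter = {}
    if len(truth.triplets):
        for t in truth.triplets.itertuples():
            if t.is_decoy:
                continue
            j = draw_jitter()
            for fid in (t.cerna_id, t.mirna_id, t.mrna_id):
                jitter[fid] = j

    out = {}
    for cl, sub in truth.de.groupby("rna_class", sort=False):
        n_feat = len(sub)
        mu = rng.uniform(*config.mu_log2_range, size=n_feat)
        beta = sub["true_log2fc"].to_numpy()
        x = mu[:, None] + beta[:, None] * gvec[None, :]
        for row, fid in enumerate(sub["feature_id"]):
            if beta[row] == 0:
                continue
            if fid not in jitter:
                jitter[fid] = draw_jitter()
            x[row] += beta[row] * jitter[fid]
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, size=x.shape)
        values = np.exp2(x)
        if config.count_model == "negbin":
            r = config.negbin_dispersion
            p = r / (r + values)
            values = rng.negative_binomial(r, p).astype(float)
        values = pd.DataFrame(values, index=list(sub["feature_id"]),
                              columns=samples)
        out[cl] = ExpressionMatrix(rna_class=cl, values=values, groups=groups,
                                   kind="abundance")
    return out


# ---------------------------------------------------------------------------
# target tables and annotation sets
# ---------------------------------------------------------------------------

def emit_target_tables(genome: GenomeModel, truth: TruthTable) -> pd.DataFrame:
    """Seed-match interaction table over all miRNAs x all target transcripts.

    A row exists iff the canonical seed-site rule fires on the target's
    sequence; with scrubbed synthetic genomes this is exactly the planted
    interaction set.
    """
    from .cerna import predict_targets

    if not truth.mirna_seqs:
        raise ValueError("no miRNA sequences in truth; plant regulatory truth first")
    targets = {tid: (seq, tclass)
               for tid, (seq, tclass, _m, _c) in _target_sequences(genome, truth).items()}
    return predict_targets(truth.mirna_seqs, targets)


def emit_annotation_sets(genome: GenomeModel, truth: TruthTable, seed: int = 0,
                         n_random_terms: int = 10,
                         term_size_range: tuple = (5, 15)) -> dict:
    """Toy GMT-style annotation: random terms plus one planted-up-mRNA term."""
    rng = np.random.default_rng(derive_seed(seed, "annotation"))
    universe = [g.gene_id for g in genome.genes_of_class("mRNA")]
    terms = {}
    for i in range(n_random_terms):
        size = int(rng.integers(*term_size_range))
        members = sorted(rng.choice(universe, size=min(size, len(universe)),
                                    replace=False).tolist())
        terms[f"RND{i:02d}"] = ("random gene set", members)
    if len(truth.de):
        up = sorted(truth.de.query("rna_class == 'mRNA' and true_log2fc > 0")
                    ["feature_id"].tolist())
        if up:
            terms["IFN_UP"] = ("planted interferon-responsive genes", up)
    return terms
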