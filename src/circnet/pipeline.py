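"""End-to-end orchestration: synthetic or real-data runs under one config.

Stage order: synthdata -> circcall -> quantify -> descreen -> cerna ->
enrich. Every text artifact carries the config hash in a header comment;
identical config + seed gives byte-identical outputs. Wall-clock timings
go to the run log (they are the one non-reproducible quantity); the run
report itself is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import cerna as _cerna
from . import circcall as _circcall
from . import descreen as _descreen
from . import enrich as _enrich
from . import quantify as _quantify
from . import synthdata as _synth
from .splice import SpliceSiteModel
from .utils import config_hash


@dataclass
class PipelineConfig:
    """All thresholds, defaulted exactly as in the emulated study design."""

    mode: str = "synthetic"            # synthetic | real
    seed: int = 0
    max_sep: int = 1_000_000
    min_reads: int = 2
    min_score: float = 10.0
    min_overhang: int = 6
    lfc_cut: float = 2.0
    p_cut: float = 0.01
    r_cut: float = 0.9
    adjp_cut: float = 0.1
    enrich_p_cut: float = 0.05
    n_per_group: int = 9
    noise_sd: float = 0.25
    de_test: str = "welch"
    paired: bool = False
    epsilon: float = 1.0
    mirna_rule: str = "opposite"
    search_radius: int = 10
    flank: int = 150
    synth: _synth.SynthConfig = field(default_factory=_synth.SynthConfig)
    # real-mode inputs
    sam_path: str | None = None
    genome_fasta: str | None = None
    annotation_path: str | None = None
    matrix_paths: dict = field(default_factory=dict)   # rna_class -> tsv
    target_table_path: str | None = None
    gmt_path: str | None = None

    def __post_init__(self):
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        for name in ("max_sep", "min_reads", "min_score", "min_overhang",
                     "lfc_cut", "p_cut", "r_cut", "adjp_cut", "enrich_p_cut",
                     "n_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        self.synth.noise_sd = self.noise_sd
        self.synth.n_per_group = self.n_per_group

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return config_hash(self.to_dict())

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_raw = raw.pop("synth", {})
        synth = _synth.SynthConfig(**{k: tuple(v) if isinstance(v, list) else v
                                      for k, v in synth_raw.items()})
        return cls(synth=synth, **raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    config_hash: str
    seed: int
    counts: dict = field(default_factory=dict)

    def check_consistency(self) -> None:
        c = self.counts
        if c.get("calls", 0) > c.get("candidates", 0):
            raise AssertionError("calls exceed candidates")
        if c.get("coexp_edges_retained", 0) == 0 and c.get("triplets", 0) > 0:
            raise AssertionError("triplets without retained co-expression edges")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "seed": self.seed,
                       "counts": self.counts}, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            fh.write(f"config_hash\t{self.config_hash}\n")
            fh.write(f"seed\t{self.seed}\n")
            for k in sorted(self.counts):
                fh.write(f"{k}\t{self.counts[k]}\n")


def _log(fh, stage, msg):
    fh.write(f"[{stage}] {msg}\n")


def run_pipeline(config: PipelineConfig, outdir) -> RunReport:
    """Execute all stages; writes every stage artifact under ``outdir``."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    stamp = [f"config={chash}", f"seed={config.seed}"]
    report = RunReport(config_hash=chash, seed=config.seed)
    counts = report.counts
    model = SpliceSiteModel.load()
    log = open(outdir / "run.log", "w")
    t0 = time.perf_counter()

    def tick(stage):
        nonlocal t0
        dt = time.perf_counter() - t0
        _log(log, stage, f"done in {dt:.2f}s")
        t0 = time.perf_counter()

    # ------------------------------------------------------------- synthdata
    if config.mode == "synthetic":
        syn = config.synth
        genome = _synth.generate_genome(syn, config.seed)
        plantings, truth = _synth.plant_circrnas(
            genome, syn.n_true_circs, syn.n_decoys, config.seed, syn)
        _synth.plant_regulatory_truth(genome, truth, syn, config.seed)
        sam_path = outdir / "alignments.sam"
        sim_reads = _synth.simulate_split_alignments(
            genome, plantings, read_len=syn.read_len, seed=config.seed,
            n_background=syn.n_background_reads, sam_path=sam_path,
            truth=truth)
        genome.write_fasta(outdir / "genome.fa")
        genome.write_annotation(outdir / "annotation.tsv")
        truth.write(outdir)
        matrices = _synth.simulate_expression(
            truth, n_per_group=config.n_per_group, noise_sd=config.noise_sd,
            seed=config.seed, config=syn)
        target_edges = _synth.emit_target_tables(genome, truth)
        gmt_sets = [
            _enrich.AnnotationSet(term_id=t, term_name=desc,
                                  members=frozenset(members))
            for t, (desc, members) in
            _synth.emit_annotation_sets(genome, truth, config.seed).items()]
        _enrich.write_gmt(gmt_sets, outdir / "annotation_sets.gmt")
        counts["planted_circs"] = len(truth.callable_circs())
        counts["planted_decoys"] = len(truth.decoys())
        counts["planted_triplets"] = int((~truth.triplets["is_decoy"]).sum()) \
            if len(truth.triplets) else 0
        counts["reads"] = len(sim_reads)
        tick("synthdata")
    else:
        genome = _synth.GenomeModel.from_files(config.genome_fasta,
                                               config.annotation_path)
        sam_path = pathlib.Path(config.sam_path)
        matrices = {cl: _quantify.ExpressionMatrix.read_tsv(p, rna_class=cl)
                    for cl, p in config.matrix_paths.items()}
        target_edges = pd.read_csv(config.target_table_path, sep="\t",
                                   comment="#") \
            if config.target_table_path else None
        gmt_sets = _enrich.read_gmt(config.gmt_path) if config.gmt_path else []
        truth = None
        tick("load")

    # --------------------------------------------------------------- circcall
    alignments = _circcall.read_sam(sam_path)
    candidates, cand_rej, tallies = _circcall.find_chimeric_candidates(
        alignments, max_sep=config.max_sep)
    calls, call_rej = _circcall.call_circrnas(
        candidates, genome, model, min_reads=config.min_reads,
        min_score=config.min_score, max_sep=config.max_sep,
        search_radius=config.search_radius)
    _circcall.write_bed(calls, outdir / "circ_calls.bed", stamp)
    _circcall.write_rejections(cand_rej + call_rej,
                               outdir / "rejections.tsv")
    counts["alignments"] = len(alignments)
    counts["candidates"] = len(candidates)
    counts["calls"] = len(calls)
    for rule, n in sorted(tallies.items()):
        counts[f"rejected_reads_{rule}"] = n
    for rec in call_rej:
        key = f"rejected_candidates_{rec['reason']}"
        counts[key] = counts.get(key, 0) + 1
    tick("circcall")

    # --------------------------------------------------------------- quantify
    refs = [_quantify.build_junction_reference(c, genome, flank=config.flank)
            for c in calls]
    with open(outdir / "junction_refs.fa", "w") as fh:
        for r in refs:
            fh.write(f">{r.circ_id}\n{r.sequence}\n")
    if config.mode == "synthetic":
        pool = [r.seq for r in sim_reads]
    else:
        pool = _read_pool_from_sam(sam_path)
    jcounts = _quantify.count_junction_reads(refs, pool,
                                             min_overhang=config.min_overhang)
    jcounts.to_csv(outdir / "junction_counts.tsv", sep="\t")
    if len(jcounts) and jcounts.values.sum() > 0:
        jnorm = _quantify.normalize(jcounts, method="rpm",
                                    rna_class="circRNA")
        jnorm.to_tsv(outdir / "junction_rpm.tsv", stamp)
    counts["junction_reads_counted"] = int(jcounts.values.sum())
    tick("quantify")

    # --------------------------------------------------------------- descreen
    de_frames = {}
    for cl, mat in matrices.items():
        rec = _descreen.de_screen(mat, test=config.de_test,
                                  lfc_cut=config.lfc_cut, p_cut=config.p_cut,
                                  epsilon=config.epsilon,
                                  paired=config.paired)
        de_frames[cl] = rec
        mat.to_tsv(outdir / f"expression_{cl}.tsv", stamp)
        _descreen.write_de_tsv(rec, outdir / f"de_{cl}.tsv", config.epsilon,
                               stamp)
    de_all = pd.concat(de_frames.values(), ignore_index=True)
    summary = _descreen.summarize_de(de_all)
    summary.to_csv(outdir / "de_summary.tsv", sep="\t")
    for cl, rec in de_frames.items():
        for st in ("up", "down"):
            counts[f"de_{cl}_{st}"] = int((rec["status"] == st).sum())
    tick("descreen")

    # ------------------------------------------------------------------ cerna
    if target_edges is None:
        target_edges = pd.DataFrame(columns=["mirna_id", "target_id",
                                             "target_class", "site_type",
                                             "position"])
    target_edges.to_csv(outdir / "target_edges.tsv", sep="\t", index=False)
    values_by_id = {}
    for mat in matrices.values():
        for fid in mat.values.index:
            values_by_id[fid] = mat.values.loc[fid]
    de_status = dict(zip(de_all["feature_id"], de_all["status"]))
    pairs = set()
    for mid, grp in target_edges.groupby("mirna_id"):
        cer = sorted(set(grp.loc[grp["target_class"]
                                 .isin(("circRNA", "lncRNA")), "target_id"]))
        mr = sorted(set(grp.loc[grp["target_class"] == "mRNA", "target_id"]))
        for c in cer:
            for m in mr:
                if de_status.get(c, "ns") != "ns" \
                        and de_status.get(m, "ns") != "ns":
                    pairs.add((c, m))
    pairs = sorted(pairs)
    if pairs:
        vx = pd.DataFrame({c: values_by_id[c] for c, _ in pairs}).T
        vy = pd.DataFrame({m: values_by_id[m] for _, m in pairs}).T
        vx = vx.loc[~vx.index.duplicated()]
        vy = vy.loc[~vy.index.duplicated()]
        coexp, skipped = _cerna.correlate_pairs(
            vx, vy, pairs, r_cut=config.r_cut, adjp_cut=config.adjp_cut)
    else:
        coexp, skipped = pd.DataFrame(columns=["id_x", "id_y", "pearson_r",
                                               "p_value", "adj_p",
                                               "retained"]), []
    coexp.to_csv(outdir / "coexpression_edges.tsv", sep="\t", index=False,
                 float_format="%.10g")
    net = _cerna.assemble_network(de_all, target_edges, coexp,
                                  mirna_rule=config.mirna_rule)
    net.triplets.to_csv(outdir / "triplets.tsv", sep="\t", index=False,
                        float_format="%.10g")
    net.summary().to_csv(outdir / "subnetwork_summary.tsv", sep="\t",
                         index=False)
    _cerna.export_network(net, outdir / "network.sif", "sif")
    _cerna.export_network(net, outdir / "network.graphml", "graphml")
    counts["target_edges"] = len(target_edges)
    counts["coexp_pairs_tested"] = len(coexp)
    counts["coexp_pairs_skipped"] = len(skipped)
    counts["coexp_edges_retained"] = int(coexp["retained"].sum()) \
        if len(coexp) else 0
    counts["triplets"] = len(net.triplets)
    for row in net.summary().itertuples():
        counts[f"subnet_{row.subnetwork}_triplets"] = row.n_triplets
    tick("cerna")

    # ----------------------------------------------------------------- enrich
    universe = sorted(de_all.loc[de_all["rna_class"] == "mRNA", "feature_id"])
    query = sorted({n for g in net.subnetworks.values()
                    for n, a in g.nodes(data=True)
                    if a["rna_class"] == "mRNA"})
    if query and gmt_sets:
        enr = _enrich.ora_test(query, gmt_sets, universe,
                               p_cut=config.enrich_p_cut)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                   float_format="%.10g")
        counts["enrich_terms_tested"] = len(enr)
        counts["enrich_terms_significant"] = int(enr["significant"].sum())
    else:
        counts["enrich_terms_tested"] = 0
        counts["enrich_terms_significant"] = 0
    tick("enrich")

    report.check_consistency()
    report.to_json(outdir / "report.json")
    report.to_tsv(outdir / "report.tsv")
    log.close()
    return report


def _read_pool_from_sam(sam_path) -> list:
    """Recover original read sequences (primary records) from a SAM file."""
    import pysam
    from .utils import revcomp
    pool = []
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.query_sequence or ""
            if rec.is_reverse:
                seq = revcomp(seq)
            pool.append(seq)
    return pool
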