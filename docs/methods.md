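# Methods

This note documents the models, parameter choices and numerical
conventions behind `circnet`, and what the synthetic benchmark does and
does not demonstrate about real data.

## Coordinate and strand conventions

All coordinates are 0-based half-open internally; BED output follows the
BED standard, annotation TSV is 1-based inclusive like GTF. A circRNA
call spans `[start, end)` with the back-splice acceptor at the lower
coordinate on the plus strand and the donor at the lower coordinate on
the minus strand. The head-to-tail ("reverse order") rule is
strand-aware: on the plus strand the earlier read part must map
downstream of the later part (compared by segment starts); on the minus
strand the rule is the exact mirror image (compared by segment ends).
The mirror formulation matters only for pathological nested segments,
but it is what makes the caller exactly symmetric under
reverse-complementing the genome — an invariant the test suite checks.

## Splice-site model

Junction refinement scores candidate donor/acceptor positions with a
position-weight-matrix log-odds model over the standard MaxEntScan-style
windows: donor 9 nt (3 exonic + 6 intronic, consensus `CAG|GTAAGT`) and
acceptor 23 nt (20 intronic + 3 exonic, a polypyrimidine tract ending in
the invariant `AG`). The matrix lives in
`src/circnet/data/splice_model.json` together with a scale factor chosen
so that a perfect consensus donor+acceptor pair scores 20.0; the
decision threshold of 10 then sits halfway between consensus (20) and
the null: random sequence scores about −14 on average, and the maximum
over a ±10 nt search window of 1000 random regions stays below 10 (a
test asserts this). A maximum-entropy or differently trained model can
be dropped in through the same JSON interface; only the window shapes
and the column-stochastic constraint are fixed. Ties between
equal-scoring pairs go to the pair closest to the observed segment
breakpoints, then to the smaller genomic coordinate — the tie-break is
deliberately total so output order is reproducible.

Search radius defaults to 10 nt around the segment breakpoints; reads
whose implied breakpoints differ by ≤ 5 nt are merged into one candidate
before scoring. Both are configurable; neither matters on synthetic data
(simulated breakpoints are exact) but they give real split alignments,
whose clip positions wobble, a place to land.

## Junction quantification

The pseudo-reference for a call is `genome[end−flank:end] +
genome[start:start+flank]` (reverse-complemented for minus-strand
calls), flank 150 nt by default, truncated only when the circle itself
is shorter than the flank. Counting is exact substring matching of the
read (or its reverse complement) with the requirement of ≥ 6 matched nt
on both sides of the junction centre, each read counting at most once
per circRNA. Exact matching is a deliberate simplification: the
re-alignment tool whose behaviour it replaces is out of scope, and on
synthetic reads (no sequencing-error model) exact matching is lossless.
With mismatching reads from a real instrument, counts would be
conservative.

RPM (`count × 1e6 / library size`) is used for junction and miRNA
counts, which have no meaningful length; RPKM (`RPM × 1e3 / length`)
for mRNA/lncRNA. The emulated design names a single "RPM" method for
everything; splitting by class keeps the screening thresholds'
behaviour while staying dimensionally coherent.

## Differential-expression screen

Defaults: Welch's t on `log2(x + ε)`, ε = 1, unpaired, two-sided;
`log2FC = log2((mean_B + ε)/(mean_A + ε))` on arithmetic group means of
the normalized values; status *up* iff `log2FC > 2 ∧ p < 0.01`, *down*
mirrored, both strict. Features with zero variance in both groups get
p = 0 when the means differ and p = 1 otherwise (the limit of the t
test). BH q values are reported as a courtesy column but never gate
status, matching the raw-p screening of the emulated design; a paired
variant and two pooled-count tests (a MARS-style two-proportion z test
and an exact binomial test) sit behind the same interface because the
original analysis names two different packages without choosing.
ε only matters near zero counts; at the simulated abundance range
(log2 means 5–12) its distortion of log2FC is ≪ 0.01.

## ceRNA assembly

Seed matching implements the canonical site vocabulary on miRNA
positions 2–8 (6mer, 7mer-A1, 7mer-m8, 8mer, with 8mer > 7mer-m8 >
7mer-A1 > 6mer precedence per site). Externally supplied interaction
TSVs in the same schema are accepted wherever predicted tables are,
so database exports can replace the emulation. Correlation is Pearson
across all samples pooled (n = 18 by default; a per-group option
exists), p from the t transform of r, BH adjustment over exactly the
tested pair set — pairs are only formed between differentially
expressed, target-sharing ceRNA/mRNA candidates, so the multiplicity
burden reflects the actual hypothesis set. Gates are strict
(`r > 0.9`, `adj_p < 0.1`). A triplet requires all three members DE,
ceRNA and mRNA sharing the sub-network direction, and — under the
default sponge rule — the miRNA regulated oppositely; triplets excluded
solely by the miRNA-direction rule are logged so the permissive reading
(`mirna_rule="any"`) stays auditable. Zero-variance expression vectors
make r undefined; such pairs are skipped and reported, not scored.

Enrichment is over-representation (upper-tail hypergeometric) of
network mRNAs against GMT sets within an explicit universe, flagged at
raw p < 0.05 with BH q reported. The named ranked-list enrichment
statistic is out of scope: the screened input is a set, not a ranking.

## Synthetic cohort: what it emulates

The generator mirrors a paired 9-vs-9 PBMC design (group A pre-, group
B post-treatment) profiled with 150 bp reads. Defaults: two 100 kb
chromosomes carrying 40 mRNA, 14 lncRNA and 16 miRNA genes (3–5 exons,
GT..AG consensus at every internal boundary); 50 planted circRNAs at
exon-pair slots with junction depths 10–20 and overhangs 20–130 nt;
20 decoys, each violating exactly one calling rule (wrong chromosome,
> 1 Mb separation, opposite strand, linear order, single read, weak
motif). The > 1 Mb decoy cannot exist on a 100 kb chromosome, so the
genome carries an auxiliary gene-free 1.05 Mb chromosome solely to host
it. Junction reads are genomic-flank reads around the planted junction
(no isoform structure), written as SAM primary + supplementary records
with constant Q30 qualities; there is no sequencing-error, duplicate or
insert-size model.

Expression is log-normal: `log2 x = μ_f + β_f·(g_s + u_s) + N(0, σ)`,
with μ_f ~ U(5, 12), β_f the planted log2 fold change (±3 for DE
features, 0 otherwise), g the 0/1 group indicator and u a per-feature
latent sample factor (SD 0.4). Triplet members share their u exactly —
that drives within-triplet correlation to 1 in the noiseless limit —
while every other DE feature draws its own, which caps the pooled
correlation between unrelated DE features near
`0.25/(0.25+0.4²) ≈ 0.61`, well under the 0.9 gate. Two constructions
make noiseless recovery exact rather than approximate for every seed:
u is centred within each group, and group B's u values are a
permutation of group A's, so both groups carry the same multiset and
arithmetic-mean fold changes equal 2^β exactly at zero noise
(arithmetic means of heavy-tailed log-normals would otherwise wobble
by enough to cross the |log2FC| > 2 cut). A rounded negative-binomial
count option exists behind `count_model="negbin"`; the noiseless-limit
guarantees hold only for the log-normal default.

Seed sites are planted as 8mers into exons of the triplet members;
miRNA seeds are drawn to be mutually non-overlapping, and accidental
seed-core matches elsewhere are scrubbed by point mutation. Matches
that cannot be scrubbed are planted sites seen through genomically
overlapping targets (circRNAs share exons with their host gene and
sibling circles); the truth table accounts for them, and triplet mRNAs
are drawn from a reserved circRNA-free gene pool so that this overlap
can never fabricate a triplet. Decoy triplets plant the failure modes
the gates must reject: a non-DE mRNA, a missing ceRNA seed site, and a
same-direction miRNA.

Passing the benchmark therefore shows that the decision logic —
candidate rules, score threshold, overhang rule, screening cuts,
correlation gate, triplet invariant — is implemented exactly, and that
the screens hold their nominal levels on null data. It does not
demonstrate robustness to alignment artefacts, sequencing error,
isoform structure, library-composition effects or count overdispersion,
none of which the generator simulates.

## Problem sizes and determinism

The default benchmark (≈ 1.2 Mb of genome, ~1000 reads, ~120 expression
features × 18 samples, 20 replicate expression draws for the noisy
recovery and calibration checks) was chosen so the full test suite and
the acceptance script each finish in seconds while still planting every
failure mode the thresholds must separate. All randomness flows from a
single integer seed through per-stage derived streams
(`utils.derive_seed`); a fixed config + seed reproduces every artifact
byte-for-byte. Wall-clock timings are the one non-reproducible
quantity and are confined to `run.log`; the run report carries only
deterministic counts plus the config hash that is stamped into every
text artifact.

## Known limitations

* The splice-score scale is a calibration of this package's PWM model,
  not a reproduction of MaxEntScan's units; only the decision structure
  (max-scoring pair, threshold 10) carries over.
* Junction counting ignores mismatches and indels (config-gated
  extension point).
* The circRNA expression matrix used by the network stage comes from
  the expression simulator, keyed to the planted truth; junction counts
  from the SAM path are validated against truth depths separately
  rather than being re-used as the DE input.
* Real-data mode consumes the documented SAM/FASTA/TSV/GMT formats but
  has only been exercised on round-trips of the generator's own output.
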