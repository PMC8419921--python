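"""Junction quantification and expression normalization.

A circular junction cannot be counted against the linear genome, so for
each call the sequence 5' of the back-splice acceptor is concatenated
after the sequence 3' of the donor to form a linear pseudo-reference with
the junction at its centre. Reads are counted for a circRNA when their
match crosses that centre with at least ``min_overhang`` matched
nucleotides on both sides (default 6 nt). Expression is normalized as RPM
(reads per million mapped) for junction/miRNA counts, which have no
meaningful length, and RPKM (additionally per kilobase of feature) for
mRNA/lncRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .utils import revcomp


@dataclass
class JunctionReference:
    """Fixed-length pseudo-sequence with the back-splice junction at centre."""

    circ_id: str
    sequence: str
    flank: int          # junction offset == flank exactly

    def __post_init__(self):
        if len(self.sequence) != 2 * self.flank:
            raise ValueError("pseudo-sequence length must be 2 x flank")


@dataclass
class ExpressionMatrix:
    """Features x samples abundances for one RNA class, with group labels."""

    rna_class: str
    values: pd.DataFrame            # features x samples
    groups: pd.Series               # sample -> 'A' | 'B'
    kind: str = "abundance"         # raw | rpm | rpkm | abundance
    library_sizes: pd.Series | None = None

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")

    def samples_in_group(self, group: str) -> list:
        return [s for s in self.values.columns if self.groups[s] == group]

    def swap_groups(self) -> "ExpressionMatrix":
        flipped = self.groups.map({"A": "B", "B": "A"})
        return ExpressionMatrix(rna_class=self.rna_class, values=self.values,
                                groups=flipped, kind=self.kind,
                                library_sizes=self.library_sizes)

    def to_tsv(self, path, header_comments: list | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_comments or []:
                fh.write(f"# {line}\n")
            fh.write("feature_id\t" + "\t".join(self.values.columns) + "\n")
            fh.write("group\t" + "\t".join(self.groups[c] for c in
                                           self.values.columns) + "\n")
            for fid, row in self.values.iterrows():
                fh.write(fid + "\t" + "\t".join(format(v, ".10g") for v in row)
                         + "\n")

    @classmethod
    def read_tsv(cls, path, rna_class: str = "mRNA",
                 kind: str = "abundance") -> "ExpressionMatrix":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
        samples = lines[0].split("\t")[1:]
        glabels = lines[1].split("\t")[1:]
        recs, index = [], []
        for ln in lines[2:]:
            parts = ln.split("\t")
            index.append(parts[0])
            recs.append([float(v) for v in parts[1:]])
        values = pd.DataFrame(recs, index=index, columns=samples)
        groups = pd.Series(glabels, index=samples, name="group")
        return cls(rna_class=rna_class, values=values, groups=groups, kind=kind)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_junction_reference(call, genome, flank: int = 150) -> JunctionReference:
    """Spell the circular junction: donor-side flank then acceptor-side flank.

    For a plus-strand call spanning ``[start, end)`` the pseudo-sequence is
    ``genome[end-flank:end] + genome[start:start+flank]``; minus-strand
    calls are the reverse complement of that construction. Calls nearer
    than ``flank`` to a chromosome edge are truncated symmetrically.
    """
    seq = genome.chromosomes[call.chrom]
    span = call.end - call.start
    # flank may not run past the opposite junction edge or the chromosome
    eff = min(flank, span, call.end, len(seq) - call.start)
    if eff < flank:
        warnings.warn(f"{call.circ_id}: flank truncated to {eff} nt "
                      "(chromosome edge or short circle)")
    pseudo = seq[call.end - eff:call.end] + seq[call.start:call.start + eff]
    if call.strand == "-":
        pseudo = revcomp(pseudo)
    return JunctionReference(circ_id=call.circ_id, sequence=pseudo, flank=eff)


def count_junction_reads(refs: list, reads, min_overhang: int = 6) -> pd.DataFrame:
    """Count reads crossing each junction with >= min_overhang on both sides.

    ``reads`` is either a list of read sequences (one unnamed sample) or a
    mapping ``sample -> list of sequences``. Matching is exact substring
    matching of the read (or its reverse complement) against the
    pseudo-reference; a read counts at most once per circRNA.
    """
    if not isinstance(reads, dict):
        reads = {"sample": list(reads)}
    counts = pd.DataFrame(0, index=[r.circ_id for r in refs],
                          columns=list(reads), dtype=int)
    for sample, pool in reads.items():
        for ref in refs:
            n = 0
            for seq in pool:
                if _crosses_junction(ref, seq, min_overhang) or \
                        _crosses_junction(ref, revcomp(seq), min_overhang):
                    n += 1
            counts.loc[ref.circ_id, sample] = n
    return counts


def _crosses_junction(ref: JunctionReference, seq: str, min_overhang: int) -> bool:
    idx = ref.sequence.find(seq)
    while idx != -1:
        left = ref.flank - idx
        right = idx + len(seq) - ref.flank
        if left >= min_overhang and right >= min_overhang:
            return True
        idx = ref.sequence.find(seq, idx + 1)
    return False


def normalize(raw_counts: pd.DataFrame, feature_lengths: pd.Series | None = None,
              library_sizes: pd.Series | None = None, method: str = "rpm",
              rna_class: str = "circRNA",
              groups: pd.Series | None = None) -> ExpressionMatrix:
    """RPM (count * 1e6 / library) or RPKM (RPM * 1e3 / length) matrices.

    ``library_sizes`` defaults to per-sample column sums; RPKM requires
    ``feature_lengths`` (nt) for every feature.
    """
    if library_sizes is None:
        library_sizes = raw_counts.sum(axis=0)
    bad = [s for s in raw_counts.columns if library_sizes[s] <= 0]
    if bad:
        raise ValueError(f"zero library size for sample(s): {bad}")
    rpm = raw_counts * 1e6 / library_sizes
    if method == "rpm":
        values = rpm
    elif method == "rpkm":
        if feature_lengths is None:
            raise ValueError("rpkm normalization requires feature lengths")
        lengths = feature_lengths.reindex(raw_counts.index)
        if lengths.isna().any():
            raise ValueError("missing feature lengths for: "
                             f"{lengths[lengths.isna()].index.tolist()}")
        values = rpm.mul(1e3 / lengths, axis=0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if groups is None:
        groups = pd.Series("A", index=raw_counts.columns, name="group")
    return ExpressionMatrix(rna_class=rna_class, values=values, groups=groups,
                            kind=method, library_sizes=library_sizes)
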