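"""Position-weight-matrix splice-site strength scoring.

Back-splice junctions are refined by scoring candidate donor and acceptor
sites and keeping the pair with the highest combined splicing strength.
The scorer is a log-odds PWM over the standard splice-site windows:

* donor: 9 nt, 3 exonic + 6 intronic, consensus ``CAG|GTAAGT``;
* acceptor: 23 nt, 20 intronic + 3 exonic, polypyrimidine tract ending
  in the invariant ``AG`` dinucleotide.

Scores are log2 odds against a uniform background, multiplied by a scale
factor stored with the model so that a perfect consensus donor+acceptor
pair scores 20.0 and random sequence scores far below the call threshold
of 10. The model is loaded from a JSON file, so a differently trained
matrix (or a maximum-entropy table exported to the same shape) can be
dropped in without code changes.

Genomic coordinate conventions (0-based half-open, ``pos`` is the exon
boundary itself):

* plus-strand donor at ``d``: window ``seq[d-3 : d+6]`` (intron starts at d);
* plus-strand acceptor at ``a``: window ``seq[a-20 : a+3]`` (exon starts at a);
* minus-strand sites use the reverse complement of the mirrored window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .utils import BASES, revcomp

DONOR_LEN = 9
DONOR_EXONIC = 3
ACCEPTOR_LEN = 23
ACCEPTOR_EXONIC = 3

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class SpliceSiteModel:
    """PWM donor/acceptor scorer with a calibrated score scale."""

    donor: np.ndarray          # (9, 4) column-stochastic over ACGT
    acceptor: np.ndarray       # (23, 4)
    background: np.ndarray     # (4,)
    scale: float
    _donor_lo: np.ndarray = field(init=False, repr=False)
    _acceptor_lo: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.validate()
        self._donor_lo = np.log2(self.donor / self.background)
        self._acceptor_lo = np.log2(self.acceptor / self.background)

    # -- construction -------------------------------------------------
    @classmethod
    def load(cls, path=None) -> "SpliceSiteModel":
        """Load a model JSON; ``path=None`` loads the packaged default."""
        if path is None:
            ref = resources.files("circnet.data").joinpath("splice_model.json")
            raw = json.loads(ref.read_text())
        else:
            with open(path) as fh:
                raw = json.load(fh)
        donor = np.array([[col[b] for b in BASES] for col in raw["donor"]])
        acceptor = np.array([[col[b] for b in BASES] for col in raw["acceptor"]])
        bg = np.array([raw["background"][b] for b in BASES])
        return cls(donor=donor, acceptor=acceptor, background=bg,
                   scale=float(raw["scale"]))

    def validate(self) -> None:
        if self.donor.shape != (DONOR_LEN, 4):
            raise ValueError(f"donor PWM must be {DONOR_LEN}x4")
        if self.acceptor.shape != (ACCEPTOR_LEN, 4):
            raise ValueError(f"acceptor PWM must be {ACCEPTOR_LEN}x4")
        for name, pwm in (("donor", self.donor), ("acceptor", self.acceptor)):
            if np.any(pwm <= 0):
                raise ValueError(f"{name} PWM has non-positive entries")
            if np.any(np.abs(pwm.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError(f"{name} PWM columns must sum to 1")
        # invariant GT / AG dinucleotides must be modal
        g, t, a = _BASE_IDX["G"], _BASE_IDX["T"], _BASE_IDX["A"]
        if not (self.donor[DONOR_EXONIC].argmax() == g
                and self.donor[DONOR_EXONIC + 1].argmax() == t):
            raise ValueError("donor PWM consensus must carry GT at intron start")
        if not (self.acceptor[ACCEPTOR_LEN - ACCEPTOR_EXONIC - 2].argmax() == a
                and self.acceptor[ACCEPTOR_LEN - ACCEPTOR_EXONIC - 1].argmax() == g):
            raise ValueError("acceptor PWM consensus must carry AG at intron end")

    # -- consensus ----------------------------------------------------
    def consensus_donor(self) -> str:
        return "".join(BASES[i] for i in self.donor.argmax(axis=1))

    def consensus_acceptor(self) -> str:
        return "".join(BASES[i] for i in self.acceptor.argmax(axis=1))

    # -- scoring ------------------------------------------------------
    def _score(self, window: str, lo: np.ndarray) -> float:
        if len(window) != lo.shape[0]:
            return float("-inf")
        total = 0.0
        for i, base in enumerate(window):
            j = _BASE_IDX.get(base)
            if j is None:
                return float("-inf")
            total += lo[i, j]
        return self.scale * total

    def score_donor_window(self, window: str) -> float:
        return self._score(window, self._donor_lo)

    def score_acceptor_window(self, window: str) -> float:
        return self._score(window, self._acceptor_lo)

    def donor_score(self, chrom_seq: str, pos: int, strand: str) -> float:
        """Score the donor site whose exon boundary sits at ``pos``."""
        if strand == "+":
            lo, hi = pos - DONOR_EXONIC, pos + (DONOR_LEN - DONOR_EXONIC)
            if lo < 0 or hi > len(chrom_seq):
                return float("-inf")
            return self.score_donor_window(chrom_seq[lo:hi])
        lo, hi = pos - (DONOR_LEN - DONOR_EXONIC), pos + DONOR_EXONIC
        if lo < 0 or hi > len(chrom_seq):
            return float("-inf")
        return self.score_donor_window(revcomp(chrom_seq[lo:hi]))

    def acceptor_score(self, chrom_seq: str, pos: int, strand: str) -> float:
        """Score the acceptor site whose exon boundary sits at ``pos``."""
        intronic = ACCEPTOR_LEN - ACCEPTOR_EXONIC
        if strand == "+":
            lo, hi = pos - intronic, pos + ACCEPTOR_EXONIC
            if lo < 0 or hi > len(chrom_seq):
                return float("-inf")
            return self.score_acceptor_window(chrom_seq[lo:hi])
        lo, hi = pos - ACCEPTOR_EXONIC, pos + intronic
        if lo < 0 or hi > len(chrom_seq):
            return float("-inf")
        return self.score_acceptor_window(revcomp(chrom_seq[lo:hi]))
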