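"""Small shared helpers: DNA alphabet ops, deterministic hashing, TSV headers."""

from __future__ import annotations

import hashlib
import json

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N passed through)."""
    return seq.translate(_COMP)[::-1]


def comp(seq: str) -> str:
    return seq.translate(_COMP)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable config; stamped into artifacts."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def derive_seed(seed: int, tag: str) -> int:
    """Derive an independent 31-bit stream seed from a master seed and a stage tag."""
    h = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)
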