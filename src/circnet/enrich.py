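"""Over-representation analysis (ORA) of network gene sets.

Functional annotation arrives as GMT-style gene sets (GO terms, KEGG
pathways, or anything else); the query -- typically the mRNA nodes of an
assembled ceRNA sub-network -- is tested for over-representation in each
set with the upper-tail hypergeometric probability

    p = P[X >= k],  X ~ Hypergeom(N, K, n)

where N is the universe size, K the term size within the universe, n the
query size and k the observed overlap. Significance is flagged at raw
p < 0.05; BH q values are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationSet:
    term_id: str
    term_name: str
    members: frozenset
    category: str = "pathway"   # BP | MF | CC | pathway


def read_gmt(path) -> list:
    """Parse GMT: term, description, tab-separated members (one per line)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(AnnotationSet(term_id=parts[0], term_name=parts[1],
                                      members=frozenset(p for p in parts[2:]
                                                        if p)))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write(s.term_id + "\t" + s.term_name + "\t"
                     + "\t".join(sorted(s.members)) + "\n")


def ora_test(query, annotation, universe, p_cut: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each annotation set.

    ``query`` must be a non-empty subset of ``universe``; annotation
    members outside the universe are ignored when sizing terms. Results
    are sorted by p value then term id.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query gene set")
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query genes absent from universe: {stray}")
    N, n = len(universe), len(query)
    rows = []
    for s in annotation:
        members = s.members & universe
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": s.term_id, "term_name": s.term_name,
                     "k": k, "n": n, "K": K, "N": N, "p_value": p})
    res = pd.DataFrame(rows)
    if len(res):
        res["q_value"] = multipletests(res["p_value"], method="fdr_bh")[1]
        res["significant"] = res["p_value"] < p_cut
        res = res.sort_values(["p_value", "term_id"]).reset_index(drop=True)
    return res
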