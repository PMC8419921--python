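"""ceRNA network assembly: seed-match targets, co-expression gating, triplets.

A competing-endogenous-RNA (ceRNA) triplet is a (circRNA-or-lncRNA,
miRNA, mRNA) trio in which the ceRNA and the mRNA share a binding site
for the miRNA and are co-expressed. The pipeline emulates the external
target databases with canonical TargetScan-style seed matching, gates
ceRNA-mRNA pairs on Pearson correlation (r > 0.9 with BH-adjusted
p < 0.1, across all samples pooled), and requires a coherent
differential-expression pattern: ceRNA and mRNA share the sub-network's
direction while the shared miRNA is regulated in the opposite direction
(the sponge logic; a permissive variant that only requires the miRNA to
be differentially expressed is available behind ``mirna_rule``).

Seed-site vocabulary (miRNA positions are 1-based, 5'->3'):

* 6mer      -- target complements miRNA positions 2-7;
* 7mer-m8   -- 6mer plus pairing at position 8;
* 7mer-A1   -- 6mer plus an A opposite position 1;
* 8mer      -- both extensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .utils import comp, revcomp

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
SUBNET_LABELS = ("circ-up", "circ-down", "lnc-up", "lnc-down")

_CLASS_PREFIX = {"circRNA": "circ", "lncRNA": "lnc"}


def _clean(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    if set(s) - set("ACGT"):
        raise ValueError(f"{what}: non-ACGU/ACGT symbols in sequence")
    return s


# ---------------------------------------------------------------------------
# target prediction
# ---------------------------------------------------------------------------

def predict_targets(mirnas: dict, targets: dict) -> pd.DataFrame:
    """Scan every target for canonical seed sites of every miRNA.

    ``mirnas`` maps id -> sequence (>= 8 nt); ``targets`` maps
    id -> (sequence, rna_class). Returns a frame with one row per site:
    mirna_id, target_id, target_class, site_type, position (0-based
    position of the site's 5'-most paired base on the target).
    """
    rows = []
    for mid in sorted(mirnas):
        mseq = _clean(mirnas[mid], mid)
        if len(mseq) < 8:
            raise ValueError(f"{mid}: miRNA shorter than 8 nt")
        core = revcomp(mseq[1:7])          # complements positions 2-7
        m8_base = comp(mseq[7])            # pairs position 8, 5' of the core
        for tid in sorted(targets):
            tseq_raw, tclass = targets[tid]
            tseq = _clean(tseq_raw, tid)
            if len(tseq) < 8:
                raise ValueError(f"{tid}: target shorter than 8 nt")
            idx = tseq.find(core)
            while idx != -1:
                has_m8 = idx >= 1 and tseq[idx - 1] == m8_base
                has_a1 = idx + 6 < len(tseq) and tseq[idx + 6] == "A"
                if has_m8 and has_a1:
                    stype = "8mer"
                elif has_m8:
                    stype = "7mer-m8"
                elif has_a1:
                    stype = "7mer-A1"
                else:
                    stype = "6mer"
                rows.append({"mirna_id": mid, "target_id": tid,
                             "target_class": tclass, "site_type": stype,
                             "position": idx - (1 if has_m8 else 0)})
                idx = tseq.find(core, idx + 1)
    return pd.DataFrame(rows, columns=["mirna_id", "target_id",
                                       "target_class", "site_type",
                                       "position"])


# ---------------------------------------------------------------------------
# co-expression gating
# ---------------------------------------------------------------------------

def pearson_with_p(x: np.ndarray, y: np.ndarray):
    """Closed-form Pearson r and the two-sided p from its t transform."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return np.nan, np.nan
    r = float((xc * yc).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    from scipy import stats
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlate_pairs(values_x: pd.DataFrame, values_y: pd.DataFrame,
                    pairs, r_cut: float = 0.9, adjp_cut: float = 0.1):
    """Pearson-correlate candidate (x, y) pairs across all samples pooled.

    BH adjustment runs over exactly the tested pair set; an edge is
    retained when r > r_cut and adjusted p < adjp_cut (both strict).
    Zero-variance vectors make r undefined; those pairs are skipped and
    reported separately. Returns ``(edges, skipped)``.
    """
    if not values_x.columns.equals(values_y.columns):
        values_y = values_y[values_x.columns]
    if values_x.shape[1] < 3:
        raise ValueError("need at least 3 paired samples")
    rows, skipped = [], []
    for id_x, id_y in pairs:
        x = values_x.loc[id_x].to_numpy(dtype=float)
        y = values_y.loc[id_y].to_numpy(dtype=float)
        r, p = pearson_with_p(x, y)
        if np.isnan(r):
            skipped.append({"id_x": id_x, "id_y": id_y,
                            "reason": "zero_variance"})
            continue
        rows.append({"id_x": id_x, "id_y": id_y, "pearson_r": r, "p_value": p})
    edges = pd.DataFrame(rows, columns=["id_x", "id_y", "pearson_r", "p_value"])
    if len(edges):
        edges["adj_p"] = multipletests(edges["p_value"], method="fdr_bh")[1]
        edges["retained"] = (edges["pearson_r"] > r_cut) & \
                            (edges["adj_p"] < adjp_cut)
    else:
        edges["adj_p"] = pd.Series(dtype=float)
        edges["retained"] = pd.Series(dtype=bool)
    return edges, skipped


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

@dataclass
class CeRNANetwork:
    """Assembled triplets plus per-sub-network graphs."""

    triplets: pd.DataFrame
    subnetworks: dict = field(default_factory=dict)   # label -> nx.Graph
    excluded_by_mirna_rule: pd.DataFrame = field(default_factory=pd.DataFrame)

    def union_graph(self) -> nx.Graph:
        g = nx.Graph()
        for label in sorted(self.subnetworks):
            sub = self.subnetworks[label]
            for n, attrs in sorted(sub.nodes(data=True)):
                g.add_node(n, **attrs)
            for u, v, attrs in sorted(sub.edges(data=True)):
                g.add_edge(u, v, **attrs)
        return g

    def summary(self) -> pd.DataFrame:
        rows = []
        for label in SUBNET_LABELS:
            g = self.subnetworks.get(label, nx.Graph())
            by_class = {"circRNA": 0, "lncRNA": 0, "miRNA": 0, "mRNA": 0}
            for _n, attrs in g.nodes(data=True):
                by_class[attrs["rna_class"]] += 1
            rows.append({"subnetwork": label, **{f"n_{k}": v for k, v
                                                 in by_class.items()},
                         "n_edges": g.number_of_edges(),
                         "n_triplets": int((self.triplets["subnetwork"] ==
                                            label).sum())
                         if len(self.triplets) else 0})
        return pd.DataFrame(rows)


def assemble_network(de_records: pd.DataFrame, target_edges: pd.DataFrame,
                     coexp_edges: pd.DataFrame,
                     mirna_rule: str = "opposite") -> CeRNANetwork:
    """Assemble circRNA/lncRNA-miRNA-mRNA triplets passing all gates.

    ``de_records`` must cover every id referenced by the edge tables
    (hard error otherwise). A triplet requires: both target edges, a
    retained co-expression edge between ceRNA and mRNA, all three members
    differentially expressed, ceRNA and mRNA sharing a direction, and --
    under the default sponge rule -- the miRNA regulated oppositely.
    Triplets excluded solely by the miRNA-direction rule are logged.
    """
    if mirna_rule not in ("opposite", "any"):
        raise ValueError("mirna_rule must be 'opposite' or 'any'")
    status = dict(zip(de_records["feature_id"], de_records["status"]))
    referenced = set(target_edges["mirna_id"]) | set(target_edges["target_id"])
    if len(coexp_edges):
        referenced |= set(coexp_edges["id_x"]) | set(coexp_edges["id_y"])
    missing = sorted(referenced - set(status))
    if missing:
        raise KeyError(f"ids present in edges but absent from DE table: "
                       f"{missing}")
    rna_class = dict(zip(de_records["feature_id"], de_records["rna_class"]))

    retained = coexp_edges[coexp_edges["retained"]] if len(coexp_edges) else \
        coexp_edges
    coexp_lookup = {(r.id_x, r.id_y): r for r in retained.itertuples()}

    cerna_edges = target_edges[target_edges["target_class"]
                               .isin(("circRNA", "lncRNA"))]
    mrna_edges = target_edges[target_edges["target_class"] == "mRNA"]

    rows, excluded = [], []
    for mid, ce_grp in cerna_edges.groupby("mirna_id", sort=True):
        m_grp = mrna_edges[mrna_edges["mirna_id"] == mid]
        if m_grp.empty:
            continue
        for cerna_id in sorted(ce_grp["target_id"].unique()):
            for mrna_id in sorted(m_grp["target_id"].unique()):
                edge = coexp_lookup.get((cerna_id, mrna_id)) or \
                    coexp_lookup.get((mrna_id, cerna_id))
                if edge is None:
                    continue
                st_c, st_m, st_mi = status[cerna_id], status[mrna_id], \
                    status[mid]
                if "ns" in (st_c, st_m, st_mi) or st_c != st_m:
                    continue
                row = {"cerna_id": cerna_id,
                       "cerna_class": rna_class[cerna_id],
                       "mirna_id": mid, "mrna_id": mrna_id,
                       "direction": st_c,
                       "pearson_r": edge.pearson_r, "adj_p": edge.adj_p,
                       "subnetwork": f"{_CLASS_PREFIX[rna_class[cerna_id]]}"
                                     f"-{st_c}"}
                if mirna_rule == "opposite" and st_mi == st_c:
                    excluded.append({**row, "mirna_status": st_mi})
                    continue
                rows.append(row)
    triplets = pd.DataFrame(rows, columns=["cerna_id", "cerna_class",
                                           "mirna_id", "mrna_id", "direction",
                                           "pearson_r", "adj_p", "subnetwork"])
    subnetworks = {}
    for label in SUBNET_LABELS:
        sub = triplets[triplets["subnetwork"] == label] if len(triplets) \
            else triplets
        if not len(sub):
            continue
        g = nx.Graph(label=label)
        for t in sub.itertuples():
            for node in (t.cerna_id, t.mirna_id, t.mrna_id):
                g.add_node(node, rna_class=rna_class[node],
                           status=status[node])
            g.add_edge(t.mirna_id, t.cerna_id, type="mirna-target")
            g.add_edge(t.mirna_id, t.mrna_id, type="mirna-target")
            g.add_edge(t.cerna_id, t.mrna_id, type="coexpression")
        subnetworks[label] = g
    return CeRNANetwork(triplets=triplets, subnetworks=subnetworks,
                        excluded_by_mirna_rule=pd.DataFrame(excluded))


# ---------------------------------------------------------------------------
# import/export
# ---------------------------------------------------------------------------

def export_network(net, path, fmt: str = "sif") -> None:
    """Write the union network as SIF or GraphML (round-trip safe)."""
    graph = net.union_graph() if isinstance(net, CeRNANetwork) else net
    if fmt == "sif":
        with open(path, "w") as fh:
            seen = set()
            for u, v, attrs in sorted(graph.edges(data=True)):
                a, b = sorted((u, v))
                fh.write(f"{a}\t{attrs.get('type', 'interacts')}\t{b}\n")
                seen.update((a, b))
            for n in sorted(graph.nodes):
                if n not in seen:
                    fh.write(f"{n}\n")
    elif fmt == "graphml":
        ordered = nx.Graph()
        for n, attrs in sorted(graph.nodes(data=True)):
            ordered.add_node(n, **attrs)
        for u, v, attrs in sorted(graph.edges(data=True)):
            ordered.add_edge(u, v, **attrs)
        nx.write_graphml(ordered, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def import_network(path, fmt: str = "sif") -> nx.Graph:
    if fmt == "sif":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1 and parts[0]:
                    g.add_node(parts[0])
                elif len(parts) == 3:
                    g.add_edge(parts[0], parts[2], type=parts[1])
        return g
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown network format {fmt!r}")
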