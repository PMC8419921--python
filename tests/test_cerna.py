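"""Seed matching, co-expression gating, triplet assembly, export."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circnet import cerna as cn
from circnet.utils import comp, random_dna, revcomp

MIRNA = "UGAGGUAGUAGGUUGUAUAGUU"  # let-7a; seed 2-7 = GAGGUA


def _target_with(site: str, rng):
    return random_dna(rng, 30) + site + random_dna(rng, 30)


class TestSeedMatching:
    core = revcomp(MIRNA.replace("U", "T")[1:7])          # TACCTC
    m8 = comp(MIRNA.replace("U", "T")[7])                  # pairs position 8

    @pytest.mark.parametrize("site,expected", [
        (m8 + core + "A", "8mer"),
        (m8 + core + "G", "7mer-m8"),
        ("G" + core + "A", "7mer-A1"),
        ("G" + core + "G", "6mer"),
    ])
    def test_site_type_classification(self, site, expected):
        rng = np.random.default_rng(3)
        target = _target_with(site, rng)
        while self.core in target[:30] or self.core in target[-30:]:
            target = _target_with(site, rng)
        edges = cn.predict_targets({"let7": MIRNA},
                                   {"t": (target, "mRNA")})
        assert list(edges["site_type"]) == [expected]

    def test_no_complement_no_edges(self):
        target = "A" * 50
        edges = cn.predict_targets({"let7": MIRNA}, {"t": (target, "mRNA")})
        assert edges.empty

    def test_invalid_symbols_raise(self):
        with pytest.raises(ValueError, match="non-ACGU"):
            cn.predict_targets({"m": "ACGUNACGU"}, {"t": ("ACGT" * 5, "mRNA")})
        with pytest.raises(ValueError, match="shorter"):
            cn.predict_targets({"m": "ACGU"}, {"t": ("ACGT" * 5, "mRNA")})

    def test_edges_equal_sliding_window_oracle(self):
        """On random sequences the edge set equals an exhaustive, position-by-
        position re-derivation of the seed rules."""
        rng = np.random.default_rng(11)
        mirnas = {f"m{i}": random_dna(rng, 22) for i in range(10)}
        targets = {f"t{j}": (random_dna(rng, 120), "mRNA") for j in range(50)}
        edges = cn.predict_targets(mirnas, targets)
        got = set(zip(edges["mirna_id"], edges["target_id"],
                      edges["position"], edges["site_type"]))
        expected = set()
        for mid, mseq in mirnas.items():
            for tid, (tseq, _c) in targets.items():
                for i in range(len(tseq) - 5):
                    if tseq[i:i + 6] != revcomp(mseq[1:7]):
                        continue
                    m8 = i >= 1 and tseq[i - 1] == comp(mseq[7])
                    a1 = i + 6 < len(tseq) and tseq[i + 6] == "A"
                    st = {(1, 1): "8mer", (1, 0): "7mer-m8",
                          (0, 1): "7mer-A1", (0, 0): "6mer"}[(m8, a1)]
                    expected.add((mid, tid, i - (1 if m8 else 0), st))
        assert got == expected


class TestCorrelation:
    def test_identical_vectors_r_one(self):
        vx = pd.DataFrame([[1.0, 2, 3, 4, 5]], index=["x"])
        vy = pd.DataFrame([[2.0, 4, 6, 8, 10]], index=["y"])
        edges, skipped = cn.correlate_pairs(vx, vy, [("x", "y")])
        assert edges.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert bool(edges.loc[0, "retained"])

    def test_zero_variance_pair_skipped(self):
        vx = pd.DataFrame([[1.0, 1, 1, 1]], index=["x"])
        vy = pd.DataFrame([[2.0, 4, 6, 8]], index=["y"])
        edges, skipped = cn.correlate_pairs(vx, vy, [("x", "y")])
        assert edges.empty
        assert skipped == [{"id_x": "x", "id_y": "y",
                            "reason": "zero_variance"}]

    def test_r_p_match_scipy_and_bh_matches_step_up(self):
        """Closed-form r/p against scipy.stats.pearsonr and BH against a
        hand-rolled step-up, both to 1e-12, on 100 random pairs."""
        rng = np.random.default_rng(7)
        n = 18
        vx = pd.DataFrame(rng.normal(size=(100, n)),
                          index=[f"x{i}" for i in range(100)])
        vy = pd.DataFrame(rng.normal(size=(100, n)),
                          index=[f"y{i}" for i in range(100)])
        pairs = [(f"x{i}", f"y{i}") for i in range(100)]
        edges, _ = cn.correlate_pairs(vx, vy, pairs)
        for row in edges.itertuples():
            r_ref, p_ref = stats.pearsonr(vx.loc[row.id_x], vy.loc[row.id_y])
            assert abs(row.pearson_r - r_ref) < 1e-12
            assert abs(row.p_value - p_ref) < 1e-12
        p = edges["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(m)
        prev = 1.0
        for rank, idx in reversed(list(enumerate(order))):
            prev = min(prev, p[idx] * m / (rank + 1))
            adj[idx] = prev
        assert np.max(np.abs(adj - edges["adj_p"].to_numpy())) < 1e-12

    def test_too_few_samples_raises(self):
        vx = pd.DataFrame([[1.0, 2]], index=["x"])
        vy = pd.DataFrame([[1.0, 2]], index=["y"])
        with pytest.raises(ValueError, match="3"):
            cn.correlate_pairs(vx, vy, [("x", "y")])

    def test_gate_monotonicity(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(40, 18))
        vx = pd.DataFrame(base + 0.1 * rng.normal(size=(40, 18)),
                          index=[f"x{i}" for i in range(40)])
        vy = pd.DataFrame(base + 0.1 * rng.normal(size=(40, 18)),
                          index=[f"y{i}" for i in range(40)])
        pairs = [(f"x{i}", f"y{i}") for i in range(40)]
        loose, _ = cn.correlate_pairs(vx, vy, pairs, r_cut=0.8, adjp_cut=0.2)
        tight, _ = cn.correlate_pairs(vx, vy, pairs, r_cut=0.95,
                                      adjp_cut=0.05)
        kept = lambda e: set(map(tuple, e.loc[e["retained"],
                                              ["id_x", "id_y"]].values))
        assert kept(tight) <= kept(loose)


def _toy_inputs(mirna_status="down"):
    de = pd.DataFrame([
        {"feature_id": "circ1", "rna_class": "circRNA", "status": "up"},
        {"feature_id": "mir1", "rna_class": "miRNA", "status": mirna_status},
        {"feature_id": "gene1", "rna_class": "mRNA", "status": "up"},
        {"feature_id": "gene2", "rna_class": "mRNA", "status": "ns"},
    ])
    targets = pd.DataFrame([
        {"mirna_id": "mir1", "target_id": "circ1", "target_class": "circRNA",
         "site_type": "8mer", "position": 10},
        {"mirna_id": "mir1", "target_id": "gene1", "target_class": "mRNA",
         "site_type": "8mer", "position": 20},
        {"mirna_id": "mir1", "target_id": "gene2", "target_class": "mRNA",
         "site_type": "8mer", "position": 30},
    ])
    coexp = pd.DataFrame([
        {"id_x": "circ1", "id_y": "gene1", "pearson_r": 0.99,
         "p_value": 1e-9, "adj_p": 1e-8, "retained": True},
        {"id_x": "circ1", "id_y": "gene2", "pearson_r": 0.99,
         "p_value": 1e-9, "adj_p": 1e-8, "retained": True},
    ])
    return de, targets, coexp


class TestAssembly:
    def test_valid_triplet_lands_in_circ_up_subnetwork(self):
        net = cn.assemble_network(*_toy_inputs())
        assert len(net.triplets) == 1
        t = net.triplets.iloc[0]
        assert (t.cerna_id, t.mirna_id, t.mrna_id) == ("circ1", "mir1",
                                                       "gene1")
        assert t.subnetwork == "circ-up"
        g = net.subnetworks["circ-up"]
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3

    def test_ns_mrna_excluded(self):
        net = cn.assemble_network(*_toy_inputs())
        assert "gene2" not in set(net.triplets["mrna_id"])

    def test_same_direction_mirna_excluded_and_logged(self):
        net = cn.assemble_network(*_toy_inputs(mirna_status="up"))
        assert net.triplets.empty
        assert len(net.excluded_by_mirna_rule) == 1
        permissive = cn.assemble_network(*_toy_inputs(mirna_status="up"),
                                         mirna_rule="any")
        assert len(permissive.triplets) == 1

    def test_missing_de_id_is_hard_error(self):
        de, targets, coexp = _toy_inputs()
        with pytest.raises(KeyError, match="gene1"):
            cn.assemble_network(de[de["feature_id"] != "gene1"], targets,
                                coexp)

    def test_every_triplet_satisfies_invariant(self, scene):
        from circnet import descreen as d
        from circnet import synthdata as s
        mats = s.simulate_expression(scene.truth, 9, 0.25, seed=31,
                                     config=scene.config)
        de_all = pd.concat([d.de_screen(m) for m in mats.values()],
                           ignore_index=True)
        edges = s.emit_target_tables(scene.genome, scene.truth)
        status = dict(zip(de_all["feature_id"], de_all["status"]))
        values = {fid: m.values.loc[fid] for m in mats.values()
                  for fid in m.values.index}
        pairs = sorted({
            (c, m2) for _mid, grp in edges.groupby("mirna_id")
            for c in grp.loc[grp["target_class"].isin(("circRNA", "lncRNA")),
                             "target_id"]
            for m2 in grp.loc[grp["target_class"] == "mRNA", "target_id"]
            if status[c] != "ns" and status[m2] != "ns"})
        vx = pd.DataFrame({c: values[c] for c, _ in pairs}).T
        vy = pd.DataFrame({m2: values[m2] for _, m2 in pairs}).T
        vx, vy = vx.loc[~vx.index.duplicated()], vy.loc[~vy.index.duplicated()]
        coexp, _ = cn.correlate_pairs(vx, vy, pairs)
        net = cn.assemble_network(de_all, edges, coexp)
        tset = set(zip(edges["mirna_id"], edges["target_id"]))
        for t in net.triplets.itertuples():
            assert (t.mirna_id, t.cerna_id) in tset
            assert (t.mirna_id, t.mrna_id) in tset
            assert status[t.cerna_id] == status[t.mrna_id] == t.direction
            assert status[t.mirna_id] not in ("ns", t.direction)
            assert t.pearson_r > 0.9 and t.adj_p < 0.1


class TestExport:
    def test_sif_three_nodes_three_edges(self, tmp_path):
        net = cn.assemble_network(*_toy_inputs())
        path = tmp_path / "net.sif"
        cn.export_network(net, path, "sif")
        lines = path.read_text().splitlines()
        assert len(lines) == 3
        nodes = {p for l in lines for p in (l.split("\t")[0],
                                            l.split("\t")[2])}
        assert nodes == {"circ1", "mir1", "gene1"}

    @pytest.mark.parametrize("fmt", ["sif", "graphml"])
    def test_export_import_export_idempotent(self, tmp_path, fmt):
        net = cn.assemble_network(*_toy_inputs())
        p1 = tmp_path / f"a.{fmt}"
        p2 = tmp_path / f"b.{fmt}"
        cn.export_network(net, p1, fmt)
        back = cn.import_network(p1, fmt)
        cn.export_network(back, p2, fmt)
        assert p1.read_bytes() == p2.read_bytes()
        assert nx.is_isomorphic(net.union_graph(), back)

    def test_graphml_carries_class_and_status(self, tmp_path):
        net = cn.assemble_network(*_toy_inputs())
        path = tmp_path / "net.graphml"
        cn.export_network(net, path, "graphml")
        g = nx.read_graphml(path)
        for _n, attrs in g.nodes(data=True):
            assert {"rna_class", "status"} <= set(attrs)

    def test_unknown_format_raises(self, tmp_path):
        net = cn.assemble_network(*_toy_inputs())
        with pytest.raises(ValueError, match="format"):
            cn.export_network(net, tmp_path / "x.foo", "foo")
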