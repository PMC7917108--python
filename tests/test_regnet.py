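"""cis/trans edge construction, combination, SA pairs, and degrees."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncregnet.identify import LncRNA
from lncregnet.io_formats import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)
from lncregnet.regnet import (
    RegEdge,
    cis_targets,
    combine_cis_trans,
    degree_tables,
    sa_pairs,
    trans_targets,
)


def _lnc(tid, start, end, strand="+", chrom="chr1", klass="lincRNA"):
    iv = GenomicInterval(chrom, start, end, strand)
    tx = TranscriptModel(tid, iv, [iv])
    return LncRNA(tx, klass)


def _gene(gid, start, end, strand="+", chrom="chr1", biotype="protein_coding"):
    iv = GenomicInterval(chrom, start, end, strand)
    tx = TranscriptModel(gid + ".t", iv, [iv])
    return GeneModel(gid, iv, [tx], biotype=biotype)


class TestCis:
    def test_window_boundaries(self):
        lnc = [_lnc("L", 500_000, 501_000)]
        genes = [
            _gene("overlap", 500_500, 502_000),
            _gene("at_window", 601_000, 602_000),  # gap exactly 100,000
            _gene("beyond", 601_001, 602_000),  # gap 100,001
            _gene("noncoding", 505_000, 506_000, biotype="lncRNA_gene"),
        ]
        edges = cis_targets(lnc, genes, window=100_000)
        by_id = {e.mrna_id: e for e in edges}
        assert by_id["overlap"].distance_bp == 0
        assert by_id["at_window"].distance_bp == 100_000  # inclusive boundary
        assert "beyond" not in by_id
        assert "noncoding" not in by_id

    def test_exclusive_window_option(self):
        lnc = [_lnc("L", 0, 1000)]
        genes = [_gene("g", 101_000, 102_000)]  # gap exactly 100,000
        assert len(cis_targets(lnc, genes, window=100_000, inclusive=True)) == 1
        assert cis_targets(lnc, genes, window=100_000, inclusive=False) == []


def _expr_from(vectors):
    samples = [f"S{i}-1" for i in range(5)]
    df = pd.DataFrame({fid: v for fid, v in vectors.items()}, index=samples).T
    return ExpressionMatrix(df, {s: s.rsplit("-", 1)[0] for s in samples},
                            [f"S{i}" for i in range(5)])


class TestTrans:
    def test_perfect_pair_found_and_r_threshold_is_strict(self):
        x = np.array([2.0, 40.0, 18.0, 8.0, 4.0])
        e = _expr_from({"L1": x, "G1": 3 * x, "G2": np.array([5.0, 4, 9, 2, 7])})
        edges = trans_targets({"L1"}, {"G1", "G2"}, e)
        assert [(ed.lncrna_id, ed.mrna_id) for ed in edges] == [("L1", "G1")]
        assert edges[0].r == pytest.approx(1.0)
        # strictness: a pair whose |r| equals r_min exactly must be dropped
        y = np.array([2.1, 38.0, 20.0, 7.0, 4.5])
        e2 = _expr_from({"L1": x, "G1": y})
        r_exact = abs(trans_targets({"L1"}, {"G1"}, e2, r_min=0.0, p_max=1.0)[0].r)
        assert trans_targets({"L1"}, {"G1"}, e2, r_min=r_exact, p_max=1.0) == []
        assert len(trans_targets({"L1"}, {"G1"}, e2, r_min=r_exact - 1e-9, p_max=1.0)) == 1

    def test_p_threshold_is_strict(self):
        x = np.array([2.0, 40.0, 18.0, 8.0, 4.0])
        y = np.array([2.1, 38.0, 20.0, 7.0, 4.5])
        e = _expr_from({"L1": x, "G1": y})
        p_exact = trans_targets({"L1"}, {"G1"}, e, r_min=0.0, p_max=1.1)[0].p
        assert trans_targets({"L1"}, {"G1"}, e, r_min=0.0, p_max=p_exact) == []

    def test_constant_vector_skipped(self):
        e = _expr_from({"L1": np.ones(5), "G1": np.arange(5.0)})
        assert trans_targets({"L1"}, {"G1"}, e) == []

    def test_matches_all_pairs_bruteforce_oracle(self):
        rng = np.random.default_rng(21)
        shapes = np.array([[2, 40, 18, 8, 4], [30, 6, 4, 3, 2], [8, 8, 9, 8, 8.0]])
        vectors = {}
        for i in range(25):
            base = shapes[i % 3] * rng.uniform(0.5, 2)
            vectors[f"L{i}"] = base * 2 ** rng.normal(0, 0.05, 5)
        for i in range(25):
            base = shapes[i % 3] * rng.uniform(0.5, 2)
            vectors[f"G{i}"] = base * 2 ** rng.normal(0, 0.05, 5)
        e = _expr_from(vectors)
        lset = {f"L{i}" for i in range(25)}
        mset = {f"G{i}" for i in range(25)}
        edges = trans_targets(lset, mset, e)
        got = {(ed.lncrna_id, ed.mrna_id) for ed in edges}
        oracle = set()
        for l in lset:
            for g in mset:
                r, p = stats.pearsonr(vectors[l], vectors[g])
                if abs(r) > 0.95 and p < 0.01:
                    oracle.add((l, g))
        assert got == oracle

    def test_comparison_membership_requires_both_endpoints(self):
        x = np.array([2.0, 40.0, 18.0, 8.0, 4.0])
        e = _expr_from({"L1": x, "G1": 2 * x})
        comps = {
            "T1_vs_control": ({"L1"}, {"G1"}),
            "T4_vs_control": ({"L1"}, set()),
        }
        edges = trans_targets({"L1"}, {"G1"}, e, de_by_comparison=comps)
        assert edges[0].comparisons_present == frozenset({"T1_vs_control"})


class TestCombineAndSA:
    def test_combine_intersection(self):
        c = [RegEdge("L1", "G1", "cis", distance_bp=0),
             RegEdge("L2", "G2", "cis", distance_bp=5)]
        t = [RegEdge("L1", "G1", "trans", r=0.99, p=1e-4),
             RegEdge("L3", "G3", "trans", r=0.97, p=1e-3)]
        both = combine_cis_trans(c, t)
        assert len(both) == 1
        e = both[0]
        assert e.mode == "both" and e.distance_bp == 0 and e.r == 0.99
        assert len(both) <= min(len(c), len(t))
        assert combine_cis_trans(c, []) == []

    def test_sa_requires_antisense_overlap(self):
        lncs = [
            _lnc("L_ov", 1000, 2000, "-"),
            _lnc("L_same", 3000, 4000, "+"),
            _lnc("L_far", 10_000, 11_000, "-"),
        ]
        genes = [
            _gene("G_ov", 1500, 2500, "+"),
            _gene("G_same", 3500, 4500, "+"),
            _gene("G_far", 16_000, 17_000, "+"),
        ]
        edges = [
            RegEdge("L_ov", "G_ov", "cis", distance_bp=0),
            RegEdge("L_same", "G_same", "cis", distance_bp=0),
            RegEdge("L_far", "G_far", "cis", distance_bp=5000),
        ]
        sa = sa_pairs(edges, lncs, genes)
        assert [(e.lncrna_id, e.mrna_id) for e in sa] == [("L_ov", "G_ov")]
        assert all(e.sa_pair for e in sa)
        # SA pairs are a subset of zero-distance cis edges
        assert all(e.distance_bp == 0 for e in sa)


class TestDegrees:
    def test_handshake_identity(self):
        edges = [
            RegEdge("L1", "G1", "trans", r=1.0, p=0.0),
            RegEdge("L1", "G2", "trans", r=1.0, p=0.0),
            RegEdge("L1", "G3", "trans", r=1.0, p=0.0),
            RegEdge("L2", "G3", "trans", r=1.0, p=0.0),
        ]
        lnc, mrna = degree_tables(edges)
        assert lnc == {"L1": 3, "L2": 1}
        assert mrna == {"G1": 1, "G2": 1, "G3": 2}
        assert sum(lnc.values()) == sum(mrna.values()) == len(edges)
        assert degree_tables([]) == ({}, {})


def test_planted_trans_pairs_recovered(expr_sim):
    """All planted coexpressed pairs survive the |r|>0.95, p<0.01 screen."""
    pl = sorted({a for a, _ in expr_sim.trans_pairs})
    pm = sorted({b for _, b in expr_sim.trans_pairs})
    edges = trans_targets(pl, pm, expr_sim.expr)
    found = {(e.lncrna_id, e.mrna_id) for e in edges}
    recovered = sum(1 for pair in expr_sim.trans_pairs if pair in found)
    assert recovered / len(expr_sim.trans_pairs) >= 0.95
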