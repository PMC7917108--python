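"""Duplex enumeration, energy model, decoy rules, targets, and triads."""

import itertools
import json
from importlib import resources

import numpy as np
import pytest

from lncregnet.cerna import (
    BULGE_LENS,
    BULGE_POINTS,
    DecoyRules,
    Duplex,
    build_triads,
    decoy_filter,
    decoy_search,
    duplex_mfe,
    duplex_search,
    expectation_score,
    load_stack_table,
    predict_targets,
)

COMP = str.maketrans("ACGU", "UGCA")


def _rna(s):
    return s.upper().replace("T", "U")


def _perfect_site(mirna, bulge=None, mm_positions=()):
    """Site 5'->3' pairing the miRNA antiparallel (same construction rules
    as the generator, re-derived here by hand)."""
    partners = [
        (b if pos in mm_positions else b.translate(COMP))
        for pos, b in enumerate(_rna(mirna), start=1)
    ]
    if bulge:
        k, blen = bulge
        partners = partners[:k] + ["A"] * blen + partners[k:]
    return "".join(reversed(partners))


MIR = "ACGGAUGCAGCCGUGCAAUCU"  # 21 nt


class TestDuplexSearch:
    def test_exact_complement_all_wc(self):
        site = _perfect_site(MIR)
        lnc = "AAGG" + site + "CCAA"
        best = duplex_search(MIR, lnc)[0]
        assert best.bulge is None
        assert set(best.pair_state) == {"WC"}
        assert best.site_start == 4
        assert best.mfe_kcal_mol < -25

    def test_bulged_site_recovered(self):
        site = _perfect_site(MIR, bulge=(10, 3))
        lnc = "GG" + site + "UU"
        best = duplex_search(MIR, lnc)[0]
        assert best.bulge == (10, 3)
        assert set(best.pair_state) == {"WC"}

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="shorter than 9"):
            duplex_search("ACGUACGU", "ACGU" * 30)

    def test_candidate_set_matches_exhaustive_oracle(self):
        """Every (offset, bulge length, insertion point) candidate — and its
        energy — matches a plain-Python exhaustive enumerator."""
        rng = np.random.default_rng(17)
        mir = "".join(rng.choice(list("ACGU"), size=21))
        lnc = "".join(rng.choice(list("ACGU"), size=150))
        got = {
            (d.site_start, d.bulge or (0, 0), d.pair_state): d.mfe_kcal_mol
            for d in duplex_search(mir, lnc)
        }
        exp = _oracle_candidates(mir, lnc)
        assert set(got) == set(exp)
        for key in exp:
            assert got[key] == pytest.approx(exp[key], abs=1e-9)


def _oracle_candidates(mir, lnc):
    """Independent enumerator: string slicing plus a direct summation over
    the shipped stack table."""
    tab = load_stack_table()
    stack = tab["stack_dg37"]
    bulge_dg = {int(k): v for k, v in tab["bulge_initiation_dg37"].items()}
    mm_dg = tab["interior_mismatch_penalty_dg37"]
    wc = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
    gu = {("G", "U"), ("U", "G")}
    L = len(mir)
    out = {}
    for b in (0,) + BULGE_LENS:
        ks = (0,) if b == 0 else BULGE_POINTS
        for k in ks:
            W = L + b
            for o in range(len(lnc) - W + 1):
                rsite = lnc[o : o + W][::-1]
                partners = [rsite[i] if (i + 1) <= k or b == 0 else rsite[i + b] for i in range(L)]
                states = tuple(
                    "WC" if (m, p) in wc else "GU" if (m, p) in gu else "MM"
                    for m, p in zip(mir, partners)
                )
                paired = [s != "MM" for s in states]
                if not any(paired):
                    e = 0.0
                else:
                    e = 0.0
                    for i in range(L - 1):
                        if paired[i] and paired[i + 1] and (b == 0 or (i + 1) != k):
                            e += stack[f"{mir[i]}{mir[i + 1]}/{partners[i]}{partners[i + 1]}"]
                    if b:
                        e += bulge_dg[b]
                    e += mm_dg * sum(1 for s in states if s == "MM")
                    e = min(0.0, e)
                out[(o, (k, b) if b else (0, 0), states)] = e
    return out


class TestEnergyModel:
    def test_no_pairs_is_zero(self):
        d = Duplex("ACGUACGUA", "ACGUACGUA"[::-1], tuple(["MM"] * 9), 0.0)
        assert duplex_mfe(d) == 0.0

    def test_all_wc_is_stack_sum(self):
        site = _perfect_site(MIR)
        d = duplex_search(MIR, site)[0]
        stack = load_stack_table()["stack_dg37"]
        partners = [b.translate(COMP) for b in MIR]
        expected = sum(
            stack[f"{MIR[i]}{MIR[i + 1]}/{partners[i]}{partners[i + 1]}"]
            for i in range(20)
        )
        assert d.mfe_kcal_mol == pytest.approx(expected, abs=1e-9)

    def test_wc_stacks_all_negative_and_symmetric(self):
        stack = load_stack_table()["stack_dg37"]
        wc = {"AU", "UA", "CG", "GC"}
        for key, dg in stack.items():
            top, bottom = key.split("/")
            p1, p2 = top[0] + bottom[0], top[1] + bottom[1]
            if p1 in wc and p2 in wc:
                assert dg < 0
            # helix reversal symmetry: read the duplex from the other end
            rev = f"{bottom[1]}{bottom[0]}/{top[1]}{top[0]}"
            assert stack[rev] == dg

    def test_helix_reversal_leaves_stack_sum_invariant(self):
        stack = load_stack_table()["stack_dg37"]
        rng = np.random.default_rng(3)
        top = "".join(rng.choice(list("ACGU"), size=12))
        bottom = top.translate(COMP)  # aligned partner, 3'->5'
        fwd = sum(stack[f"{top[i]}{top[i+1]}/{bottom[i]}{bottom[i+1]}"] for i in range(11))
        rtop, rbot = bottom[::-1], top[::-1]
        rev = sum(stack[f"{rtop[i]}{rtop[i+1]}/{rbot[i]}{rbot[i+1]}"] for i in range(11))
        assert fwd == pytest.approx(rev, abs=1e-12)


class TestDecoyFilter:
    def _duplex(self, states, mfe, bulge=None):
        b = bulge[1] if bulge else 0
        return Duplex(MIR, "A" * (21 + b), tuple(states), mfe, bulge=bulge)

    def test_conformant_accepted(self):
        ok, reasons = decoy_filter(self._duplex(["WC"] * 21, -30.0, bulge=(10, 3)))
        assert ok and reasons == []

    @pytest.mark.parametrize(
        "states,mfe,bulge,expected_reason",
        [
            (["WC"] * 4 + ["MM"] + ["WC"] * 16, -30.0, None, "seed-violation"),
            (["WC"] * 8 + ["MM"] * 5 + ["WC"] * 8, -30.0, None, "mismatch-count"),
            (["WC"] * 21, -20.0, None, "energy"),
            (["WC"] * 21, -25.0, None, "energy"),  # boundary: -25 is not < -25
            (["WC"] * 21, -30.0, (10, 5), "bulge"),  # bulge too long
            (["WC"] * 21, -30.0, (5, 3), "bulge"),  # bulge at a bad point
        ],
    )
    def test_single_rule_violations(self, states, mfe, bulge, expected_reason):
        ok, reasons = decoy_filter(self._duplex(states, mfe, bulge))
        assert not ok and reasons == [expected_reason]

    def test_gu_in_seed_violates_unless_relaxed(self):
        d = self._duplex(["WC"] * 4 + ["GU"] + ["WC"] * 16, -30.0)
        assert decoy_filter(d)[0] is False
        assert decoy_filter(d, DecoyRules(seed_allow_gu=True))[0] is True

    def test_acceptance_monotone_in_energy(self):
        base = self._duplex(["WC"] * 21, -26.0, bulge=(9, 2))
        assert decoy_filter(base)[0]
        deeper = Duplex(base.mirna_seq, base.site_seq, base.pair_state, -60.0,
                        bulge=base.bulge)
        assert decoy_filter(deeper)[0]


class TestExpectation:
    def test_scoring_scheme(self):
        assert expectation_score(["WC"] * 21) == 0.0
        assert expectation_score(["WC"] * 15 + ["GU"] + ["WC"] * 5) == 0.5  # pos 16
        assert expectation_score(["WC"] * 3 + ["MM"] + ["WC"] * 17) == 2.0  # pos 4
        assert expectation_score(["GU"] + ["WC"] * 20) == 0.5  # pos 1 unweighted
        assert expectation_score(["WC"] * 4 + ["GU"] + ["WC"] * 16) == 1.0  # pos 5


class TestPredictTargets:
    def test_perfect_site_found(self):
        site = _perfect_site(MIR)
        mrna = "GG" + site + "AAC"
        hits = predict_targets({"m": MIR}, {"g": mrna})
        assert len(hits) == 1
        h = hits[0]
        assert h.expectation == 0.0 and h.hsp_len == 21 and h.site == (2, 23)

    def test_expectation_boundary_inclusive(self):
        # three MMs beyond position 13 -> expectation exactly 3.0: kept
        at3 = _perfect_site(MIR, mm_positions=(15, 17, 19))
        # plus one extra GU-free MM in the unweighted tail -> 3.5 via a GU
        hits = predict_targets({"m": MIR}, {"g": at3})
        assert len(hits) == 1 and hits[0].expectation == 3.0
        # 3.5: replace a WC at position 16 by a G:U (+0.5)
        site35 = list(at3)
        # partner of miRNA position 16 sits at reversed index 15
        pos16 = len(at3) - 16
        m16 = _rna(MIR)[15]
        wobble = {"G": "U", "U": "G"}
        if m16 in wobble:
            site35[pos16] = wobble[m16]
            hits = predict_targets({"m": MIR}, {"g": "".join(site35)})
            assert all(h.expectation != 3.5 for h in hits)

    def test_short_mirna_skipped(self):
        hits = predict_targets({"m": "ACGUACGUACGUACG"}, {"g": "ACGU" * 30}, hsp_min=20)
        assert hits == []


class TestTriads:
    def test_join_on_shared_mirna(self, cerna_sim):
        decoys = decoy_search(cerna_sim.mirnas, cerna_sim.lncrnas)
        targets = predict_targets(cerna_sim.mirnas, cerna_sim.mrnas)
        triads = build_triads(decoys, targets)
        # combinatorial identity: sum over miRNAs of decoy-degree x target-degree
        dd, td = {}, {}
        for d in decoys:
            if d.accepted:
                dd[d.mirna_id] = dd.get(d.mirna_id, 0) + 1
        for t in {(t.mirna_id, t.mrna_id) for t in targets}:
            td[t[0]] = td.get(t[0], 0) + 1
        expected = sum(dd.get(m, 0) * td.get(m, 0) for m in set(dd) | set(td))
        assert len(triads) == expected
        assert len(triads) > 0

    def test_no_shared_mirna_no_triad(self):
        from lncregnet.cerna import DecoyHit, TargetHit

        d = DecoyHit("L1", "M1", (0, 21),
                     Duplex(MIR, "A" * 21, tuple(["WC"] * 21), -30.0), True)
        t = TargetHit("G1", "M2", (0, 21), 0.0, 21)
        assert build_triads([d], [t]) == []
        t2 = TargetHit("G1", "M1", (0, 21), 0.0, 21)
        assert [(x.lncrna_id, x.mirna_id, x.mrna_id) for x in build_triads([d], [t2])] == [
            ("L1", "M1", "G1")
        ]
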