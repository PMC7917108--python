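"""miRNA-decoy (endogenous target mimic) search and ceRNA triad assembly.

A decoy site is a near-complementary lncRNA site that sequesters a miRNA.
Candidate duplexes are enumerated over every lncRNA window that aligns the
full miRNA antiparallel, either perfectly apposed (no bulge) or with a
2–4 nt target-side bulge inserted opposite miRNA positions 9–12 (insertion
points k in {9, 10, 11}, i.e. between miRNA positions k and k+1, counting
from the miRNA 5' end).  Each miRNA position is classified Watson–Crick
(WC), G:U wobble (GU) or mismatch (MM).

A candidate is accepted as a decoy iff all of:

1. hybridization energy < −25 kcal/mol (strict);
2. any bulge lies at an allowed insertion point with length 2–4;
3. positions 2–8 from the miRNA 5' end pair perfectly (WC; G:U counts as a
   violation unless explicitly relaxed);
4. at most 4 mismatches outside the bulge.

Hybridization energy is a nearest-neighbor sum over consecutive paired
positions using a shipped Turner-2004 stack table (kcal/mol at 37 °C), plus
a bulge-loop initiation penalty by bulge length and a fixed loop penalty
per mismatched position.  An alignment whose net energy is positive is
reported as 0 (no stable hybrid); a duplex with no paired positions has
energy 0.

miRNA→mRNA target prediction uses the plant-target convention: a
complementarity expectation score (WC 0, G:U 0.5, MM 1, 2 per gapped nt,
all doubled at miRNA positions 2–13), accepted at expectation <= 3 with
alignment (HSP) length >= 20.  Triads (lncRNA, miRNA, mRNA) join accepted
decoy and target pairs on the shared miRNA.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import write_network_tsv

__all__ = [
    "Duplex",
    "DecoyHit",
    "TargetHit",
    "CeRNATriad",
    "DecoyRules",
    "duplex_search",
    "duplex_mfe",
    "decoy_filter",
    "decoy_search",
    "decoy_empirical_p",
    "expectation_score",
    "predict_targets",
    "build_triads",
    "export_cerna_network",
    "load_stack_table",
]

WC, GU, MM = "WC", "GU", "MM"

BULGE_LENS = (2, 3, 4)
BULGE_POINTS = (9, 10, 11)

_BASES = "ACGU"
_B2I = {b: i for i, b in enumerate(_BASES)}
_WC_PAIRS = {(0, 3), (3, 0), (1, 2), (2, 1)}  # A-U, U-A, C-G, G-C
_GU_PAIRS = {(2, 3), (3, 2)}  # G-U, U-G


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(_rna(seq).encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for b, i in _B2I.items():
        out[arr == ord(b)] = i
    return out


# --- energy table -----------------------------------------------------------


def load_stack_table() -> dict:
    with resources.files("lncregnet.data").joinpath("rna_stack_dg37.json").open() as fh:
        return json.load(fh)


def _build_energy_arrays() -> tuple[np.ndarray, np.ndarray, dict[int, float], float]:
    """(state table 4x4, stack table 16x16 by pair index b_top*4+b_bottom,
    bulge penalties, mismatch penalty)."""
    tab = load_stack_table()
    state = np.zeros((5, 5), dtype=np.uint8)  # 0 = MM (incl. N), 1 = GU, 2 = WC
    for a, b in _WC_PAIRS:
        state[a, b] = 2
    for a, b in _GU_PAIRS:
        state[a, b] = 1
    stack = np.zeros((17, 17), dtype=float)
    for key, dg in tab["stack_dg37"].items():
        top, bottom = key.split("/")
        i1 = _B2I[top[0]] * 4 + _B2I[bottom[0]]
        i2 = _B2I[top[1]] * 4 + _B2I[bottom[1]]
        stack[i1, i2] = dg
    # sanity of the shipped constants: every WC-on-WC stack is stabilizing
    for (a1, b1) in _WC_PAIRS:
        for (a2, b2) in _WC_PAIRS:
            assert stack[a1 * 4 + b1, a2 * 4 + b2] < 0
    bulge = {int(k): v for k, v in tab["bulge_initiation_dg37"].items()}
    return state, stack, bulge, float(tab["interior_mismatch_penalty_dg37"])


_STATE, _STACK, _BULGE_DG, _MM_DG = _build_energy_arrays()
_STATE_NAMES = {0: MM, 1: GU, 2: WC}


# --- duplex -----------------------------------------------------------------


@dataclass(frozen=True)
class Duplex:
    """One miRNA:site alignment.  ``pair_state[i]`` describes miRNA position
    i+1 (1-based from the 5' end).  ``bulge`` is (insertion point k,
    bulge length): ``bulge_len`` target nt inserted between the partners of
    miRNA positions k and k+1."""

    mirna_seq: str
    site_seq: str
    pair_state: tuple[str, ...]
    mfe_kcal_mol: float
    bulge: tuple[int, int] | None = None
    site_start: int | None = None

    def __post_init__(self) -> None:
        if len(self.pair_state) != len(self.mirna_seq):
            raise ValueError("pair_state length != miRNA length")
        if self.mfe_kcal_mol > 0:
            raise ValueError("mfe must be <= 0")
        if self.bulge is not None:
            k, blen = self.bulge
            if not (1 <= k < len(self.mirna_seq)) or blen < 1:
                raise ValueError("malformed bulge")

    @property
    def n_mismatches(self) -> int:
        return sum(1 for s in self.pair_state if s == MM)


def _state_row(mirna_codes: np.ndarray, partner_codes: np.ndarray) -> tuple[str, ...]:
    st = _STATE[np.minimum(mirna_codes, 4), np.minimum(partner_codes, 4)]
    return tuple(_STATE_NAMES[int(s)] for s in st)


def duplex_mfe(d: Duplex) -> float:
    """Nearest-neighbor energy of a duplex (kcal/mol); see module docstring."""
    mc = _encode(d.mirna_seq)
    # reconstruct partners from the site: site is 5'->3'; reversed it aligns
    # with the miRNA 5'->3', with the bulge inserted after position k
    rsite = _encode(d.site_seq)[::-1]
    L = len(mc)
    b = d.bulge[1] if d.bulge else 0
    k = d.bulge[0] if d.bulge else L + 1
    cols = np.array([i if (i + 1) <= k else i + b for i in range(L)])
    partners = rsite[cols]
    paired = np.array([s != MM for s in d.pair_state])
    if not paired.any():
        return 0.0
    pair_idx = np.minimum(mc, 3).astype(int) * 4 + np.minimum(partners, 3).astype(int)
    e = 0.0
    for i in range(L - 1):
        if paired[i] and paired[i + 1] and (i + 1) != k:
            e += _STACK[pair_idx[i], pair_idx[i + 1]]
    if d.bulge:
        e += _BULGE_DG.get(b, _BULGE_DG[max(_BULGE_DG)])
    e += _MM_DG * int((~paired).sum())
    return min(0.0, round(e, 6))


def _candidate_arrays(
    mirna: str,
    lncrna: str,
    bulge_lens: Sequence[int] = BULGE_LENS,
    bulge_points: Sequence[int] = BULGE_POINTS,
):
    """Yield (b, k, offsets, states O x L, energies O) for every bulge layout.

    Offsets index the site start on the lncRNA (5'->3'); states code
    0=MM, 1=GU, 2=WC per miRNA position.
    """
    mc = _encode(mirna)
    L = len(mc)
    if L < 9:
        raise ValueError("miRNA shorter than 9 nt: bulge constraint undefined")
    lc = _encode(lncrna)
    rlnc = lc[::-1]
    N = len(lc)
    mc4 = np.minimum(mc, 4)
    pair_m = np.minimum(mc, 3).astype(np.int16) * 4

    layouts = [(0, 0)] + [(b, k) for b in bulge_lens for k in bulge_points if k < L]
    for b, k in layouts:
        W = L + b
        if W > N:
            continue
        sw = np.lib.stride_tricks.sliding_window_view(rlnc, W)  # row t = rlnc[t:t+W]
        # row t corresponds to site offset o = N - W - t
        cols = np.array([i if (i + 1) <= k or b == 0 else i + b for i in range(L)])
        partners = sw[:, cols]
        states = _STATE[mc4[None, :], np.minimum(partners, 4)]
        paired = states > 0
        pair_idx = pair_m[None, :] + np.minimum(partners, 3).astype(np.int16)
        stack_ok = paired[:, :-1] & paired[:, 1:]
        if b > 0:
            stack_ok[:, k - 1] = False  # bulge interrupts the helix there
        stacks = _STACK[pair_idx[:, :-1], pair_idx[:, 1:]] * stack_ok
        e = stacks.sum(axis=1)
        if b > 0:
            e = e + _BULGE_DG.get(b, _BULGE_DG[max(_BULGE_DG)])
        e = e + _MM_DG * (~paired).sum(axis=1)
        e = np.where(paired.any(axis=1), np.minimum(0.0, np.round(e, 6)), 0.0)
        offsets = N - W - np.arange(sw.shape[0])
        yield b, k, offsets, states, e


def duplex_search(
    mirna: str,
    lncrna: str,
    bulge_lens: Sequence[int] = BULGE_LENS,
    bulge_points: Sequence[int] = BULGE_POINTS,
) -> list[Duplex]:
    """Enumerate every candidate duplex of ``mirna`` against ``lncrna``.

    Every window of length L+b (b in {0} + bulge_lens) at every offset is
    aligned antiparallel; for b > 0 every insertion point k in bulge_points
    is enumerated.  Returns all candidates, sorted by (energy, offset).
    """
    lnc_rna = _rna(lncrna)
    mir_rna = _rna(mirna)
    out: list[Duplex] = []
    for b, k, offsets, states, energies in _candidate_arrays(
        mir_rna, lnc_rna, bulge_lens, bulge_points
    ):
        L = len(mir_rna)
        for row in range(states.shape[0]):
            o = int(offsets[row])
            out.append(
                Duplex(
                    mirna_seq=mir_rna,
                    site_seq=lnc_rna[o : o + L + b],
                    pair_state=tuple(_STATE_NAMES[int(s)] for s in states[row]),
                    mfe_kcal_mol=float(energies[row]),
                    bulge=(k, b) if b else None,
                    site_start=o,
                )
            )
    out.sort(key=lambda d: (d.mfe_kcal_mol, d.site_start, d.bulge or (0, 0)))
    return out


# --- decoy rules ------------------------------------------------------------


@dataclass(frozen=True)
class DecoyRules:
    mfe_max: float = -25.0
    seed_start: int = 2
    seed_end: int = 8
    mm_max: int = 4
    allowed_bulge_points: tuple[int, ...] = BULGE_POINTS
    allowed_bulge_lens: tuple[int, ...] = BULGE_LENS
    seed_allow_gu: bool = False


def decoy_filter(d: Duplex, rules: DecoyRules | None = None) -> tuple[bool, list[str]]:
    """Apply the four decoy acceptance rules; returns (accepted, reasons),
    with ``reasons`` naming every violated rule."""
    rules = rules or DecoyRules()
    reasons: list[str] = []
    if not (d.mfe_kcal_mol < rules.mfe_max):
        reasons.append("energy")
    if d.bulge is not None:
        k, blen = d.bulge
        if k not in rules.allowed_bulge_points or blen not in rules.allowed_bulge_lens:
            reasons.append("bulge")
    seed = d.pair_state[rules.seed_start - 1 : rules.seed_end]
    seed_ok = all(s == WC or (rules.seed_allow_gu and s == GU) for s in seed)
    if not seed_ok:
        reasons.append("seed-violation")
    if d.n_mismatches > rules.mm_max:
        reasons.append("mismatch-count")
    return (not reasons, reasons)


@dataclass(frozen=True)
class DecoyHit:
    lncrna_id: str
    mirna_id: str
    site: tuple[int, int]
    duplex: Duplex
    accepted: bool
    rejection_reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.accepted != (len(self.rejection_reasons) == 0):
            raise ValueError("accepted flag inconsistent with rejection reasons")


def decoy_search(
    mirnas: Mapping[str, str],
    lncrnas: Mapping[str, str],
    rules: DecoyRules | None = None,
) -> list[DecoyHit]:
    """Best decoy call per (lncRNA, miRNA) pair.

    Accepted pairs report their most stable accepted duplex; rejected pairs
    report the most stable candidate and its failed rules.  Vectorized rule
    screening keeps this fast enough to run over whole sequence sets.
    """
    rules = rules or DecoyRules()
    hits: list[DecoyHit] = []
    for mid in sorted(mirnas):
        mir = _rna(mirnas[mid])
        L = len(mir)
        seed_lo, seed_hi = rules.seed_start - 1, rules.seed_end
        for lid in sorted(lncrnas):
            lnc = _rna(lncrnas[lid])
            if len(lnc) < L:
                continue
            best_acc = None  # (e, o, b, k, states)
            best_any = None
            for b, k, offsets, states, energies in _candidate_arrays(mir, lnc):
                seed = states[:, seed_lo:seed_hi]
                seed_ok = (
                    (seed >= 1).all(axis=1) if rules.seed_allow_gu else (seed == 2).all(axis=1)
                )
                mm_ok = (states == 0).sum(axis=1) <= rules.mm_max
                e_ok = energies < rules.mfe_max
                acc = seed_ok & mm_ok & e_ok
                i = int(np.argmin(energies))
                cand = (float(energies[i]), int(offsets[i]), b, k, states[i])
                if best_any is None or cand[:2] < best_any[:2]:
                    best_any = cand
                if acc.any():
                    j = int(np.argmin(np.where(acc, energies, np.inf)))
                    cand = (float(energies[j]), int(offsets[j]), b, k, states[j])
                    if best_acc is None or cand[:2] < best_acc[:2]:
                        best_acc = cand
            chosen = best_acc if best_acc is not None else best_any
            if chosen is None:
                continue
            e, o, b, k, st = chosen
            d = Duplex(
                mirna_seq=mir,
                site_seq=lnc[o : o + L + b],
                pair_state=tuple(_STATE_NAMES[int(s)] for s in st),
                mfe_kcal_mol=e,
                bulge=(k, b) if b else None,
                site_start=o,
            )
            accepted, reasons = decoy_filter(d, rules)
            hits.append(
                DecoyHit(
                    lncrna_id=lid,
                    mirna_id=mid,
                    site=(o, o + L + b),
                    duplex=d,
                    accepted=accepted,
                    rejection_reasons=tuple(reasons),
                )
            )
    return hits


def decoy_empirical_p(
    mirna: str,
    lncrna: str,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value of the best duplex energy: fraction of
    dinucleotide-preserving-free shuffles of the lncRNA whose best candidate
    is at least as stable.  Optional analogue of a duplex-significance test."""
    best = min(d.mfe_kcal_mol for d in duplex_search(mirna, lncrna))
    rng = random.Random(seed)
    chars = list(_rna(lncrna))
    hits = 0
    for _ in range(n_shuffles):
        rng.shuffle(chars)
        e = min(
            e_row.min()
            for _, _, _, _, e_row in _candidate_arrays(_rna(mirna), "".join(chars))
        )
        if e <= best:
            hits += 1
    return (hits + 1) / (n_shuffles + 1)


# --- target prediction ------------------------------------------------------


def expectation_score(
    pair_state: Sequence[str],
    bulge: tuple[int, int] | None = None,
) -> float:
    """Plant-target complementarity expectation: WC 0, GU 0.5, MM 1, plus 2
    per bulged (gapped) target nt; penalties are doubled at miRNA positions
    2–13 (the gap penalty is weighted by its insertion point)."""
    cost = {WC: 0.0, GU: 0.5, MM: 1.0}
    score = 0.0
    for pos, s in enumerate(pair_state, start=1):
        w = 2.0 if 2 <= pos <= 13 else 1.0
        score += w * cost[s]
    if bulge is not None:
        k, blen = bulge
        w = 2.0 if 2 <= k <= 13 else 1.0
        score += w * 2.0 * blen
    return score


@dataclass(frozen=True)
class TargetHit:
    mrna_id: str
    mirna_id: str
    site: tuple[int, int]
    expectation: float
    hsp_len: int
    upe_proxy: float | None = None


def _upe_proxy(site: str) -> float:
    """Crude accessibility proxy: stability (kcal/mol, positive) of the best
    gapless self-complementary fold of the site, from the same stack table."""
    half = len(site) // 2
    left, right = site[:half], site[half:]
    best = 0.0
    for b, k, offs, states, energies in _candidate_arrays(
        _rna(left), _rna(right), bulge_lens=(), bulge_points=()
    ):
        best = min(best, float(energies.min()))
    return -best


def predict_targets(
    mirnas: Mapping[str, str],
    mrnas: Mapping[str, str],
    expectation_max: float = 3.0,
    upe_max: float = 25.0,
    hsp_min: int = 20,
    check_upe: bool = False,
) -> list[TargetHit]:
    """Gapless sliding-window target sites with expectation <= expectation_max
    (inclusive) and alignment length >= hsp_min.  UPE screening is an
    optional proxy and is off by default."""
    hits: list[TargetHit] = []
    for mid in sorted(mirnas):
        mir = _rna(mirnas[mid])
        L = len(mir)
        if L < hsp_min:
            continue
        w = np.where((np.arange(1, L + 1) >= 2) & (np.arange(1, L + 1) <= 13), 2.0, 1.0)
        cost = np.array([1.0, 0.5, 0.0])  # by state code MM, GU, WC
        for gid in sorted(mrnas):
            seq = _rna(mrnas[gid])
            if len(seq) < L:
                continue
            for b, k, offsets, states, energies in _candidate_arrays(
                mir, seq, bulge_lens=(), bulge_points=()
            ):
                exp = (cost[states] * w[None, :]).sum(axis=1)
                for row in np.nonzero(exp <= expectation_max)[0]:
                    o = int(offsets[row])
                    upe = _upe_proxy(seq[o : o + L]) if check_upe else None
                    if check_upe and upe > upe_max:
                        continue
                    hits.append(
                        TargetHit(
                            mrna_id=gid,
                            mirna_id=mid,
                            site=(o, o + L),
                            expectation=float(exp[row]),
                            hsp_len=L,
                            upe_proxy=upe,
                        )
                    )
    hits.sort(key=lambda h: (h.mirna_id, h.mrna_id, h.site))
    return hits


# --- triads -----------------------------------------------------------------


@dataclass(frozen=True)
class CeRNATriad:
    lncrna_id: str
    mirna_id: str
    mrna_id: str


def build_triads(
    decoys: Iterable[DecoyHit],
    targets: Iterable[TargetHit],
) -> list[CeRNATriad]:
    """Join accepted decoy pairs and accepted target pairs on the miRNA."""
    decoy_pairs = sorted({(d.mirna_id, d.lncrna_id) for d in decoys if d.accepted})
    target_pairs = sorted({(t.mirna_id, t.mrna_id) for t in targets})
    by_mir: dict[str, list[str]] = {}
    for mid, gid in target_pairs:
        by_mir.setdefault(mid, []).append(gid)
    triads = [
        CeRNATriad(lncrna_id=lid, mirna_id=mid, mrna_id=gid)
        for mid, lid in decoy_pairs
        for gid in by_mir.get(mid, ())
    ]
    return triads


def export_cerna_network(triads: Sequence[CeRNATriad], path_prefix) -> dict[str, int]:
    """Node/edge TSVs of the triad network; returns node counts by type."""
    nodes = (
        {(t.lncrna_id, "lncRNA") for t in triads}
        | {(t.mirna_id, "miRNA") for t in triads}
        | {(t.mrna_id, "mRNA") for t in triads}
    )
    edges = sorted(
        {(t.lncrna_id, t.mirna_id, "decoy") for t in triads}
        | {(t.mirna_id, t.mrna_id, "target") for t in triads}
    )
    rows = [{"source": a, "target": b, "edge_type": et} for a, b, et in edges]
    write_network_tsv(sorted(nodes), rows, path_prefix)
    counts: dict[str, int] = {"lncRNA": 0, "miRNA": 0, "mRNA": 0}
    for _, typ in nodes:
        counts[typ] += 1
    return counts
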