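"""Cross-species lncRNA homology and miRNA-precursor accounting.

Homology is assessed with a built-in k-mer-seeded, gap-free local aligner
(word size 11, match +1, mismatch −2) whose scores are converted to
Karlin–Altschul-style E-values; hits are kept at a strict ``E < 1e-5``.
Precomputed BLAST tabular hits (``io_formats.read_blast_tab``) can be
substituted on the production path — the built-in aligner makes the test
suite independent of any external binary.

miRNA precursors are lncRNAs with a qualifying hit against a hairpin
database; the family of a hit is the hairpin's family token (header token
before any species suffix), so cross-species hits to the same family
collapse.  Common/unique family logic over a family x species presence
matrix follows plain set semantics: *common to a subset* = present in every
subset member; *unique* = present in exactly one species overall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import HomologyHit

__all__ = [
    "SpeciesSet",
    "PresenceMatrix",
    "AlignerParams",
    "homology_search",
    "homolog_share",
    "precursor_scan",
    "family_presence",
    "unique_common",
    "hairpin_family",
]


@dataclass
class SpeciesSet:
    species: str
    lncrna_seqs: dict[str, str]

    def __post_init__(self) -> None:
        if any(not k for k in self.lncrna_seqs):
            raise ValueError("empty sequence id")


@dataclass
class PresenceMatrix:
    families: list[str]
    species: list[str]
    present: np.ndarray  # bool, families x species

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.families), len(self.species)):
            raise ValueError("presence grid shape mismatch")
        if len(self.families) and not self.present.any(axis=1).all():
            raise ValueError("a family row has no presence")


@dataclass(frozen=True)
class AlignerParams:
    """Scoring for the built-in seeded aligner and its E-value calibration.

    Karlin–Altschul parameters are the fixed defaults for +1/−2 scoring
    (lambda=1.33, K=0.621); they are not tuned.
    """

    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    x_drop: int = 10
    lam: float = 1.33
    k: float = 0.621


def _extend(q: str, s: str, qi: int, si: int, p: AlignerParams) -> tuple[int, int, int, int]:
    """Gap-free X-drop extension of a word match; returns
    (qstart, qend, score, identities) with qend exclusive."""
    w = p.word_size
    score = best = p.match * w
    ident = w
    # right
    i, j = qi + w, si + w
    cur, qend, ident_at_best_r = score, qi + w, w
    extra = 0
    while i < len(q) and j < len(s):
        cur += p.match if q[i] == s[j] else p.mismatch
        extra += 1 if q[i] == s[j] else 0
        i += 1
        j += 1
        if cur > best:
            best, qend, ident_at_best_r = cur, i, w + extra
        if best - cur > p.x_drop:
            break
    score, ident = best, ident_at_best_r
    # left
    i, j = qi - 1, si - 1
    cur, best_l, qstart = score, score, qi
    extra = 0
    ident_l = 0
    while i >= 0 and j >= 0:
        cur += p.match if q[i] == s[j] else p.mismatch
        extra += 1 if q[i] == s[j] else 0
        if cur > best_l:
            best_l, qstart, ident_l = cur, i, extra
        if best_l - cur > p.x_drop:
            break
        i -= 1
        j -= 1
    return qstart, qend, best_l, ident + ident_l


def _evalue(score: int, m: int, n: int, p: AlignerParams) -> float:
    return p.k * m * n * math.exp(-p.lam * score)


def homology_search(
    query: SpeciesSet,
    subject: SpeciesSet,
    max_evalue: float = 1e-5,
    params: AlignerParams | None = None,
) -> list[HomologyHit]:
    """Seeded gap-free local search of every query against every subject.

    Returns at most one hit (the best-scoring locus) per (query, subject)
    sequence pair, filtered at strict ``E < max_evalue``.  Deterministic for
    fixed inputs.
    """
    p = params or AlignerParams()
    if not query.lncrna_seqs or not subject.lncrna_seqs:
        return []
    n_db = sum(len(s) for s in subject.lncrna_seqs.values())

    # word index over subjects
    index: dict[str, list[tuple[str, int]]] = {}
    for sid, seq in subject.lncrna_seqs.items():
        for i in range(len(seq) - p.word_size + 1):
            index.setdefault(seq[i : i + p.word_size], []).append((sid, i))

    hits: list[HomologyHit] = []
    for qid, qseq in query.lncrna_seqs.items():
        best: dict[str, tuple[int, int, int, int, int]] = {}  # sid -> (score, qs, qe, ident, diag)
        seen_diag: dict[str, set[int]] = {}
        for i in range(len(qseq) - p.word_size + 1):
            for sid, j in index.get(qseq[i : i + p.word_size], ()):
                diag = i - j
                if diag in seen_diag.setdefault(sid, set()):
                    continue
                seen_diag[sid].add(diag)
                qs, qe, score, ident = _extend(qseq, subject.lncrna_seqs[sid], i, j, p)
                cur = best.get(sid)
                if cur is None or score > cur[0]:
                    best[sid] = (score, qs, qe, ident, diag)
        for sid in sorted(best):
            score, qs, qe, ident, _ = best[sid]
            ev = _evalue(score, len(qseq), n_db, p)
            if ev < max_evalue:
                aln_len = qe - qs
                hits.append(
                    HomologyHit(
                        query_id=qid,
                        subject_id=sid,
                        percent_identity=round(100.0 * ident / aln_len, 2),
                        alignment_length=aln_len,
                        e_value=ev,
                        bit_score=float(score),
                        subject_species=subject.species,
                    )
                )
    return hits


def homolog_share(query: SpeciesSet, hits: Iterable[HomologyHit]) -> tuple[int, float]:
    """How many query lncRNAs have >=1 homolog, and the percent (2 dp)."""
    from .enrich_report import percent_of

    qids = set(query.lncrna_seqs)
    with_hom = {h.query_id for h in hits if h.query_id in qids}
    n = len(with_hom)
    total = len(qids)
    return n, percent_of(n, total) if total else 0.0


def hairpin_family(hairpin_id: str) -> str:
    """Family token of a miRBase-style hairpin id (``MIR400_bra`` -> ``MIR400``)."""
    return hairpin_id.split("_")[0].split("-")[0].upper()


def precursor_scan(
    lncrnas: SpeciesSet,
    hairpins: Mapping[str, str],
    max_evalue: float = 1e-5,
    params: AlignerParams | None = None,
) -> list[tuple[str, str]]:
    """(lncRNA id, miRNA family) records for lncRNAs matching a hairpin at
    strict ``E < max_evalue``.  A lncRNA may match several families."""
    db = SpeciesSet("hairpins", dict(hairpins))
    hits = homology_search(lncrnas, db, max_evalue=max_evalue, params=params)
    records = sorted({(h.query_id, hairpin_family(h.subject_id)) for h in hits})
    return records


def family_presence(
    records_per_species: Mapping[str, Iterable[tuple[str, str]]],
) -> PresenceMatrix:
    """Build the family x species presence matrix from per-species
    ``precursor_scan`` records."""
    species = sorted(records_per_species)
    families = sorted({fam for recs in records_per_species.values() for _, fam in recs})
    grid = np.zeros((len(families), len(species)), dtype=bool)
    fi = {f: i for i, f in enumerate(families)}
    si = {s: i for i, s in enumerate(species)}
    for sp, recs in records_per_species.items():
        for _, fam in recs:
            grid[fi[fam], si[sp]] = True
    return PresenceMatrix(families, species, grid)


def unique_common(
    matrix: PresenceMatrix,
    species_subset: Sequence[str],
) -> tuple[list[str], list[str]]:
    """(common, unique): families present in ALL subset members, and families
    present in exactly one species of the whole matrix."""
    for sp in species_subset:
        if sp not in matrix.species:
            raise KeyError(f"species {sp!r} not in presence matrix")
    cols = [matrix.species.index(sp) for sp in species_subset]
    common = [
        fam
        for i, fam in enumerate(matrix.families)
        if cols and matrix.present[i, cols].all()
    ]
    unique = [
        fam
        for i, fam in enumerate(matrix.families)
        if matrix.present[i].sum() == 1
    ]
    return common, unique
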