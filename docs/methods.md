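# Methods

This note documents the models, parameters and numerical choices behind
`lncregnet`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinates and formats

All genomic intervals are 0-based, half-open internally; GFF3/GTF 1-based
inclusive coordinates are converted only in `io_formats`. Sequences are
normalised to DNA (U→T) on read; the duplex code re-interprets T as U when
pairing strands, so DNA and RNA inputs are interchangeable. GFF3/GTF
parsing is delegated to gffutils (in-memory database); transcripts without
a parent gene get a synthesized single-transcript gene. BLAST tabular
import keeps rows at strict `E < threshold`, matching the screening
convention "E value < 1e-5" used throughout.

## lncRNA screen

Filters run in a fixed order and each decision is recorded in a trace:

1. **Length ≥ 200 nt.** The boundary is inclusive: a 200-nt transcript is
   kept, 199 nt is removed.
2. **Mono-exonic reliability.** "Low-reliability single-exon transcripts"
   is operationalised as mono-exonic AND max FPKM < 2 across all samples
   (configurable). Expression is the only reliability signal available
   after assembly; a transcript absent from the matrix counts as FPKM 0.
3. **Coding-exon overlap, same strand only** (≥ 1 bp at exon level).
   Antisense overlappers are deliberately kept — they are the lncNAT class.
   A direct interval test replaces assembler class codes.
4. **Coding potential.** External labels are authoritative when supplied.
   The built-in stand-in removes transcripts whose longest forward-frame
   ATG…stop ORF is ≥ 100 aa; it is *not* equivalent to CNCI/CPC/Pfam
   screening and is documented as a stand-in only.

Positional classes: lncNAT iff ≥ 1 bp antisense exon overlap with a coding
exon; else incRNA iff the transcript span lies wholly inside one intron of
a coding transcript (either strand — strandness of intronic lncRNAs is a
genuinely open convention, so containment is strand-agnostic); else
lincRNA. Precedence lncNAT > incRNA resolves transcripts that do both.

## Conservation

The built-in aligner is word-seeded (word size 11), gap-free, X-drop
extended (match +1, mismatch −2, X = 10), reporting the best locus per
query×subject pair. E-values use fixed Karlin–Altschul parameters for
+1/−2 scoring (λ = 1.33, K = 0.621) against the summed subject length;
they are not tuned. This makes tests deterministic and binary-free; BLAST
outfmt-6 import is the production path for real data. Hairpin hits
collapse to the family token of the subject id (text before the first
`_`/`-`), so cross-species hits to one family count once. Common/unique
family logic is plain set semantics on the presence matrix: common to a
subset = present in every member; unique = present in exactly one species
overall.

## Expression and correlation

Detection: mean stage FPKM > 0.1 (strict; the threshold is a package
default — no standard exists — and is carried in outputs). The DE caller
is a stand-in for assembly-level tools: equal-variance two-sample t-test
on log2(FPKM+1) per feature, BH across features within a comparison, DE at
q < 0.05; features with identical values in both groups get p = 1.
Precomputed DE TSVs can replace it.

Pearson correlations default to the **five stage means** (the treatment
stages are the experimental unit); `basis="replicates"` uses all 15
columns. The choice changes n and therefore the p-value materially
(at n = 5, the two-sided 1% critical value is |r| ≈ 0.9587), so it is
always an explicit parameter. p-values come from the t-transform
t = r·√((n−2)/(1−r²)) on n−2 df; constant vectors are an error (skipped
with a log entry in network construction).

## Regulatory network

*cis*: protein-coding genes whose span is within 100 kb of the lncRNA
span, measured boundary-to-boundary (not TSS-anchored — the anchoring is
unspecified in common usage, and span boundaries are assembly-robust);
distance 0 for overlap; the boundary is inclusive (gap = 100,000 bp kept),
with `inclusive=False` available. *trans*: |r| > 0.95 AND p < 0.01, both
strict. Per-comparison edge membership requires both endpoints DE in that
comparison. Sense–antisense pairs are edges whose endpoints lie on
opposite strands with ≥ 1 bp span overlap; they are necessarily
distance-0 cis edges.

## ceRNA model

**Candidate space.** For a miRNA of length L, every lncRNA window of
length L+b (b ∈ {0, 2, 3, 4}) at every offset is aligned antiparallel;
for b > 0 the bulged target bases are inserted between the partners of
miRNA positions k and k+1 for k ∈ {9, 10, 11} — i.e. the bulge lies
opposite the interval spanned by miRNA positions 9–12, counted from the
miRNA 5′ end. (The insertion-point reading covers the canonical eTM bulge
centred at positions 10–11.) Positions are classified WC / G:U / MM.

**Energy.** Nearest-neighbor sum over consecutive paired positions using
the shipped Turner-2004 RNA stack table
(`data/rna_stack_dg37.json`, ΔG°37 in kcal/mol, 36 entries over the six
pairs including wobble; the two GG/UU wobble-on-wobble entries use the
published −0.50). A bulge adds a length-dependent loop initiation penalty
(2.8/3.2/3.6 kcal/mol for 2/3/4 nt); each mismatch adds a fixed 1.1
kcal/mol loop penalty. The helix is not given terminal or initiation
terms — the quantity is a comparative hybridization score against the −25
kcal/mol cutoff, not an absolute folding free energy. A net-positive
alignment reports 0 (no stable hybrid), and a duplex with no paired
positions has energy 0. The table satisfies helix-reversal symmetry and
all WC-on-WC entries are stabilizing (asserted at load).

**Decoy rules.** Accepted iff MFE < −25 (strict); any bulge at an allowed
insertion point with length 2–4; positions 2–8 perfectly WC (G:U counts
as a violation by default — strictest reading; `seed_allow_gu` relaxes
it); ≤ 4 mismatches, bulged bases not counted. Rejection reasons enumerate
every failed rule. An extreme-value duplex p-value (as computed inside
duplex tools) needs a background calibration that is tool-internal; a
permutation alternative (`decoy_empirical_p`, 1000 shuffles) is provided
and off by default.

**Targets.** Gapless sliding-window alignment; expectation = Σ w(p)·c(p)
with c = 0 (WC), 0.5 (G:U), 1 (MM), 2 per gapped nt, and w = 2 at miRNA
positions 2–13 (the plant-target convention); accepted at expectation ≤ 3
(inclusive) and HSP length ≥ 20 nt. Target-site unpairing energy (UPE)
screening requires a partition-function fold; a documented proxy (best
gapless self-complementary fold of the site under the same stack table) is
available and disabled by default. Triads join accepted decoy pairs and
target pairs on the shared miRNA; the triad count equals
Σ_miRNA (decoy degree × target degree).

## Synthetic data

The generator emulates a 5-stage × 3-replicate stress time course:
200 coding genes (3 exons, a 2-kb intron to host intronic lncRNAs),
30 planted lncRNAs per positional class, 5 removal decoys per filter
category, a stage-profile library (early spike, early drop, late rise,
mid peak, flat) mirroring heat-shock-protein-like and ABA-receptor-like
response shapes, 100 planted coexpressed pairs with multiplicative
log-normal noise (sd 0.05 on log2), 10 miRNAs each with one conformant
decoy site and one single-rule violator per rule, and 5 species with
planted homolog blocks (0–5% mutations) and 8 hairpin families. These
scales keep a full end-to-end run under a minute on one CPU.

Rule isolation is engineered, then verified: the energy violator uses
exactly 4 scattered mismatches plus a legal bulge so the best candidate
fails *only* the energy rule; the mismatch-count violator clusters 5
mismatches on a GC-biased miRNA so the energy rule still passes. Every
planted object is re-checked against the consuming module's predicate
before emission (classification truth against the screen, decoy truth
against the search+filter, presence truth against the precursor scan) and
redrawn on failure, so emitted truth tables cannot be inconsistent. All
outputs are a deterministic function of the seed.

**What passing does not show.** The fixtures have uniform base
composition, clean exon structures, no assembly artifacts, no strand
ambiguity, well-separated planted signals and idealised noise. Recovery
rates of 100% on them demonstrate correctness of the logic and thresholds,
not expected sensitivity/specificity on real assemblies, where coding
potential, fragmented models and correlated noise dominate the error
budget.

## Numerical choices

Percentages print with half-even rounding at 2 digits (decimal
arithmetic, so printed numbers are platform-deterministic). Hypergeometric
enrichment is the plain upper tail P(X ≥ k) with BH across terms —
no gene-length bias weighting and no ontology-graph propagation (recorded
limitations); the default background is the expressed/annotated gene set
supplied by the caller, which must contain the query. Network exports are
sorted for byte-stable output; the pipeline manifest records the package
version, config hash, seed and input checksums.
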