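# Methods

its2kit re-implements, as a tested pipeline, the ITS2 sequence-structure
procedure for discriminating *Ampelomyces* sensu stricto rDNA sequences
from misattributed environmental sequences: ITS delimitation, proximal
5.8S–28S stem hybridization, ITS2 minimum-free-energy folding and model
classification, group statistics, sequence-structure phylogenetics and
barcode-gap evaluation. This note documents the models, the parameters
that matter, the synthetic-data design, and the numerical choices.

## ITS delimitation

The ITS region (ITS1–5.8S–ITS2) is located by degenerate-consensus motif
search for four anchors: the 18S 3' tail, the 5.8S start and end, and the
28S 5' head. This replaces the profile-HMM annotation of the ITS2
databases, whose trained models are not redistributable; the published
gates are kept as-is: an E-value-like significance threshold of 0.001 and
a minimum ITS2 length of 150 nt. The significance of a hit with *k*
mismatches is the expected number of equally good windows in an i.i.d.
sequence of the same length (computed by a small DP over per-position
mismatch probabilities); on random 500-nt sequences the best spurious hit
is insignificant in ≥99% of trials (tested). Coordinates are 0-based
half-open internally and 1-based inclusive in reports.

Parameters: `max_mismatches` (default 3 per motif), `evalue_threshold`
(0.001), `min_its2_len` (150 nt), `max_its_len` (697 bp, the
ITS1f/ITS4-bounded ascomycete maximum used for length normalization).

## Proximal-stem hybridization

The duplex between the 5.8S 3' tail and the 28S 5' head (default window
25 nt per strand, roughly two helical turns) is scored with a
nearest-neighbor model: Watson–Crick stack ΔG37/ΔH from Xia et al. (1998),
flat representative values for wobble-containing stacks, duplex initiation
(+4.09 / +3.61 kcal/mol), terminal AU/GU penalties (+0.45 / +3.72), and
tabulated bulge/internal-loop penalties with Jacobson–Stockmayer
extrapolation (loop enthalpies taken as zero). The optimal duplex is found
by DP over antiparallel pairings with interruptions up to 6 nt. The
literature does not state which parameter set produced the published
typical-stem energies (ΔG −19, ΔH −147.1), so agreement is tolerance-based
by design; under this table the synthetic typical stem evaluates to
ΔG −18.97 / ΔH −145.1.

The free-nucleotide pattern is read at the ITS2-proximal end of the
optimal duplex: exactly one free nucleotide on each strand is TYPICAL;
other finite patterns are VARIANT_MULTI_FREE; a 28S strand shorter than
the window (or no stabilizing duplex) is UNMODELABLE — a result, not an
error, mirroring the large unmodelable fraction of real records.
Stability classes for pseudogene screening: DESTABILIZED for ΔG > −15,
FLEXIBLE for −19 ≤ ΔG ≤ −15 (both boundaries inclusive, since the
published −19 and −15 values are described as conferring flexibility),
STABLE below −19. Thresholds are configurable.

## ITS2 folding and the four-helix core

Folding uses a simplified Turner-style energy function — the same stack
table plus linear hairpin/bulge/internal penalties and an affine
multibranch term (a=3.4, b=0.4/branch, c=0/unpaired) — in a standard
pseudoknot-free MFE dynamic program (interior loops capped at 30 nt,
minimum hairpin 3). The full 2004 parameter set (dangles, special
hairpins, sequence-dependent 1×1 loops) is deliberately not reproduced:
the claims this package evaluates are structural (helix counts, motifs,
energy bands), not absolute reference energies. Two independent checks
guard the implementation: an energy audit (loop-decomposition re-scoring
of every reported structure must reproduce the MFE to machine precision)
and a maximum-pairing (Nussinov) oracle bound on short sequences. Ties are
broken by a fixed traceback evaluation order that prefers 5'-most
pairings, making folding deterministic.

Decomposition takes the top-level stems of the structure, ordered 5'→3',
as helices I–IV when exactly four are present (fewer than 2 or more than
6 set a not-four-fingered flag). Per helix: paired count, 1×1/2×2…
internal loops, bulges, terminal loop. Rings are the single-stranded
spans between consecutive helices; the ring I–IV is the exterior span
joining helix IV's 3' side back to helix I's 5' side (circular layout).

### Diagnostic motifs and model labels

* U-U mismatch on helix II: a 1×1 internal loop with U opposite U.
* Helix III motif: UGGU (with an optional separate UU) or UGG, scanned on
  both arms.
* Ring I–IV signatures (DNA letters, ≤1 mismatch, cyclic): GTACCC (Model 1
  family), GTCTCC/GTGTCC (Model 2 family — the two printed variants are
  both accepted and the matched one is reported), TCCATG (putative
  pattern).
* A-rich II–III spacer: ≥3 consecutive A.

The classifier is a fixed-order rule cascade: not four helices →
UNCLASSIFIED; TCCATG ring with no helix III motif → PUTATIVE; GTACCC +
UGG → M1 family; GTCTCC + UGGU+UU → M2 (M3 when helix III carries ≥4
bulges); A-rich spacer + UGGU + helix I internal loop → M6 (3-bp helix IV
ending in a CCC loop) or M4/M5 (helix III without/with bulges). Evidence
lists every satisfied predicate; UNCLASSIFIED carries empty evidence.

Sub-variant diagnostics are not structurally defined in the literature,
so this package fixes recorded conventions: M7 = M1 signature with a
C→U transition adjacent to the UGG ("UUGG" context); M1-3 = extra
pyrimidine in the II–III spacer; M1-2 = helix II bulge (the pyrimidine
deletion variant); M4 vs M5 split on helix III bulges. These conventions
are configurable in spirit (the rules read decomposition counts that are
all exposed) and the generator plants them consistently.

## Sequence statistics

A/T% and G/C% exclude ambiguity codes from numerator and denominator.
Lengths are normalized to 697 bp (ITS1f/ITS4 maximum); 139 bp → 19.94%,
157 bp → 22.52% (printed precision). Kruskal–Wallis uses average ranks
with tie correction (via scipy) and a χ² reference with k−1 df; Dunn's
post-hoc z uses the shared ranking and tie-corrected variance, two-sided,
with no multiplicity adjustment (the published procedure). Both are
validated against permutation nulls.

An indel event is a distinct gap-run signature: a maximal run of '-'
with identical [start, end) columns, counted once however many rows share
it (the event-based convention; a per-row count can be derived from the
reported member lists). All-gap columns are stripped with a warning.
Because multiple alignment can occasionally place the same biological
deletion in adjacent columns for rows with nearby substitutions, the
measured event count can exceed the designed count by a small margin on
unfavorable seeds.

## Alignment and phylogenetics

Plain DNA MSA is progressive (k-mer guide tree, profile–profile Gotoh
affine DP, match 1 / transition −0.6 / transversion −1.0, gap open 1.53 /
extend 0.123) with one remove-and-realign refinement round; deterministic
given input order. The sequence-structure alignment first folds, then
encodes each position into a 12-letter alphabet (4 bases × unpaired /
opening / closing) and aligns with the published score set: structure
weight 200, indel open 800 / extend 50 (cost scale), match 50 /
mismatch 0, plus a RIBOSUM-style negative term (−100) for base changes
inside paired states — without it the structure term dominates and
sequence registers drift inside long helices. Simultaneous fold-and-align
(Sankoff) is out of scope by design; fold-then-encode-then-align is
recorded in the output metadata.

Distances: K2P (−½ln(1−2P−Q) − ¼ln(1−2Q), transition/transversion
proportions after pairwise deletion) and the log-det distance
d = −¼[ln det F − ½Σ ln(f_a f_b)] from the pairwise joint-frequency
matrix, robust to compositional heterogeneity. Saturation (log domain
violations, singular F) yields NaN entries that are masked/flagged in
reports. Discrete-gamma corrections: K2P uses the exact α-corrected
closed form; for log-det the published tooling does not specify how the
shape parameter enters, so the distance-level map α(e^{d/α} − 1) is
applied (it reduces to d as α → ∞). The shape defaults to 5 for distance
tables, following the published analysis.

Trees: neighbor-joining with the standard Q criterion, ties broken by the
smallest taxon index pair, negative branch lengths clamped to zero with a
flag. Maximum-likelihood tree search is deliberately replaced by NJ
topology + Felsenstein-pruning likelihood scoring (K2P or TN93 with
empirical frequencies, discrete gamma with median-of-bin rates normalized
to mean 1) and coordinate-wise 1-D branch-length optimization (bounded
Brent, tolerance 1e-6); the gamma shape can be estimated by maximizing
the pruning likelihood on the fixed topology. Bootstrap supports resample
alignment columns (default 1000 replicates, seeded) and count internal
bipartitions; an optimized path reuses per-pair site-category counts with
column weights.

The barcode-gap report compares the maximum within-group pairwise
distance to the minimum between-group pairwise distance (flag = min inter
> max intra) and also tabulates between-group means with column-bootstrap
standard errors.

## Synthetic data: what it emulates, and what it does not

Records are built constructively (design-then-verify): flanks carry the
delimitation anchors; the 5.8S is a fixed 157-nt gene whose 3' tail forms
the designed proximal stem; ITS1 templates carry designed indel sites
with placement modes (UNIFORM / HEAD / TAIL / BOTH_ENDS) reproducing the
group length ranges (182–193 bp for *Ampelomyces*, ~139–143 bp for the
putative/outgroup backbones, 8 designed events within *Ampelomyces* and 6
in the putative+outgroup alignment); ITS2 sequences are assembled from
four reverse-complementary stem pairs and linkers carrying each model's
ring and helix III motif, verified to refold into their designed
structures. All twelve templates derive from one sequence skeleton so
that intra-*Ampelomyces* divergence (≤ ~0.23 substitutions/site on the
sequence-structure alignment) stays below the *Ampelomyces*-vs-putative
and putative-vs-putative divergences (≥ ~0.3) — the designed barcode gap.

Within-group divergence (default 1%) is applied compensatorily: paired
positions mutate with their partners to another Watson–Crick pair, loop
positions only between non-pairing bases, and diagnostic elements (rings,
motif segments, anchors, short critical stems, indel-site flanks) are
conserved — the generator's analogue of the structural constraint the
method itself exploits. Because stems must be GC-rich to fold reliably,
the designed ITS2 is more GC-rich than real spacers; the A/T budget is
rebalanced into the ITS1 template so the whole-ITS A/T content falls in
the reported 54.05–58.92% band (the per-component contents therefore do
not individually match the reported component ranges — a known
limitation). The default study is 376 *Ampelomyces* (a mixture dominated
by Model 1 with rarer Models 2–7), 5 + 5 putative and 5 outgroup records,
with a 2% typical→variant stem rate.

Passing tests on this generator demonstrate internal consistency of the
pipeline (boundary recovery, model recovery ≥95%, designed gap detected,
determinism), not accuracy on real GenBank data: real spacers have
AT-rich stems, HMM-worthy anchor variation, chimeras and length outliers
that the generator deliberately omits.

## Problem sizes and reproducibility

Default analysis sizes follow the study layout: 391-record studies for
statistics, a stratified ≤25-taxon subset for the phylogenetic stage
(mirroring the published 21–26-taxon trees), 1000 bootstrap replicates.
Calibration experiments use 1000 records for boundary recovery, 500 draws
per model for classification recovery, 100 random additive trees, and
10-kb simulated pairs for distance recovery. All randomness flows from a
single master seed through named substreams; a fixed configuration
reproduces every artifact byte-for-byte.
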