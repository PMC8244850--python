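# its2kit

Tools for screening fungal rDNA **ITS** sequences attributed to the
mycoparasite genus *Ampelomyces*. Public databases contain many
environmental ITS sequences deposited under the name *Ampelomyces* that do
not belong to the genus; plain sequence distances often cannot separate
them because the barcode gap is weak. its2kit implements the
sequence-*structure* screening strategy: delimit the ITS region
(ITS1–5.8S–ITS2), evaluate the thermodynamics of the ITS2-proximal
5.8S–28S stem, fold the ITS2 spacer into its secondary structure, classify
the fold against the genus's structural models, and build
sequence-structure phylogenies whose group distances exhibit a usable
barcode gap.

It is written for mycologists and molecular ecologists who need a
reproducible, scriptable version of this workflow, and for methods
developers who want each stage (delimitation, duplex thermodynamics, MFE
folding, rank statistics, distances/trees) as a tested library function.

## The core methods

* **Delimitation** — conserved flank motifs (18S tail, 5.8S start/end,
  28S head) located by degenerate-consensus search with an analytic
  E-value-like significance (threshold 0.001).
* **Proximal stem** — the 5.8S 3' tail / 28S 5' head duplex scored with a
  nearest-neighbor model (ΔG37, ΔH; stacks + initiation + loop
  penalties). The typical *Ampelomyces* stem leaves one free nucleotide
  per strand; weak stems (ΔG > −15 kcal/mol) flag candidate pseudogenes.
* **ITS2 secondary structure** — pseudoknot-free MFE folding by dynamic
  programming; decomposition into the four-helix core (helix III
  longest); diagnostic motifs (U-U mismatch on helix II, UGG/UGGU on
  helix III, ring I–IV signatures GTACCC / GTCTCC / TCCATG) drive a rule
  cascade assigning models M1–M7 or the putative pattern.
* **Statistics** — per-group length/content tables, lengths normalized to
  the 697-bp ITS1f/ITS4 maximum, Kruskal–Wallis with Dunn post-hoc
  (unadjusted, tie-corrected), indel-event counts on the ITS1 alignment.
* **Phylogenetics** — 12-letter sequence-structure alignment (structure
  weight 200, indel −800/−50, match 50), K2P and log-det (Tamura–Kumar
  style) distances with discrete-gamma correction (shape 5), neighbor
  joining with 1000 bootstrap replicates, Felsenstein-pruning
  log-likelihood, and the barcode-gap report
  (min between-group > max within-group distance).
* **Synthetic studies** — a constructive generator producing labeled
  datasets with known boundaries, stem patterns, structural models and
  designed group separation, so the whole pipeline is testable offline.

See `docs/methods.md` for model details, defaults and limitations.

## Worked example

Run the full pipeline on a synthetic study (60 *Ampelomyces* + 5 + 5 + 5
records) and inspect the bundle:

```bash
its2kit run --config study.yaml --out out/ --seed 3
```

with `study.yaml`:

```yaml
synthetic:
  n_ampelomyces: 60
bootstrap_reps: 1000
max_phylo_taxa: 25
```

The run log prints the per-stage accounting, e.g.:

```
loaded 75 records in 4 groups
delimited 75/75 records
Kruskal-Wallis H=36.18 (df=3, p=6.86e-08) on normalized ITS lengths
indel events: [['AMPELOMYCES', 60, 8, '25;34;61;...'], ['PUTATIVE+OUTGROUP', 15, 7, '25;40;60;...']]
proximal stems: 74 typical, 1 variant, 0 unmodelable
folded 75 ITS2s; 74 classified into models
barcode gap (sequence-structure distances): True
sequence-structure NJ tree logL=-1231.00, gamma shape~2.58
ITS-region NJ tree logL=-2001.62
```

Reading: all 75 records were delimited exactly; the ITS length difference
between groups is highly significant (H is the Kruskal–Wallis chi-squared
statistic on lengths normalized to 697 bp); the *Ampelomyces* ITS1
alignment contains the 8 designed indel events, while the
putative+outgroup alignment shows 7 (6 designed; alignment ambiguity can
occasionally split an event); nearly all proximal stems show the typical
one-free-nucleotide
hybridization (ΔG ≈ −19.0, ΔH ≈ −145 kcal/mol under the shipped table);
and the between-group sequence-structure distances all exceed every
within-group distance — the designed barcode gap.

The bundle (`out/`) contains the delimitation, hybridization, statistics,
indel and structure tables (TSV), the sequence-structure alignment
(FASTA + dot-bracket), distance matrices with bootstrap SEs, Newick trees
with support values and log-likelihoods, per-group consensus structures,
and a parameter manifest that reproduces the run byte-for-byte.

Library use mirrors the CLI:

```python
from its2kit import (DelimitParams, delimit_its, find_flank_motifs,
                     fold_mfe, decompose_helices, detect_motifs,
                     classify_model, hybridize_stem)

part = delimit_its(rec, find_flank_motifs(rec, params := DelimitParams()), params)
stem = hybridize_stem(part, rec)              # stem.dG, stem.pattern
ss = fold_mfe(rec.seq[slice(*part.its2)])     # ss.structure, ss.mfe
label = classify_model(hs := decompose_helices(ss), detect_motifs(hs))
```

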