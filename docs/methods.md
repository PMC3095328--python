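# Methods

This note documents the models, conventions and design choices behind
`bacpool`, and what its synthetic-data generators do and do not emulate.

## Coordinates and report precision

Internal coordinates are 0-based half-open everywhere; GFF3 emission
converts to the format's 1-based closed convention, BED output stays
0-based half-open. Report tables distinguish the machine value (full
float precision, always retained) from the *report view*:

- mean sizes truncate to integers (6,206,490 bp / 87 scaffolds prints
  71,338, not 71,339) — the convention of assembly summary tables;
- gene density, EST-support percent, discrepancy rate and kb-per-SSR
  round half-up to one decimal;
- TE percents truncate: two decimals below 1%, one decimal at 1% and
  above. This two-regime rule is what reproduces published TE-content
  tables consistently (0.79, 0.93, 5.0, 7.2 all come out of it).

## Scaffold-to-clone assignment

Markers and BAC ends are placed by infix edit-distance alignment
(edlib), both strands, with a 95% identity floor and a 50 bp length
floor. These floors are deliberate: loose enough to tolerate the ~0.2%
consensus error a pyrosequencing assembly carries, tight enough to
reject paralogous placements in the test pools. The best hit per marker
maximises identity × aligned length; exact ties are logged as ambiguous
and broken by scaffold order — never silently.

Border detection follows three search modes: (1) either 30 bp vector
junction, either strand, within a 500 bp window of each scaffold extreme
(the window allows a small untrimmed residue; "at the extreme" with no
stated distance would be fragile); (2) when raw reads are supplied,
reads containing a junction are stripped of it and aligned back to the
extremes; (3) clone end sequences aligned anywhere on the scaffolds,
since an end can sit mid-superscaffold. A clone's `ends_found` is the
number of distinct (scaffold, side) border placements among its assigned
scaffolds, capped at two.

Completeness is a total rule cascade: two borders → `complete`; one
border and > 100 kb → `likely_complete`; one border and 60–100 kb →
`partial`; no border but a marker anchor → `fragmentary`; anything else
→ `unassigned`. The cascade is applied literally; a one-border scaffold
under 60 kb is `unassigned` rather than `fragmentary` because the
fragmentary class is defined by marker-only evidence.

Superscaffolding inserts one N gap per junction; the total inserted gap
is `max(target − Σ parts, 100 × n_junctions)`, split evenly with the
remainder on the last junction. The 100 N floor is the common convention
for a gap of unknown size; manually curated insert-size gaps in real
projects (500–12,064 bp) all exceed it. When the floor binds, a warning
is issued instead of silently shrinking the assembly. Part orientation
must be supplied (it is inferred upstream from end-hit strands);
unresolvable orientation is the caller's problem to flag, never guessed.

## Accuracy census

The locus aligner anchors on exact 31-mers that are unique in both
sequences, chains them co-linearly (longest increasing subsequence on
the test coordinate, merged into maximal exact blocks), and closes the
gaps between anchors with an affine-gap Gotoh DP: match +1, mismatch −2,
first gap base −4, each further base −1. The scheme is declared for
determinism, not tuned; on near-identical sequence pairs (the only
regime the census is meant for) the anchored path achieves the same
score as an unanchored full DP, which the test suite verifies against an
independently written score-only aligner. Sequence pairs with no shared
unique 31-mer are rejected with an identity estimate rather than
force-aligned.

Columns whose test base is N are excluded from the census (the
N stretches are reported separately), and indel columns immediately
flanking an N stretch are pulled into the exclusion so a gap-length
mismatch at a mask boundary is not miscounted.

Classification groups contiguous difference columns (bridging excluded
columns) into blocks. A block of same-base indels adjoining a maximal
mononucleotide run of length ≥ 2 is a *homopolymer* record with
delta = test − reference run length; ambiguous placement between two
runs resolves leftmost. A block overlapping a perfect primitive
dinucleotide array of ≥ 6 units in the reference is a
*dinucleotide_repeat* record (6 units keeps genuine microsatellites in
and incidental 2-unit repeats out). Remaining mismatches are
substitutions, remaining indels `other_indel`; every difference column
is counted exactly once. The run census bins A/T runs ≤ 10 and C/G runs
5–7 in the report view, mirroring how such tables are printed. The
headline rate counts only the two repeat classes per 10 kb, rounded
half-up to one decimal.

## Annotation census

The SSR detector reports maximal whole-unit perfect arrays of primitive
1–6 bp units above class minima (10/12/12/16/20/24 bp). Primitivity
makes an A-run a mononucleotide array rather than an (AA) dinucleotide;
whole-unit maximality means extending by one unit breaks perfection.
Overlapping candidates are suppressed left-to-right preferring the
smaller unit. Motifs are canonicalised to the lexicographically minimal
rotation over the unit and its reverse complement. Compound or
interrupted repeats are not merged; N breaks arrays.

Denominators follow the arithmetic that makes published summary tables
self-consistent: SSR fraction and kb-per-SSR divide by the *non-N*
length; gene density and TE percents divide by the *total* length
including Ns.

Gene summaries exclude TE-flagged models, compute exon/intron length
means over all exons/introns, and average the per-gene intron fraction
of the coding span; per-scaffold density and GC standard deviations use
n−1.

## Microsynteny

Ortholog pairing is reciprocal-best (e-value, then identity) after
dropping TEs, at a default e-value cut of 1e-46 — the regime where
protein-level homology calls between closely related genomes are
unambiguous; both cut and identity floor are configurable. Reciprocity
is chosen over one-way best as the deterministic reading of
"tentatively selected, then confirmed" pairing.

Tandem collapsing merges maximal runs of adjacent same-region genes in
which every consecutive pair has a passing homology row; the
representative is the member with a cross-region pair, else the first.
Blocks chain pairs sorted along region A: a break occurs when
consecutive pairs are separated by more than `max_gap = 3` unpaired
collapsed genes on either region ("contiguous" needs a declared radius);
local inversions do not break a block, and single-pair runs are
discarded. A block's quality is computed over its span;
`region_quality` computes the same statistic over two entire annotated
regions, which is the figure to quote when comparing a scaffold against
its counterpart region end to end. Structural ratios are means of
per-pair A/B ratios (protein length, exon count, mean intron length),
two decimals; the intron ratio uses only pairs where both genes have
introns. Pseudogene handling is not modelled; callers exclude putative
pseudogenes from the input gene lists if desired.

## Synthetic data

`make_genome` places non-overlapping gene and TE annotations on a
random base-composition backbone: exon counts geometric with mean 4.9
(capped at 29), exon lengths log-normal with mean 238 bp, intron lengths
log-normal with mean 393 bp, EST support drawn at 73.2%, TE family drawn
with copy-number weights of a gene-rich plant genome fraction. Defaults
elsewhere follow the same study conditions: 33% GC, 9.9 genes/100 kb,
139 kb mean insert with 10 kb SD, 30 bp junctions, 500 bp Sanger ends,
~7 N stretches per scaffold.

`make_bac_pool` tiles clones without overlap by default so that each
marker and end region is unique to its clone — the situation of a
marker-anchored BAC selection, and the premise under which 100% 
assignment recovery is a meaningful check (`allow_overlap=True` restores
unconstrained draws). BamHI sites are planted at insert boundaries when
the backbone lacks them (positions recorded), avoiding rejection loops
on random sequence.

`ErrorProfile` injects consensus-level errors only: contractions of 1–3
nt in mononucleotide runs ≥ 11 nt with probability 0.58 (the observed
fraction of long runs affected in a Sanger-vs-454 comparison), unit-count
changes in dinucleotide arrays of ≥ 6 units, and N-stretch masking at 5
stretches per 100 kb. Runs below the threshold are never touched, which
is what makes the "zero discrepancies at run length ≤ 10" check a real
statement about the classifier rather than about the generator. There is
no read-level flowgram simulation, no quality values, and no coverage
model; passing tests therefore demonstrate correctness of the
*accounting* (alignment, classification, census arithmetic) on the
error structure pyrosequencing is known to produce — not error-rate
realism of any particular instrument.

`make_accuracy_locus` plants long mononucleotide runs and dinucleotide
arrays into the backbone because a random 100 kb sequence contains
almost no run of ≥ 11 nt; an AT-rich finished BAC contains dozens, and
the census is pointless without them.

`make_synteny_pair` derives region A from region B (the genome) by
per-site substitution at the requested divergence, intron-length scaling
(sequence added or trimmed at the intron midpoint), intergenic TE
insertions (log-normal lengths, mean 5.3 kb — fifteen insertions expand
a 100 kb region by roughly 1.8×), and optional tandem expansion of
chosen genes with slightly elevated divergence so reciprocal-best picks
the original copy. Gene order and orientation are conserved by
construction; the truth table records every cross-region ortholog and
within-region tandem relation with measured exon identity (13% coding
divergence yields ~87% mean identity).

## Problem sizes

The shipped checks run at desk scale by choice: a 3.5 Mb genome with
twenty 139 kb clones for assignment recovery, a 99 kb locus for the
error census, 100 kb regions with ~10 genes for synteny, 500 random
instances per brute-force oracle. These sizes exercise every code path
(multi-scaffold pools, all three border modes, every discrepancy class,
tandem arrays, TE exclusion) while keeping a full run in tens of
seconds.

## Known limitations

- Marker/end placement is edit-distance based; it has no affine-gap or
  scoring-matrix model, and very repetitive scaffolds can tie (ties are
  logged, first-by-order kept).
- The anchored aligner assumes the two sequences are versions of the
  same locus; structural rearrangements between anchors are classified
  as runs of substitutions/indels, not as rearrangements.
- Homopolymer attribution is leftmost-deterministic; a single indel
  exactly between two different-base runs joins the left one.
- `classify` completeness uses total assigned scaffold length when a
  clone maps to several scaffolds; it does not attempt to order them.
- No pseudogene model, no EST alignment (support is an input flag), no
  de-novo TE discovery, no read-level simulation.
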