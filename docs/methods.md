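# Methods

## The QTY transform

The transform is a positional substitution: every L, I, V, F whose 1-based
position falls inside a segment of the targeted kinds is replaced by Q, T,
T, Y respectively; every other position is untouched.  The default target
set is `{TM_HELIX}` only.  Intramembrane hairpin helices (the HP1/HP2
re-entrant loops of the EAAT fold, kind `INTRAMEMBRANE`) are excluded by
default and selectable explicitly: they sit in the membrane but do not span
it, and the variation percentages conventionally reported for QTY designs
normalize by membrane-*spanning* helix residues.  The transform is
idempotent (Q, T, Y are outside its domain), length-preserving, and never
touches D, E, H, K, R, which is why the isoelectric point of a variant
stays within ~0.2 pH units of the native protein.

**Variation accounting.** `tm_variation_pct` divides the number of
substituted positions inside target segments by the number of residues
inside target segments; `overall_variation_pct` divides by the full
sequence length.  A topology with zero target residues reports 0 with a
warning rather than NaN, so tabular reports stay numeric.

**Molecular weight** is the Expasy convention: sum of average-isotopic
residue masses plus one water (18.015 Da), via Biopython's `ProtParam`.
Note that each L→Q substitution *adds* ~14.97 Da and F→Y adds 15.999 Da
(one oxygen); the net MW drift of a design is bounded by 16.1 Da per
substitution, a few hundred Da for a full transporter.

**Isoelectric point** uses the Bjellqvist pK set (Expasy's, including the
residue-specific N-terminal pKs), with the net charge at a given pH from
Biopython's `IsoelectricPoint` and the zero crossing found by bisection on
[0, 14].  The charge curve is strictly decreasing, so the crossing is
unique; bisection runs to an interval of 0.005 pH units and the result is
reported to 2 decimals, matching the precision of standard pI calculators.
The bisection is verified in the tests against a dense (0.001-step) grid
search on the same charge curve.

## Codon-level analysis

The standard genetic code is taken from Biopython's codon table, in the RNA
alphabet (DNA input is transliterated on read).  `min_nt_changes` is the
minimum Hamming distance over the full codon-set product;
`single_change_paths` enumerates every codon pair differing at exactly one
position and annotates the changed position and its transition (within
purines or within pyrimidines) / transversion class.  Paths are reported
pair-exhaustively rather than collapsed by position, because variant tables
annotate per-variant base changes.  Stop codons are present in the table
but excluded from residue-level operations.  The central combinatorial
facts — L→Q, I→T, F→Y (and inverses) each have distance 1 with every
minimal path at position 2, while V↔T has distance 2 — are checked against
a brute-force double-loop oracle over the codon sets.

`second_base_reachable` is deliberately strict: it requires at least one
single-nucleotide path *and* that every such path sits at position 2.  L→I
(paths at positions 1 and 3) therefore fails it, as intended.

## Variant classification and summaries

Variants are protein-consequence level (HGVS short tokens such as `I59T`);
no nucleotide VCF handling.  Direction: QTY iff (ref, alt) ∈ {(L,Q), (I,T),
(V,T), (F,Y)}, RQTY iff the inverse, OTHER otherwise.  Cross-tabulations
count TM = membrane-spanning helix locations only; intramembrane (IM)
segments count as non-TM, which is the convention under which the curated
table's printed splits (34 TM / 29 non-TM QTY with 3 IM among the 29) are
internally consistent.  "Helical" includes the 3/10 helix alongside the
canonical α-helix.  Effect labels map "? damaging" → POSSIBLY_DAMAGING and
"damaging" → PROBABLY_DAMAGING.  Residue roles: FUNCTIONAL = exposed and
highly conserved, STRUCTURAL = buried and highly conserved, with the grade
threshold a parameter (default 8 of 9); rows missing exposure or grade are
NEITHER with a warning, and remain in all totals.

The packaged reference table (`data/glutamate_variants.tsv`) is a
transcription of curated natural QTY/rQTY variants of the eight human
glutamate transporters, 95 rows, version-pinned in the repository; no live
database is queried at any point.  Conservation grades and exposure calls
in that table come from its original curation and are never recomputed by
this package's stand-ins.

## Structure tools

**Superposition** is the Kabsch algorithm: centre both coordinate sets,
SVD of the cross-covariance, and a determinant-sign correction so the
returned rotation is always proper (det = +1).  Pairing is by residue
index — the natural pairing between a native model and a same-numbering
designed variant — optionally restricted to a caller-supplied index subset
(e.g. to drop flexible loops; which subset enters a reported RMSD is the
caller's choice).  Fewer than 3 pairs is an error; a rank-deficient
(collinear) pairing is solved but flagged.  The tests cross-check the SVD
route against an independently implemented quaternion-eigenvector method
(Horn) to 1e-8 and verify rigid-motion invariance to 1e-6.

**Burial** is a CA coordination number: BURIED iff ≥ 14 other CA atoms lie
within 10 Å.  These defaults give sensible labels on packed synthetic
bundles; the proxy is *not* a solvent-accessibility computation and is not
used to second-guess curated exposure calls.

**Hydropathy** uses the Kyte–Doolittle scale (pluggable dictionary).  The
profile is a sliding-window mean with truncated windows at the ends;
`gravy` is the whole-sequence mean.  Every QTY substitution lowers KD
(L 3.8→Q −3.5, I 4.5→T −0.7, V 4.2→T −0.7, F 2.8→Y −1.3), so the mean TM
hydropathy strictly decreases under the transform — the quantitative proxy
for "the hydrophobic surface became hydrophilic".

## Mutation libraries and the stand-in scorer

A site library is the 19 non-wild alternatives at one position; the TM
library takes every L/I/V/F inside TM helices, 19 × n_sites candidates.
Substitution classes partition the 19 alternatives: the QTY cognate(s) of
the wild residue (for wild T, both I and V), the remaining members of the
polar set {D,E,R,K,H,N,S,T,Q,Y}, and the remaining members of the nonpolar
set {A,C,G,I,L,M,F,P,W,V}.

Effect scoring is an injected interface.  The shipped stand-in is

    score = clamp01( |KD(wild) − KD(alt)| / 9  ×  (0.5 + 0.5·buried)  ×  grade/9 )

with grade defaulting to 5 and burial to exposed; 9.0 is the KD range.  It
is deterministic, bounded in [0, 1], and preserves one qualitative
property of real missense predictors: chemically conservative substitutions
score lower.  It does not reproduce any external predictor's numbers.  One
subtlety: at pure-leucine sites the cognate Q has the same KD as D/E/N, so
the cognate-vs-other-polar ordering is not guaranteed per wild residue;
it holds at the library level on transporter-like L/I/V/F mixtures, and
that library-level ordering (QTY cognate mean ≤ other-polar mean) is what
the tests assert.

## Conservation grading

Per-column score = Shannon entropy of residue frequencies normalized by
log 20, gaps excluded by default (columns > 50% gap are flagged
low-confidence; an all-gap column is NaN).  Grades 1–9 come from
equal-frequency binning of the scores with 9 the lowest-entropy bin; tied
scores share their group's best grade, so invariant columns always grade 9
when any variable column exists.  All-equal scores collapse to grade 5
("average"), and fewer than 9 columns falls back to a linear min-max
mapping with a warning.  "More than averagely conserved" is read strictly
(grade > 5).  This statistic measures column variability only — no
homologue search, no phylogeny, no rate model — and is a documented
stand-in for Bayesian conservation servers, not a re-implementation.

## Synthetic data

Generators draw from independent streams derived from one seed via fixed
spawn keys, so outputs are bit-reproducible and adding a generator never
perturbs another.  Defaults were chosen once to resemble the study system:

* **Transporters**: 8 TM helices (12 for MFS-like topologies) of length
  18–25, loops of 15–45 residues alternating intracellular/extracellular
  with an intracellular N-terminus, total length typically ~350–560
  residues.  TM composition puts ≥ 55% weight on L,I,V,F,A,M,G; loops are
  polar-biased.  Under these compositions the QTY transform rewrites
  roughly 40–55% of TM residues, the range reported for real transporter
  designs.
* **Variant tables**: exact planted QTY/rQTY/other counts; QTY rows draw
  from {L→Q, I→T, F→Y} with V→T behind an off-by-default flag, mirroring
  the two-nucleotide barrier that keeps V→T out of natural single-base
  variation; locations and effects are sampled from configurable mixes
  (defaults ~54% TM, ~54% benign).
* **Helix bundles**: ideal α-helix CA geometry (1.5 Å rise, 100° turn,
  2.3 Å radius), parallel axes ~10 Å apart on a circle; only the residue
  identities and helix phases are random.
* **Alignments**: a planted fraction of invariant columns, the rest i.i.d.
  uniform over the 20 residues.

What the generators do *not* emulate: real fold geometry, codon usage,
site-frequency spectra, phylogenetic correlation between alignment rows,
and any correlation between location, conservation and effect beyond the
planted mixes.  Tests that pass on synthetic data therefore validate the
*computations* (counting, classification, superposition, grading), not
biological claims about real transporters.

## Problem sizes and numerical choices

The test suite and the acceptance script run on one CPU in well under a
minute: codon enumerations are exhaustive (61 codons), the variant table
has 95 rows, generated proteins are a few hundred residues, bundles ≤ 200
CA atoms, alignments ≤ 200 columns.  Tolerances: rigid-motion RMSD 1e-6 Å,
SVD-vs-quaternion agreement 1e-8, pI bisection 0.005 pH (reported to 2
decimals), hydropathy and mass assertions at the precision of the
published scales.  Ties: alternate locations resolve to highest occupancy
then alphabetical; grade ties share the best grade of their group; codon
paths sort lexicographically.

## Known limitations

* No structure prediction: RMSDs between predicted native and QTY models
  of real transporters require an external structure predictor and are out
  of scope; the superposition machinery is validated on synthetic geometry.
* The effect scorer and conservation grader are stand-ins with the
  qualitative properties documented above; their absolute values carry no
  meaning outside this package.
* Topology-dependent results (variation %, library sizes) are only as good
  as the supplied topology annotation; annotations from different database
  releases can shift TM boundaries by a few residues.
* Signal peptides are not treated specially: variation percentages are
  computed over the sequence as supplied.
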