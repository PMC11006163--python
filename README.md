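# qtycode

Structural-bioinformatics toolkit for the **QTY code** — the protein-design
strategy that renders membrane proteins water-soluble by replacing the four
dominant hydrophobic residues of transmembrane (TM) helices with their
polar structural twins:

    L -> Q (leucine -> glutamine)
    I -> T (isoleucine -> threonine)
    V -> T (valine -> threonine)
    F -> Y (phenylalanine -> tyrosine)

Each pair shares a near-identical side-chain shape, so the substitution
strips the hydrophobic surface of a TM helix without disturbing the helical
fold or introducing any charged residue.  The package is written for people
studying transporters and other α-helical membrane proteins who want to
design QTY variants, reason about the genetics of the substitutions, and
analyse natural variants that perform the same swaps.

## What it does

* **QTY transform** (`apply_qty`) — substitute L/I/V/F inside designated
  topology segments (TM helices by default; intramembrane hairpins
  selectable) and report the accounting: TM and overall variation %,
  molecular weight and isoelectric point of native and variant
  (Expasy-convention average masses and Bjellqvist pK set).
* **Codon-level genetics** (`single_change_paths`, `min_nt_changes`) —
  enumerate single-nucleotide codon paths between residues under the
  standard genetic code, with transition/transversion classes.  Every
  QTY/rQTY pair is one *second-position* base change; V↔T needs two
  changes, which is why natural V→T variants are not observed.
* **Natural-variant analysis** (`classify_direction`, `summarize`) —
  classify missense variants as QTY / reverse-QTY / other and cross-tabulate
  by membrane location, secondary structure and predicted effect.  A curated
  table of 95 natural QTY/rQTY variants of the eight human glutamate
  transporters (EAAT1–4, VGLUT1–3, YLAT2) ships with the package.
* **Structure tools** (`kabsch_superpose`, `burial_classes`,
  `hydropathy_profile`) — SVD-based Kabsch superposition with RMSD over CA
  pairs, a coordination-number burial proxy, and Kyte–Doolittle hydropathy
  profiles for native-vs-variant surface comparison.
* **Saturation mutation libraries** (`build_tm_library`,
  `aggregate_by_class`) — all 19 substitutions per targeted site with a
  pluggable effect scorer and class-wise aggregation (QTY cognate vs other
  polar vs other nonpolar).
* **Conservation grading** (`profile_alignment`) — entropy-based 1–9
  conservation grades from an MSA (a stand-in for Bayesian conservation
  servers).
* **Synthetic data** (`generate_transporter`, `generate_variant_table`,
  `generate_helix_bundle`, `generate_alignment`) — seeded generators for
  every input, so the whole pipeline runs without downloads.

## Worked example

```bash
python examples/classify_natural_variants.py
```

```
total variants        95
QTY / reverse-QTY     63 / 32
QTY in TM helices     34 (54.0 %), 19 benign
QTY outside TM        29 (46.0 %)
rQTY outside TM       24 (75.0 %)
benign rQTY overall   17
helical QTY variants  53
second-base reachable 95 of 95
```

Of the 95 natural variants, 63 run in the QTY direction and 32 in reverse;
54% of the QTY changes sit inside TM helices and over half of those are
predicted benign — nature routinely performs the substitutions the QTY
design applies systematically — and every one of the 95 is reachable by a
single base change at codon position 2, the base that sets an amino acid's
chemistry.

Designing a variant end to end on a synthetic 8-TM transporter:

```bash
python examples/design_qty_variant.py
```

```
protein            SYN0001 (435 residues, 8 TM helices)
substitutions      71 (first three: I45T, V49T, F51Y ...)
TM variation       43.03 %
overall variation  16.32 %
MW  native/QTY     47.5 / 48.0 kDa
pI  native/QTY     6.05 / 6.05
```

About 43% of the TM residues are rewritten, yet the molecular weight moves
by ~0.5 kDa and the pI not at all: the QTY code never touches a charged
residue.  The other `examples/` scripts cover codon paths, superposition,
mutation libraries and conservation, one capability each.

There is also a thin `qty` command-line wrapper
(`qty design`, `qty codon-paths`, `qty variants summarize`,
`qty superpose`, `qty library`, `qty conserve`, `qty simulate`, `qty run`).

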