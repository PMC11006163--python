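"""Entropy-based conservation grading of an alignment with planted structure.

Generates an MSA in which 40% of columns are invariant, grades every column
1-9 (9 = most conserved) from normalized Shannon entropy, and checks that
the planted conserved fraction is recovered.
"""

import qtycode as q

alignment = q.generate_alignment(seed=3, n_rows=40, length=200, conserved_fraction=0.4)
profile = q.profile_alignment(alignment)
count, fraction = q.conserved_fraction(profile, threshold=5)

print(f"alignment              {len(alignment.rows)} rows x {alignment.length} columns")
print(f"planted invariant      40 % of columns")
print(f"grade-9 columns        {int((profile.grades == 9).sum())}")
print(f"above-average grades   {count}/{alignment.length} ({100 * fraction:.1f} %)")

# Invariant columns all land in grade 9; the fraction graded above 'average'
# (grade > 5) recovers the planted 40% within the 1/9 granularity of
# equal-frequency binning.  This entropy statistic is a stand-in for
# phylogeny-aware conservation servers and measures column variability only.
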