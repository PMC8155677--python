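"""Three-way accounting of curated disease-variant databases in a cohort.

Builds three curated-variant sets whose cohort overlaps mirror a published
autoinflammatory-disease analysis (5 ClinVar-like, 72 HGMD-like, 95
Infevers-like variants found in the cohort) and prints the exclusive Venn
regions. The union is the number of distinct curated variants the cohort
carries.
"""

import itertools

from popepi import VariantKey, venn_counts

counter = itertools.count()


def fresh(n):
    return {VariantKey("1", next(counter) + 1, "A", "C") for _ in range(n)}


triple, clinvar_hgmd, hgmd_infevers = fresh(1), fresh(3), fresh(22)
clinvar_only, hgmd_only, infevers_only = fresh(1), fresh(46), fresh(72)

clinvar = clinvar_only | clinvar_hgmd | triple
hgmd = hgmd_only | clinvar_hgmd | hgmd_infevers | triple
infevers = infevers_only | hgmd_infevers | triple

v = venn_counts(clinvar, hgmd, infevers)
print(f"per-database cohort overlap: ClinVar-like {v.a_total}, "
      f"HGMD-like {v.b_total}, Infevers-like {v.c_total}")
print(f"exclusive regions: {v.a_only} / {v.b_only} / {v.c_only}, "
      f"pairwise {v.ab_only} / {v.bc_only} / {v.ac_only}, triple {v.abc}")
print(f"distinct curated variants in the cohort (union): {v.union}")
# The union (145 here) is the denominator for everything downstream:
# each of these variants gets an ACMG verdict and a frequency comparison.
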