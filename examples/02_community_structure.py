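"""Community structure of a synthetic three-group cohort.

Generates a cohort with a planted compositional gradient, then computes
UniFrac distances between samples, tests group separation with a
permutational pseudo-F (PERMANOVA), and screens every SGB for differential
abundance with Kruskal-Wallis + Benjamini-Hochberg correction.
"""

from wildgut import (
    CohortSpec,
    gen_cohort,
    kruskal_wallis_per_sgb,
    pcoa,
    permanova,
    unifrac,
)

spec = CohortSpec(n_sgbs=60, n_samples_per_group=(16, 10, 18),
                  n_gradient_sgbs=12, n_module_sgbs=10, seed=1)
table, tree, truth = gen_cohort(spec)
print(f"cohort: {len(table.sgb_ids)} SGBs x {len(table.samples)} samples "
      f"in groups {sorted(set(table.groups))}")

for weighted, tag in ((False, "unweighted"), (True, "weighted")):
    d = unifrac(table, tree, weighted=weighted)
    f, p = permanova(d, table.groups, n_perm=999, seed=1)
    ord_res = pcoa(d, n_axes=2)
    var = ord_res.proportion_explained()[:2] * 100
    print(f"{tag} UniFrac: pseudo-F={f:.2f}, p={p:.3f} "
          f"(PCoA axes explain {var[0]:.0f}% and {var[1]:.0f}%)")
# p = 0.001 is the smallest value attainable with 999 permutations: no
# permuted labelling separates the groups as well as the observed one.

results = kruskal_wallis_per_sgb(table)
sig = [r for r in results if r.q_value <= 0.05]
planted = set(truth["gradient_sgbs"])
print(f"{len(sig)} SGBs differ across groups at FDR 0.05; "
      f"all {len(planted)} planted gradient SGBs recovered: "
      f"{planted <= {r.sgb_id for r in sig}}")
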