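"""Moderated ANOVA on a synthetic time course with planted trends.

Generates a 4-time-point x 3-replicate matrix in which 100 of 1000 genes
rise by 1.5 log2 units per interval, fits the random-variance-model prior,
and screens for time-differential genes at p < 0.05 and permutation
FDR < 0.05.
"""

import hepacore as h
from hepacore.synthetic import SyntheticSpec

spec = SyntheticSpec(
    n_genes=1000,
    variance_prior=(2.0, 10.0),          # E[sigma^2] = 0.1 log2^2
    planted_profiles=[((1, 1, 1), 100, 1.5)],
    seed=1,
)
matrix, truth = h.generate_profiled_matrix(spec)

s2, d = h.pooled_variances(matrix)
prior = h.fit_variance_prior(s2, d)
print(f"fitted variance prior: a = {prior.a:.3f}, b = {prior.b:.3f} "
      f"(residual df {d}, +{2 * prior.a:.1f} from the prior)")

results = h.rvm_f_test(matrix, prior)
results["fdr"] = h.permutation_fdr(matrix, prior, n_perm=500, seed=1)
hits = h.select_significant(results, 0.05, 0.05)

planted = set(truth.index[truth != "null"])
print(f"{len(hits)} significant genes; "
      f"{len(planted & set(hits))}/100 planted trends recovered, "
      f"{len(set(hits) - planted)} null genes slipped through")
# The moderated F-test borrows variance strength across genes, so with only
# 3 replicates per group it keeps near-nominal error while catching the
# planted time trends.
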