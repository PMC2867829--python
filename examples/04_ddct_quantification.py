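"""Comparative-Ct (ddCt) quantification of qPCR validation data.

Simulates duplicate Ct measurements for a gene induced 4-fold at 1 h
(reference gene flat), then recovers the fold change with the
2^(-ddCt) method and tests the group difference with Student's t-test.
"""

import hepacore as h

table = h.generate_ct_table(
    n_genes=1,
    groups=["control", "1h"],
    fold_changes={"t001": {"1h": 4.0}},
    ct_noise_sd=0.1,
    seed=5,
    animals_per_group=6,
)
results = h.compute_ddct(table, control_group="control")
summary = h.compare_groups(results, control_group="control")
print(summary[["gene", "group", "n_animals", "mean_fold", "sd_fold", "p",
               "significant"]].to_string(index=False))
# A 4-fold induction is one target Ct cycle gained twice: ddCt ~ -2, fold
# 2^2 = 4.  The t-test compares per-animal dCt (target minus reference) in
# the treated group against control; with 0.1-cycle noise the recovery is
# within a few percent of the planted fold.
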