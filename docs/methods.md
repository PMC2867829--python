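# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Random variance model (RVM) moderated ANOVA

**Model.** For gene *g* with pooled within-group variance s²_g on
d = N − k degrees of freedom, the reciprocal true variances are treated as
exchangeable draws 1/σ² ~ Γ(shape a, scale b).  Marginally this makes
*a·b·s² ~ F(d, 2a)*: the prior acts like 2a extra degrees of freedom worth
of variance information shared across genes.  The prior is fitted once per
matrix by maximising the marginal likelihood of all positive s² (density
`a·b·f_F(a·b·s²; d, 2a)`, the a·b factor being the change-of-variable
Jacobian), with `a` box-bounded to [0.01, 100] so degenerate inputs (e.g.
identical variances) terminate at the bound with a flag instead of
diverging.  Optimisation is L-BFGS-B over (log a, log b) from five
moment-matched starts; genes with s² = 0 are excluded and counted.

**Test.** Each gene's variance is shrunk to
s̃² = (d·s² + 2/b)/(d + 2a) — a strictly increasing function of s² whose
fixed point is 1/(ab); smaller variances are pulled up, larger ones down.
The moderated statistic MS_between/s̃² is referred to F(k−1, d+2a).  As
a → 0 and 1/b → 0 the procedure reduces exactly to classical one-way
ANOVA (tested to 1e−9), which is why no separate "plain ANOVA" code path
exists: pass a vanishing prior.  A gene with zero between-group mean
square gets F = 0, p = 1 (no evidence, no 0/0).

**FDR.** Group labels of the sample columns are permuted globally per
iteration and the whole matrix re-tested with the observed-data prior,
preserving inter-gene correlation.  For each gene,
FDR(p) = (mean permutation count of p-values ≤ p) / (observed count ≤ p),
clipped to [0, 1]; the denominator includes the gene itself so it is never
zero.  Default 1000 permutations; calibration tests use 60–500 as their
stated problem sizes.  Significance requires p < 0.05 **and** FDR < 0.05.

The design default is four time groups × 3 replicates (d = 8), but any
k ≥ 2 groups with ≥ 2 replicates each is accepted.

## Temporal model profiles

Per-group expression is the geometric mean of the linear-scale replicate
signals, computed as the arithmetic mean of log2 values (an identity, not
an approximation).  Trajectories are anchored by subtracting the
first-time-point value, so every gene starts at 0.

Profiles are all step vectors in {−c..+c}^(T−1) except the flat one —
(2c+1)^(T−1) − 1 patterns, i.e. 26 for the default T = 4, c = 1, which
covers *every* possible unit-step pattern; the representative-profile
selection used by short-time-series miners for larger T is therefore
unnecessary and not implemented.  Numbering is lexicographic (−c < … < +c,
earliest interval most significant): the monotone-decreasing profile is
id 1 and the monotone-increasing one id 26.  Published analyses of this
design use other numberings for the two monotone profiles, so the package
always identifies profiles by step vector.

Assignment maximises Pearson correlation between the anchored gene
trajectory and each profile's anchored trajectory (all T points, including
the leading 0); ties break to the lowest profile id; zero-variance genes
are UNASSIGNED.  Enrichment uses the time-permutation null: for each
permutation of the T positions (all T! exhaustively for T ≤ 7; seeded
sampling beyond), permuted vectors are re-anchored and re-assigned, the
expected count E_p is the permutation mean (the identity permutation is
included, so ΣE_p equals the number of assigned genes), and the p-value is
the exact binomial upper tail P[X ≥ O_p] with X ~ Bin(n_assigned,
E_p/n_assigned).  Raw p is compared with α = 0.05, matching the
convention of reporting per-profile significance without multiplicity
correction; a Bonferroni column is emitted alongside for reference.

## Co-expression network and k-cores

Pairwise Pearson correlation is computed across **all individual samples**
(n = 12 in the default design), not the T group means — with only 4
points, |r| ≥ 0.9 would be nearly meaningless (the null probability of
|r| ≥ 0.9 at n = 4 is 0.10, versus 6.6e−5 at n = 12).  Edges require
|r| ≥ 0.9 by default ("absolute" rule): the network joins rising and
falling profile genes, which are strongly anti-correlated, and a signed
rule would bipartition it; the "positive" rule is kept for sensitivity
analysis.  The threshold is inclusive (≥) and configurable.  Zero-variance
genes get correlation 0 with a flag rather than NaN.

Topology per node: degree; local clustering coefficient C = 2e/(k(k−1))
with C := 0 for k < 2 (such nodes close no triangles); core number by
standard minimum-degree peeling (networkx), cross-checked in the tests
against an independent brute-force peeler.  Core genes are those within
`depth = 2` levels of the maximum core — the depth-2 rule reproduces the
visible core span (11, 10, 9) of the published 26-gene hub table that
`network.reference_hub_table()` carries; that table's printed clustering
coefficients invert to integer neighbour-edge counts under this C
definition (checked to 1e−4), which is the only validation of it that
does not require the original arrays.

## ΔΔCt quantification

Technical duplicates are averaged per (animal, gene, role); per animal,
ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the control group's mean
ΔCt per gene, so the control mean ΔΔCt is 0 by construction and each
group's fold change 2^(−ΔΔCt) can be summarised as mean ± SD across
animals.  Amplification efficiency is fixed at 2.0 (the plain comparative
method; no efficiency correction).  Group comparison is a two-sample
Student's t-test on per-animal ΔCt (equal variances, per the classical
protocol; Welch is an option).  Groups with < 2 animals are flagged
untestable rather than raising.  Invariances: adding a constant to every
Ct changes nothing; shifting a group's target Ct by −x multiplies its fold
by 2^x (both tested).

## Synthetic generator

Emulates: log2-scale Gaussian noise (RMA-like signals are roughly
log-normal); gene variances from the reciprocal-gamma prior, matching the
RVM assumption (marginal law of pooled variances verified by KS test
against the F closed form); baselines uniform in [4, 12] log2 units
(arbitrary, nothing depends on it); planted step-profile trends
(group means μ + effect·cumulative(steps)); latent-factor modules with
expected pairwise correlation loading² (loading 1 on the flat baseline
gives exactly r = 1; `preserve_trend=True` lets a module ride on planted
trends for end-to-end runs); Ct tables with duplicate wells and
target Ct = baseline − log2(fold) + noise.

Not emulated: probe-level effects, spatial artifacts, missing values,
heavy-tailed noise, between-replicate batch structure, or heterogeneous
per-gene effect sizes (all planted genes of a profile share one effect).
Passing tests therefore demonstrate the machinery's correctness and
calibration under the model's own assumptions, not robustness to real
microarray pathology.  One consequence worth knowing: because planted
profile genes share a single effect size, the end-to-end network is a
near-clique of trend-correlated genes and a planted module is only
marginally more connected than the other planted genes; module recovery
through the core-gene rule averages ≈ 94–96% rather than ~100%.

Default study conditions are the 4 × 3 design with prior (a=2, b=1);
planted-trend fixtures use effect 1.5 log2 per step with prior (2, 10)
(mean σ² = 0.1), the regime in which profile assignment is expected to
recover ≥ 90% of planted genes.

## Problem sizes and numerics

Simulation-based tests use 200–5000 genes, 40–50 seeded replicates and
60–1000 permutations, chosen so the full suite and the acceptance script
each finish in a few minutes on one CPU while leaving Monte-Carlo error
well inside the asserted bands.  All randomness flows through explicit
integer seeds (numpy Generator); identical seed + parameters give
bit-identical matrices, FDRs and run summaries.  Table writers print 9
significant digits with fixed orderings (hub tables: descending core,
degree, then gene id) so outputs are byte-reproducible.  Config files are
flat YAML; unknown keys and range violations are reported together in one
error.
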