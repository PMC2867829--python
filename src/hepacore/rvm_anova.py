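"""Random-variance-model (RVM) moderated one-way ANOVA with permutation FDR.

With only a few arrays per time group, gene-wise variance estimates have
very few degrees of freedom and the plain ANOVA F-test is unstable.  The
random variance model assumes the reciprocal gene variances are exchangeable
draws from a gamma distribution, ``1/sigma^2 ~ Gamma(a, scale=b)``.  Under
that prior the scaled residual variance follows a known law,

    a * b * s^2  ~  F(d, 2a),          d = N - k residual df,

which lets (a, b) be fitted by maximum likelihood across all genes, and each
gene's variance be shrunk toward the prior:

    s~^2 = (d * s^2 + 2/b) / (d + 2a).

The moderated statistic ``F = MS_between / s~^2`` is referred to an
``F(k - 1, d + 2a)`` distribution — the prior contributes ``2a`` extra
denominator degrees of freedom.  In the vanishing-prior limit
(``a -> 0``, ``1/b -> 0``) this reduces exactly to classical one-way ANOVA.

The false discovery rate is estimated by globally permuting the sample
group labels and re-running the moderated test on the whole matrix per
permutation, which preserves inter-gene correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from hepacore.io_formats import ExpressionMatrix

__all__ = [
    "RVMPrior",
    "group_summarize",
    "pooled_variances",
    "fit_variance_prior",
    "rvm_f_test",
    "permutation_fdr",
    "select_significant",
]

A_BOUNDS = (0.01, 100.0)

# significance thresholds used throughout the pipeline
P_THRESHOLD = 0.05
FDR_THRESHOLD = 0.05


@dataclass(frozen=True)
class RVMPrior:
    """Gamma prior of reciprocal gene variances: 1/sigma^2 ~ Gamma(a, scale=b).

    ``bound_hit`` flags that the maximum-likelihood fit of ``a`` landed on
    its box bound [0.01, 100] (degenerate variance dispersion);
    ``n_zero_excluded`` counts genes with zero pooled variance excluded
    from the fit.
    """

    a: float
    b: float
    bound_hit: bool = False
    n_zero_excluded: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("prior parameters must be finite")
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"prior requires a > 0, b > 0; got ({self.a}, {self.b})")

    def shrink(self, s2: np.ndarray, d: float) -> np.ndarray:
        """Posterior-shrunken variance (d*s^2 + 2/b) / (d + 2a)."""
        return (d * np.asarray(s2, float) + 2.0 / self.b) / (d + 2.0 * self.a)


def group_summarize(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-group expression: geometric mean of linear signals, on log2 scale.

    Because the matrix holds log2 signals, the log2 geometric mean of the
    linear-scale replicates is exactly the arithmetic mean of the log2
    values, which is what is computed.  Columns follow the design's time
    order.

    Returns
    -------
    pandas.DataFrame
        genes x groups, log2 scale.
    """
    matrix.require_replicated(1)
    groups = matrix.groups.to_numpy()
    out = matrix.values.T.groupby(groups, sort=False).mean().T
    return out[matrix.group_order]


def _group_stats(values: np.ndarray, codes: np.ndarray, k: int):
    """Vectorised one-way ANOVA pieces: MS_between, pooled s^2, d."""
    n = values.shape[1]
    counts = np.bincount(codes, minlength=k).astype(float)
    if np.any(counts == 0):
        raise ValueError("every group must be non-empty")
    sums = np.zeros((values.shape[0], k))
    for j in range(k):
        sums[:, j] = values[:, codes == j].sum(axis=1)
    means = sums / counts[None, :]
    grand = values.mean(axis=1)
    ss_between = (counts[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    centered = values - means[:, codes]
    ss_within = (centered**2).sum(axis=1)
    d = n - k
    ms_between = ss_between / (k - 1)
    s2 = ss_within / d if d > 0 else np.full(values.shape[0], np.nan)
    return ms_between, s2, d


def pooled_variances(matrix: ExpressionMatrix):
    """Pooled within-group variance per gene and the residual df d = N - k.

    Returns
    -------
    (pandas.Series, int)
    """
    matrix.require_replicated(2)
    codes, k = _codes(matrix)
    _msb, s2, d = _group_stats(matrix.values.to_numpy(), codes, k)
    return pd.Series(s2, index=matrix.gene_ids, name="pooled_variance"), d


def _codes(matrix: ExpressionMatrix):
    order = {g: i for i, g in enumerate(matrix.group_order)}
    codes = np.array([order[g] for g in matrix.groups], dtype=int)
    return codes, len(order)


def fit_variance_prior(pooled_variances, residual_df: int) -> RVMPrior:
    """Fit (a, b) by maximising the marginal likelihood of observed s^2.

    Under the model ``x = a*b*s^2 ~ F(d, 2a)``, so the density of ``s^2``
    is ``a*b * f_F(a*b*s^2; d, 2a)`` (the a*b factor is the change-of-
    variable Jacobian).  Optimised over log(a), log(b) with ``a`` boxed to
    [0.01, 100]; genes with s^2 = 0 are excluded and counted.

    Raises
    ------
    ValueError
        If fewer than 50 genes have positive variance (fit unreliable) or
        residual_df < 1.
    """
    s2 = np.asarray(pooled_variances, dtype=float)
    if residual_df < 1:
        raise ValueError(f"residual df must be >= 1, got {residual_df}")
    n_zero = int(np.sum(s2 <= 0))
    s2 = s2[s2 > 0]
    if s2.size < 50:
        raise ValueError(
            f"need >= 50 genes with positive variance to fit the prior, "
            f"got {s2.size}"
        )
    d = float(residual_df)

    def nll(theta: np.ndarray) -> float:
        log_a, log_b = theta
        a, b = np.exp(log_a), np.exp(log_b)
        x = a * b * s2
        ll = np.log(a * b) + stats.f.logpdf(x, d, 2.0 * a)
        val = -np.sum(ll)
        return val if np.isfinite(val) else 1e300

    mean_s2 = float(np.mean(s2))
    starts = []
    for a0 in (0.5, 1.0, 2.0, 5.0, 20.0):
        # match b so that E[a*b*s^2] ~ F-mean a0/(a0-1) (or 1 for small a0)
        target = a0 / (a0 - 1.0) if a0 > 1.2 else 1.0
        b0 = target / (a0 * mean_s2)
        starts.append((np.log(a0), np.log(b0)))
    lo, hi = np.log(A_BOUNDS[0]), np.log(A_BOUNDS[1])
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0=np.array(x0), method="L-BFGS-B",
            bounds=[(lo, hi), (None, None)],
        )
        if best is None or res.fun < best.fun:
            best = res
    a_hat, b_hat = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    eps = 1e-6
    bound_hit = a_hat <= A_BOUNDS[0] * (1 + eps) or a_hat >= A_BOUNDS[1] * (1 - eps)
    # keep a inside the box exactly
    a_hat = min(max(a_hat, A_BOUNDS[0]), A_BOUNDS[1])
    return RVMPrior(a=a_hat, b=b_hat, bound_hit=bound_hit, n_zero_excluded=n_zero)


def rvm_f_test(matrix: ExpressionMatrix, prior: RVMPrior) -> pd.DataFrame:
    """Moderated one-way F-test per gene.

    Returns a DataFrame with columns ``ms_between``, ``shrunken_variance``,
    ``F``, ``p`` indexed by gene; ``fdr`` and ``significant`` are filled by
    :func:`permutation_fdr` / :func:`select_significant`.  There is no
    silent fallback to plain ANOVA: a prior is required (use a vanishing
    prior explicitly to recover the classical test).
    """
    if prior is None:
        raise ValueError("an RVMPrior is required (no fallback to plain ANOVA)")
    matrix.require_replicated(2)
    codes, k = _codes(matrix)
    values = matrix.values.to_numpy()
    msb, s2, d = _group_stats(values, codes, k)
    return _f_test_from_stats(msb, s2, d, k, prior, matrix.gene_ids)


def _f_test_from_stats(msb, s2, d, k, prior: RVMPrior, index) -> pd.DataFrame:
    shrunk = prior.shrink(s2, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(shrunk > 0, msb / shrunk, np.where(msb == 0, 0.0, np.inf))
    p = stats.f.sf(F, k - 1, d + 2.0 * prior.a)
    p = np.where((shrunk == 0) & (msb == 0), 1.0, p)
    return pd.DataFrame(
        {
            "ms_between": msb,
            "shrunken_variance": shrunk,
            "F": F,
            "p": p,
        },
        index=pd.Index(index, name="gene_id"),
    )


def permutation_fdr(
    matrix: ExpressionMatrix,
    prior: RVMPrior,
    p_threshold: float | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Permutation estimate of the per-gene false discovery rate.

    Group labels of the sample columns are permuted globally once per
    iteration and the moderated test re-run on the whole matrix (the prior
    is held fixed at its observed-data fit).  For each gene's observed p,

        FDR(p) = mean_perm #{permutation p-values <= p}
                 / #{observed p-values <= p},

    clipped to [0, 1].  The denominator always counts the gene itself, so
    no division by zero can occur.  If ``p_threshold`` is given, the
    returned series is restricted to genes with observed p <= threshold
    (possibly empty).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    matrix.require_replicated(2)
    codes, k = _codes(matrix)
    values = matrix.values.to_numpy()
    msb, s2, d = _group_stats(values, codes, k)
    obs = _f_test_from_stats(msb, s2, d, k, prior, matrix.gene_ids)["p"].to_numpy()

    rng = np.random.default_rng(seed)
    n_genes = obs.size
    null_counts = np.zeros(n_genes)
    for _ in range(n_perm):
        perm_codes = rng.permutation(codes)
        msb_p, s2_p, _ = _group_stats(values, perm_codes, k)
        p_perm = _f_test_from_stats(msb_p, s2_p, d, k, prior, matrix.gene_ids)[
            "p"
        ].to_numpy()
        p_perm.sort()
        null_counts += np.searchsorted(p_perm, obs, side="right")
    mean_null = null_counts / n_perm

    obs_sorted = np.sort(obs)
    ranks = np.searchsorted(obs_sorted, obs, side="right")  # >= 1 always
    fdr = np.clip(mean_null / ranks, 0.0, 1.0)
    out = pd.Series(fdr, index=pd.Index(matrix.gene_ids, name="gene_id"), name="fdr")
    if p_threshold is not None:
        out = out[obs <= p_threshold]
    return out


def select_significant(
    results: pd.DataFrame,
    p_threshold: float = P_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> list:
    """Genes with p < p_threshold AND fdr < fdr_threshold, input order kept."""
    if "fdr" not in results.columns:
        raise ValueError("results must carry an 'fdr' column; run permutation_fdr")
    mask = (results["p"] < p_threshold) & (results["fdr"] < fdr_threshold)
    return list(results.index[mask])
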