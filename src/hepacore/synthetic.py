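"""Synthetic expression matrices and Ct tables with planted truth.

The generator emulates the statistical structure the pipeline assumes for
RMA-normalised time-course arrays: Gaussian noise on the log2 scale
(RMA-like signals are approximately log-normal), gene-wise variances drawn
from an inverse-gamma-like prior (reciprocal variances gamma-distributed,
the random variance model's assumption), null genes, genes following
step-profile time trends, and correlated gene modules driven by a shared
latent factor.  Every stochastic operation takes an explicit seed and is
bit-reproducible.

Planted truth labels use the vocabulary ``null``,
``profile:<step-vector>`` (e.g. ``profile:+1+1+1``) and ``module:<index>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hepacore.io_formats import ExpressionMatrix

__all__ = [
    "SyntheticSpec",
    "generate_null_matrix",
    "generate_profiled_matrix",
    "plant_correlated_module",
    "generate_ct_table",
    "profile_label",
]

#: default baseline range for gene means, log2 units (arbitrary but
#: documented; tests never depend on it)
BASELINE_RANGE = (4.0, 12.0)


def profile_label(steps) -> str:
    """Truth label for a planted step profile, e.g. ``profile:+1+1+1``."""
    return "profile:" + "".join(f"{int(s):+d}" for s in steps)


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic time-course experiment.

    Defaults mirror the replicated short time-course design the pipeline
    targets: four time groups (control, 1 h, 3 h, 6 h) with three arrays
    each, and a reciprocal-variance gamma prior of moderate dispersion.

    Parameters
    ----------
    n_genes
        Total genes in the emitted matrix (planted + null).
    time_points
        Ordered group labels, length T >= 2.
    replicates_per_group
        Arrays per time group, >= 2.
    variance_prior
        ``(a, b)`` shape/scale of the gamma law of reciprocal gene
        variances 1/sigma^2 ~ Gamma(a, scale=b).
    planted_profiles
        List of ``(step_vector, n_genes, effect)`` triples; each planted
        gene's group means follow ``mu + effect * cumulative(steps)``
        (log2 units per step).
    planted_modules
        List of ``(n_genes, loading)`` pairs; module genes share a latent
        per-sample factor with the given loading in (0, 1].
    seed
        Seed for all randomness.
    """

    n_genes: int = 1000
    time_points: tuple = ("control", "1h", "3h", "6h")
    replicates_per_group: int = 3
    variance_prior: tuple = (2.0, 1.0)
    planted_profiles: list = field(default_factory=list)
    planted_modules: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.variance_prior
        if not (a > 0 and b > 0):
            raise ValueError(f"variance prior requires a > 0 and b > 0, got ({a}, {b})")
        if len(self.time_points) < 2:
            raise ValueError("need at least 2 time points")
        if self.replicates_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        T = len(self.time_points)
        for steps, n, _effect in self.planted_profiles:
            if len(steps) != T - 1:
                raise ValueError(
                    f"step vector {tuple(steps)} has length {len(steps)}, "
                    f"expected T-1 = {T - 1}"
                )
            if n < 0:
                raise ValueError("planted gene count must be >= 0")
        planted = sum(n for _s, n, _e in self.planted_profiles)
        planted += sum(n for n, _l in self.planted_modules)
        if planted > self.n_genes:
            raise ValueError(
                f"planted gene counts sum to {planted} > n_genes = {self.n_genes}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.time_points) * self.replicates_per_group


def _design_frame(spec: SyntheticSpec) -> pd.DataFrame:
    rows = []
    i = 0
    for group in spec.time_points:
        for rep in range(1, spec.replicates_per_group + 1):
            i += 1
            rows.append({"sample_id": f"s{i}", "group": group, "replicate": str(rep)})
    return pd.DataFrame(rows).set_index("sample_id")


def _base_matrix(spec: SyntheticSpec, rng: np.random.Generator):
    """Baselines, gene noise SDs from the variance prior, and noise draws."""
    a, b = spec.variance_prior
    mu = rng.uniform(*BASELINE_RANGE, size=spec.n_genes)
    precision = rng.gamma(shape=a, scale=b, size=spec.n_genes)
    sigma = 1.0 / np.sqrt(precision)
    noise = rng.standard_normal((spec.n_genes, spec.n_samples)) * sigma[:, None]
    return mu, sigma, noise


def generate_null_matrix(spec: SyntheticSpec):
    """Generate a matrix with no group effect at all.

    Each gene g has baseline mu_g and per-sample values
    ``mu_g + eps`` with ``eps ~ N(0, sigma_g^2)``, where the reciprocal
    variance ``1/sigma_g^2`` is drawn from the gamma prior (a, b).  Used to
    calibrate the RVM test's type-I error and the permutation FDR.

    Returns
    -------
    (ExpressionMatrix, pandas.Series)
        The matrix and gene -> truth-label series (all ``null``).
    """
    if spec.planted_profiles or spec.planted_modules:
        raise ValueError("null matrix spec must not plant profiles or modules")
    rng = np.random.default_rng(spec.seed)
    design = _design_frame(spec)
    mu, _sigma, noise = _base_matrix(spec, rng)
    genes = [f"g{i + 1:05d}" for i in range(spec.n_genes)]
    values = pd.DataFrame(mu[:, None] + noise, index=genes, columns=design.index)
    matrix = ExpressionMatrix(values, design, list(spec.time_points))
    truth = pd.Series("null", index=pd.Index(genes, name="gene_id"), name="label")
    return matrix, truth


def generate_profiled_matrix(spec: SyntheticSpec):
    """Generate a matrix with step-profile trends planted in leading genes.

    Planted genes follow group means ``mu_g + effect * cumulative(steps)``;
    remaining genes (and any reserved for modules) are null.  Module
    planting itself is a separate pass (:func:`plant_correlated_module`)
    so modules can be layered on null or on profiled genes.
    """
    if not spec.planted_profiles:
        raise ValueError("profiled matrix spec needs at least one planted profile")
    rng = np.random.default_rng(spec.seed)
    design = _design_frame(spec)
    mu, _sigma, noise = _base_matrix(spec, rng)
    T = len(spec.time_points)
    reps = spec.replicates_per_group

    genes = [f"g{i + 1:05d}" for i in range(spec.n_genes)]
    truth = pd.Series("null", index=pd.Index(genes, name="gene_id"), name="label")
    signal = np.zeros((spec.n_genes, spec.n_samples))
    row = 0
    for steps, n, effect in spec.planted_profiles:
        traj = np.concatenate([[0.0], np.cumsum(steps, dtype=float)])  # length T
        per_sample = np.repeat(traj, reps) * effect
        signal[row : row + n] = per_sample[None, :]
        truth.iloc[row : row + n] = profile_label(steps)
        row += n

    values = pd.DataFrame(
        mu[:, None] + signal + noise, index=genes, columns=design.index
    )
    matrix = ExpressionMatrix(values, design, list(spec.time_points))
    return matrix, truth


def plant_correlated_module(
    matrix: ExpressionMatrix,
    n_genes: int,
    loading: float,
    seed: int,
    gene_ids=None,
    module_index: int = 0,
    noise_sd: float = 1.0,
    preserve_trend: bool = False,
):
    """Overwrite ``n_genes`` rows with a shared-latent-factor module.

    Module genes get values ``mu_g + sd * (loading * f_s +
    sqrt(1 - loading^2) * eps_gs)`` with a latent factor ``f_s ~ N(0,1)``
    per sample, so the expected pairwise correlation is ``loading^2`` (the
    factor's share of the unit variance); at loading = 1 with the flat
    baseline all pairwise r are exactly 1.

    Parameters
    ----------
    gene_ids
        Rows to overwrite; defaults to a seeded random draw of ``n_genes``
        gene ids.
    noise_sd
        Total per-gene SD around the baseline (or preserved group means).
    preserve_trend
        Keep each overwritten row's current per-group means as its
        baseline instead of a flat row mean, so a module can ride on top
        of planted temporal profiles.

    Returns
    -------
    (ExpressionMatrix, pandas.Series)
        New matrix and truth labels (``module:<index>`` for module genes).
    """
    if not 0.0 <= loading <= 1.0:
        raise ValueError(f"loading must be in [0, 1], got {loading}")
    if n_genes > matrix.n_genes:
        raise ValueError(
            f"module size {n_genes} exceeds matrix gene count {matrix.n_genes}"
        )
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = list(
            pd.Index(matrix.gene_ids)[
                rng.choice(matrix.n_genes, size=n_genes, replace=False)
            ]
        )
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    values = matrix.values.copy()
    sub = values.loc[gene_ids]
    if preserve_trend:
        groups = matrix.groups.to_numpy()
        baseline = sub.T.groupby(groups, sort=False).transform("mean").T.to_numpy()
    else:
        baseline = np.repeat(
            sub.mean(axis=1).to_numpy()[:, None], matrix.n_samples, axis=1
        )
    factor = rng.standard_normal(matrix.n_samples)
    resid = rng.standard_normal((n_genes, matrix.n_samples))
    mixed = loading * factor[None, :] + np.sqrt(1.0 - loading**2) * resid
    values.loc[gene_ids] = baseline + noise_sd * mixed

    truth = pd.Series(
        f"module:{module_index}",
        index=pd.Index(gene_ids, name="gene_id"),
        name="label",
    )
    out = ExpressionMatrix(values, matrix.design.copy(), list(matrix.group_order))
    return out, truth


def generate_ct_table(
    n_genes: int,
    groups,
    fold_changes,
    ct_noise_sd: float,
    seed: int,
    animals_per_group: int = 3,
    reference_gene: str = "ACTB",
    target_baseline: float = 24.0,
    reference_baseline: float = 16.0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table for the ddCt module.

    Per animal, the target gene's Ct is the reference-anchored baseline
    minus ``log2(fold change)`` of its group, plus Gaussian noise; the
    reference gene is flat.  Each (animal, gene) measurement is emitted in
    duplicate (two technical replicates per reaction, as is standard
    practice), each replicate with independent noise.

    Parameters
    ----------
    fold_changes
        Mapping ``gene -> {group -> fold}``; omitted groups default to
        fold 1.0.  The first group in ``groups`` is the control.

    Returns
    -------
    pandas.DataFrame
        Columns ``animal``, ``group``, ``gene``, ``role``, ``ct1``, ``ct2``.
    """
    rng = np.random.default_rng(seed)
    groups = list(groups)
    if fold_changes and len(fold_changes) == n_genes:
        genes = list(fold_changes)
    else:
        genes = [f"t{i + 1:03d}" for i in range(n_genes)]
    for gene in genes:
        for group, fold in (fold_changes.get(gene, {}) or {}).items():
            if not fold > 0:
                raise ValueError(
                    f"fold change must be positive, got {fold} for "
                    f"({gene}, {group})"
                )
    rows = []
    animal_no = 0
    for group in groups:
        for _ in range(animals_per_group):
            animal_no += 1
            animal = f"m{animal_no:03d}"
            ref_ct = reference_baseline
            rows.append(
                {
                    "animal": animal,
                    "group": group,
                    "gene": reference_gene,
                    "role": "reference",
                    "ct1": ref_ct + rng.normal(0.0, ct_noise_sd),
                    "ct2": ref_ct + rng.normal(0.0, ct_noise_sd),
                }
            )
            for gene in genes:
                fold = float(fold_changes.get(gene, {}).get(group, 1.0))
                ct = target_baseline - np.log2(fold)
                rows.append(
                    {
                        "animal": animal,
                        "group": group,
                        "gene": gene,
                        "role": "target",
                        "ct1": ct + rng.normal(0.0, ct_noise_sd),
                        "ct2": ct + rng.normal(0.0, ct_noise_sd),
                    }
                )
    return pd.DataFrame(rows)
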