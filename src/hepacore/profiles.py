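"""Temporal model-profile mining with a time-point-permutation null.

A *model profile* is a discretised temporal shape: a vector of T-1 unit
steps in {-c, ..., +c} over the successive time intervals, whose cumulative
trajectory (anchored at 0 at the first time point) summarises one possible
expression pattern.  With c = 1 and T = 4 time points there are
3^3 - 1 = 26 non-flat profiles, covering every possible pattern, so no
representative-profile selection step is needed.

Each gene's per-group trajectory is normalised by subtracting its value at
the first time point and assigned to the profile whose trajectory it
correlates with best (Pearson, argmax; ties to the lowest profile id).
Profile enrichment is tested against a permutation null: for every
permutation of the T time positions the permuted, re-anchored gene vectors
are re-assigned, the expected count per profile is the mean over
permutations, and the observed count is referred to an exact binomial
upper tail.

Profiles are numbered lexicographically over step vectors
(-c < ... < +c, earliest step most significant), so for (T=4, c=1) the
monotone-decreasing profile (-1,-1,-1) is id 1 and the monotone-increasing
profile (+1,+1,+1) is id 26.  Published analyses of this design label the
monotone profiles differently (e.g. "No. 9" decreasing / "No. 16"
increasing); this package refers to profiles by step vector, which is
unambiguous.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelProfile",
    "UNASSIGNED",
    "enumerate_model_profiles",
    "normalize_gene_trajectory",
    "assign_genes",
    "profile_significance",
    "collect_profile_genes",
]

#: profile-id value marking a zero-variance (unassignable) gene
UNASSIGNED = 0

#: exhaustive permutation mode is limited to T! <= 5040 (T <= 7)
MAX_EXHAUSTIVE_T = 7

PROFILE_ALPHA = 0.05


@dataclass(frozen=True)
class ModelProfile:
    """A temporal model profile: unit steps and the anchored trajectory."""

    id: int
    steps: tuple

    @property
    def trajectory(self) -> tuple:
        """Cumulative sums prefixed with 0 (length T)."""
        return (0.0, *np.cumsum(self.steps, dtype=float))

    def __post_init__(self) -> None:
        if not any(self.steps):
            raise ValueError("flat (all-zero) profiles are excluded")


def enumerate_model_profiles(T: int, c: int = 1) -> list[ModelProfile]:
    """All (2c+1)^(T-1) - 1 non-flat step vectors, lexicographically ordered.

    Steps are compared in time order with -c < ... < +c; ids are assigned
    1..N in that order.  For (T=4, c=1) this yields 26 profiles.
    """
    if T < 2:
        raise ValueError(f"need T >= 2 time points, got {T}")
    if c < 1:
        raise ValueError(f"need c >= 1, got {c}")
    profiles = []
    next_id = 1
    for steps in itertools.product(range(-c, c + 1), repeat=T - 1):
        if not any(steps):
            continue
        profiles.append(ModelProfile(id=next_id, steps=steps))
        next_id += 1
    return profiles


def normalize_gene_trajectory(values) -> np.ndarray:
    """Anchor a per-group trajectory at its first time point: v(t) - v(t0).

    Accepts a vector (one gene) or a genes x T array / DataFrame; the
    first entry of every returned row is exactly 0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        return arr - arr[0]
    return arr - arr[:, [0]]


def _profile_matrix(profiles: list[ModelProfile]) -> np.ndarray:
    return np.array([p.trajectory for p in profiles], dtype=float)


def _assign_array(norm: np.ndarray, traj: np.ndarray):
    """Argmax-Pearson assignment. Returns (profile ids, best r) arrays.

    ``norm`` is genes x T (anchored), ``traj`` profiles x T.  Zero-variance
    genes get (UNASSIGNED, nan).  Ties go to the lowest profile id
    (argmax returns the first maximum).
    """
    gc = norm - norm.mean(axis=1, keepdims=True)
    pc = traj - traj.mean(axis=1, keepdims=True)
    gs = np.sqrt((gc**2).sum(axis=1))
    ps = np.sqrt((pc**2).sum(axis=1))
    ok = gs > 0
    r = np.full((norm.shape[0], traj.shape[0]), np.nan)
    if ok.any():
        r[ok] = (gc[ok] @ pc.T) / np.outer(gs[ok], ps)
    # clamp numeric overshoot
    np.clip(r, -1.0, 1.0, out=r)
    ids = np.where(ok, np.nanargmax(np.where(np.isnan(r), -np.inf, r), axis=1) + 1,
                   UNASSIGNED)
    best = np.where(ok, np.nanmax(np.where(np.isnan(r), -np.inf, r), axis=1), np.nan)
    return ids.astype(int), best


def assign_genes(normalized, profiles: list[ModelProfile]) -> pd.DataFrame:
    """Assign each gene to its best-correlated model profile.

    Parameters
    ----------
    normalized
        genes x T DataFrame of anchored trajectories (first column 0),
        e.g. ``normalize_gene_trajectory(group_summarize(matrix))``.

    Returns
    -------
    pandas.DataFrame
        Indexed by gene, columns ``profile_id`` (``UNASSIGNED`` = 0 for
        zero-variance genes) and ``r`` (the winning Pearson correlation).
    """
    norm = np.asarray(normalized, dtype=float)
    traj = _profile_matrix(profiles)
    if norm.shape[1] != traj.shape[1]:
        raise ValueError(
            f"gene vectors have length {norm.shape[1]} but profiles expect "
            f"T = {traj.shape[1]}"
        )
    ids, best = _assign_array(norm, traj)
    index = (
        normalized.index
        if isinstance(normalized, pd.DataFrame)
        else pd.RangeIndex(norm.shape[0])
    )
    return pd.DataFrame(
        {"profile_id": ids, "r": best}, index=pd.Index(index, name="gene_id")
    )


def profile_significance(
    assignments: pd.DataFrame,
    normalized,
    profiles: list[ModelProfile],
    mode: str = "exhaustive",
    n_perm: int | None = None,
    seed: int | None = None,
    alpha: float = PROFILE_ALPHA,
) -> pd.DataFrame:
    """Enrichment test of each profile against the time-permutation null.

    For each permutation pi of the T time positions, every gene's permuted
    vector is re-anchored to start at 0 and re-assigned; the expected count
    E_p for profile p is the mean count over permutations (the identity
    permutation is included and reproduces the observed counts).  The
    p-value is the exact binomial upper tail
    ``P[X >= O_p], X ~ Binomial(n_assigned, E_p / n_assigned)``.

    ``mode="exhaustive"`` enumerates all T! permutations (T <= 7);
    ``mode="sampled"`` draws ``n_perm`` permutations and requires a seed.
    A ``p_bonferroni`` column is emitted for reference; the ``significant``
    flag uses the raw p against ``alpha``.
    """
    norm = np.asarray(normalized, dtype=float)
    T = norm.shape[1]
    if mode == "exhaustive":
        if T > MAX_EXHAUSTIVE_T:
            raise ValueError(
                f"exhaustive mode supports T <= {MAX_EXHAUSTIVE_T}, got {T}"
            )
        perms = sorted(itertools.permutations(range(T)))
    elif mode == "sampled":
        if seed is None:
            raise ValueError("sampled mode requires a seed")
        if not n_perm or n_perm < 1:
            raise ValueError("sampled mode requires n_perm >= 1")
        rng = np.random.default_rng(seed)
        perms = [tuple(rng.permutation(T)) for _ in range(n_perm)]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    traj = _profile_matrix(profiles)
    n_profiles = len(profiles)
    counts = np.zeros(n_profiles)
    for perm in perms:
        permuted = norm[:, list(perm)]
        permuted = permuted - permuted[:, [0]]
        ids, _ = _assign_array(permuted, traj)
        counts += np.bincount(ids, minlength=n_profiles + 1)[1:]
    expected = counts / len(perms)

    obs_ids = assignments["profile_id"].to_numpy()
    observed = np.bincount(obs_ids, minlength=n_profiles + 1)[1:]
    n_assigned = int((obs_ids != UNASSIGNED).sum())

    if n_assigned > 0:
        q = expected / n_assigned
        pvals = stats.binom.sf(observed - 1, n_assigned, q)
    else:
        pvals = np.ones(n_profiles)
    bonf = np.minimum(pvals * n_profiles, 1.0)
    return pd.DataFrame(
        {
            "steps": [p.steps for p in profiles],
            "observed": observed,
            "expected": expected,
            "p": pvals,
            "p_bonferroni": bonf,
            "significant": pvals < alpha,
        },
        index=pd.Index([p.id for p in profiles], name="profile_id"),
    )


def collect_profile_genes(
    assignments: pd.DataFrame,
    significance: pd.DataFrame,
    which: str = "all-significant",
) -> dict[int, list]:
    """Gene sets of selected significant profiles.

    ``which`` is one of ``most-significant-increasing`` (the monotone
    all-(+1) profile), ``most-significant-decreasing`` (all-(-1)), or
    ``all-significant``.  A requested monotone profile that is not
    significant contributes an empty set (a warning condition, not an
    error).  Returned as ``{profile_id: [gene ids]}``; sets are disjoint
    because assignment is single-best.
    """
    def genes_of(pid: int) -> list:
        return list(assignments.index[assignments["profile_id"] == pid])

    steps = significance["steps"]
    if which == "all-significant":
        return {
            int(pid): genes_of(int(pid))
            for pid in significance.index[significance["significant"]]
        }
    if which in ("most-significant-increasing", "most-significant-decreasing"):
        sign = 1 if which.endswith("increasing") else -1
        # the constant monotone profile: every step equal to +1 (or -1)
        matches = [
            pid for pid in significance.index
            if set(steps.loc[pid]) == {sign}
        ]
        if not matches:
            return {}
        pid = int(matches[0])
        if not bool(significance.loc[pid, "significant"]):
            return {pid: []}
        return {pid: genes_of(pid)}
    raise ValueError(f"unknown selection {which!r}")
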