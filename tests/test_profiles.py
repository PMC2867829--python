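"""Model-profile enumeration, assignment and the time-permutation null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hepacore as h
from hepacore.profiles import UNASSIGNED


def _norm_frame(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=genes)


# ------------------------------------------------------------- enumeration

def test_profile_count_canonical_design():
    profiles = h.enumerate_model_profiles(4, 1)
    assert len(profiles) == 26
    assert profiles[0].steps == (-1, -1, -1)
    assert profiles[-1].steps == (1, 1, 1)
    assert [p.id for p in profiles] == list(range(1, 27))


def test_profile_count_two_timepoints():
    profiles = h.enumerate_model_profiles(2, 1)
    assert [p.steps for p in profiles] == [(-1,), (1,)]


def test_profile_count_c2():
    assert len(h.enumerate_model_profiles(4, 2)) == 124  # 5^3 - 1


@settings(max_examples=20, deadline=None, derandomize=True)
@given(T=st.integers(2, 5), c=st.integers(1, 2))
def test_profile_count_formula(T, c):
    profiles = h.enumerate_model_profiles(T, c)
    assert len(profiles) == (2 * c + 1) ** (T - 1) - 1
    # lexicographic, flat excluded, trajectories anchored at 0
    steps = [p.steps for p in profiles]
    assert steps == sorted(steps)
    assert all(any(s) for s in steps)
    assert all(p.trajectory[0] == 0 for p in profiles)


def test_enumeration_rejects_degenerate():
    with pytest.raises(ValueError):
        h.enumerate_model_profiles(1, 1)


# ------------------------------------------------------------ normalisation

@pytest.mark.parametrize(
    "vec,expected",
    [
        ((5, 6, 7, 8), (0, 1, 2, 3)),
        ((3, 3, 3, 3), (0, 0, 0, 0)),
        ((3, 2, 2, 1), (0, -1, -1, -2)),
    ],
)
def test_normalize_gene_trajectory(vec, expected):
    assert tuple(h.normalize_gene_trajectory(vec)) == expected


# -------------------------------------------------------------- assignment

def test_assign_exact_match():
    profiles = h.enumerate_model_profiles(4, 1)
    out = h.assign_genes(_norm_frame([[0, 1, 2, 3]]), profiles)
    assigned = profiles[out["profile_id"].iloc[0] - 1]
    assert assigned.steps == (1, 1, 1)
    assert out["r"].iloc[0] == pytest.approx(1.0)


def test_assign_zero_variance_unassigned():
    profiles = h.enumerate_model_profiles(4, 1)
    out = h.assign_genes(_norm_frame([[0, 0, 0, 0]]), profiles)
    assert out["profile_id"].iloc[0] == UNASSIGNED
    assert np.isnan(out["r"].iloc[0])


def test_assign_matches_bruteforce_argmax():
    """Winner's correlation beats every other profile (exhaustive scan)."""
    rng = np.random.default_rng(17)
    profiles = h.enumerate_model_profiles(4, 1)
    norm = h.normalize_gene_trajectory(rng.normal(0, 1, (200, 4)))
    out = h.assign_genes(_norm_frame(norm), profiles)
    for g in range(200):
        rs = [np.corrcoef(norm[g], p.trajectory)[0, 1] for p in profiles]
        best = int(np.argmax(rs)) + 1
        assert out["profile_id"].iloc[g] == best
        assert out["r"].iloc[g] == pytest.approx(max(rs), abs=1e-12)


def test_assign_affine_invariance():
    rng = np.random.default_rng(18)
    profiles = h.enumerate_model_profiles(4, 1)
    norm = h.normalize_gene_trajectory(rng.normal(0, 1, (50, 4)))
    a = h.assign_genes(_norm_frame(norm), profiles)
    b = h.assign_genes(_norm_frame(norm * 3.0), profiles)
    assert (a["profile_id"] == b["profile_id"]).all()


def test_assign_length_mismatch_rejected():
    profiles = h.enumerate_model_profiles(4, 1)
    with pytest.raises(ValueError, match="length"):
        h.assign_genes(_norm_frame([[0, 1, 2]]), profiles)


# ------------------------------------------------------------ significance

def test_significance_enriched_profile():
    """500 genes tracing one profile exactly: its enrichment p < 0.001."""
    profiles = h.enumerate_model_profiles(4, 1)
    target = [p for p in profiles if p.steps == (1, 0, 1)][0]
    norm = _norm_frame(np.tile(target.trajectory, (500, 1)))
    assignments = h.assign_genes(norm, profiles)
    sig = h.profile_significance(assignments, norm, profiles)
    assert sig.loc[target.id, "p"] < 0.001
    assert bool(sig.loc[target.id, "significant"])


def test_significance_expected_counts_conserved():
    rng = np.random.default_rng(19)
    profiles = h.enumerate_model_profiles(4, 1)
    norm = _norm_frame(h.normalize_gene_trajectory(rng.normal(0, 1, (300, 4))))
    assignments = h.assign_genes(norm, profiles)
    sig = h.profile_significance(assignments, norm, profiles)
    n_assigned = int((assignments["profile_id"] != UNASSIGNED).sum())
    assert sig["expected"].sum() == pytest.approx(n_assigned, abs=1e-9)
    assert sig["observed"].sum() == n_assigned


def test_identity_permutation_reproduces_observed_counts():
    """Permuting with the identity alone must reproduce the observed counts."""
    rng = np.random.default_rng(20)
    profiles = h.enumerate_model_profiles(4, 1)
    norm_arr = h.normalize_gene_trajectory(rng.normal(0, 1, (100, 4)))
    norm = _norm_frame(norm_arr)
    assignments = h.assign_genes(norm, profiles)
    observed = np.bincount(assignments["profile_id"], minlength=27)[1:]
    # identity permutation: re-anchor and re-assign changes nothing
    re_assigned = h.assign_genes(_norm_frame(norm_arr - norm_arr[:, [0]]), profiles)
    re_observed = np.bincount(re_assigned["profile_id"], minlength=27)[1:]
    assert (observed == re_observed).all()


def test_significance_null_calibration():
    """Time-shuffled (null) genes: on average <= 10% of profiles significant."""
    profiles = h.enumerate_model_profiles(4, 1)
    rates = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        norm = _norm_frame(h.normalize_gene_trajectory(rng.normal(0, 1, (150, 4))))
        assignments = h.assign_genes(norm, profiles)
        sig = h.profile_significance(assignments, norm, profiles)
        rates.append(sig["significant"].mean())
    assert np.mean(rates) <= 0.10


def test_sampled_mode_requires_seed():
    profiles = h.enumerate_model_profiles(4, 1)
    norm = _norm_frame([[0, 1, 2, 3]])
    assignments = h.assign_genes(norm, profiles)
    with pytest.raises(ValueError, match="seed"):
        h.profile_significance(assignments, norm, profiles, mode="sampled",
                               n_perm=10)


def test_sampled_mode_close_to_exhaustive():
    rng = np.random.default_rng(23)
    profiles = h.enumerate_model_profiles(4, 1)
    norm = _norm_frame(h.normalize_gene_trajectory(rng.normal(0, 1, (200, 4))))
    assignments = h.assign_genes(norm, profiles)
    ex = h.profile_significance(assignments, norm, profiles)
    sa = h.profile_significance(assignments, norm, profiles, mode="sampled",
                                n_perm=500, seed=1)
    assert np.allclose(ex["expected"], sa["expected"], atol=2.0)


# -------------------------------------------------------------- collection

def test_collect_monotone_profiles_disjoint():
    profiles = h.enumerate_model_profiles(4, 1)
    inc = [p for p in profiles if p.steps == (1, 1, 1)][0]
    dec = [p for p in profiles if p.steps == (-1, -1, -1)][0]
    norm = _norm_frame(
        np.vstack([np.tile(inc.trajectory, (60, 1)), np.tile(dec.trajectory, (40, 1))])
    )
    assignments = h.assign_genes(norm, profiles)
    sig = h.profile_significance(assignments, norm, profiles)
    up = h.collect_profile_genes(assignments, sig, "most-significant-increasing")
    down = h.collect_profile_genes(assignments, sig, "most-significant-decreasing")
    assert set(up) == {inc.id} and len(up[inc.id]) == 60
    assert set(down) == {dec.id} and len(down[dec.id]) == 40
    assert not set(up[inc.id]) & set(down[dec.id])
    both = h.collect_profile_genes(assignments, sig, "all-significant")
    assert set(both[inc.id]) == set(up[inc.id])


def test_collect_no_significant_profiles_empty():
    rng = np.random.default_rng(24)
    profiles = h.enumerate_model_profiles(4, 1)
    norm = _norm_frame(h.normalize_gene_trajectory(rng.normal(0, 1, (30, 4))))
    assignments = h.assign_genes(norm, profiles)
    sig = h.profile_significance(assignments, norm, profiles)
    sig["significant"] = False  # force the no-significant case
    assert h.collect_profile_genes(assignments, sig, "all-significant") == {}
    up = h.collect_profile_genes(assignments, sig, "most-significant-increasing")
    assert list(up.values()) in ([], [[]])  # empty set with a warning flag
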