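"""Comparative-Ct (ddCt) relative quantification for qPCR validation.

The comparative method assumes amplification efficiency 2.0 per cycle.  For
each animal, technical duplicate Ct values are averaged per (animal, gene,
role), then

    dCt   = Ct_target - Ct_reference              (per animal)
    ddCt  = dCt - mean dCt over control animals   (per animal, per gene)
    fold  = 2 ** (-ddCt)

so the control group's mean ddCt is 0 by construction and each group's fold
change can be reported as mean +- SD over its animals.  Group differences
are tested on the per-animal dCt values with a two-sample Student's t-test
(equal variances; Welch available as an option).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["compute_ddct", "compare_groups"]

ALPHA = 0.05


def _mean_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Average duplicate Ct columns per (animal, group, gene, role) row."""
    required = {"animal", "group", "gene", "role", "ct1", "ct2"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    ct = table[["ct1", "ct2"]].astype(float)
    if not np.all(np.isfinite(ct.to_numpy())) or np.any(ct.to_numpy() <= 0):
        raise ValueError("Ct values must be finite and positive")
    out = table.copy()
    out["ct"] = ct.mean(axis=1)
    # a gene measured in several rows for one animal: average those too
    return (
        out.groupby(["animal", "group", "gene", "role"], sort=False, as_index=False)[
            "ct"
        ].mean()
    )


def compute_ddct(table: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Per-animal ddCt and fold change of every target gene vs the control group.

    Parameters
    ----------
    table
        Long-format Ct table with columns ``animal``, ``group``, ``gene``,
        ``role`` (``target`` / ``reference``), ``ct1``, ``ct2``.
    control_group
        Group label the ddCt is referenced to.

    Returns
    -------
    pandas.DataFrame
        One row per (animal, gene) with ``dct``, ``ddct``, ``fold``
        (= 2**-ddct) plus the animal's group.

    Raises
    ------
    ValueError
        If an animal lacks reference-gene rows (named in the message) or
        the control group is absent.
    """
    means = _mean_ct(table)
    if control_group not in set(means["group"]):
        raise ValueError(f"control group {control_group!r} absent from Ct table")

    ref = means[means["role"] == "reference"].groupby("animal")["ct"].mean()
    targets = means[means["role"] == "target"]
    missing_ref = sorted(set(targets["animal"]) - set(ref.index))
    if missing_ref:
        raise ValueError(
            f"animal {missing_ref[0]!r} has no reference-gene measurement"
        )

    out = targets.rename(columns={"ct": "ct_target"}).copy()
    out["ct_reference"] = out["animal"].map(ref)
    out["dct"] = out["ct_target"] - out["ct_reference"]

    control_mean = (
        out[out["group"] == control_group].groupby("gene")["dct"].mean()
    )
    missing_ctrl = sorted(set(out["gene"]) - set(control_mean.index))
    if missing_ctrl:
        raise ValueError(
            f"gene {missing_ctrl[0]!r} has no control-group measurements"
        )
    out["ddct"] = out["dct"] - out["gene"].map(control_mean)
    out["fold"] = 2.0 ** (-out["ddct"])
    return out[
        ["animal", "group", "gene", "dct", "ddct", "fold"]
    ].reset_index(drop=True)


def compare_groups(
    results: pd.DataFrame,
    control_group: str,
    alpha: float = ALPHA,
    welch: bool = False,
) -> pd.DataFrame:
    """Group-level summary with a t-test of each treatment group vs control.

    The test compares per-animal dCt values (treatment vs control) with a
    two-sample Student's t-test (``welch=True`` drops the equal-variance
    assumption).  A group with fewer than 2 animals is flagged
    ``untestable`` (p = NaN) rather than raising.

    Returns
    -------
    pandas.DataFrame
        One row per (gene, group) with mean/SD of the fold change, mean
        ddct, ``p``, ``significant`` and ``untestable`` flags.  The control
        group's rows carry p = NaN.
    """
    rows = []
    for gene, sub in results.groupby("gene", sort=False):
        control_dct = sub.loc[sub["group"] == control_group, "dct"].to_numpy()
        for group, grp in sub.groupby("group", sort=False):
            fold = grp["fold"].to_numpy()
            dct = grp["dct"].to_numpy()
            untestable = len(dct) < 2 or len(control_dct) < 2
            if group == control_group or untestable:
                p = np.nan
            else:
                p = float(
                    stats.ttest_ind(dct, control_dct, equal_var=not welch).pvalue
                )
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "n_animals": len(dct),
                    "mean_fold": float(fold.mean()),
                    "sd_fold": float(fold.std(ddof=1)) if len(fold) > 1 else np.nan,
                    "mean_ddct": float(grp["ddct"].mean()),
                    "p": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                    "untestable": bool(untestable and group != control_group),
                }
            )
    return pd.DataFrame(rows)
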