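"""Differential epigenetic heterogeneity (DEH) locus identification.

Two-stage procedure between two sample groups:

1. An effect-size filter independent of the statistical test retains loci
   whose absolute group-mean difference exceeds a threshold (default 0.2).
2. A per-locus test on the surviving loci — Welch's t-test for bounded
   metrics (PDR, epipolymorphism) or a label-permutation test on the group
   mean difference (default for Shannon entropy; 1000 permutations) —
   followed by Benjamini–Hochberg adjustment over the tested loci only.

A locus is a DEH call when its adjusted p-value falls below alpha; its
direction (increased/decreased) is the sign of mean(group_b) - mean(group_a).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import HetMatrix
from .epiallele import EpihetError

logger = logging.getLogger(__name__)

DEFAULT_MIN_ABS_DIFF = 0.2
DEFAULT_N_PERM = 1000
#: metrics tested by permutation when test='auto'
PERMUTATION_METRICS = frozenset({"shannon"})


def stage1_filter(
    matrix: HetMatrix,
    group_a: str,
    group_b: str,
    min_abs_diff: float = DEFAULT_MIN_ABS_DIFF,
) -> pd.DataFrame:
    """Effect-size pre-filter: keep loci with |mean_b - mean_a| > threshold.

    A locus is testable when each group has >= 2 non-missing values; others
    are skipped (count logged).  Returns mean_a, mean_b, diff per retained
    locus.  The filter never inspects p-values.
    """
    sa = matrix.group_samples(group_a)
    sb = matrix.group_samples(group_b)
    if not sa or not sb:
        raise EpihetError(f"unknown or empty group: {group_a!r} / {group_b!r}")
    va, vb = matrix.values[sa], matrix.values[sb]
    n_a, n_b = va.notna().sum(axis=1), vb.notna().sum(axis=1)
    testable = (n_a >= 2) & (n_b >= 2)
    n_skipped = int((~testable).sum())
    if n_skipped:
        logger.info("stage-1: %d loci skipped (fewer than 2 values in a group)", n_skipped)
    mean_a = va.mean(axis=1, skipna=True)[testable]
    mean_b = vb.mean(axis=1, skipna=True)[testable]
    diff = mean_b - mean_a
    keep = diff.abs() > min_abs_diff
    return pd.DataFrame(
        {"mean_a": mean_a[keep], "mean_b": mean_b[keep], "diff": diff[keep]}
    )


def t_test_deh(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variant: str = "welch",
) -> tuple[float, float]:
    """Two-sided t-test on two groups of metric values.

    Welch degrees of freedom by default (``variant='pooled'`` for the
    equal-variance form).  Degenerate inputs follow the conventions: zero
    variance in both groups with equal means gives (0, 1); zero variance
    with unequal means gives an infinite statistic and p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise EpihetError("t-test needs >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        logger.warning("zero variance with unequal means; p -> 0 limit")
        return float(np.sign(b.mean() - a.mean()) * np.inf), 0.0
    res = sps.ttest_ind(b, a, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def permutation_test_deh(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = None,
    alternative: str = "two_sided",
    smooth: bool = False,
) -> float:
    """Label-permutation p-value for the group mean difference.

    All values are pooled, shuffled ``n_perm`` times, and the first
    ``len(values_a)`` entries of each shuffle re-assigned to group a.  The
    p-value is the proportion of permuted differences at least as extreme as
    the observed one: on |difference| for ``two_sided`` (default), or the
    literal one-sided rule (permuted >= observed) for ``greater``.

    ``smooth=True`` uses the (r+1)/(B+1) estimator, which cannot return 0.
    """
    if n_perm < 1:
        raise EpihetError("n_perm must be >= 1")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n1 = a.size
    if n1 + b.size < 4:
        raise EpihetError("permutation test needs >= 4 values in total")
    pool = np.concatenate([a, b])
    observed = b.mean() - a.mean()
    rng = np.random.default_rng(seed)
    # vectorized permutations: argsort of uniforms = random permutation per row
    order = np.argsort(rng.random((n_perm, pool.size)), axis=1)
    shuffled = pool[order]
    perm_diff = shuffled[:, n1:].mean(axis=1) - shuffled[:, :n1].mean(axis=1)
    if alternative == "two_sided":
        hits = np.abs(perm_diff) >= abs(observed) - 1e-12
    elif alternative == "greater":
        hits = perm_diff >= observed - 1e-12
    else:
        raise EpihetError(f"unknown alternative: {alternative!r}")
    r = int(hits.sum())
    if smooth:
        return (r + 1) / (n_perm + 1)
    return r / n_perm


def call_deh(
    matrix: HetMatrix,
    group_a: str,
    group_b: str,
    min_abs_diff: float = DEFAULT_MIN_ABS_DIFF,
    alpha: float = 0.05,
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = None,
    test: str = "auto",
    alternative: str = "two_sided",
) -> pd.DataFrame:
    """Run the full two-stage DEH procedure on a metric matrix.

    ``test`` is ``'auto'`` (permutation for Shannon entropy, t-test
    otherwise), ``'t'``, or ``'permutation'``.  Returns one row per tested
    locus with mean_a, mean_b, diff, statistic, p_value, adjusted_p,
    direction and significant (adjusted_p < alpha).  An empty frame (no
    stage-1 survivor) is a valid result, not an error.
    """
    if test == "auto":
        test = "permutation" if matrix.metric_name in PERMUTATION_METRICS else "t"
    if test not in ("t", "permutation"):
        raise EpihetError(f"unknown test: {test!r}")
    survivors = stage1_filter(matrix, group_a, group_b, min_abs_diff)
    if survivors.empty:
        logger.info("no locus passed the stage-1 filter")
        cols = ["mean_a", "mean_b", "diff", "statistic", "p_value",
                "adjusted_p", "direction", "significant"]
        return pd.DataFrame(columns=cols)
    sa = matrix.group_samples(group_a)
    sb = matrix.group_samples(group_b)
    rng = np.random.default_rng(seed)
    stats_, pvals = [], []
    for locus in survivors.index:
        va = matrix.values.loc[locus, sa].dropna().to_numpy()
        vb = matrix.values.loc[locus, sb].dropna().to_numpy()
        if test == "t":
            stat, p = t_test_deh(va, vb)
        else:
            p = permutation_test_deh(
                va, vb, n_perm=n_perm,
                seed=int(rng.integers(2 ** 31)), alternative=alternative,
            )
            stat = float(np.mean(vb) - np.mean(va))
        stats_.append(stat)
        pvals.append(p)
    out = survivors.copy()
    out["statistic"] = stats_
    out["p_value"] = pvals
    # BH over the stage-1 survivors only (independent filtering)
    out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["direction"] = np.where(out["diff"] > 0, "increased", "decreased")
    out["significant"] = out["adjusted_p"] < alpha
    out.attrs["metadata"] = {
        "metric": matrix.metric_name, "test": test, "alternative": alternative,
        "min_abs_diff": min_abs_diff, "alpha": alpha,
        "adjustment": "fdr_bh over stage-1 survivors", "n_perm": n_perm,
        "groups": (group_a, group_b), "diff_direction": f"{group_b} - {group_a}",
    }
    return out
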