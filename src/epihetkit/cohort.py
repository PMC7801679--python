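"""Locus x sample heterogeneity matrix and group-comparison views.

Builds a matrix with one row per 4-CpG locus and one column per sample,
restricted to loci observed in at least a configurable fraction of samples,
then offers the standard cohort views: grouped boxplot of per-sample means,
PCA, hierarchical clustering heatmap of the most variable loci, t-SNE, and
MA-plot data for differential-heterogeneity visualization.

Missing-data policy: multivariate views (PCA, t-SNE, hierarchical
clustering) use the complete-case row subset; univariate summaries use all
available cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .epiallele import EpihetError, EpialleleProfile
from .extraction import LocusComparison, read_profile_table
from .metrics import evaluate_metric, get_metric

logger = logging.getLogger(__name__)

matplotlib_backend_set = False


def _pyplot():
    """Import pyplot lazily with a file-writing backend."""
    global matplotlib_backend_set
    import matplotlib

    if not matplotlib_backend_set:
        matplotlib.use("Agg", force=False)
        matplotlib_backend_set = True
    import matplotlib.pyplot as plt

    return plt


class EmptyMatrixError(EpihetError):
    pass


@dataclass
class HetMatrix:
    """Locus x sample matrix of one heterogeneity metric with group labels."""

    values: pd.DataFrame  # rows: locus ids; columns: sample ids; NaN = missing
    metric_name: str
    groups: Dict[str, str]  # sample id -> group label

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise EpihetError(f"samples without group labels: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def loci(self) -> list[str]:
        return list(self.values.index)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def complete_cases(self) -> pd.DataFrame:
        return self.values.dropna(axis=0)


ProfileSource = Union[str, Sequence[EpialleleProfile]]


def _load_profiles(source: ProfileSource) -> Sequence[EpialleleProfile]:
    if isinstance(source, str):
        records, mode = read_profile_table(source)
        if mode == "paired":
            records = [r.profile_a for r in records if isinstance(r, LocusComparison)]
        return records
    return source


def build_matrix(
    sample_tables: Mapping[str, ProfileSource],
    metric_name: str,
    groups: Mapping[str, str],
    shared_fraction: float = 1.0,
) -> HetMatrix:
    """Assemble the locus x sample metric matrix.

    ``sample_tables`` maps sample id to either a profile-table path or an
    in-memory list of profiles.  Rows are restricted to loci observed in at
    least ``shared_fraction`` of the samples; unobserved cells are NaN.
    """
    if len(sample_tables) < 2:
        raise EpihetError("need at least 2 samples to build a matrix")
    if not (0 < shared_fraction <= 1):
        raise EpihetError("shared_fraction must lie in (0, 1]")
    get_metric(metric_name)  # fail early on unknown metric
    columns = {}
    for sample, source in sample_tables.items():
        profiles = _load_profiles(source)
        columns[sample] = {p.locus.id: evaluate_metric(metric_name, p) for p in profiles}
    values = pd.DataFrame(columns)
    n = values.shape[1]
    keep = values.notna().sum(axis=1) >= shared_fraction * n
    values = values.loc[keep].sort_index()
    if values.empty:
        raise EmptyMatrixError(
            f"no locus is observed in >= {shared_fraction:.0%} of the {n} samples"
        )
    return HetMatrix(values, metric_name, dict(groups))


def group_mean_summary(matrix: HetMatrix, out: Optional[str] = None) -> pd.DataFrame:
    """Per-sample mean metric over non-missing loci, with a grouped boxplot.

    Samples with no observed loci are excluded with a warning.  If ``out``
    is given, a boxplot of the means by group is written there.
    """
    means = matrix.values.mean(axis=0, skipna=True)
    dropped = means.index[means.isna()]
    for s in dropped:
        logger.warning("sample %s has no observed loci; excluded from summary", s)
    means = means.dropna()
    summary = pd.DataFrame(
        {"mean": means, "group": [matrix.groups[s] for s in means.index]}
    )
    if out:
        plt = _pyplot()
        fig, ax = plt.subplots(figsize=(4, 4))
        order = sorted(summary["group"].unique())
        data = [summary.loc[summary["group"] == g, "mean"] for g in order]
        ax.boxplot(data, tick_labels=order)
        ax.set_ylabel(f"mean {matrix.metric_name}")
        fig.tight_layout()
        fig.savefig(out)
        plt.close(fig)
    return summary


def pca_view(
    matrix: HetMatrix,
    center: bool = True,
    scale: bool = False,
    out: Optional[str] = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the complete-case loci.

    Returns (coordinates, variance_explained): sample coordinates on all
    principal components and the per-component variance fractions (sum 1).
    """
    cc = matrix.complete_cases()
    if cc.shape[0] < 2 or cc.shape[1] < 2:
        raise EpihetError("PCA needs >= 2 complete-case loci and >= 2 samples")
    X = cc.T.to_numpy(dtype=float)  # samples x loci
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    coords = U * S
    var = S ** 2
    var_explained = var / var.sum()
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    coords_df = pd.DataFrame(coords, index=cc.columns, columns=cols)
    if out:
        plt = _pyplot()
        fig, ax = plt.subplots(figsize=(4, 4))
        for g in sorted(set(matrix.groups.values())):
            idx = [s for s in coords_df.index if matrix.groups[s] == g]
            ax.scatter(coords_df.loc[idx, "PC1"], coords_df.loc[idx, "PC2"], label=g)
        ax.set_xlabel(f"PC1 ({var_explained[0]:.1%})")
        ax.set_ylabel(f"PC2 ({var_explained[1]:.1%})")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out)
        plt.close(fig)
    return coords_df, var_explained


def hierarchical_view(
    matrix: HetMatrix,
    distance: str = "euclidean",
    linkage: str = "ward",
    top_sd_fraction: float = 0.05,
    out: Optional[str] = None,
):
    """Cluster samples on the most variable loci.

    Loci are ranked by row standard deviation over the complete-case subset
    and the top fraction retained (default 5%).  Returns the sample-linkage
    matrix and the retained sub-matrix.
    """
    cc = matrix.complete_cases()
    n_keep = int(np.floor(top_sd_fraction * cc.shape[0]))
    if top_sd_fraction >= 1.0:
        n_keep = cc.shape[0]
    if n_keep < 2:
        raise EpihetError(
            f"top_sd_fraction={top_sd_fraction} keeps {n_keep} loci; need >= 2"
        )
    sd = cc.std(axis=1, ddof=1)
    kept = cc.loc[sd.sort_values(ascending=False).index[:n_keep]]
    dist = pdist(kept.T.to_numpy(dtype=float), metric=distance)
    Z = hierarchy.linkage(dist, method=linkage)
    if out:
        plt = _pyplot()
        fig, axes = plt.subplots(
            2, 1, figsize=(max(4, 0.5 * kept.shape[1]), 6),
            height_ratios=[1, 3], sharex=False,
        )
        dn = hierarchy.dendrogram(Z, labels=list(kept.columns), ax=axes[0])
        order = dn["ivl"]
        axes[1].imshow(kept[order].to_numpy(), aspect="auto", cmap="RdBu_r")
        axes[1].set_xticks(range(len(order)))
        axes[1].set_xticklabels(
            [f"{s} ({matrix.groups[s]})" for s in order], rotation=90, fontsize=6
        )
        fig.tight_layout()
        fig.savefig(out)
        plt.close(fig)
    return Z, kept


def tsne_view(
    matrix: HetMatrix,
    perplexity: float = 5.0,
    seed: int = 0,
    out: Optional[str] = None,
) -> pd.DataFrame:
    """Two-dimensional t-SNE embedding of the samples (PCA initialization).

    Deterministic for a fixed seed.  Requires perplexity < (n_samples - 1)/3.
    """
    from sklearn.manifold import TSNE

    cc = matrix.complete_cases()
    n = cc.shape[1]
    bound = (n - 1) / 3
    if perplexity >= bound:
        raise EpihetError(
            f"perplexity must be < (n_samples - 1)/3 = {bound:.2f}; got {perplexity}"
        )
    X = cc.T.to_numpy(dtype=float)
    emb = TSNE(
        n_components=2, perplexity=perplexity, init="pca", random_state=seed
    ).fit_transform(X)
    coords = pd.DataFrame(emb, index=cc.columns, columns=["TSNE1", "TSNE2"])
    if out:
        plt = _pyplot()
        fig, ax = plt.subplots(figsize=(4, 4))
        for g in sorted(set(matrix.groups.values())):
            idx = [s for s in coords.index if matrix.groups[s] == g]
            ax.scatter(coords.loc[idx, "TSNE1"], coords.loc[idx, "TSNE2"], label=g)
        ax.legend()
        fig.tight_layout()
        fig.savefig(out)
        plt.close(fig)
    return coords


def ma_data(
    matrix: HetMatrix,
    group_a: str,
    group_b: str,
    highlight: Optional[Sequence[str]] = None,
    out: Optional[str] = None,
) -> pd.DataFrame:
    """Per-locus (A, M) pairs for an MA plot.

    M = mean(group_b) - mean(group_a); A is the average of the two group
    means.  Loci missing in an entire group are excluded (count logged).
    """
    sa = matrix.group_samples(group_a)
    sb = matrix.group_samples(group_b)
    if not sa or not sb:
        raise EpihetError(f"both groups must be non-empty: {group_a!r}, {group_b!r}")
    mean_a = matrix.values[sa].mean(axis=1, skipna=True)
    mean_b = matrix.values[sb].mean(axis=1, skipna=True)
    ok = mean_a.notna() & mean_b.notna()
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("MA data: %d loci missing in an entire group; excluded", n_excluded)
    df = pd.DataFrame(
        {"A": (mean_a[ok] + mean_b[ok]) / 2, "M": mean_b[ok] - mean_a[ok]}
    )
    df["highlight"] = df.index.isin(set(highlight)) if highlight is not None else False
    if out:
        plt = _pyplot()
        fig, ax = plt.subplots(figsize=(4, 4))
        bg = df[~df["highlight"]]
        fg = df[df["highlight"]]
        ax.scatter(bg["A"], bg["M"], s=4, c="grey")
        ax.scatter(fg["A"], fg["M"], s=6, c="red")
        ax.axhline(0, lw=0.5, c="k")
        # direction convention stated on the axis: group_b minus group_a
        ax.set_xlabel(f"A: mean {matrix.metric_name}")
        ax.set_ylabel(f"M: {group_b} - {group_a}")
        fig.tight_layout()
        fig.savefig(out)
        plt.close(fig)
    return df
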