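"""Co-epigenetic-heterogeneity networks, modules, and module annotation.

Starting from DEH loci, this module maps loci to genes by interval overlap,
builds locus- or gene-level correlation networks across samples (Pearson or
biweight midcorrelation), detects modules by weighted-network hierarchical
clustering (soft-threshold adjacency, topological overlap, average linkage,
height cut with a minimum module size; unassigned nodes are labelled
"grey"), summarizes each module by its first principal component, correlates
module PC1 with clinical traits, annotates modules by hypergeometric
enrichment of gene sets (DEGs, pathways), and reports node topology
(degree, eigenvector centrality, betweenness, closeness) of thresholded
module subnetworks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .epiallele import EpihetError, LocusKey

logger = logging.getLogger(__name__)

#: module color palette (decreasing module size); "grey" is reserved for
#: unassigned nodes and never used for a module.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]
GREY = "grey"

REGION_CLASSES = {"promoter", "intron", "exon", "cgi", "shore", "custom"}


# ---------------------------------------------------------------------------
# Annotations and gene sets
# ---------------------------------------------------------------------------

def read_bed(path: str) -> pd.DataFrame:
    """Read genomic region annotations from BED (0-based half-open).

    Columns used: chrom, start, end, name (gene id); optional score, strand
    and a 7th column giving the region class (defaults to "custom").
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise EpihetError(f"{path}:{lineno}: BED line needs >= 4 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise EpihetError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise EpihetError(f"{path}:{lineno}: end must exceed start")
            gene = fields[3]
            if not gene:
                raise EpihetError(f"{path}:{lineno}: empty gene id")
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            region = fields[6] if len(fields) > 6 and fields[6] else "custom"
            rows.append((fields[0], start, end, strand, gene, region))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "gene", "region_class"]
    )


def read_gmt(path: str) -> Dict[str, Set[str]]:
    """Read gene sets from GMT (set name, description, members...)."""
    sets: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EpihetError(f"{path}:{lineno}: GMT line needs name, description, genes")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def map_loci_to_genes(
    deh_loci: Sequence[LocusKey],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Assign loci to genes by >= 1 bp overlap of the locus CpG span.

    The locus span is the closed interval [positions[0], positions[3]]
    treated as half-open [positions[0], positions[3] + 1); annotation
    intervals are 0-based half-open.  A locus may map to multiple genes;
    unmapped loci are reported in the frame with gene = NaN.
    """
    out = []
    by_chrom = {c: g for c, g in annotation.groupby("chrom")}
    for locus in deh_loci:
        lo, hi = locus.positions[0], locus.positions[3] + 1
        hits = by_chrom.get(locus.chrom)
        mapped = False
        if hits is not None:
            overlap = hits[(hits["start"] < hi) & (hits["end"] > lo)]
            for _, row in overlap.iterrows():
                out.append((locus.id, row["gene"], row["region_class"]))
                mapped = True
        if not mapped:
            out.append((locus.id, np.nan, np.nan))
    df = pd.DataFrame(out, columns=["locus", "gene", "region_class"])
    n_unmapped = int(df["gene"].isna().sum())
    if n_unmapped:
        logger.info("%d loci did not map to any gene", n_unmapped)
    return df


def gene_level_matrix(
    locus_values: pd.DataFrame,
    assignments: pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate a locus x sample matrix to gene level.

    The gene value per sample is the mean over that gene's loci with
    non-missing values; a gene with all loci missing in a sample gets NaN.
    """
    mapped = assignments.dropna(subset=["gene"])
    if mapped.empty:
        raise EpihetError("no locus-to-gene assignments")
    joined = locus_values.reindex(mapped["locus"])
    joined.index = pd.Index(mapped["gene"], name="gene")
    return joined.groupby(level="gene").mean()


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def _bicor_prepare(X: np.ndarray) -> np.ndarray:
    """Per-row robust standardization for the biweight midcorrelation."""
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    u = (X - med) / (9.0 * mad)
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    xt = (X - med) * w
    norm = np.sqrt((xt ** 2).sum(axis=1, keepdims=True))
    return xt / norm


def correlation_matrix(values: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Node x node correlation across samples (rows are nodes).

    ``method`` is "pearson" or "bicor" (biweight midcorrelation with the
    standard 9-MAD tuning and hard weight cutoff at |u| = 1).  Constant rows
    (zero variance / zero MAD) have undefined correlation and are excluded
    with a logged count.  Complete-case rows are required.
    """
    X = values.dropna(axis=0).to_numpy(dtype=float)
    nodes = values.dropna(axis=0).index
    if X.shape[1] < 3:
        raise EpihetError("correlation needs >= 3 samples")
    if method == "pearson":
        ok = X.std(axis=1) > 0
    elif method == "bicor":
        med = np.median(X, axis=1, keepdims=True)
        ok = np.median(np.abs(X - med), axis=1) > 0
    else:
        raise EpihetError(f"unknown correlation method: {method!r}")
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%d constant rows excluded from the correlation matrix", n_dropped)
    X, nodes = X[ok], nodes[ok]
    if method == "pearson":
        C = np.corrcoef(X)
    else:
        Z = _bicor_prepare(X)
        C = Z @ Z.T
    C = np.clip((C + C.T) / 2, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=nodes, columns=nodes)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

@dataclass
class ModuleSet:
    """Node -> module assignment plus per-module summaries."""

    labels: Dict[str, str]  # node -> color ("grey" = unassigned)
    linkage: np.ndarray = field(repr=False, default=None)
    pc1: Optional[pd.DataFrame] = None  # module x sample
    pc1_var_explained: Dict[str, float] = field(default_factory=dict)
    trait_r: Optional[pd.DataFrame] = None
    trait_p: Optional[pd.DataFrame] = None
    enrichment: Optional[pd.DataFrame] = None
    topology: Optional[pd.DataFrame] = None

    @property
    def modules(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for node, color in self.labels.items():
            if color != GREY:
                out.setdefault(color, []).append(node)
        return out

    def members(self, color: str) -> List[str]:
        return self.modules.get(color, [])


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix of a weighted adjacency."""
    A = adjacency.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (shared + A) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    correlations: pd.DataFrame,
    power: float = 6.0,
    network_type: str = "unsigned",
    min_module_size: int = 30,
    cut_height: Optional[float] = None,
) -> ModuleSet:
    """Detect co-heterogeneity modules from a correlation matrix.

    Pipeline: soft-threshold adjacency (|cor|^power unsigned, or
    ((1+cor)/2)^power signed), topological-overlap dissimilarity,
    average-linkage hierarchical tree, height cut, clusters below
    ``min_module_size`` relabelled "grey".  When ``cut_height`` is None the
    tree is cut inside the largest gap of the merge-height sequence (the
    usual elbow heuristic for branch separation); pass an explicit height
    on the [0, 1] overlap-dissimilarity scale to override.  Modules are
    named from a fixed color palette in decreasing size order (ties broken
    by smallest member id).  Fewer nodes than ``min_module_size``
    trivially yields all-grey.
    """
    nodes = list(correlations.index)
    if len(nodes) < min_module_size:
        logger.warning(
            "only %d nodes (< min_module_size=%d); all grey", len(nodes), min_module_size
        )
        return ModuleSet(labels={n: GREY for n in nodes})
    C = correlations.to_numpy(dtype=float)
    if network_type == "unsigned":
        A = np.abs(C) ** power
    elif network_type == "signed":
        A = ((1.0 + C) / 2.0) ** power
    else:
        raise EpihetError(f"unknown network type: {network_type!r}")
    diss = 1.0 - topological_overlap(A)
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2, 0.0, None)
    Z = hierarchy.linkage(squareform(diss, checks=False), method="average")
    if cut_height is None:
        heights = Z[:, 2]
        if len(heights) > 1:
            gaps = np.diff(heights)
            i = int(np.argmax(gaps))
            cut_height = float((heights[i] + heights[i + 1]) / 2)
        else:
            cut_height = float(heights[-1]) / 2
    flat = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    clusters: Dict[int, List[str]] = {}
    for node, cl in zip(nodes, flat):
        clusters.setdefault(int(cl), []).append(node)
    kept = [m for m in clusters.values() if len(m) >= min_module_size]
    kept.sort(key=lambda m: (-len(m), min(m)))
    labels = {n: GREY for n in nodes}
    for color, members in zip(MODULE_COLORS, kept):
        for n in members:
            labels[n] = color
    if len(kept) > len(MODULE_COLORS):
        for i, members in enumerate(kept[len(MODULE_COLORS):]):
            for n in members:
                labels[n] = f"module{len(MODULE_COLORS) + i + 1}"
    if not kept:
        logger.warning("no module reached min_module_size=%d; all nodes grey", min_module_size)
    return ModuleSet(labels=labels, linkage=Z)


# ---------------------------------------------------------------------------
# Module summaries
# ---------------------------------------------------------------------------

def module_pc1(values: pd.DataFrame, members: Sequence[str]) -> tuple[pd.Series, float]:
    """First principal component of a module across samples.

    Member rows are z-scored, and PC1 of the member x sample matrix is
    returned as one score per sample together with its variance-explained
    fraction.  The sign is oriented so PC1 correlates non-negatively with
    the module's mean profile.
    """
    if len(members) < 2:
        raise EpihetError("module PC1 needs >= 2 members")
    sub = values.loc[list(members)].dropna(axis=0)
    X = sub.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    tol = 1e-12 * max(1.0, float(np.abs(X).max()))
    if (sd <= tol).all():
        raise EpihetError("degenerate module: all member rows constant")
    X = X[sd > tol]
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    score = Vt[0]
    var_explained = float(S[0] ** 2 / (S ** 2).sum())
    mean_profile = X.mean(axis=0)
    if np.dot(score, mean_profile - mean_profile.mean()) < 0:
        score = -score
    return pd.Series(score, index=sub.columns, name="PC1"), var_explained


def module_eigengenes(values: pd.DataFrame, modules: ModuleSet) -> pd.DataFrame:
    """PC1 scores for every non-grey module (module x sample frame)."""
    rows = {}
    for color, members in sorted(modules.modules.items()):
        score, ve = module_pc1(values, members)
        rows[color] = score
        modules.pc1_var_explained[color] = ve
    pc1 = pd.DataFrame(rows).T
    modules.pc1 = pc1
    return pc1


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided t-distribution p-value."""
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    if not np.isfinite(r):
        return np.nan, np.nan
    r_ = min(max(r, -1.0), 1.0)
    if abs(r_) == 1.0:
        return r_, 0.0
    t = r_ * np.sqrt((n - 2) / (1.0 - r_ ** 2))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r_, float(p)


def module_trait_correlation(
    pc1: pd.DataFrame,
    traits: pd.DataFrame,
    out: Optional[str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate each module's PC1 with each clinical trait.

    Returns (r, p) frames (module x trait).  Pearson correlation over
    samples with a non-missing trait; at least 3 such samples required per
    cell, and constant traits yield NaN cells (flagged in the log).
    """
    samples = [s for s in pc1.columns if s in traits.index]
    r_df = pd.DataFrame(index=pc1.index, columns=traits.columns, dtype=float)
    p_df = r_df.copy()
    for trait in traits.columns:
        tv = traits.loc[samples, trait].astype(float)
        ok = tv.notna()
        if ok.sum() < 3:
            raise EpihetError(f"trait {trait!r} has < 3 non-missing samples")
        if tv[ok].nunique() == 1:
            logger.warning("trait %r is constant; correlations undefined", trait)
            continue
        for module in pc1.index:
            x = pc1.loc[module, tv[ok].index].to_numpy(dtype=float)
            r, p = pearson_with_p(x, tv[ok].to_numpy())
            r_df.loc[module, trait] = r
            p_df.loc[module, trait] = p
    if out:
        from .cohort import _pyplot

        plt = _pyplot()
        fig, ax = plt.subplots(figsize=(2 + r_df.shape[1], 1 + 0.4 * r_df.shape[0]))
        im = ax.imshow(r_df.to_numpy(dtype=float), cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_xticks(range(r_df.shape[1]), r_df.columns, rotation=45)
        ax.set_yticks(range(r_df.shape[0]), r_df.index)
        for i in range(r_df.shape[0]):
            for j in range(r_df.shape[1]):
                r, p = r_df.iat[i, j], p_df.iat[i, j]
                if np.isfinite(r):
                    ax.text(j, i, f"{r:.2f}\n({p:.2g})", ha="center", va="center",
                            fontsize=6)
        fig.colorbar(im, ax=ax, label="Pearson r")
        fig.tight_layout()
        fig.savefig(out)
        plt.close(fig)
    return r_df, p_df


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def hypergeometric_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N population, K successes, n draws)."""
    if k <= 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def enrich_hypergeometric(
    module_genes: Mapping[str, Iterable[str]],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    deg_fallback: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in modules.

    For each (module, set) pair, p = P[X >= k] with k the overlap, K the set
    size, n the module size and N the universe size; BH adjustment spans all
    tested pairs.  With ``deg_fallback`` (the DEG-annotation mode), if no
    pair is significant the rows with any overlap are flagged instead.
    """
    universe = set(universe)
    if not universe:
        raise EpihetError("empty gene universe")
    rows = []
    for module, genes in module_genes.items():
        mod = set(genes) & universe
        if set(genes) - universe:
            raise EpihetError(f"module {module!r} has genes outside the universe")
        for name, members in gene_sets.items():
            gs = set(members) & universe
            if not gs:
                raise EpihetError(f"gene set {name!r} has no genes in the universe")
            k = len(mod & gs)
            p = hypergeometric_tail(k, len(universe), len(gs), len(mod))
            rows.append((module, name, k, len(gs), len(mod), len(universe), p))
    df = pd.DataFrame(
        rows, columns=["module", "set", "k", "set_size", "module_size", "universe", "p"]
    )
    from statsmodels.stats.multitest import multipletests

    df["adjusted_p"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    df["significant"] = df["adjusted_p"] < alpha
    df["pct_overlap"] = df["k"] / df["module_size"].replace(0, np.nan)
    if deg_fallback and not df["significant"].any():
        logger.info("no module significantly enriched; returning modules containing set genes")
        df["contains_genes"] = df["k"] > 0
    return df


def enrichment_scatter(enrichment: pd.DataFrame, out: str, y: str = "adjusted_p") -> None:
    """Scatter of module size vs -log10 adjusted p (or percentage overlap)."""
    from .cohort import _pyplot

    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(4, 4))
    yv = (
        -np.log10(enrichment["adjusted_p"].clip(lower=1e-300))
        if y == "adjusted_p"
        else 100 * enrichment["pct_overlap"]
    )
    colors = [
        m if s else GREY
        for m, s in zip(enrichment["module"], enrichment["significant"])
    ]
    safe = []
    import matplotlib.colors as mcolors

    for c in colors:
        safe.append(c if c in mcolors.CSS4_COLORS else "tab:blue")
    ax.scatter(enrichment["module_size"], yv, c=safe, s=18)
    ax.set_xlabel("module size")
    ax.set_ylabel("-log10 adjusted p" if y == "adjusted_p" else "% genes in set")
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def module_graph(
    members: Sequence[str],
    correlations: pd.DataFrame,
    edge_cutoff: float = 0.2,
) -> nx.Graph:
    """Thresholded undirected module subnetwork: edges where |cor| > cutoff."""
    if not (0 <= edge_cutoff < 1):
        raise EpihetError("edge_cutoff must lie in [0, 1)")
    members = list(members)
    G = nx.Graph()
    G.add_nodes_from(members)
    sub = correlations.loc[members, members].to_numpy(dtype=float)
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if abs(sub[i, j]) > edge_cutoff:
                G.add_edge(members[i], members[j], weight=float(sub[i, j]))
    return G


def module_topology(
    members: Sequence[str],
    correlations: pd.DataFrame,
    edge_cutoff: float = 0.2,
) -> pd.DataFrame:
    """Per-node degree, eigenvector centrality, betweenness and closeness.

    Metrics are computed on the |cor| > cutoff subnetwork.  Closeness uses
    the Wasserman–Faust per-component normalization; isolated nodes get 0
    for every metric.  Eigenvector centrality is taken from the adjacency
    spectrum (largest eigenvalue), which handles disconnected graphs.
    """
    G = module_graph(members, correlations, edge_cutoff)
    degree = dict(G.degree())
    betweenness = nx.betweenness_centrality(G)
    closeness = nx.closeness_centrality(G, wf_improved=True)
    if G.number_of_edges() == 0:
        eigen = {n: 0.0 for n in G}
    else:
        A = nx.to_numpy_array(G, nodelist=list(G), weight=None)
        vals, vecs = np.linalg.eigh(A)
        v = np.abs(vecs[:, int(np.argmax(vals))])
        v = v / v.sum() if v.sum() else v
        eigen = dict(zip(list(G), v))
    return pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "eigenvector": pd.Series(eigen),
            "betweenness": pd.Series(betweenness),
            "closeness": pd.Series(closeness),
        }
    ).loc[list(members)]


def export_subnetwork(G: nx.Graph, graphml_path: Optional[str] = None,
                      edgelist_path: Optional[str] = None) -> None:
    """Write a module subnetwork as GraphML and/or a TSV edge list."""
    if graphml_path:
        nx.write_graphml(G, graphml_path)
    if edgelist_path:
        with open(edgelist_path, "w") as fh:
            fh.write("node_a\tnode_b\tcorrelation\n")
            for u, v, d in G.edges(data=True):
                fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):.6f}\n")
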