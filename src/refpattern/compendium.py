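"""Reference-transcriptome compendium: harmonisation and pattern discovery.

A compendium merges reference arrays (purified cell types, stimulated and
control arms) onto one shared probe-set universe and quantile-normalises
them so co-expression is not driven by platform or study scale. Gene
patterns are then found by hierarchically clustering the gene-to-gene
Pearson correlation matrix (Euclidean distance, average linkage) computed
over the reference arrays, and each gene cluster is aligned with the
condition whose arrays express it most strongly (maximal mean z-score).
Sample-level structure (hierarchical clustering and PCA of z-normalised
log2 signals) summarises how well a gene list separates sample groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .types import ConfigurationError, ExpressionMatrix, PipelineError

__all__ = [
    "Compendium",
    "CoexpressionMatrix",
    "ClusteringParams",
    "GeneClustering",
    "SampleStructure",
    "quantile_normalize",
    "build_compendium",
    "gene_coexpression",
    "cluster_genes",
    "assign_patterns",
    "sample_structure",
    "zscore_log2",
]

_META_COLUMNS = ("array_id", "dataset_id", "condition", "cell_class", "control_of")


@dataclass(frozen=True)
class ClusteringParams:
    """Agglomeration settings; restricted to the supported combinations."""

    distance: str = "euclidean"
    linkage: str = "average"
    k: int | None = None

    def __post_init__(self) -> None:
        if self.distance not in ("euclidean", "correlation"):
            raise ConfigurationError(f"unsupported distance {self.distance!r}")
        if self.linkage not in ("average", "complete", "single", "ward"):
            raise ConfigurationError(f"unsupported linkage {self.linkage!r}")
        if self.k is not None and self.k < 1:
            raise ConfigurationError("tree-cut k must be >= 1")


@dataclass
class Compendium:
    """Quantile-normalised reference arrays plus per-array annotations.

    Arrays reused as controls for several stimulated arms are stored once;
    ``metadata['control_of']`` records the stimulated->control links at the
    condition level. ``normalized`` records whether quantile normalisation
    has been applied.
    """

    expr: ExpressionMatrix
    metadata: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in _META_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise PipelineError(f"compendium metadata lacks columns: {missing}")
        unknown = set(self.expr.samples) - set(self.metadata["array_id"])
        if unknown:
            raise PipelineError(f"arrays without metadata: {sorted(unknown)[:5]}")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.metadata["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def arrays_of(self, condition: str) -> list[str]:
        ids = self.metadata.loc[self.metadata["condition"] == condition, "array_id"]
        return [a for a in ids if a in set(self.expr.samples)]

    def control_condition_of(self, condition: str) -> str | None:
        rows = self.metadata.loc[self.metadata["condition"] == condition, "control_of"]
        links = {str(v) for v in rows if isinstance(v, str) and v}
        return links.pop() if links else None


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the rank-wise mean distribution.

    After normalisation all columns share one multiset of values: position
    k of each sorted column equals the mean of the k-th order statistics
    of the input columns. Tied input values receive the mean of the target
    values at their tied ranks, which makes the transform idempotent.
    """
    if values.shape[1] < 2:
        raise PipelineError("quantile normalization needs >= 2 arrays")
    if values.shape[0] == 0:
        raise PipelineError("empty probe-set universe")
    arr = values.to_numpy(dtype=float)
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = target
        # average target values over tied input ranks
        ties = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = ties.to_numpy()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def build_compendium(
    sources: list[tuple[ExpressionMatrix, pd.DataFrame]],
    normalize: bool = True,
) -> Compendium:
    """Merge reference sources on the intersection of probe-set universes.

    Each source is (expression, metadata). Only probe-sets shared by all
    sources are retained (no imputation across platforms); the merged
    arrays are then quantile-normalised unless ``normalize`` is False.
    """
    if not sources:
        raise PipelineError("no sources to merge")
    shared = sources[0][0].probe_sets
    for expr, _ in sources[1:]:
        shared = shared.intersection(expr.probe_sets)
    if len(shared) == 0:
        raise PipelineError("empty intersection of probe-set universes")
    shared = sources[0][0].probe_sets[sources[0][0].probe_sets.isin(shared)]
    values = pd.concat([expr.values.loc[shared] for expr, _ in sources], axis=1)
    meta = pd.concat([m for _, m in sources], axis=0)
    if meta["array_id"].duplicated().any():
        dup = meta.loc[meta["array_id"].duplicated(), "array_id"].tolist()
        raise PipelineError(f"duplicate array IDs across sources: {dup[:5]}")
    if normalize:
        values = quantile_normalize(values)
    groups = meta.set_index("array_id")["condition"].loc[values.columns]
    expr = ExpressionMatrix(values, groups)
    return Compendium(expr, meta.reset_index(drop=True), normalized=normalize)


@dataclass
class CoexpressionMatrix:
    """Gene x gene Pearson correlations over the reference arrays.

    Constant genes cannot carry a correlation; their rows/columns are set
    to 0 (diagonal kept at 1) and listed in ``constant_genes``.
    """

    r: pd.DataFrame
    constant_genes: list[str] = field(default_factory=list)


def gene_coexpression(comp: Compendium, gene_list: list[str]) -> CoexpressionMatrix:
    """Pearson correlation of every gene pair across all distinct arrays.

    Each distinct array counts once, regardless of how often it is reused
    as a control in condition links.
    """
    missing = [g for g in gene_list if g not in comp.expr.probe_sets]
    if missing:
        raise PipelineError(f"genes outside the compendium universe: {missing[:5]}")
    if len(comp.expr.samples) < 3:
        raise PipelineError("need >= 3 arrays for co-expression")
    block = comp.expr.values.loc[gene_list].to_numpy(dtype=float)
    sd = block.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s); correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(np.where(constant[:, None], 0.0, block))
    r = (r + r.T) / 2.0  # exact symmetry despite float rounding
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    df = pd.DataFrame(r, index=gene_list, columns=gene_list)
    return CoexpressionMatrix(df, [g for g, c in zip(gene_list, constant) if c])


@dataclass
class GeneClustering:
    """Dendrogram over genes plus a deterministic leaf order."""

    linkage: np.ndarray
    genes: list[str]
    leaf_order: list[str]
    labels: pd.Series | None = None  # gene -> cluster id when k was given


def cluster_genes(
    cm: CoexpressionMatrix, params: ClusteringParams = ClusteringParams()
) -> GeneClustering:
    """Hierarchical clustering of the correlation-matrix rows.

    The feature vector of a gene is its row of correlations to all genes,
    so two genes cluster together when they co-vary with the same partners.
    scipy's agglomeration is deterministic for fixed input order, giving a
    reproducible leaf order (ties resolve to the lower original index).
    """
    genes = list(cm.r.index)
    if len(genes) < 2:
        raise PipelineError("need >= 2 genes to cluster")
    features = cm.r.to_numpy(dtype=float)
    if params.distance == "euclidean":
        dist = pdist(features, metric="euclidean")
    else:
        dist = pdist(features, metric="correlation")
    Z = hierarchy.linkage(dist, method=params.linkage)
    order = hierarchy.leaves_list(Z)
    labels = None
    if params.k is not None:
        flat = hierarchy.fcluster(Z, t=params.k, criterion="maxclust")
        labels = pd.Series(flat, index=genes, name="cluster")
    return GeneClustering(Z, genes, [genes[i] for i in order], labels)


def zscore_log2(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score of log2 signals across arrays; constant genes -> 0."""
    log2 = np.log2(values)
    mean = log2.mean(axis=1)
    sd = log2.std(axis=1, ddof=1)
    z = log2.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def assign_patterns(comp: Compendium, labels: pd.Series) -> pd.DataFrame:
    """Align each gene cluster with its best-matching condition.

    Signals are log2-transformed and z-normalised per probe-set across all
    distinct arrays; each cluster's score for a condition is the mean
    z-score over the cluster's genes and the condition's replicate arrays.
    The cluster is labelled with the arg-max condition; clusters whose
    best score is not positive (e.g. all-constant genes) are 'unassigned'.

    Returns the full cluster x condition score table with columns
    ``assigned_condition`` and ``assigned_score`` appended.
    """
    genes = list(labels.index)
    missing = [g for g in genes if g not in comp.expr.probe_sets]
    if missing:
        raise PipelineError(f"labelled genes outside the compendium: {missing[:5]}")
    z = zscore_log2(comp.expr.values.loc[genes])
    rows = []
    for cluster_id in sorted(labels.unique()):
        cluster_genes = labels.index[labels == cluster_id]
        scores = {}
        for cond in comp.conditions:
            arrays = comp.arrays_of(cond)
            scores[cond] = float(z.loc[cluster_genes, arrays].to_numpy().mean())
        best = max(scores, key=lambda c: (scores[c], c))
        assigned = best if scores[best] > 1e-12 else "unassigned"
        rows.append(
            {
                "cluster": cluster_id,
                **scores,
                "assigned_condition": assigned,
                "assigned_score": scores[best],
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


@dataclass
class SampleStructure:
    """Sample dendrogram and PCA of z-normalised log2 signals."""

    linkage: np.ndarray
    leaf_order: list[str]
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    percent_variance: np.ndarray


def sample_structure(
    expr: ExpressionMatrix,
    selected_genes: list[str] | None = None,
    n_components: int = 3,
    params: ClusteringParams = ClusteringParams(),
) -> SampleStructure:
    """Cluster samples and compute PCA on a (selected) gene panel.

    Signals are log2-transformed and z-normalised per probe-set across the
    analysed samples; PCA treats samples as observations, so percent
    variance of component i is its eigenvalue over the eigenvalue total.
    Requests beyond the matrix rank are truncated with a warning.
    """
    if len(expr.samples) < 3:
        raise PipelineError("need >= 3 samples")
    genes = selected_genes if selected_genes is not None else list(expr.probe_sets)
    missing = [g for g in genes if g not in expr.probe_sets]
    if missing:
        raise PipelineError(f"genes not in matrix: {missing[:5]}")
    z = zscore_log2(expr.values.loc[genes])

    X = z.to_numpy(dtype=float).T  # samples x genes, columns centred by z-norm
    X = X - X.mean(axis=0, keepdims=True)  # re-centre over the analysed samples
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigenvalues = s**2 / max(X.shape[0] - 1, 1)
    rank = int((s > s.max() * 1e-10).sum()) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    total = eigenvalues.sum()
    pct = 100.0 * eigenvalues[:n_components] / total if total > 0 else np.zeros(n_components)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (U[:, :n_components] * s[:n_components]), index=expr.samples, columns=comp_names
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=genes, columns=comp_names)

    dist = pdist(X, metric=params.distance)
    Z = hierarchy.linkage(dist, method=params.linkage)
    order = hierarchy.leaves_list(Z)
    samples = list(expr.samples)
    return SampleStructure(Z, [samples[i] for i in order], scores, loadings, pct)
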