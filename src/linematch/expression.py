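"""Expression-side concordance analyses.

Robust z-scores (median-centred values divided by the plain median absolute
deviation, no 1.4826 consistency factor by default), selection of the most
variable genes by interquartile range, sample clustering on the correlation
distance 1 - c (c = Pearson's correlation), PCA embeddings, ranking of cell
lines by their average correlation with tumours, and a Kendall tau-b
rank-concordance test between two orderings (exact permutation p-value for
small n, normal approximation with continuity correction otherwise).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalisation and gene selection
# ---------------------------------------------------------------------------


def robust_z(matrix: ExpressionMatrix, consistency_factor: bool = False) -> ExpressionMatrix:
    """Robust z-score each gene across samples: (x - median) / MAD.

    The MAD is unscaled by default (``consistency_factor=True`` multiplies it
    by 1.4826 for normal consistency).  Genes with MAD = 0 have no defined
    z-score and are dropped; the count is logged.
    """
    if matrix.values.empty:
        raise ValidationError("empty expression matrix")
    if matrix.values.shape[1] < 2:
        raise ValidationError("robust z-scoring needs at least 2 samples")
    vals = matrix.values
    med = vals.median(axis=1)
    mad = vals.sub(med, axis=0).abs().median(axis=1)
    if consistency_factor:
        mad = mad * 1.4826
    keep = mad > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("robust_z: dropped %d gene(s) with MAD = 0", dropped)
    z = vals[keep].sub(med[keep], axis=0).div(mad[keep], axis=0)
    return ExpressionMatrix(values=z, sample_datasets=matrix.sample_datasets.copy())


def select_top_iqr(matrix: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Keep the ``n`` genes with the largest interquartile range across samples.

    IQR is the 75th minus the 25th percentile with linear-interpolation
    quantiles (numpy's default, the type-7 convention).  Ties at the
    boundary are broken by lexicographic gene symbol.
    """
    n_genes = matrix.values.shape[0]
    if n > n_genes:
        raise ValidationError(f"requested top {n} genes but only {n_genes} available")
    q25, q75 = np.quantile(matrix.values.to_numpy(dtype=float), [0.25, 0.75], axis=1)
    iqr = pd.Series(q75 - q25, index=matrix.values.index)
    order = iqr.to_frame("iqr").assign(gene=iqr.index.astype(str))
    order = order.sort_values(["iqr", "gene"], ascending=[False, True], kind="mergesort")
    keep = order.index[:n]
    return ExpressionMatrix(
        values=matrix.values.loc[keep], sample_datasets=matrix.sample_datasets.copy()
    )


# ---------------------------------------------------------------------------
# correlation distance and clustering
# ---------------------------------------------------------------------------


def correlation_distance_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Sample-by-sample distance 1 - c, with c Pearson's correlation.

    Symmetric with a zero diagonal; entries lie in [0, 2].  A sample with
    zero variance has no defined correlation and raises, naming the sample.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if vals.shape[0] < 2:
        raise ValidationError("need at least 2 genes for correlation distances")
    sd = vals.std(axis=0)
    if (sd == 0).any():
        bad = matrix.values.columns[np.flatnonzero(sd == 0)[0]]
        raise ValidationError(f"sample {bad!r} has zero expression variance")
    corr = np.corrcoef(vals.T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=matrix.values.columns, columns=matrix.values.columns)


@dataclass
class ClusteringResult:
    """A deterministic agglomerative merge tree over samples.

    ``merges`` is the scipy linkage matrix (n-1 rows for n leaves);
    ``labels`` the leaf labels in input order; ``leaf_order`` the dendrogram
    leaf sequence.
    """

    merges: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    linkage_method: str

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels at ``k`` clusters."""
        flat = fcluster(self.merges, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels)

    def to_newick(self) -> str:
        """Serialise the merge tree in Newick format (heights as branch lengths)."""
        tree = to_tree(self.merges)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.left), walk(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


def hierarchical_cluster(distances: pd.DataFrame, linkage_method: str = "ward") -> ClusteringResult:
    """Agglomerative clustering of a precomputed distance matrix.

    ``linkage_method`` is ``"ward"`` (all-cell-line analysis) or
    ``"complete"`` (combined cell-line/tumour analysis); the merge tree is
    deterministic given the input.
    """
    if linkage_method not in ("ward", "complete"):
        raise ValidationError(f"unsupported linkage {linkage_method!r}")
    arr = distances.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-10):
        raise ValidationError("distance matrix must be square and symmetric")
    condensed = squareform(arr, checks=False)
    merges = linkage(condensed, method=linkage_method)
    labels = [str(c) for c in distances.columns]
    leaves = dendrogram(merges, no_plot=True)["leaves"]
    return ClusteringResult(
        merges=merges,
        labels=labels,
        leaf_order=[labels[i] for i in leaves],
        linkage_method=linkage_method,
    )


# ---------------------------------------------------------------------------
# dataset combination and PCA
# ---------------------------------------------------------------------------


def combine_datasets(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    """Robust z-score two datasets separately, then join on shared genes.

    Platform-specific location and scale are removed within each dataset
    before the matrices are combined over the gene intersection; each
    sample keeps its dataset label.
    """
    za, zb = robust_z(a), robust_z(b)
    shared = za.values.index.intersection(zb.values.index)
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared genes after z-scoring; need >= 3")
    clash = set(za.values.columns) & set(zb.values.columns)
    if clash:
        raise ValidationError(f"sample identifiers present in both datasets: {sorted(clash)[:5]}")
    values = pd.concat([za.values.loc[shared], zb.values.loc[shared]], axis=1)
    labels = pd.concat([za.sample_datasets, zb.sample_datasets])
    return ExpressionMatrix(values=values, sample_datasets=labels)


@dataclass
class PcaResult:
    """Sample coordinates on the top principal axes of the gene-centred matrix."""

    coordinates: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # genes x components


def pca_embedding(matrix: ExpressionMatrix, k: int) -> PcaResult:
    """Project samples onto the top-``k`` principal axes.

    The matrix is centred per gene; the sign of each axis is fixed so that
    its largest-magnitude gene loading is positive, making outputs
    reproducible across runs.
    """
    from sklearn.decomposition import PCA

    n_genes, n_samples = matrix.values.shape
    if not 1 <= k <= min(n_genes, n_samples):
        raise ValidationError(f"k={k} out of range for a {n_genes}x{n_samples} matrix")
    X = matrix.values.to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x k
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            coords[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=matrix.values.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(loadings, index=matrix.values.index, columns=comp_names),
    )


# ---------------------------------------------------------------------------
# expression-based ranking and rank concordance
# ---------------------------------------------------------------------------


def expression_rank(cell_lines: ExpressionMatrix, tumours: ExpressionMatrix) -> pd.DataFrame:
    """Rank cell lines by their mean Pearson correlation with the tumours.

    Correlations are computed over the shared-gene intersection; the result
    frame is ordered by mean correlation descending (ties by sample id) with
    columns ``sample`` and ``mean_correlation``.
    """
    shared = cell_lines.values.index.intersection(tumours.values.index)
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared genes; need >= 3")
    C = cell_lines.values.loc[shared].to_numpy(dtype=float)
    T = tumours.values.loc[shared].to_numpy(dtype=float)
    for name, block, cols in (("cell line", C, cell_lines.values.columns),
                              ("tumour", T, tumours.values.columns)):
        sd = block.std(axis=0)
        if (sd == 0).any():
            bad = cols[np.flatnonzero(sd == 0)[0]]
            raise ValidationError(f"{name} {bad!r} has zero expression variance")
    Zc = (C - C.mean(axis=0)) / C.std(axis=0)
    Zt = (T - T.mean(axis=0)) / T.std(axis=0)
    corr = Zc.T @ Zt / len(shared)  # cell lines x tumours
    mean_r = pd.Series(corr.mean(axis=1), index=cell_lines.values.columns)
    out = mean_r.rename("mean_correlation").rename_axis("sample").reset_index()
    out = out.sort_values(["mean_correlation", "sample"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


@dataclass
class RankConcordance:
    """Kendall tau-b and its two-sided p-value for two orderings."""

    tau: float
    p_value: float
    method: str  # "exact" | "normal_approximation"
    n: int


def _kendall_stats(rx: np.ndarray, ry: np.ndarray) -> tuple[float, float]:
    """Raw concordance score S = P - Q and tau-b for two rank vectors."""
    n = len(rx)
    dx = np.sign(rx[:, None] - rx[None, :])
    dy = np.sign(ry[:, None] - ry[None, :])
    iu = np.triu_indices(n, k=1)
    s = float((dx[iu] * dy[iu]).sum())
    n0 = n * (n - 1) / 2
    n1 = float((dx[iu] == 0).sum())
    n2 = float((dy[iu] == 0).sum())
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        raise ValidationError("tau-b undefined: a ranking is completely tied")
    return s, s / denom


def kendall_concordance(
    order1, order2, exact_max_n: int = 8
) -> RankConcordance:
    """Tie-corrected Kendall rank concordance between two orderings.

    ``order1``/``order2`` are sequences over the same item set (position =
    rank) or mappings item -> rank (which may contain ties).  For
    ``n <= exact_max_n`` the two-sided p-value comes from exhaustive
    enumeration of all permutations of one ranking; otherwise from the
    tie-corrected normal approximation with a continuity correction.  The
    method used is recorded on the result.
    """
    def to_ranks(order) -> pd.Series:
        if isinstance(order, dict) or isinstance(order, pd.Series):
            return pd.Series(dict(order), dtype=float)
        return pd.Series({item: i + 1 for i, item in enumerate(order)}, dtype=float)

    r1, r2 = to_ranks(order1), to_ranks(order2)
    if set(r1.index) != set(r2.index):
        raise ValidationError("orderings cover different item sets")
    n = len(r1)
    if n < 3:
        raise ValidationError("rank concordance needs at least 3 items")
    items = sorted(r1.index)
    rx = r1.reindex(items).to_numpy()
    ry = r2.reindex(items).to_numpy()
    s_obs, tau = _kendall_stats(rx, ry)

    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            _, tau_p = _kendall_stats(rx, np.asarray(perm))
            if abs(tau_p) >= abs(tau) - 1e-12:
                count += 1
            total += 1
        return RankConcordance(tau=tau, p_value=count / total, method="exact", n=n)

    # tie-corrected variance of S (Kendall 1970), continuity-corrected z
    def tie_sizes(r: np.ndarray) -> np.ndarray:
        _, counts = np.unique(r, return_counts=True)
        return counts[counts > 1].astype(float)

    t, u = tie_sizes(rx), tie_sizes(ry)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float((t * (t - 1) * (2 * t + 5)).sum())
    vu = float((u * (u - 1) * (2 * u + 5)).sum())
    v1 = float((t * (t - 1)).sum()) * float((u * (u - 1)).sum()) / (2 * n * (n - 1))
    v2 = (
        float((t * (t - 1) * (t - 2)).sum())
        * float((u * (u - 1) * (u - 2)).sum())
        / (9 * n * (n - 1) * (n - 2))
    )
    var_s = (v0 - vt - vu) / 18 + v1 + v2
    if var_s <= 0:
        raise ValidationError("degenerate variance in Kendall test")
    z = (abs(s_obs) - 1) / np.sqrt(var_s) if abs(s_obs) > 1 else 0.0
    p = float(min(1.0, 2 * norm.sf(z)))
    return RankConcordance(tau=tau, p_value=p, method="normal_approximation", n=n)
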