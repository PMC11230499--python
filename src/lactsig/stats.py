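"""Replicate-level statistics, multiple testing, per-gene DE and ordering.

Group comparisons across replicate mice (n = 3 per group in the emulated
design) use a two-tailed Welch t-test with Welch-Satterthwaite degrees of
freedom; an unequal-variance test is the safer default at n = 3, and a
pooled-variance Student's t is available behind a flag. Zero-variance
groups receive a machine-epsilon-scaled variance floor so complete
separation returns a finite statistic instead of NaN.

Multiple testing is Benjamini-Hochberg step-up throughout. Per-gene DE
between two cell groups is a two-sided rank-sum (Wilcoxon/Mann-Whitney)
test on log2(1 + median-depth-normalized) expression with the log2 fold
change taken as the difference of group means on that scale.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .errors import LactsigError
from .scoring import depth_normalize

__all__ = [
    "welch_t_two_tailed",
    "bh_adjust",
    "per_gene_de",
    "top_n_genes",
    "hierarchical_linkage",
    "hierarchical_order",
    "tumor_volume",
    "welch_de_log2cpm",
]


def welch_t_two_tailed(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-tailed t-test between two replicate groups.

    Welch (unequal variance) by default; ``equal_var=True`` switches to
    the pooled Student's t. Each group needs at least two values. Sample
    variances are floored at an epsilon scaled to the data magnitude so
    identical-vs-identical returns (0, 1) and complete separation returns
    a huge finite t rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise LactsigError("each group needs at least 2 values")
    scale = max(1.0, float(np.max(np.abs(np.concatenate([a, b])))))
    floor = (np.finfo(float).eps * scale) ** 2
    va = max(float(a.var(ddof=1)), floor)
    vb = max(float(b.var(ddof=1)), floor)
    na, nb = a.size, b.size
    diff = float(a.mean() - b.mean())
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = diff / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return t, min(p, 1.0)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise LactsigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def per_gene_de(
    adata: ad.AnnData,
    cells_a: Sequence[str],
    cells_b: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Rank-sum DE between two disjoint cell groups over all genes.

    Expression is log2(pseudocount + median-depth-normalized count).
    Returns a DE table (gene, log2fc, pvalue, padj) with BH-adjusted
    p-values; log2fc > 0 means higher in ``cells_a``. Genes constant
    across both groups get p = 1 exactly.
    """
    idx_a, idx_b = pd.Index(cells_a), pd.Index(cells_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise LactsigError("both cell groups must be non-empty")
    overlap = idx_a.intersection(idx_b)
    if len(overlap):
        raise LactsigError(f"cell groups overlap, e.g. {list(overlap[:5])}")
    if not adata.uns.get("depth_normalized", False):
        adata = depth_normalize(adata)
    sub = adata[idx_a.append(idx_b)]
    X = np.log2(pseudocount + np.asarray(sp.csr_matrix(sub.X).todense()))
    na = len(idx_a)
    A, B = X[:na], X[na:]
    lfc = A.mean(axis=0) - B.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = sps.mannwhitneyu(A, B, axis=0, alternative="two-sided")
    constant = np.all(X == X[0, :], axis=0)
    pvals = np.where(constant, 1.0, pvals)
    pvals = np.nan_to_num(pvals, nan=1.0)
    return pd.DataFrame(
        {
            "gene": sub.var_names.to_numpy(),
            "log2fc": lfc,
            "pvalue": pvals,
            "padj": bh_adjust(pvals),
        }
    )


def top_n_genes(table: pd.DataFrame, n: int = 40, p_cutoff: float = 0.0002) -> list[str]:
    """Genes below the raw-p cutoff, best first, truncated to n.

    Order: ascending p, then descending |log2fc|, then symbol — fully
    deterministic under ties.
    """
    df = table.loc[table["pvalue"].astype(float) < p_cutoff].copy()
    df["_abs_lfc"] = df["log2fc"].abs()
    df = df.sort_values(
        ["pvalue", "_abs_lfc", "gene"], ascending=[True, False, True], kind="mergesort"
    )
    return df["gene"].astype(str).head(n).tolist()


def _correlation_distance(M: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r between rows; zero-variance rows get r = 0."""
    M = np.asarray(M, dtype=float)
    sd = M.std(axis=1)
    ok = sd > 0
    Z = np.zeros_like(M)
    Z[ok] = (M[ok] - M[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    r = Z @ Z.T / M.shape[1]
    r[~ok, :] = 0.0
    r[:, ~ok] = 0.0
    np.fill_diagonal(r, 1.0)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def hierarchical_linkage(M: np.ndarray) -> np.ndarray:
    """Average-linkage merge tree of rows under correlation distance."""
    M = np.asarray(M, dtype=float)
    if M.shape[0] < 2:
        raise LactsigError("need at least 2 rows to cluster")
    return linkage(squareform(_correlation_distance(M), checks=False), method="average")


def hierarchical_order(matrix: pd.DataFrame) -> tuple[list, list]:
    """Leaf orders for heatmap display of a genes x samples submatrix.

    Average-linkage agglomeration on 1 - Pearson correlation distance,
    applied to rows and to columns independently. Leaf order is the
    deterministic dendrogram order (earlier-formed cluster first at each
    merge). Returns (row labels in order, column labels in order).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise LactsigError("need at least 2 rows and 2 columns to cluster")

    def order(M: np.ndarray) -> np.ndarray:
        return leaves_list(hierarchical_linkage(M))

    rows = order(matrix.to_numpy())
    cols = order(matrix.to_numpy().T)
    return list(matrix.index[rows]), list(matrix.columns[cols])


def tumor_volume(length: float, width: float) -> float:
    """Modified ellipsoidal tumor volume, 0.5 x length x width^2.

    Length is the greatest longitudinal caliper diameter, width the
    greatest transverse one; width > length (caliper noise) warns but
    still computes.
    """
    if length < 0 or width < 0:
        raise LactsigError("caliper measurements must be nonnegative")
    if width > length:
        warnings.warn("width exceeds length; computing anyway", stacklevel=2)
    return 0.5 * length * width * width


def welch_de_log2cpm(
    counts: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.DataFrame:
    """Convenience per-gene Welch t DE on log2 CPM for bulk count tables.

    A simple gene-wise Welch t-test on log2(1 + counts-per-million) with
    BH adjustment, for exercising the set logic on synthetic bulk counts.
    It is not the method behind any published table and is not used by
    the pipeline unless asked for explicitly.
    """
    cols_a, cols_b = list(group_a), list(group_b)
    cpm = counts / counts.sum(axis=0) * 1e6
    L = np.log2(1.0 + cpm)
    res = [
        welch_t_two_tailed(L.loc[g, cols_a].to_numpy(), L.loc[g, cols_b].to_numpy())
        for g in L.index
    ]
    pvals = np.array([p for _, p in res])
    lfc = (L[cols_a].mean(axis=1) - L[cols_b].mean(axis=1)).to_numpy()
    return pd.DataFrame(
        {"gene": L.index.astype(str), "log2fc": lfc, "pvalue": pvals, "padj": bh_adjust(pvals)}
    )
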