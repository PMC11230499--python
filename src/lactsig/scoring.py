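"""Feature-sum signature scoring and the PPBC-like co-expression classifier.

A signature score for a cell is the log2-transformed sum of that cell's
(optionally depth-normalized) expression over the signature's genes,

    score(cell) = log2(pseudocount + sum_g expr(cell, g)),

the "log2 feature sum". A cell is called positive for a signature when its
score reaches half of the maximum score observed across all pooled
barcodes (and is strictly positive, so an all-zero score vector yields no
positives). PPBC-like cells are those positive for BOTH the proliferation
list and the 14-gene regulon.

Normalization and pseudocount are recorded on every score vector, since
the exact transform behind the browser-derived published analysis is not
fully specified; the defaults here are median-depth normalization and a
pseudocount of 1, and both are explicit parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import LactsigError
from .signatures import GeneSignature

__all__ = [
    "ScoreResult",
    "ClassificationResult",
    "depth_normalize",
    "score_signature",
    "half_max_threshold",
    "classify_ppbc_like",
    "gene_positive_count",
]

Normalization = Literal["none", "median_depth"]


@dataclass
class ScoreResult:
    """Per-cell signature scores plus the settings that produced them."""

    scores: pd.Series  # indexed by barcode
    signature_name: str
    normalization: Normalization
    pseudocount: float
    log_base2: bool = True
    missing_genes: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class ClassificationResult:
    """Per-cell positivity calls for a pair of signatures and their AND."""

    calls: pd.DataFrame  # columns: positive_<sig> per signature, is_ppbc_like
    thresholds: dict[str, float] = field(default_factory=dict)


def depth_normalize(adata: ad.AnnData) -> ad.AnnData:
    """Median-depth normalization in count-quantum units.

    Counts are first expressed in units of the matrix's count quantum
    (its minimum nonzero entry — 1 for any genuine UMI matrix, so this is
    a no-op on raw data), then each cell is scaled so its total equals
    the median per-cell total. The quantum step makes the normalized
    matrix, and hence every downstream score, threshold and call, exactly
    invariant under a global rescaling of the raw counts.

    Cells with zero total are left all-zero and flagged in
    ``obs['depth_zero']``; per-cell scale factors land in
    ``obs['depth_factor']``. Raises if every cell is zero. The result is
    a new AnnData with float X; raw counts are kept in
    ``layers['counts']``.
    """
    X = sp.csr_matrix(adata.X, dtype=np.float64)
    if X.nnz == 0:
        raise LactsigError("cannot depth-normalize an all-zero matrix")
    quantum = float(np.min(np.abs(X.data)))
    X = X / quantum
    totals = np.asarray(X.sum(axis=1)).ravel()
    median_total = float(np.median(totals[totals > 0]))
    factors = np.ones_like(totals)
    nz = totals > 0
    factors[nz] = median_total / totals[nz]
    out = adata.copy()
    out.layers["counts"] = adata.X.copy()
    out.X = sp.csr_matrix(sp.diags(factors) @ X)
    out.obs["depth_zero"] = ~nz
    out.obs["depth_factor"] = factors
    out.uns["depth_normalized"] = True
    out.uns["median_total"] = median_total
    out.uns["count_quantum"] = quantum
    return out


def _signature_expression(
    adata: ad.AnnData, signature: GeneSignature, normalization: Normalization
) -> tuple[np.ndarray, tuple[str, ...]]:
    present = [g for g in signature.genes if g in adata.var_names]
    missing = tuple(g for g in signature.genes if g not in adata.var_names)
    if not present:
        raise LactsigError(
            f"no gene of signature {signature.name!r} is present in the matrix"
        )
    if normalization == "median_depth":
        if not adata.uns.get("depth_normalized", False):
            adata = depth_normalize(adata)
    elif normalization != "none":
        raise LactsigError(f"unknown normalization {normalization!r}")
    sub = adata[:, present].X
    sums = np.asarray(sub.sum(axis=1)).ravel().astype(np.float64)
    return sums, missing


def score_signature(
    adata: ad.AnnData,
    signature: GeneSignature,
    normalization: Normalization = "median_depth",
    pseudocount: float = 1.0,
) -> ScoreResult:
    """Log2 feature-sum score of a signature for every cell.

    Missing signature genes contribute zero and are reported in the
    result; scoring fails only if no signature gene is present at all.
    """
    if pseudocount <= 0:
        raise LactsigError("pseudocount must be positive")
    sums, missing = _signature_expression(adata, signature, normalization)
    scores = np.log2(pseudocount + sums)
    return ScoreResult(
        scores=pd.Series(scores, index=adata.obs_names, name=signature.name),
        signature_name=signature.name,
        normalization=normalization,
        pseudocount=pseudocount,
        missing_genes=missing,
    )


def half_max_threshold(scores: ScoreResult | pd.Series | Sequence[float]) -> float:
    """Half of the maximum score over all pooled barcodes.

    The maximum is taken across the whole experiment (all samples pooled),
    giving one cutoff per feature list.
    """
    values = scores.scores if isinstance(scores, ScoreResult) else pd.Series(scores)
    if len(values) == 0:
        raise LactsigError("cannot take a half-max threshold of an empty score vector")
    return 0.5 * float(np.max(values.to_numpy(dtype=float)))


def _positive(values: pd.Series, threshold: float) -> np.ndarray:
    v = values.to_numpy(dtype=float)
    return (v >= threshold) & (v > 0)


def classify_ppbc_like(
    score_proliferation: ScoreResult,
    score_regulon: ScoreResult,
    half_max_factor: float = 0.5,
    groups: pd.Series | None = None,
) -> ClassificationResult:
    """Call PPBC-like cells by co-expression of both feature lists.

    A cell is positive for a list iff its score is at least
    ``half_max_factor`` times that list's pooled maximum and strictly
    positive; PPBC-like = positive for both lists. Thresholds are recorded
    in the result. By default the maximum pools every barcode of the
    experiment (one cutoff per list); passing ``groups`` (a per-barcode
    sample label) switches to per-group thresholds instead, recorded as
    ``<list>@<group>``.
    """
    a, b = score_proliferation, score_regulon
    if not a.scores.index.equals(b.scores.index):
        raise LactsigError("score vectors are not over identical barcodes")
    if groups is not None:
        groups = groups.reindex(a.scores.index)
        if groups.isna().any():
            raise LactsigError("groups must cover every scored barcode")
        thresholds: dict[str, float] = {}
        pos_a = np.zeros(len(a.scores), dtype=bool)
        pos_b = np.zeros(len(b.scores), dtype=bool)
        for g in pd.unique(groups):
            mask = (groups == g).to_numpy()
            for res, pos in ((a, pos_a), (b, pos_b)):
                thr = half_max_factor * float(res.scores[mask].max())
                thresholds[f"{res.signature_name}@{g}"] = thr
                pos[mask] = _positive(res.scores[mask], thr)
        calls = pd.DataFrame(
            {
                f"positive_{a.signature_name}": pos_a,
                f"positive_{b.signature_name}": pos_b,
                "is_ppbc_like": pos_a & pos_b,
            },
            index=a.scores.index,
        )
        return ClassificationResult(calls=calls, thresholds=thresholds)
    thresholds = {
        a.signature_name: half_max_factor * float(a.scores.max()),
        b.signature_name: half_max_factor * float(b.scores.max()),
    }
    pos_a = _positive(a.scores, thresholds[a.signature_name])
    pos_b = _positive(b.scores, thresholds[b.signature_name])
    calls = pd.DataFrame(
        {
            f"positive_{a.signature_name}": pos_a,
            f"positive_{b.signature_name}": pos_b,
            "is_ppbc_like": pos_a & pos_b,
        },
        index=a.scores.index,
    )
    return ClassificationResult(calls=calls, thresholds=thresholds)


def gene_positive_count(
    adata: ad.AnnData,
    gene_symbol: str,
    cell_subset: Sequence[str] | pd.Index | None = None,
) -> int:
    """Number of cells in the subset with a raw count > 0 for the gene.

    Positivity is a detection call on raw counts, not a normalized cutoff.
    """
    if gene_symbol not in adata.var_names:
        raise LactsigError(f"gene {gene_symbol!r} absent from the matrix")
    if cell_subset is None:
        sub = adata
    else:
        cell_subset = pd.Index(cell_subset)
        missing = cell_subset.difference(adata.obs_names)
        if len(missing):
            raise LactsigError(
                f"cells absent from the matrix: {list(missing[:5])}"
            )
        if len(cell_subset) == 0:
            return 0
        sub = adata[cell_subset]
    layer = sub.layers["counts"] if "counts" in sub.layers else sub.X
    col = np.asarray(sp.csr_matrix(layer)[:, sub.var_names.get_loc(gene_symbol)].todense()).ravel()
    return int(np.count_nonzero(col > 0))
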