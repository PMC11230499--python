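"""Marker-based epithelial cell-type annotation and per-sample proportions.

Each cell is assigned one of the three epithelial compartments of the
mouse mammary gland — luminal alveolar (AV), luminal hormone-sensing (HS)
or myoepithelial (ME) — or left unassigned. The rule is a per-cell argmax
over z-standardized marker-signature scores: each marker list is scored
with the same log2 feature sum used elsewhere, the scores are
z-standardized per signature across all cells (marker lists differ in
length and baseline, so a raw-score argmax would favor long lists), and a
cell takes the label of its highest z-score provided that z is positive;
otherwise it is ``unassigned``. Ties break in the fixed order AV < HS < ME.
"""

from __future__ import annotations

from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd

from .errors import LactsigError
from .scoring import Normalization, depth_normalize, score_signature
from .signatures import GeneSignature

__all__ = ["CELL_TYPES", "assign_cell_types", "type_proportions"]

CELL_TYPES = ("AV", "HS", "ME")
LABELS = CELL_TYPES + ("unassigned",)


def assign_cell_types(
    adata: ad.AnnData,
    markers: Mapping[str, GeneSignature],
    normalization: Normalization = "median_depth",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Label every cell by marker-signature argmax.

    Returns a DataFrame indexed by barcode with a ``celltype`` column and
    one ``z_<type>`` column per marker signature.
    """
    missing = [t for t in CELL_TYPES if t not in markers]
    if missing:
        raise LactsigError(f"marker signatures missing for cell types: {missing}")
    if normalization == "median_depth" and not adata.uns.get("depth_normalized", False):
        adata = depth_normalize(adata)
    zcols = {}
    for celltype in CELL_TYPES:  # fixed order doubles as the tie-break order
        res = score_signature(adata, markers[celltype], normalization, pseudocount)
        v = res.scores.to_numpy(dtype=float)
        sd = v.std()
        zcols[celltype] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    Z = np.column_stack([zcols[t] for t in CELL_TYPES])
    best = np.argmax(Z, axis=1)  # argmax takes the first maximum: AV < HS < ME
    labels = np.where(
        Z[np.arange(len(best)), best] > 0,
        np.asarray(CELL_TYPES, dtype=object)[best],
        "unassigned",
    )
    out = pd.DataFrame({"celltype": labels}, index=adata.obs_names)
    for t in CELL_TYPES:
        out[f"z_{t}"] = zcols[t]
    return out


def type_proportions(annotation: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fractions of each cell-type label (including unassigned).

    ``annotation`` and ``metadata`` must cover identical barcodes; each
    row of the result sums to 1.
    """
    meta = metadata.set_index("barcode")
    ann_idx = annotation.index
    if set(ann_idx) != set(meta.index):
        raise LactsigError("annotation and metadata do not cover identical barcodes")
    joined = pd.DataFrame(
        {
            "celltype": annotation["celltype"],
            "sample_id": meta.reindex(ann_idx)["sample_id"],
        }
    )
    counts = (
        joined.groupby("sample_id", sort=True)["celltype"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(LABELS), fill_value=0)
    )
    totals = counts.sum(axis=1)
    empty = totals[totals == 0].index.tolist()
    if empty:
        raise LactsigError(f"samples with no cells: {empty}")
    props = counts.div(totals, axis=0)
    props.columns.name = "celltype"
    return props
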