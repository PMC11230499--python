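"""Synthetic single-cell and bulk data with planted ground truth.

The single-cell generator emulates the study design the pipeline targets:
two mouse genotypes differing only in mitochondrial haplotype (C57, NZB),
each sampled non-lactating (NL) and at lactation day 21 (LacD21), three
replicate mice per condition. Counts are gene-wise negative binomial
(mean/dispersion parameterization, variance mu + mu^2/size) with
per-cell log-normal depth factors applied to the mean, so fold changes
act on mu and the family is preserved. Each cell is one of three
epithelial types (luminal AV, luminal HS, myoepithelial) whose marker
genes are elevated ``marker_fold``-fold in their own type; alveolar cells
expand during lactation via state-specific type fractions. A configurable
fraction of cells per condition is additionally PPBC-like: every gene of
the proliferation list and of the 14-gene regulon has its mean multiplied
by ``ppbc_fold``. PPBC-like cells are enriched in the HS compartment
(default 61%). Luminal HS cells in selected conditions have Trp53 forced
to a structural zero with a configured probability, so downstream
p53-detection calls have exact ground truth.

All randomness flows from the single ``seed``; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError
from .signatures import (
    MARKER_GENES,
    PROLIFERATION_GENES,
    REGULON_GENES,
    default_registry,
)

__all__ = [
    "SimulationConfig",
    "simulate_cells",
    "BulkDEResult",
    "simulate_bulk_de",
    "condition_key",
]

TRP53 = "Trp53"
CELL_TYPES = ("AV", "HS", "ME")


def condition_key(genotype: str, state: str) -> str:
    return f"{genotype}:{state}"


def _default_conditions() -> tuple[tuple[str, str, int], ...]:
    return (
        ("C57", "NL", 3),
        ("C57", "LacD21", 3),
        ("NZB", "NL", 3),
        ("NZB", "LacD21", 3),
    )


def _simplex(fracs: Mapping[str, float], where: str) -> dict[str, float]:
    out = {t: float(fracs[t]) for t in CELL_TYPES}
    if any(not 0 <= v < 1 for v in out.values()):
        raise ConfigError(f"{where}: cell-type fractions must lie in [0, 1)")
    if abs(sum(out.values()) - 1.0) > 1e-9:
        raise ConfigError(f"{where}: cell-type fractions must sum to 1")
    return out


@dataclass
class SimulationConfig:
    """Parameters of the planted-truth single-cell simulation.

    Defaults encode the emulated study design: 4 conditions x 3 mice,
    alveolar expansion during lactation, a PPBC-like fraction elevated
    only in NZB-LacD21, and Trp53 silencing of luminal HS cells in
    NZB-LacD21 only.
    """

    n_genes: int = 1000
    n_cells_per_sample: int = 2000
    conditions: tuple[tuple[str, str, int], ...] = field(
        default_factory=_default_conditions
    )
    baseline_mean: float = 0.40       # NB mean scale per gene
    gene_mean_sigma: float = 0.1      # log-normal spread of per-gene means
    dispersion: float = 10.0          # NB size; variance = mu + mu^2/size
    depth_factor_sd: float = 0.3      # per-cell log-normal depth sd (log scale)
    celltype_fractions: dict[str, float] = field(
        default_factory=lambda: {"AV": 0.40, "HS": 0.35, "ME": 0.25}
    )
    celltype_fractions_by_state: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"LacD21": {"AV": 0.70, "HS": 0.18, "ME": 0.12}}
    )
    marker_fold: float = 8.0
    marker_mean_fold: float = 4.0    # lineage markers are abundant transcripts
    proliferation_baseline_factor: float = 0.55  # cell-cycle transcript baseline scale
    regulon_baseline_factor: float = 0.25       # regulon TF baseline scale
    ppbc_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "C57:NL": 0.005, "C57:LacD21": 0.005,
            "NZB:NL": 0.005, "NZB:LacD21": 0.05,
        }
    )
    ppbc_fold: float = 8.0
    ppbc_hs_enrichment: float = 0.61  # fraction of planted cells that are HS
    trp53_silencing: dict[str, float] = field(
        default_factory=lambda: {"NZB:LacD21": 0.8}
    )
    trp53_mean_fold: float = 4.0      # Trp53 is a well-detected housekeeping-ish gene
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells_per_sample < 1:
            raise ConfigError("n_genes and n_cells_per_sample must be positive")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ConfigError("baseline_mean and dispersion must be positive")
        if self.depth_factor_sd < 0 or self.gene_mean_sigma < 0:
            raise ConfigError("scale spreads must be nonnegative")
        if self.marker_fold < 1 or self.ppbc_fold < 1 or self.trp53_mean_fold < 1:
            raise ConfigError("fold parameters must be >= 1")
        if self.marker_mean_fold < 1:
            raise ConfigError("marker_mean_fold must be >= 1")
        for nm in ("proliferation_baseline_factor", "regulon_baseline_factor"):
            if not 0 < getattr(self, nm) <= 1:
                raise ConfigError(f"{nm} must lie in (0, 1]")
        _simplex(self.celltype_fractions, "celltype_fractions")
        for state, fr in self.celltype_fractions_by_state.items():
            _simplex(fr, f"celltype_fractions_by_state[{state}]")
        for name, mapping in (
            ("ppbc_fraction", self.ppbc_fraction),
            ("trp53_silencing", self.trp53_silencing),
        ):
            for key, v in mapping.items():
                if not 0 <= float(v) < 1:
                    raise ConfigError(f"{name}[{key}] must lie in [0, 1)")
        if not 0 <= self.ppbc_hs_enrichment < 1:
            raise ConfigError("ppbc_hs_enrichment must lie in [0, 1)")
        core = gene_universe_core()
        if self.n_genes < len(core):
            raise ConfigError(
                f"n_genes={self.n_genes} too small for the {len(core)} "
                f"signature/reporter genes"
            )

    def fractions_for_state(self, state: str) -> dict[str, float]:
        return self.celltype_fractions_by_state.get(state, self.celltype_fractions)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["conditions"] = [list(c) for c in self.conditions]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        if "conditions" in d:
            d["conditions"] = tuple(tuple(c) for c in d["conditions"])
        return cls(**d)


def gene_universe_core() -> list[str]:
    """Signature and reporter genes that every simulated matrix contains."""
    core: list[str] = []
    for sig in default_registry().values():
        for g in sig.genes:
            if g not in core:
                core.append(g)
    if TRP53 not in core:
        core.append(TRP53)
    return core


def _gene_universe(n_genes: int) -> list[str]:
    core = gene_universe_core()
    fillers = [f"Gm{i:05d}" for i in range(n_genes - len(core))]
    return core + fillers


def simulate_cells(
    config: SimulationConfig,
) -> tuple[ad.AnnData, pd.DataFrame, pd.DataFrame]:
    """Draw a planted-truth experiment.

    Returns ``(counts, metadata, truth)``: a cells x genes AnnData of UMI
    counts, the per-barcode sample metadata table, and the ground-truth
    table (barcode, celltype, is_ppbc_like, trp53_silenced).
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_universe(config.n_genes)
    gene_idx = {g: i for i, g in enumerate(genes)}

    gene_means = config.baseline_mean * rng.lognormal(
        0.0, config.gene_mean_sigma, size=len(genes)
    )
    gene_means[gene_idx[TRP53]] *= config.trp53_mean_fold

    marker_cols = {
        t: np.array([gene_idx[g] for g in MARKER_GENES[t]]) for t in CELL_TYPES
    }
    ppbc_genes = sorted(set(PROLIFERATION_GENES) | set(REGULON_GENES))
    ppbc_cols = np.array([gene_idx[g] for g in ppbc_genes])

    # lineage markers (milk proteins, keratins, hormone receptors) are
    # abundant transcripts; cell-cycle and regulon transcripts are depleted
    # in largely postmitotic secretory tissue. Genes shared between the two
    # groups (Esr1) keep the scored-gene baseline so the planted scoring
    # structure is controlled by ppbc_fold alone.
    scored = set(ppbc_genes)
    for cols in marker_cols.values():
        for c in cols:
            if genes[c] not in scored:
                gene_means[c] *= config.marker_mean_fold
    for g in PROLIFERATION_GENES:
        gene_means[gene_idx[g]] *= config.proliferation_baseline_factor
    for g in REGULON_GENES:
        gene_means[gene_idx[g]] *= config.regulon_baseline_factor
    trp53_col = gene_idx[TRP53]

    blocks: list[sp.csr_matrix] = []
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []
    type_counts: list[dict] = []

    for genotype, state, n_mice in config.conditions:
        cond = condition_key(genotype, state)
        ppbc_p = float(config.ppbc_fraction.get(cond, 0.0))
        sil_p = float(config.trp53_silencing.get(cond, 0.0))
        base_fr = config.fractions_for_state(state)
        ppbc_fr = _ppbc_type_fractions(base_fr, config.ppbc_hs_enrichment)
        for mouse in range(1, n_mice + 1):
            sample_id = f"{genotype}-{state}-m{mouse}"
            n = config.n_cells_per_sample
            is_ppbc = rng.random(n) < ppbc_p

            types = np.empty(n, dtype=object)
            for mask, fr in ((~is_ppbc, base_fr), (is_ppbc, ppbc_fr)):
                k = int(mask.sum())
                if k:
                    types[mask] = rng.choice(
                        CELL_TYPES, size=k, p=[fr[t] for t in CELL_TYPES]
                    )

            depth = rng.lognormal(0.0, config.depth_factor_sd, size=n)
            mu = np.outer(depth, gene_means)
            for t in CELL_TYPES:
                rows = np.flatnonzero(types == t)
                if rows.size:
                    mu[np.ix_(rows, marker_cols[t])] *= config.marker_fold
            rows = np.flatnonzero(is_ppbc)
            if rows.size:
                mu[np.ix_(rows, ppbc_cols)] *= config.ppbc_fold

            size = config.dispersion
            counts = rng.negative_binomial(size, size / (size + mu)).astype(np.int32)

            silenced = (types == "HS") & (rng.random(n) < sil_p)
            counts[silenced, trp53_col] = 0

            blocks.append(sp.csr_matrix(counts))
            barcodes = [f"{sample_id}:c{i:05d}" for i in range(n)]
            for i, bc in enumerate(barcodes):
                meta_rows.append(
                    {
                        "barcode": bc, "sample_id": sample_id,
                        "genotype": genotype, "state": state, "mouse": str(mouse),
                    }
                )
                truth_rows.append(
                    {
                        "barcode": bc, "celltype": types[i],
                        "is_ppbc_like": bool(is_ppbc[i]),
                        "trp53_silenced": bool(silenced[i]),
                    }
                )
            tc = {"sample_id": sample_id}
            for t in CELL_TYPES:
                tc[t] = int((types == t).sum())
            type_counts.append(tc)

    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    adata = ad.AnnData(
        X=sp.vstack(blocks).tocsr(),
        obs=pd.DataFrame(index=pd.Index(meta["barcode"], name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.uns["planted_type_counts"] = pd.DataFrame(type_counts)
    adata.uns["simulation_seed"] = int(config.seed)
    return adata, meta, truth


def _ppbc_type_fractions(base: Mapping[str, float], hs_enrichment: float) -> dict[str, float]:
    rest = base["AV"] + base["ME"]
    if rest <= 0:
        av = me = (1.0 - hs_enrichment) / 2.0
    else:
        av = (1.0 - hs_enrichment) * base["AV"] / rest
        me = (1.0 - hs_enrichment) * base["ME"] / rest
    return {"AV": av, "HS": hs_enrichment, "ME": me}


@dataclass
class BulkDEResult:
    """Per-day DE tables plus the planted membership blocks."""

    tables: dict[int, pd.DataFrame]
    membership: dict[str, frozenset[str]]  # keys: up_core, up_day<d>, down_core, down_day<d>


def simulate_bulk_de(
    n_genes: int,
    exclusive_up: Mapping[int, float],
    core_up: float,
    exclusive_down: Mapping[int, float] | None = None,
    core_down: float = 0.0,
    effect_size: float = 2.0,
    days: tuple[int, ...] = (8, 14, 21),
    seed: int = 0,
) -> BulkDEResult:
    """Per-day DE tables with exactly known Venn structure.

    Membership is assigned deterministically from the seed-shuffled gene
    list: a shared core block is significant on every day, then one
    exclusive block per day; counts are ``round(fraction * n_genes)``
    exactly. Significant genes receive padj < 0.05 with the configured
    sign of log2 fold change at +-``effect_size``; all other genes are
    null (padj >= 0.05).
    """
    if not set(days) <= {8, 14, 21}:
        raise ConfigError(f"days must be a subset of (8, 14, 21), got {days}")
    exclusive_down = dict(exclusive_down or {})
    for d in days:
        exclusive_down.setdefault(d, 0.0)
    for name, frac in (
        ("core_up", core_up), ("core_down", core_down),
        *[(f"exclusive_up[{d}]", exclusive_up.get(d, 0.0)) for d in days],
        *[(f"exclusive_down[{d}]", exclusive_down[d]) for d in days],
    ):
        if not 0 <= float(frac) <= 1:
            raise ConfigError(f"{name} must lie in [0, 1]")
    total = core_up + core_down + sum(exclusive_up.get(d, 0.0) for d in days) + sum(
        exclusive_down[d] for d in days
    )
    if total > 1 + 1e-12:
        raise ConfigError(f"significant fractions sum to {total:.3f} > 1")

    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:05d}" for i in range(n_genes)])
    order = rng.permutation(n_genes)

    cursor = 0

    def take(frac: float) -> frozenset[str]:
        nonlocal cursor
        k = int(round(frac * n_genes))
        block = frozenset(genes[order[cursor:cursor + k]])
        cursor += k
        return block

    membership: dict[str, frozenset[str]] = {"up_core": take(core_up)}
    for d in sorted(days):
        membership[f"up_day{d}"] = take(exclusive_up.get(d, 0.0))
    membership["down_core"] = take(core_down)
    for d in sorted(days):
        membership[f"down_day{d}"] = take(exclusive_down[d])

    tables: dict[int, pd.DataFrame] = {}
    for d in sorted(days):
        up = membership["up_core"] | membership[f"up_day{d}"]
        down = membership["down_core"] | membership[f"down_day{d}"]
        padj = rng.uniform(0.06, 1.0, size=n_genes)
        lfc = rng.normal(0.0, 0.2, size=n_genes)
        for block, sign in ((up, 1.0), (down, -1.0)):
            idx = np.array([i for i, g in enumerate(genes) if g in block], dtype=int)
            if idx.size:
                padj[idx] = rng.uniform(0.0005, 0.049, size=idx.size)
                lfc[idx] = sign * effect_size * rng.uniform(0.75, 1.25, size=idx.size)
        pval = padj * rng.uniform(0.05, 1.0, size=n_genes)
        tables[d] = pd.DataFrame(
            {"gene": genes, "log2fc": lfc, "pvalue": pval, "padj": padj}
        )
    return BulkDEResult(tables=tables, membership=membership)
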