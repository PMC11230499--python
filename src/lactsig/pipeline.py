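"""End-to-end orchestration: simulate/load -> annotate -> score -> classify
-> count -> test -> export.

A run consumes either a simulation config or a real 10x triplet plus
metadata CSV, and produces a report bundle on disk: per-sample PPBC-like
counts, per-sample p53-positive luminal-HS counts, cell-type proportions,
the lactating C57-vs-NZB luminal-HS DE table with its top-N gene list,
optional bulk Venn region counts, and a manifest recording every
parameter and threshold so any number in the report is reproducible from
manifest + inputs alone.

The single global seed is fanned out per stage through a named substream
derivation (stage name -> CRC32 -> child seed), so stages are locally
reproducible without coupling.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from . import __version__
from .annotate import assign_cell_types, type_proportions
from .errors import ConfigError
from .io import (
    attach_metadata,
    read_10x_triplet,
    read_de_table,
    read_metadata,
    write_de_table,
)
from .scoring import (
    classify_ppbc_like,
    depth_normalize,
    gene_positive_count,
    score_signature,
)
from .signatures import GeneSignature, default_registry
from .simulate import SimulationConfig, simulate_cells
from .stats import per_gene_de, top_n_genes, welch_t_two_tailed
from .venn import cross_genotype_unique, de_filter, venn_partition

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "stage_seed"]

_CSV_FLOAT = "%.10g"


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage child seed from the global seed and stage name."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on. Exactly one input source:
    either ``sim_config`` or (``matrix_dir`` and ``metadata_path``)."""

    sim_config: SimulationConfig | None = None
    matrix_dir: str | None = None
    metadata_path: str | None = None
    registry: dict[str, GeneSignature] = field(default_factory=default_registry)
    normalization: str = "median_depth"
    pseudocount: float = 1.0
    half_max_factor: float = 0.5
    alpha: float = 0.05
    de_p_cutoff: float = 0.0002
    top_n: int = 40
    p53_gene: str = "Trp53"
    run_de: bool = True
    bulk_tables: dict[str, dict[int, str]] | None = None  # genotype -> day -> path
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        have_real = self.matrix_dir is not None or self.metadata_path is not None
        have_sim = self.sim_config is not None
        if have_real == have_sim:
            raise ConfigError(
                "provide exactly one of: sim_config, or matrix_dir + metadata_path"
            )
        if have_real and (self.matrix_dir is None or self.metadata_path is None):
            raise ConfigError("real input needs both matrix_dir and metadata_path")
        for sig in ("proliferation", "regulon", "AV", "HS", "ME"):
            if sig not in self.registry:
                raise ConfigError(f"registry is missing the {sig!r} signature")


@dataclass
class ReportBundle:
    annotation: pd.DataFrame
    proportions: pd.DataFrame
    scores: pd.DataFrame
    ppbc_calls: pd.DataFrame
    thresholds: dict[str, float]
    ppbc_counts: pd.DataFrame        # per sample
    p53_positive: pd.DataFrame       # per sample, HS subset
    ttests: pd.DataFrame
    hs_de: pd.DataFrame | None
    hs_top_genes: list[str]
    venn_counts: pd.DataFrame | None
    manifest: dict


def _per_sample_counts(meta: pd.DataFrame, flags: pd.Series, name: str) -> pd.DataFrame:
    df = meta.set_index("barcode").copy()
    df[name] = flags.reindex(df.index).astype(bool)
    out = (
        df.groupby(["sample_id", "genotype", "state", "mouse"], sort=True, observed=True)[name]
        .sum()
        .reset_index()
        .rename(columns={name: "count"})
    )
    out["measure"] = name
    return out


def _group_ttests(counts: pd.DataFrame) -> pd.DataFrame:
    """All pairwise Welch tests between (genotype, state) groups."""
    rows = []
    groups = (
        counts.groupby(["genotype", "state"], sort=True)["count"].apply(list).to_dict()
    )
    keys = sorted(groups)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            if len(groups[ka]) < 2 or len(groups[kb]) < 2:
                continue
            t, p = welch_t_two_tailed(groups[ka], groups[kb])
            rows.append(
                {
                    "measure": counts["measure"].iloc[0],
                    "group_a": f"{ka[0]}:{ka[1]}", "group_b": f"{kb[0]}:{kb[1]}",
                    "mean_a": float(np.mean(groups[ka])),
                    "mean_b": float(np.mean(groups[kb])),
                    "t": t, "pvalue": p,
                }
            )
    return pd.DataFrame(rows)


def _bulk_venn(config: PipelineConfig) -> pd.DataFrame:
    rows = []
    common_up: dict[str, frozenset] = {}
    for genotype, day_paths in config.bulk_tables.items():
        tables = {d: read_de_table(p) for d, p in sorted(day_paths.items())}
        for direction in ("up", "down"):
            sets = {
                f"day{d}": de_filter(t, alpha=config.alpha, direction=direction)
                for d, t in tables.items()
            }
            part = venn_partition(sets)
            for label, genes in part.regions.items():
                rows.append(
                    {
                        "genotype": genotype, "direction": direction,
                        "region": "&".join(label), "n_genes": len(genes),
                    }
                )
            if direction == "up":
                common_up[genotype] = part.common_all()
    if len(common_up) == 2:
        (ga, sa), (gb, sb) = sorted(common_up.items())
        shared, only_a, only_b = cross_genotype_unique(sa, sb)
        for region, genes in (
            ("shared", shared), (f"unique_{ga}", only_a), (f"unique_{gb}", only_b),
        ):
            rows.append(
                {
                    "genotype": "both", "direction": "up",
                    "region": region, "n_genes": len(genes),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and (optionally) write the report bundle."""
    # --- acquire counts + metadata -------------------------------------
    if config.sim_config is not None:
        sim = dataclasses.replace(
            config.sim_config, seed=stage_seed(config.seed, "simulate")
        )
        adata, meta, _truth = simulate_cells(sim)
    else:
        d = Path(config.matrix_dir)
        adata = read_10x_triplet(
            d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv"
        )
        meta = read_metadata(config.metadata_path)
    adata = attach_metadata(adata, meta)

    # --- normalize once, annotate, score -------------------------------
    norm = (
        depth_normalize(adata) if config.normalization == "median_depth" else adata
    )
    markers = {t: config.registry[t] for t in ("AV", "HS", "ME")}
    annotation = assign_cell_types(
        norm, markers, config.normalization, config.pseudocount
    )
    proportions = type_proportions(annotation, meta)

    score_p = score_signature(
        norm, config.registry["proliferation"], config.normalization, config.pseudocount
    )
    score_r = score_signature(
        norm, config.registry["regulon"], config.normalization, config.pseudocount
    )
    classified = classify_ppbc_like(score_p, score_r, config.half_max_factor)
    scores = pd.DataFrame(
        {"proliferation": score_p.scores, "regulon": score_r.scores}
    )

    # --- per-sample counts + replicate tests ---------------------------
    ppbc_counts = _per_sample_counts(
        meta, classified.calls["is_ppbc_like"], "ppbc_like"
    )
    hs_cells = annotation.index[annotation["celltype"] == "HS"]
    p53_flags = pd.Series(False, index=annotation.index)
    if config.p53_gene in adata.var_names and len(hs_cells):
        col = adata[hs_cells, config.p53_gene].X
        detected = np.asarray(col.todense()).ravel() > 0
        p53_flags.loc[hs_cells] = detected
    p53_positive = _per_sample_counts(meta, p53_flags, "p53_positive_hs")

    ttests = pd.concat(
        [_group_ttests(ppbc_counts), _group_ttests(p53_positive)],
        ignore_index=True,
    )

    # --- lactating HS DE between genotypes -----------------------------
    hs_de, hs_top = None, []
    if config.run_de:
        meta_ix = meta.set_index("barcode")
        lac_hs = hs_cells[
            meta_ix.reindex(hs_cells)["state"].to_numpy() == "LacD21"
        ]
        geno = meta_ix.reindex(lac_hs)["genotype"].to_numpy()
        cells_c57 = lac_hs[geno == "C57"]
        cells_nzb = lac_hs[geno == "NZB"]
        if len(cells_c57) and len(cells_nzb):
            hs_de = per_gene_de(norm, list(cells_c57), list(cells_nzb), config.pseudocount)
            hs_top = top_n_genes(hs_de, n=config.top_n, p_cutoff=config.de_p_cutoff)

    # --- bulk venn (optional) ------------------------------------------
    venn_counts = _bulk_venn(config) if config.bulk_tables else None

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            s: stage_seed(config.seed, s) for s in ("simulate",)
        },
        "normalization": config.normalization,
        "pseudocount": config.pseudocount,
        "half_max_factor": config.half_max_factor,
        "thresholds": classified.thresholds,
        "alpha": config.alpha,
        "de_p_cutoff": config.de_p_cutoff,
        "top_n": config.top_n,
        "p53_gene": config.p53_gene,
        "n_cells": int(adata.n_obs),
        "n_genes": int(adata.n_vars),
        "simulated": config.sim_config is not None,
    }
    if config.sim_config is not None:
        sim_d = dataclasses.asdict(config.sim_config)
        sim_d["conditions"] = [list(c) for c in config.sim_config.conditions]
        manifest["sim_config"] = sim_d

    bundle = ReportBundle(
        annotation=annotation,
        proportions=proportions,
        scores=scores,
        ppbc_calls=classified.calls,
        thresholds=classified.thresholds,
        ppbc_counts=ppbc_counts,
        p53_positive=p53_positive,
        ttests=ttests,
        hs_de=hs_de,
        hs_top_genes=hs_top,
        venn_counts=venn_counts,
        manifest=manifest,
    )
    if config.out_dir is not None:
        write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Serialize a report bundle as deterministic CSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.annotation.to_csv(out / "annotation.csv", float_format=_CSV_FLOAT)
    bundle.proportions.to_csv(out / "proportions.csv", float_format=_CSV_FLOAT)
    bundle.scores.to_csv(out / "scores.csv", float_format=_CSV_FLOAT)
    bundle.ppbc_calls.to_csv(out / "ppbc_calls.csv")
    bundle.ppbc_counts.to_csv(out / "ppbc_counts.csv", index=False)
    bundle.p53_positive.to_csv(out / "p53_positive.csv", index=False)
    bundle.ttests.to_csv(out / "ttests.csv", index=False, float_format=_CSV_FLOAT)
    if bundle.hs_de is not None:
        write_de_table(bundle.hs_de, out / "hs_de.csv")
        with open(out / "hs_top_genes.txt", "w", encoding="utf-8") as fh:
            fh.write("\n".join(bundle.hs_top_genes) + "\n")
    if bundle.venn_counts is not None:
        bundle.venn_counts.to_csv(out / "venn_counts.csv", index=False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
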