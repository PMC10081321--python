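"""End-to-end pipeline driver and the percentile-in-reference report.

:func:`run_pipeline` wires the library stages together — simulate or load
expression data, QC, CPM normalization, universe harmonization, network
construction and aggregation, meta-markers, module scores, and (when a
reference network is supplied) preserved co-expression — writing a
deterministic directory of TSV/JSON artifacts.  Every stochastic stage reads
its seed from the config; re-running an identical config reproduces the
outputs bit-exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genesets import GeneUniverse
from .io import cpm_normalize, harmonize_universe, qc_filter, read_sparse_triplet
from .markers import (
    compute_markers,
    make_meta_markers,
    top_meta_markers,
)
from .modules import neighbor_voting_auroc
from .network import CoexpressionNetwork, aggregate_networks, build_network
from .preservation import reference_percentile, score_preservation
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "n_datasets": 3,
    "simulate": {},          # SimulationConfig overrides
    "qc": {"mito_prefix": "MT-", "mito_max": 0.5, "min_genes": 200, "max_genes": 6000},
    "de_log2fc_min": 4.0,
    "de_fdr_max": 0.05,
    "top_k_markers": 50,
    "preservation_k": 10,
    "reference_network": None,  # path to an HDF5 network, or None to skip
}


def _merge_config(config: dict | None) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if config:
        for key, value in config.items():
            if isinstance(value, dict) and isinstance(merged.get(key), dict):
                merged[key].update(value)
            else:
                merged[key] = value
    return merged


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: dict | str | Path | None, out_dir: str | Path) -> dict:
    """Run the full workflow described by ``config`` into ``out_dir``.

    ``config`` is a dict (or path to a JSON file) overriding
    ``DEFAULT_CONFIG``.  With the defaults, ``n_datasets`` synthetic labeled
    datasets are simulated with seeds ``seed, seed+1, ...``; real data can be
    substituted via ``config["datasets"]`` entries of 10x triplet paths.
    Returns the summary dictionary also written to ``summary.json``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = json.load(fh)
    cfg = _merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg["reference_network"] is not None and not Path(cfg["reference_network"]).exists():
        raise FileNotFoundError(
            f"reference network {cfg['reference_network']} does not exist"
        )

    datasets = []
    marker_map = None
    if "datasets" in cfg and cfg["datasets"]:
        for entry in cfg["datasets"]:
            datasets.append(
                read_sparse_triplet(
                    entry["matrix"], entry["features"], entry["barcodes"]
                )
            )
    else:
        for i in range(int(cfg["n_datasets"])):
            sim = simulate_dataset(
                SimulationConfig(seed=int(cfg["seed"]) + i, **cfg["simulate"])
            )
            datasets.append(sim.expression)
            marker_map = sim.marker_map

    universe = GeneUniverse(
        sorted({g for em in datasets for g in em.gene_ids}),
        dict(marker_map) if marker_map else {},
    )

    processed = []
    for em in datasets:
        em = qc_filter(em, **cfg["qc"]) if em.normalized == "counts" else em
        em = cpm_normalize(em) if em.normalized == "counts" else em
        processed.append(harmonize_universe(em, universe))

    networks = [build_network(em) for em in processed]
    aggregate = aggregate_networks(networks)

    stats = [
        compute_markers(em, dataset=f"dataset_{i}")
        for i, em in enumerate(processed)
        if "cell_type" in em.cell_meta.columns and em.cell_meta["cell_type"].notna().any()
    ]
    summary: dict = {"coexqc_version": __version__, "config": cfg}
    if stats:
        meta = make_meta_markers(
            stats, log2_fc_min=cfg["de_log2fc_min"], fdr_max=cfg["de_fdr_max"]
        )
        _write_tsv(meta, out / "meta_markers.tsv")
        marker_sets = top_meta_markers(meta, int(cfg["top_k_markers"]))
        module_rows = [
            {
                "cell_type": ct,
                "n_genes": len(genes),
                "auroc": neighbor_voting_auroc(
                    aggregate, genes, seed=int(cfg["seed"])
                ),
            }
            for ct, genes in marker_sets.items()
        ]
        module_scores = pd.DataFrame(module_rows)
        _write_tsv(module_scores, out / "module_scores.tsv")
        summary["module_scores"] = {
            r["cell_type"]: r["auroc"] for r in module_rows
        }
    else:
        marker_sets = dict(marker_map) if marker_map else {}

    if cfg["reference_network"] is not None:
        reference = CoexpressionNetwork.from_hdf5(cfg["reference_network"])
        result = score_preservation(
            reference, aggregate, gene_sets=marker_sets or None,
            k=int(cfg["preservation_k"]),
        )
        per_gene = result.per_gene.rename("auroc").rename_axis("gene").reset_index()
        _write_tsv(per_gene, out / "preserved_per_gene.tsv")
        summary["preservation"] = result.to_json_dict()
    else:
        logger.info("no reference network configured; preservation stage skipped")
        summary["preservation"] = None

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary


def render_reference_report(
    scores: dict[str, float],
    reference_table: pd.DataFrame,
    out_path: str | Path | None = None,
) -> dict:
    """Place per-cell-type scores within reference score distributions.

    ``reference_table`` holds one column per cell type, each a distribution
    of scores observed across reference datasets.  For every queried cell
    type present in the table the report gives the score, its percentile in
    the reference distribution, and distribution summaries; absent cell
    types are omitted with a notice.  The report round-trips through JSON.
    """
    if reference_table.empty or reference_table.shape[1] == 0:
        raise ValueError("empty reference table")
    report: dict[str, dict] = {}
    for ct, score in scores.items():
        if ct not in reference_table.columns:
            logger.info("cell type %r absent from the reference table; omitted", ct)
            continue
        ref = reference_table[ct].dropna().to_numpy()
        report[ct] = {
            "score": float(score),
            "percentile": reference_percentile(float(score), ref),
            "reference_n": int(ref.size),
            "reference_median": float(np.median(ref)),
            "reference_mean": float(ref.mean()),
        }
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
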