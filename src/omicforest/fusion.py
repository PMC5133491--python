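"""Orchestration of the dual classification/regression fusion workflow.

Classification branch: each platform is autoscaled and classified against
the dose classes on its own (ranking platforms by OOB error), backward
elimination selects each platform's discriminatory metabolites, the
selections are pooled into one fused matrix (feature IDs prefixed
``<dataset>:``), and elimination runs once more to yield the final
cross-platform discriminatory set, which feeds a partial-correlation
network.

Regression branch: every (platform, phenotype) pair gets an RF regression
whose Q² and feature importances are tested against permutation nulls; each
phenotype's significant features (plus the phenotype itself as a clinical
node) feed a per-phenotype partial-correlation network.

Per-dataset and per-pair seeds are derived from the global seed and the
entity names, so adding a platform never perturbs another's results and a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    AssociationResult,
    PermutationParams,
    derive_seed,
    regress_all,
)
from .io_datasets import DatasetCollection, FeatureTable, autoscale, read_manifest
from .network import NetworkGraph, NetworkParams, build_network, export_graph
from .rf_core import RFParams, fit_classifier
from .selection import SelectionParams, SelectionTrace, backward_eliminate
from .synthetic_data import simulate_study

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "DatasetClassification",
    "ClassificationStageResult",
    "classify_all",
    "fuse_and_reselect",
    "run_full_pipeline",
]


@dataclass
class PipelineConfig:
    manifest: str | None = None  # None -> default synthetic study
    outdir: str = "omicforest_out"
    seed: int = 0
    autoscale_datasets: bool = True
    rf: RFParams = field(default_factory=RFParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    permutation: PermutationParams = field(default_factory=PermutationParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    regression_phenotypes: list[str] | None = None  # None -> all
    regression_datasets: list[str] | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            manifest=raw.get("manifest"),
            outdir=raw.get("outdir", "omicforest_out"),
            seed=int(raw.get("seed", 0)),
            autoscale_datasets=bool(raw.get("autoscale_datasets", True)),
            rf=RFParams(**raw.get("rf", {})),
            selection=SelectionParams(**raw.get("selection", {})),
            permutation=PermutationParams(**raw.get("permutation", {})),
            network=NetworkParams(**raw.get("network", {})),
            regression_phenotypes=raw.get("regression_phenotypes"),
            regression_datasets=raw.get("regression_datasets"),
        )
        if cfg.manifest is not None:
            mpath = Path(path).parent / cfg.manifest
            if not mpath.exists():
                raise FileNotFoundError(f"config references missing manifest {mpath}")
            cfg.manifest = str(mpath)
        return cfg

    def to_dict(self) -> dict:
        return {
            "manifest": self.manifest,
            "outdir": self.outdir,
            "seed": self.seed,
            "autoscale_datasets": self.autoscale_datasets,
            "rf": vars(self.rf),
            "selection": vars(self.selection),
            "permutation": vars(self.permutation),
            "network": vars(self.network),
            "regression_phenotypes": self.regression_phenotypes,
            "regression_datasets": self.regression_datasets,
            "version": __version__,
        }


@dataclass
class DatasetClassification:
    dataset_name: str
    n_features: int
    full_oob_error: float
    full_oob_error_se: float
    selected_features: tuple
    selected_oob_error: float
    selected_oob_error_se: float
    trace: SelectionTrace = field(repr=False, default=None)


@dataclass
class ClassificationStageResult:
    per_dataset: dict[str, DatasetClassification]
    ranked_datasets: list[str] = field(default_factory=list)  # by full-model OOB error
    fused_features: tuple = ()
    fused_full_oob_error: float = float("nan")
    final_features: tuple = ()
    final_oob_error: float = float("nan")
    fused_trace: SelectionTrace = field(repr=False, default=None)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "dataset": d.dataset_name,
                "n_features": d.n_features,
                "full_oob_error": d.full_oob_error,
                "n_selected": len(d.selected_features),
                "selected_oob_error": d.selected_oob_error,
            }
            for d in self.per_dataset.values()
        ]
        return pd.DataFrame(rows).sort_values("full_oob_error", kind="stable").reset_index(drop=True)


def _prepared_table(table: FeatureTable, config: PipelineConfig) -> FeatureTable:
    return autoscale(table) if config.autoscale_datasets else table


def _selection_iteration(trace: SelectionTrace, features: tuple):
    for it in trace.iterations:
        if it.feature_ids == features:
            return it
    return trace.iterations[0]


def classify_all(collection: DatasetCollection, config: PipelineConfig) -> ClassificationStageResult:
    """Per-dataset multiclass RF + backward elimination; datasets ranked by
    full-model OOB error (most dose-predictive first)."""
    per_dataset: dict[str, DatasetClassification] = {}
    for table in collection.tables:
        name = table.dataset_name
        prepared = _prepared_table(table, config)
        dseed = derive_seed(config.seed, "classify", name)
        trace = backward_eliminate(
            prepared.values,
            collection.labels,
            SelectionParams(
                drop_fraction=config.selection.drop_fraction,
                min_features=config.selection.min_features,
                recompute_importance=config.selection.recompute_importance,
                rule=config.selection.rule,
                seed=dseed,
            ),
            config.rf,
            feature_ids=prepared.feature_ids,
        )
        full_it = trace.iterations[0]
        sel_it = _selection_iteration(trace, trace.selected)
        per_dataset[name] = DatasetClassification(
            dataset_name=name,
            n_features=prepared.n_features,
            full_oob_error=full_it.oob_error,
            full_oob_error_se=full_it.oob_error_se,
            selected_features=trace.selected,
            selected_oob_error=sel_it.oob_error,
            selected_oob_error_se=sel_it.oob_error_se,
            trace=trace,
        )
        logger.info(
            "%s: full OOB %.3f (%d features) -> selected OOB %.3f (%d features)",
            name, full_it.oob_error, prepared.n_features,
            sel_it.oob_error, len(trace.selected),
        )
    ranked = sorted(per_dataset, key=lambda d: (per_dataset[d].full_oob_error, d))
    return ClassificationStageResult(per_dataset=per_dataset, ranked_datasets=ranked)


def fuse_and_reselect(
    selections: dict[str, tuple],
    collection: DatasetCollection,
    config: PipelineConfig,
    result: ClassificationStageResult | None = None,
) -> ClassificationStageResult:
    """Pool per-dataset selections into one matrix and re-run selection.

    Feature IDs are prefixed ``<dataset>:`` to prevent cross-platform
    collisions.  Fills the fused fields of ``result`` (or a fresh one).
    """
    blocks = []
    for table in collection.tables:
        chosen = selections.get(table.dataset_name, ())
        if not chosen:
            continue
        prepared = _prepared_table(table, config).subset_features(chosen)
        block = prepared.data.copy()
        block.columns = [f"{table.dataset_name}:{c}" for c in block.columns]
        blocks.append(block)
    if not blocks:
        raise ValueError("empty union of per-dataset selections")
    fused = pd.concat(blocks, axis=1)

    result = result or ClassificationStageResult(per_dataset={})
    result.fused_features = tuple(fused.columns)
    trace = backward_eliminate(
        fused.to_numpy(),
        collection.labels,
        SelectionParams(
            drop_fraction=config.selection.drop_fraction,
            min_features=config.selection.min_features,
            recompute_importance=config.selection.recompute_importance,
            rule=config.selection.rule,
            seed=derive_seed(config.seed, "fused"),
        ),
        config.rf,
        feature_ids=list(fused.columns),
    )
    result.fused_full_oob_error = trace.iterations[0].oob_error
    result.final_features = trace.selected
    result.final_oob_error = _selection_iteration(trace, trace.selected).oob_error
    result.fused_trace = trace
    logger.info(
        "fused: %d features, OOB %.3f -> final %d features, OOB %.3f",
        len(result.fused_features), result.fused_full_oob_error,
        len(result.final_features), result.final_oob_error,
    )
    return result


def _fused_matrix(collection: DatasetCollection, features: tuple, config: PipelineConfig) -> pd.DataFrame:
    """Columns for prefixed feature IDs, scaled the same way as classification."""
    cols = {}
    for table in collection.tables:
        wanted = [f.split(":", 1)[1] for f in features if f.startswith(table.dataset_name + ":")]
        if not wanted:
            continue
        prepared = _prepared_table(table, config).subset_features(wanted)
        for c in prepared.data.columns:
            cols[f"{table.dataset_name}:{c}"] = prepared.data[c]
    return pd.DataFrame(cols)[list(features)]


def _phenotype_network(
    collection: DatasetCollection,
    res: AssociationResult,
    config: PipelineConfig,
) -> NetworkGraph | None:
    """Network over a phenotype's significant features plus the phenotype as a
    clinical node; skipped when too few features or n <= p+2."""
    feats = sorted(res.significant_features)
    if len(feats) < 2:
        return None
    table = _prepared_table(collection.table(res.dataset_name), config)
    X = table.data[feats].copy()
    X[res.phenotype_id] = collection.clinical.data[res.phenotype_id]
    if len(X) <= X.shape[1] + 2:
        logger.warning(
            "skipping network for %s/%s: %d significant features vs n=%d",
            res.dataset_name, res.phenotype_id, len(feats), len(X),
        )
        return None
    node_types = {f: "metabolite" for f in feats}
    node_types[res.phenotype_id] = "clinical"
    node_datasets = {f: res.dataset_name for f in feats}
    node_datasets[res.phenotype_id] = "clinical"
    return build_network(X, node_types, config.network, node_datasets)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute both branches end to end and write all artefacts to ``config.outdir``.

    Outputs: ``class_errors.tsv``, per-dataset selection traces,
    ``fused_network.graphml``/``.tsv``, ``q2_matrix.tsv``, per-phenotype
    networks, and ``run_manifest.json`` recording seeds, parameters and
    package version.  Any stage error aborts with a stage-labelled message;
    artefacts already written are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.manifest is not None:
        collection = read_manifest(config.manifest)
    else:
        collection, _ = simulate_study(seed=derive_seed(config.seed, "simulate"))

    stage = "classification"
    try:
        cls_result = classify_all(collection, config)
        selections = {
            name: d.selected_features for name, d in cls_result.per_dataset.items()
        }
        cls_result = fuse_and_reselect(selections, collection, config, cls_result)

        cls_result.summary_frame().to_csv(outdir / "class_errors.tsv", sep="\t", index=False, float_format="%.6f")
        traces_dir = outdir / "selection_traces"
        traces_dir.mkdir(exist_ok=True)
        for name, d in cls_result.per_dataset.items():
            d.trace.to_tsv(traces_dir / f"{name}.tsv")
            d.trace.to_json(traces_dir / f"{name}.json")
        cls_result.fused_trace.to_tsv(traces_dir / "fused.tsv")
        cls_result.fused_trace.to_json(traces_dir / "fused.json")

        stage = "classification network"
        final = cls_result.final_features
        fused_X = _fused_matrix(collection, final, config)
        node_datasets = {f: f.split(":", 1)[0] for f in final}
        if len(fused_X) > len(final) + 2 and len(final) >= 2:
            net = build_network(
                fused_X,
                {f: "metabolite" for f in final},
                config.network,
                node_datasets,
            )
            export_graph(net, outdir / "fused_network.graphml", "graphml")
            export_graph(net, outdir / "fused_network_edges.tsv", "edge_tsv")
        else:
            net = None
            logger.warning("final set too large for partial correlation; no fused network")

        stage = "regression"
        q2 = None
        assoc: dict = {}
        pheno_nets: dict[str, list[str]] = {}
        if collection.clinical is not None:
            q2, assoc = regress_all(
                collection,
                config.permutation,
                config.rf,
                phenotypes=config.regression_phenotypes,
                datasets=config.regression_datasets,
            )
            q2.to_csv(outdir / "q2_matrix.tsv", sep="\t", float_format="%.6f")
            with open(outdir / "association_results.json", "w") as fh:
                json.dump({f"{d}/{p}": r.to_dict() for (d, p), r in sorted(assoc.items())}, fh, indent=1)
            stage = "regression networks"
            nets_dir = outdir / "phenotype_networks"
            nets_dir.mkdir(exist_ok=True)
            for (dname, pheno), res in sorted(assoc.items()):
                if not res.q2_significant:
                    continue
                g = _phenotype_network(collection, res, config)
                if g is None:
                    continue
                fname = f"{dname}__{pheno}.graphml"
                export_graph(g, nets_dir / fname, "graphml")
                pheno_nets.setdefault(pheno, []).append(fname)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during {stage}: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "n_samples": len(collection.sample_ids),
        "datasets": {t.dataset_name: t.n_features for t in collection.tables},
        "ranked_datasets": cls_result.ranked_datasets,
        "fused_n_features": len(cls_result.fused_features),
        "final_features": list(cls_result.final_features),
        "final_oob_error": cls_result.final_oob_error,
        "phenotype_networks": pheno_nets,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "collection": collection,
        "classification": cls_result,
        "q2_matrix": q2,
        "associations": assoc,
        "fused_network": net,
        "outdir": outdir,
    }
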