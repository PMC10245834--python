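"""End-to-end orchestration: preprocess -> graph -> train -> signatures -> export.

Every stage writes its artifacts under the output directory and a manifest
records input hashes, the config snapshot, the seed and the package version,
so a run can be reproduced or resumed stage by stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, preprocess
from .export import export_cytoscape, export_upset
from .graphs import (
    assemble_hetero_graph,
    build_metabolic_edges,
    build_phylo_edges,
    edges_to_frame,
    frame_to_edges,
)
from .model import TrainingConfig, extract_attention, train
from .signatures import call_signatures, write_signatures

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    abundance: str
    metadata: str
    metabolic: str
    taxonomy: str
    out_dir: str
    threshold: float = 0.001
    filter_mode: str = "any_sample"
    training: TrainingConfig = field(default_factory=TrainingConfig)
    thres: float | None = None          # defaults to training.thres
    alpha: float = 0.05
    correction: str = "none"
    export_mode: str = "metabolic"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        tr = raw.pop("training", {})
        cfg = cls(**raw)
        if tr:
            cfg.training = TrainingConfig(**tr)
        cfg.training.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all five stages; returns the artifact directory.

    Raises on the first failing stage (partial artifacts are kept on disk).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.training.seed = config.seed
    thres = config.thres if config.thres is not None else config.training.thres

    for name in ("abundance", "metadata", "metabolic", "taxonomy"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise FileNotFoundError(f"{name} input not found: {p}")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {name: _sha256(getattr(config, name))
                   for name in ("abundance", "metadata", "metabolic", "taxonomy")},
    }

    logger.info("stage: preprocess")
    matrix = io.read_abundance(config.abundance)
    metadata = io.read_metadata(config.metadata)
    taxonomy = io.read_taxonomy(config.taxonomy)
    metabolic = io.read_metabolic(config.metabolic)
    if matrix.species_ids and isinstance(matrix.species_ids[0], str):
        matrix = io.map_names_to_taxids(matrix, taxonomy)
    io.check_samples_covered(matrix, metadata)
    metadata = metadata.subset(matrix.sample_ids)
    filtered, report = preprocess.filter_species(matrix, config.threshold, config.filter_mode)
    normalized = preprocess.normalize_tss(filtered)
    io.write_abundance(normalized, out / "normalized_abundance.tsv")
    report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    preprocess.diversity(matrix).to_csv(out / "diversity.tsv", sep="\t", index=False)

    logger.info("stage: graph construction")
    met_edges = build_metabolic_edges(list(normalized.species_ids), metabolic)
    phy_edges = build_phylo_edges(list(normalized.species_ids), taxonomy)
    edges_to_frame(met_edges).to_csv(out / "metabolic_edges.tsv", sep="\t", index=False)
    edges_to_frame(phy_edges).to_csv(out / "phylo_edges.tsv", sep="\t", index=False)
    graph = assemble_hetero_graph(normalized, metadata, met_edges, phy_edges)

    logger.info("stage: train")
    model = train(graph, config.training)
    attention = extract_attention(
        model, graph,
        average_layers=(config.training.attention_aggregation == "mean_layers"),
    )
    pd.DataFrame(attention.scores, index=attention.species_ids,
                 columns=attention.sample_ids).to_csv(
        out / "attention.tsv", sep="\t", index_label="taxid")
    pd.DataFrame({"epoch": np.arange(1, len(model.loss_trace) + 1),
                  "loss": model.loss_trace,
                  "val_macro_f1": model.val_metric_trace,
                  "lr": model.lr_trace}).to_csv(
        out / "training_trace.tsv", sep="\t", index=False)

    logger.info("stage: signatures")
    sig = call_signatures(attention, metadata, thres=thres, alpha=config.alpha,
                          correction=config.correction, taxonomy=taxonomy)
    write_signatures(sig, out / "signatures.tsv")

    logger.info("stage: export")
    export_upset(sig, out)
    if sig["significant"].any():
        export_cytoscape(sig, met_edges, phy_edges, mode=config.export_mode, out_dir=out)
    else:
        logger.warning("no significant signatures; skipping network export")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
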