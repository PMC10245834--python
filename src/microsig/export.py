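"""UpSet-ready set-membership tables and Cytoscape-importable network files.

Both exports are plain TSV: a membership matrix plus exclusive-intersection
sizes for UpSet plotting, and node/edge attribute tables (with a SIF-style
triple column file) that import directly into Cytoscape. Styling hints (node
shape/color, edge color) are emitted as attribute columns: cancer nodes are
octagons, species circles, compound nodes yellow triangles, and phylogenetic
edges gray — attention-edge weight carries the normalized attention score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import RelationEdge
from .io import ValidationError

logger = logging.getLogger(__name__)


def membership_matrix(signatures: pd.DataFrame) -> pd.DataFrame:
    """Species x cancer-type boolean grid over significant records only.

    Rows: unique significant species (taxid index); columns: cancer types with
    at least one signature.
    """
    sig = signatures[signatures["significant"]]
    if sig.empty:
        return pd.DataFrame(index=pd.Index([], name="taxid"))
    mem = pd.crosstab(sig["taxid"], sig["cancer_type"]).astype(bool)
    mem.index.name = "taxid"
    return mem.sort_index()


def exclusive_intersections(membership: pd.DataFrame) -> pd.DataFrame:
    """Size of every observed exclusive membership pattern (UpSet bar heights).

    Each species contributes to exactly one pattern, so sizes sum to the number
    of unique significant species.
    """
    if membership.empty:
        return pd.DataFrame(columns=["cancer_types", "degree", "size"])
    patterns: dict[tuple[str, ...], int] = {}
    cols = list(membership.columns)
    for _, row in membership.iterrows():
        key = tuple(c for c in cols if row[c])
        patterns[key] = patterns.get(key, 0) + 1
    rows = [
        {"cancer_types": "&".join(key), "degree": len(key), "size": size}
        for key, size in patterns.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["size", "degree", "cancer_types"], ascending=[False, True, True])
        .reset_index(drop=True)
    )


def export_upset(signatures: pd.DataFrame, out_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write membership.tsv and intersections.tsv; return both tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mem = membership_matrix(signatures)
    inter = exclusive_intersections(mem)
    if mem.empty:
        logger.warning("no significant signatures; writing header-only UpSet exports")
    mem.astype(int).to_csv(out_dir / "membership.tsv", sep="\t")
    inter.to_csv(out_dir / "intersections.tsv", sep="\t", index=False)
    return mem, inter


@dataclass
class NetworkExport:
    nodes: pd.DataFrame  # id, type, label, shape, color
    edges: pd.DataFrame  # source, target, kind, weight, color


def export_cytoscape(
    signatures: pd.DataFrame,
    metabolic_edges: list[RelationEdge] | None = None,
    phylo_edges: list[RelationEdge] | None = None,
    mode: str = "metabolic",
    out_dir=None,
) -> NetworkExport:
    """Cancer-species attention network plus, per mode, shared-compound nodes
    (metabolic) or same-genus species-species edges (phylogenetic)."""
    if mode not in ("metabolic", "phylogenetic"):
        raise ValidationError(f"unknown export mode {mode!r}")
    sig = signatures[signatures["significant"]]
    if sig.empty:
        raise ValidationError("cannot export an empty signature table")

    sig_species = {int(t) for t in sig["taxid"]}
    name_of = dict(zip(sig["taxid"].astype(int), sig["species_name"].astype(str)))

    nodes: dict[str, dict] = {}
    edges: list[dict] = []
    for ct in sorted(sig["cancer_type"].unique()):
        nodes[f"cancer:{ct}"] = dict(id=f"cancer:{ct}", type="cancer", label=ct,
                                     shape="octagon", color="#d62728")
    for t in sorted(sig_species):
        nodes[f"species:{t}"] = dict(id=f"species:{t}", type="species",
                                     label=name_of[t], shape="ellipse", color="#1f77b4")
    for row in sig.itertuples(index=False):
        edges.append(dict(source=f"cancer:{row.cancer_type}",
                          target=f"species:{int(row.taxid)}",
                          kind="attention", weight=float(row.normalized_attention),
                          color="#000000"))

    if mode == "metabolic":
        for e in metabolic_edges or []:
            if e.species_a in sig_species and e.species_b in sig_species:
                cid = f"compound:{e.annotation}"
                if cid not in nodes:
                    nodes[cid] = dict(id=cid, type="compound", label=e.annotation,
                                      shape="triangle", color="#ffd700")
                for sp in (e.species_a, e.species_b):
                    link = dict(source=f"species:{sp}", target=cid,
                                kind="metabolic", weight=1.0, color="#2ca02c")
                    if link not in edges:
                        edges.append(link)
    else:
        for e in phylo_edges or []:
            if e.species_a in sig_species and e.species_b in sig_species:
                edges.append(dict(source=f"species:{e.species_a}",
                                  target=f"species:{e.species_b}",
                                  kind="phylogenetic", weight=1.0, color="#808080"))

    node_df = pd.DataFrame(nodes.values())
    edge_df = pd.DataFrame(edges).drop_duplicates().reset_index(drop=True)
    known = set(node_df["id"])
    dangling = set(edge_df["source"]) | set(edge_df["target"]) - known
    dangling -= known
    if dangling:
        raise ValidationError(f"edges reference unknown nodes: {sorted(dangling)[:5]}")

    export = NetworkExport(nodes=node_df, edges=edge_df)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        node_df.to_csv(out_dir / "nodes.tsv", sep="\t", index=False)
        edge_df.to_csv(out_dir / "edges.tsv", sep="\t", index=False)
        sif = edge_df[["source", "kind", "target"]]
        sif.to_csv(out_dir / "network.sif", sep="\t", index=False, header=False)
    return export


def read_membership(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(bool)
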