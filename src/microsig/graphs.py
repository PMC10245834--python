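"""Species-species relation networks and the heterogeneous species+sample graph.

Two relation layers connect species nodes:

* metabolic — an edge links two species whenever both interact with the same
  small-molecule compound in an NJS16-style interaction table (direction of the
  interaction is ignored for edge formation but kept as annotation);
* phylogenetic — an edge links two species of the same genus, so each genus
  contributes a clique.

Sample and species nodes are then joined by abundance edges (one per nonzero
cell of the normalized matrix, weighted by relative abundance) to form the
heterogeneous graph consumed by the attention model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io import (
    AbundanceMatrix,
    MetabolicTable,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
    check_samples_covered,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class RelationEdge:
    """Undirected species-species edge, stored with species_a < species_b.

    ``annotation`` is the shared compound id (metabolic) or genus (phylogenetic).
    """

    species_a: int
    species_b: int
    relation: str  # "metabolic" | "phylogenetic"
    annotation: str

    def __post_init__(self) -> None:
        if self.species_a >= self.species_b:
            raise ValidationError(
                f"edge must satisfy species_a < species_b, got "
                f"({self.species_a}, {self.species_b})"
            )


def build_metabolic_edges(species: list[int], table: MetabolicTable) -> list[RelationEdge]:
    """One annotated edge per unordered species pair per shared compound.

    A pair sharing k compounds yields k annotated edges; they collapse to a
    single graph edge of multiplicity k downstream. Entries of the table that
    are not in ``species`` (e.g. NJS16 human cell types) contribute nothing.
    """
    if len(set(species)) != len(species):
        raise ValidationError("species list passed to build_metabolic_edges has duplicates")
    in_matrix = set(species)
    t = table.table
    edges: set[RelationEdge] = set()
    for compound, group in t.groupby("compound_id"):
        members = sorted(set(group["species_taxid"].astype(int)) & in_matrix)
        for a, b in combinations(members, 2):
            edges.add(RelationEdge(a, b, "metabolic", str(compound)))
    return sorted(edges)


def build_phylo_edges(species: list[int], taxonomy: TaxonomyTable) -> list[RelationEdge]:
    """Connect all species pairs that share a (non-empty) genus: one clique per genus."""
    genus_of = taxonomy.taxid_to_genus()
    by_genus: dict[str, list[int]] = {}
    absent = 0
    for s in species:
        g = genus_of.get(int(s))
        if g is None:
            absent += 1
            continue
        if g == "":
            continue
        by_genus.setdefault(g, []).append(int(s))
    if absent:
        logger.warning("%d species missing from the taxonomy table form no phylo edges", absent)
    edges: list[RelationEdge] = []
    for genus, members in by_genus.items():
        for a, b in combinations(sorted(members), 2):
            edges.append(RelationEdge(a, b, "phylogenetic", genus))
    return sorted(edges)


def edge_multiplicity(edges: list[RelationEdge]) -> dict[tuple[int, int], int]:
    """Collapse annotated edges to unique pairs with shared-annotation counts."""
    mult: dict[tuple[int, int], int] = {}
    for e in edges:
        key = (e.species_a, e.species_b)
        mult[key] = mult.get(key, 0) + 1
    return mult


@dataclass
class HeteroGraph:
    """Heterogeneous graph over species and sample nodes.

    Node features are the two views of the normalized abundance matrix:
    a species' feature vector is its relative abundance across samples; a
    sample's feature vector is its composition across species.
    """

    species_ids: list[int]
    sample_ids: list[str]
    species_features: np.ndarray  # (S, N)
    sample_features: np.ndarray   # (N, S)
    sample_labels: list[str]
    # abundance edges: one per nonzero matrix cell
    ab_species_idx: np.ndarray
    ab_sample_idx: np.ndarray
    ab_weight: np.ndarray
    # relation edges as (E, 2) index pairs into species_ids, plus multiplicity
    metabolic_pairs: np.ndarray
    metabolic_mult: np.ndarray
    phylo_pairs: np.ndarray
    phylo_mult: np.ndarray

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_species + self.n_samples

    @property
    def cancer_types(self) -> list[str]:
        return sorted(set(self.sample_labels))


def assemble_hetero_graph(
    matrix: AbundanceMatrix,
    metadata: SampleMetadata,
    metabolic_edges: list[RelationEdge],
    phylo_edges: list[RelationEdge],
) -> HeteroGraph:
    """Assemble the typed graph from the normalized matrix and relation edges.

    Relation edges whose endpoints were filtered out of the matrix are dropped
    (counted in the log); an all-zero species row yields a node with no
    abundance edges and is flagged.
    """
    if not matrix.normalized:
        raise ValidationError("assemble_hetero_graph expects a normalized matrix")
    check_samples_covered(matrix, metadata)
    labels = metadata.labels
    sample_labels = [labels[s] for s in matrix.sample_ids]

    values = matrix.values
    sp_idx, sa_idx = np.nonzero(values)
    zero_rows = np.setdiff1d(np.arange(matrix.n_species), np.unique(sp_idx))
    if zero_rows.size:
        logger.warning(
            "%d species have no nonzero abundance and thus no abundance edges: %s",
            zero_rows.size, [matrix.species_ids[i] for i in zero_rows[:5]],
        )

    index_of = {int(s): i for i, s in enumerate(matrix.species_ids)}

    def _pairs(edges: list[RelationEdge]) -> tuple[np.ndarray, np.ndarray, int]:
        mult = edge_multiplicity(edges)
        kept, counts, dropped = [], [], 0
        for (a, b), k in sorted(mult.items()):
            ia, ib = index_of.get(a), index_of.get(b)
            if ia is None or ib is None:
                dropped += 1
                continue
            kept.append((ia, ib))
            counts.append(k)
        pairs = np.array(kept, dtype=np.int64).reshape(-1, 2)
        return pairs, np.array(counts, dtype=np.int64), dropped

    met_pairs, met_mult, met_drop = _pairs(metabolic_edges)
    phy_pairs, phy_mult, phy_drop = _pairs(phylo_edges)
    if met_drop or phy_drop:
        logger.info(
            "dropped relation edges referencing filtered species: "
            "%d metabolic, %d phylogenetic", met_drop, phy_drop,
        )

    return HeteroGraph(
        species_ids=[int(s) for s in matrix.species_ids],
        sample_ids=list(matrix.sample_ids),
        species_features=values.copy(),
        sample_features=values.T.copy(),
        sample_labels=sample_labels,
        ab_species_idx=sp_idx.astype(np.int64),
        ab_sample_idx=sa_idx.astype(np.int64),
        ab_weight=values[sp_idx, sa_idx],
        metabolic_pairs=met_pairs,
        metabolic_mult=met_mult,
        phylo_pairs=phy_pairs,
        phylo_mult=phy_mult,
    )


def edges_to_frame(edges: list[RelationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.species_a, e.species_b, e.relation, e.annotation) for e in edges],
        columns=["species_a", "species_b", "relation", "annotation"],
    )


def frame_to_edges(df: pd.DataFrame) -> list[RelationEdge]:
    return [
        RelationEdge(int(r.species_a), int(r.species_b), str(r.relation), str(r.annotation))
        for r in df.itertuples(index=False)
    ]
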