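"""Synthetic study generator with planted cancer-type-specific species.

Emulates the statistical structure of intratumoral microbiome count data —
high sparsity, log-normal abundance spread, per-cancer-type planted species —
plus the two side tables (NJS16-style metabolic interactions, taxonomy
lineages) the graph construction needs. It is not a biologically calibrated
simulator; it targets exactly the structure the method assumes.

Planted species get their intensity multiplied by ``effect_multiplier`` in
samples of their target cancer type, and planted species of the same type are
guaranteed to share one metabolic compound so the metabolic edge machinery
participates in recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AbundanceMatrix,
    MetabolicTable,
    SampleMetadata,
    TaxonomyTable,
    write_abundance,
    write_metabolic,
    write_metadata,
    write_taxonomy,
)

_DIRECTIONS = ("production", "consumption", "degradation")


@dataclass
class SynthConfig:
    """Study conditions for the synthetic dataset.

    Defaults: 120 species x 300 samples over 4 cancer types with 5 planted
    species per type at an 8x intensity effect; half the cells are structural
    zeros and intensities spread log-normally (typical counts ~20, sd 0.5 on
    the log scale per cell, sd 1 between species). This mimics the sparsity
    and between-species dynamic range of tumor RNA-seq-derived microbial
    counts after the conservative decontamination and batch correction such
    data undergo upstream, and realizes the intended planted-effect regime:
    an 8x shift on 5 species separates the classes.
    """

    n_species: int = 120
    n_samples: int = 300
    n_types: int = 4
    n_planted_per_type: int = 5
    effect_multiplier: float = 8.0
    base_log_mean: float = 3.0      # log of typical per-cell intensity (~e^3 = 20)
    base_log_sd: float = 0.5        # per-cell log-normal noise
    species_log_sd: float = 1.0     # between-species spread of baseline abundance
    sparsity: float = 0.5           # fraction of structural zeros
    n_genera: int = 24
    n_compounds: int = 40
    compound_density: float = 0.08
    distribution: str = "lognormal"  # or "negbin"
    negbin_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_per_type * self.n_types > self.n_species:
            raise ValueError(
                f"{self.n_planted_per_type} planted species x {self.n_types} types "
                f"exceed {self.n_species} species"
            )
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must lie in [0, 1)")
        if self.effect_multiplier < 1.0:
            raise ValueError("effect_multiplier must be >= 1")
        if self.distribution not in ("lognormal", "negbin"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


@dataclass
class SyntheticTruth:
    """Which species were planted for which cancer type (disjoint sets)."""

    planted: dict[str, set[int]]

    def all_planted(self) -> set[int]:
        out: set[int] = set()
        for s in self.planted.values():
            out |= s
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(ct, t) for ct, taxids in sorted(self.planted.items()) for t in sorted(taxids)]
        return pd.DataFrame(rows, columns=["cancer_type", "taxid"])


def generate(
    config: SynthConfig,
) -> tuple[AbundanceMatrix, SampleMetadata, MetabolicTable, TaxonomyTable, SyntheticTruth]:
    """Draw one synthetic study, fully deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    S, N, T = config.n_species, config.n_samples, config.n_types

    taxids = [1000 + i for i in range(S)]
    types = [f"CT{t + 1:02d}" for t in range(T)]
    sample_ids = [f"S{j + 1:04d}" for j in range(N)]
    type_of_sample = np.array([j % T for j in range(N)])

    # planted species: first n_planted*T taxids, in disjoint blocks per type
    planted: dict[str, set[int]] = {}
    planted_idx: dict[int, np.ndarray] = {}
    for t in range(T):
        idx = np.arange(t * config.n_planted_per_type, (t + 1) * config.n_planted_per_type)
        planted_idx[t] = idx
        planted[types[t]] = {taxids[i] for i in idx}

    # per-cell intensity: species baseline x log-normal cell noise
    species_mu = config.base_log_mean + config.species_log_sd * rng.standard_normal(S)
    intensity = np.exp(species_mu[:, None] + config.base_log_sd * rng.standard_normal((S, N)))
    for t in range(T):
        cols = type_of_sample == t
        intensity[np.ix_(planted_idx[t], cols)] *= config.effect_multiplier

    mask = rng.random((S, N)) >= config.sparsity
    if config.distribution == "lognormal":
        counts = np.rint(intensity * mask)
    else:
        r = config.negbin_dispersion
        p = r / (r + intensity)
        counts = rng.negative_binomial(r, p) * mask
    counts = counts.astype(float)

    matrix = AbundanceMatrix(list(taxids), sample_ids, counts, normalized=False)
    metadata = SampleMetadata(pd.DataFrame({
        "sample_id": sample_ids,
        "cancer_type": [types[t] for t in type_of_sample],
    }))

    # taxonomy: uniform random genus assignment
    genus_idx = rng.integers(0, config.n_genera, size=S)
    taxonomy = TaxonomyTable(pd.DataFrame({
        "taxid": taxids,
        "name": [f"Genus{genus_idx[i] + 1:02d} species{i + 1}" for i in range(S)],
        "genus": [f"Genus{genus_idx[i] + 1:02d}" for i in range(S)],
    }))

    # metabolic table: Bernoulli species-compound incidence, plus one shared
    # compound per planted block
    compounds = [f"C{500 + c:05d}" for c in range(config.n_compounds)]
    rows = []
    incidence = rng.random((S, config.n_compounds)) < config.compound_density
    for t in range(T):
        incidence[planted_idx[t], t % config.n_compounds] = True
    for i in range(S):
        for c in np.where(incidence[i])[0]:
            rows.append((taxids[i], compounds[c],
                         _DIRECTIONS[int(rng.integers(0, len(_DIRECTIONS)))]))
    metabolic = MetabolicTable(pd.DataFrame(
        rows, columns=["species_taxid", "compound_id", "direction"]
    ))

    return matrix, metadata, metabolic, taxonomy, SyntheticTruth(planted)


def write_dataset(out_dir, matrix, metadata, metabolic, taxonomy, truth) -> None:
    """Write the four input TSVs plus truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_abundance(matrix, out / "abundance.tsv")
    write_metadata(metadata, out / "metadata.tsv")
    write_metabolic(metabolic, out / "metabolic.tsv")
    write_taxonomy(taxonomy, out / "taxonomy.tsv")
    truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
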