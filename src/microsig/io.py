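"""Readers, writers and validation for the four tab-delimited input tables.

All files are UTF-8, tab-delimited, with a mandatory header row and '.' as the
decimal separator. Species identifiers are canonicalized to NCBI taxonomy IDs
(positive integers) before any graph work, so downstream joins against the
metabolic and taxonomy tables are integer joins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIRECTIONS = {"production", "consumption", "degradation", "unspecified"}


class ValidationError(ValueError):
    """An input table violates one of its invariants."""


@dataclass
class AbundanceMatrix:
    """Species x sample grid of non-negative abundances.

    ``species_ids`` are taxids (ints) once canonicalized, or raw organism-name
    strings straight after reading a name-keyed file. ``normalized`` marks
    whether every sample column sums to 1 (total sum scaling applied).
    """

    species_ids: list
    sample_ids: list[str]
    values: np.ndarray  # shape (n_species, n_samples)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.species_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value grid shape {self.values.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.sample_ids)} samples"
            )
        self.validate()

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        dup = _duplicates(self.species_ids)
        if dup:
            raise ValidationError(f"duplicate species identifiers: {sorted(map(str, dup))}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValidationError(f"duplicate sample identifiers: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite abundance at species {self.species_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        if np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative abundance at species {self.species_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        if self.normalized:
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-8):
                bad = [self.sample_ids[i] for i in np.where(np.abs(sums - 1) > 1e-8)[0]]
                raise ValidationError(f"normalized matrix with column sums != 1: {bad[:5]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species_ids, columns=self.sample_ids)


@dataclass
class SampleMetadata:
    """Per-sample cancer-type labels."""

    table: pd.DataFrame  # columns: sample_id, cancer_type

    def __post_init__(self) -> None:
        t = self.table
        missing = {"sample_id", "cancer_type"} - set(t.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        dup = _duplicates(list(t["sample_id"]))
        if dup:
            raise ValidationError(f"duplicate sample_id in metadata: {sorted(dup)}")
        if t["cancer_type"].isna().any() or (t["cancer_type"].astype(str) == "").any():
            raise ValidationError("empty cancer_type label in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"].astype(str))

    @property
    def labels(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.table["cancer_type"].astype(str)))

    @property
    def cancer_types(self) -> list[str]:
        return sorted(self.table["cancer_type"].astype(str).unique())

    def subset(self, sample_ids: list[str]) -> "SampleMetadata":
        keep = self.table[self.table["sample_id"].astype(str).isin(set(sample_ids))]
        return SampleMetadata(keep.reset_index(drop=True))


@dataclass
class MetabolicTable:
    """Species-compound interaction rows in the NJS16 style."""

    table: pd.DataFrame  # columns: species_taxid, compound_id, direction

    def __post_init__(self) -> None:
        t = self.table
        missing = {"species_taxid", "compound_id", "direction"} - set(t.columns)
        if missing:
            raise ValidationError(f"metabolic table missing columns: {sorted(missing)}")
        t["species_taxid"] = t["species_taxid"].astype(int)
        if (t["species_taxid"] <= 0).any():
            raise ValidationError("non-positive taxid in metabolic table")
        if t["compound_id"].isna().any() or (t["compound_id"].astype(str) == "").any():
            raise ValidationError("empty compound_id in metabolic table")
        bad = set(t["direction"].astype(str)) - DIRECTIONS
        if bad:
            raise ValidationError(f"unknown interaction direction(s): {sorted(bad)}")


@dataclass
class TaxonomyTable:
    """Taxid / canonical name / genus lineage rows."""

    table: pd.DataFrame  # columns: taxid, name, genus

    def __post_init__(self) -> None:
        t = self.table
        missing = {"taxid", "name", "genus"} - set(t.columns)
        if missing:
            raise ValidationError(f"taxonomy table missing columns: {sorted(missing)}")
        t["taxid"] = t["taxid"].astype(int)
        if (t["taxid"] <= 0).any():
            raise ValidationError("non-positive taxid in taxonomy table")
        dup = _duplicates(list(t["taxid"]))
        if dup:
            raise ValidationError(f"duplicate taxid in taxonomy table: {sorted(dup)}")
        # genus may legitimately be empty for unranked lineages
        t["genus"] = t["genus"].fillna("").astype(str)

    def name_to_taxid(self) -> dict[str, int]:
        """Case-insensitive exact-match lookup (lower-cased name -> taxid)."""
        return {
            str(n).strip().lower(): int(t)
            for n, t in zip(self.table["name"], self.table["taxid"])
        }

    def taxid_to_name(self) -> dict[int, str]:
        return dict(zip(self.table["taxid"].astype(int), self.table["name"].astype(str)))

    def taxid_to_genus(self) -> dict[int, str]:
        return dict(zip(self.table["taxid"].astype(int), self.table["genus"].astype(str)))


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _read_header(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return fh.readline().rstrip("\n").split("\t")


def read_abundance(path) -> AbundanceMatrix:
    """Read a species x sample abundance TSV (first column = species id)."""
    header = _read_header(path)
    dup = _duplicates(header[1:])
    if dup:
        raise ValidationError(f"duplicate sample identifiers in header: {sorted(dup)}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                     float_precision="round_trip")
    species = [str(s) for s in df.index]
    samples = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & ~df[col].isna()
        if bad.any():
            r = int(np.where(bad)[0][0])
            raise ValidationError(
                f"non-numeric abundance {df[col].iloc[r]!r} at species "
                f"{species[r]!r}, sample {samples[j]!r}"
            )
        values[:, j] = vals.to_numpy(dtype=float)
    # all-integer species columns are taxids
    if all(s.lstrip("-").isdigit() for s in species):
        species = [int(s) for s in species]
    return AbundanceMatrix(species, samples, values, normalized=False)


def write_abundance(matrix: AbundanceMatrix, path) -> None:
    df = matrix.to_frame()
    df.index.name = "species_id"
    df.to_csv(path, sep="\t")


def map_names_to_taxids(matrix: AbundanceMatrix, taxonomy: TaxonomyTable) -> AbundanceMatrix:
    """Replace organism-name row keys by taxids via exact case-insensitive match.

    Unmatched names are dropped (with the count logged) rather than failing:
    taxonomy snapshots are never complete and the pipeline proceeds on the
    mappable fraction. Two names resolving to one taxid is a hard error because
    it would create duplicate rows.
    """
    lookup = taxonomy.name_to_taxid()
    keep_rows: list[int] = []
    taxids: list[int] = []
    dropped: list[str] = []
    for i, name in enumerate(matrix.species_ids):
        tid = lookup.get(str(name).strip().lower())
        if tid is None:
            dropped.append(str(name))
        else:
            keep_rows.append(i)
            taxids.append(tid)
    dup = _duplicates(taxids)
    if dup:
        raise ValidationError(f"multiple organism names map to the same taxid: {sorted(dup)}")
    if dropped:
        logger.warning(
            "dropped %d species with no taxonomy match (e.g. %s)",
            len(dropped), dropped[:3],
        )
    return AbundanceMatrix(
        taxids, list(matrix.sample_ids), matrix.values[keep_rows, :], matrix.normalized
    )


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMetadata(df.reset_index(drop=True))


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.table.to_csv(path, sep="\t", index=False)


def read_metabolic(path) -> MetabolicTable:
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "direction": str})
    return MetabolicTable(df.reset_index(drop=True))


def write_metabolic(table: MetabolicTable, path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "genus": str})
    return TaxonomyTable(df.reset_index(drop=True))


def write_taxonomy(table: TaxonomyTable, path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def check_samples_covered(matrix: AbundanceMatrix, metadata: SampleMetadata) -> None:
    """Every sample in the matrix must carry a metadata label."""
    orphans = [s for s in matrix.sample_ids if s not in set(metadata.sample_ids)]
    if orphans:
        raise ValidationError(f"samples without metadata labels: {orphans}")
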