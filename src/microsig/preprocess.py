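"""Low-abundance filtering, total-sum scaling and alpha-diversity reporting.

Filtering happens on raw counts and BEFORE normalization. The retention rule is
the standard compositional prevalence filter: a species is kept iff its
within-sample relative abundance reaches the threshold (default 0.1%) in at
least one sample. Two alternative readings of the cutoff are available via
``mode`` for sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from skbio.diversity.alpha import ace as _ace
from skbio.diversity.alpha import chao1 as _chao1
from skbio.diversity.alpha import enspie as _enspie
from skbio.diversity.alpha import shannon as _shannon
from skbio.diversity.alpha import simpson as _simpson

from .io import AbundanceMatrix, ValidationError

logger = logging.getLogger(__name__)


class FilterMode(str, Enum):
    """Interpretations of the relative-abundance cutoff.

    any_sample   -- keep species whose relative abundance >= threshold in >=1 sample
    grand_total  -- keep species whose share of all counts >= threshold
    prevalence   -- keep species present (count > 0) in >= threshold fraction of samples
    """

    any_sample = "any_sample"
    grand_total = "grand_total"
    prevalence = "prevalence"


@dataclass
class FilterReport:
    n_species_in: int
    n_species_out: int
    removed_ids: list
    threshold: float
    mode: FilterMode = FilterMode.any_sample

    def __post_init__(self) -> None:
        assert self.n_species_out == self.n_species_in - len(self.removed_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"removed_species_id": self.removed_ids})


def filter_species(
    matrix: AbundanceMatrix,
    threshold: float = 0.001,
    mode: FilterMode | str = FilterMode.any_sample,
) -> tuple[AbundanceMatrix, FilterReport]:
    """Drop species below the relative-abundance cutoff; preserve row order."""
    mode = FilterMode(mode)
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must lie in [0, 1], got {threshold}")
    if matrix.normalized:
        raise ValidationError("filter_species expects raw counts (normalized=False)")

    values = matrix.values
    totals = values.sum(axis=0)
    if mode is FilterMode.any_sample:
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(totals > 0, values / np.where(totals > 0, totals, 1.0), 0.0)
        keep = (rel >= threshold).any(axis=1) if threshold > 0 else np.ones(
            matrix.n_species, dtype=bool
        )
    elif mode is FilterMode.grand_total:
        grand = values.sum()
        share = values.sum(axis=1) / grand if grand > 0 else np.zeros(matrix.n_species)
        keep = share >= threshold
    else:  # prevalence
        frac_present = (values > 0).mean(axis=1)
        keep = frac_present >= threshold
    if threshold == 0:
        keep = np.ones(matrix.n_species, dtype=bool)

    if not keep.any():
        raise ValidationError(
            f"threshold {threshold} removed every species; lower the threshold"
        )
    removed = [s for s, k in zip(matrix.species_ids, keep) if not k]
    filtered = AbundanceMatrix(
        [s for s, k in zip(matrix.species_ids, keep) if k],
        list(matrix.sample_ids),
        values[keep, :],
        normalized=False,
    )
    report = FilterReport(
        n_species_in=matrix.n_species,
        n_species_out=filtered.n_species,
        removed_ids=removed,
        threshold=threshold,
        mode=mode,
    )
    logger.info(
        "filter_species: %d -> %d species (threshold=%g, mode=%s)",
        report.n_species_in, report.n_species_out, threshold, mode.value,
    )
    return filtered, report


def normalize_tss(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Total sum scaling: divide each sample by its total so columns sum to 1."""
    totals = matrix.values.sum(axis=0)
    zero = np.where(totals == 0)[0]
    if zero.size:
        bad = [matrix.sample_ids[i] for i in zero]
        raise ValidationError(f"samples with zero total abundance: {bad}")
    return AbundanceMatrix(
        list(matrix.species_ids),
        list(matrix.sample_ids),
        matrix.values / totals,
        normalized=True,
    )


def diversity(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-sample alpha diversity: Shannon (nats), Simpson (1 - sum p^2),
    inverse Simpson (1 / sum p^2), Chao1 and ACE.

    Chao1 and ACE are estimators of unseen richness built on singleton /
    doubleton (resp. <=10-count) tallies, so they require integer counts;
    fractional input raises. Chao1 uses the classic S_obs + F1^2/(2 F2) form,
    falling back to the bias-corrected form when no doubletons exist.
    """
    values = matrix.values
    if matrix.normalized or not np.allclose(values, np.rint(values)):
        raise ValidationError(
            "diversity requires integer counts: Chao1/ACE are built on "
            "singleton and doubleton tallies, which are undefined for fractions"
        )
    counts = np.rint(values).astype(np.int64)
    records = []
    for j, sample in enumerate(matrix.sample_ids):
        c = counts[:, j]
        c = c[c > 0]
        if c.size == 0:
            records.append(
                {"sample_id": sample, "shannon": 0.0, "simpson": 0.0,
                 "inv_simpson": 1.0, "chao1": 0.0, "ace": 0.0}
            )
            continue
        f2 = int((c == 2).sum())
        chao1 = float(_chao1(c, bias_corrected=(f2 == 0)))
        try:
            ace = float(_ace(c))
        except ValueError:
            # ACE is undefined when every rare taxon is a singleton; fall back
            # to bias-corrected Chao1 as the estimator's literature suggests
            ace = float(_chao1(c, bias_corrected=True))
        records.append(
            {
                "sample_id": sample,
                "shannon": float(_shannon(c, base=np.e)),
                "simpson": float(_simpson(c)),
                "inv_simpson": float(_enspie(c)),
                "chao1": chao1,
                "ace": ace,
            }
        )
    return pd.DataFrame.from_records(records)
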