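"""Signature calling: from species-to-sample attention to per-cancer species.

A species' attention profile across samples is reduced to a boolean
"high-attention" grid with a per-species z-score cutoff (mean + thres * sd,
thres defaulting to 3), and the high-attention samples of each species are
tested for enrichment within each cancer type with a hypergeometric upper-tail
test. Species with p < alpha form the cancer type's microbial signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, hypergeom
from statsmodels.stats.multitest import multipletests

from .io import SampleMetadata, TaxonomyTable, ValidationError
from .model import AttentionMatrix

logger = logging.getLogger(__name__)


def flag_high_attention(attention: AttentionMatrix | np.ndarray, thres: float = 3.0,
                        mode: str = "zscore") -> np.ndarray:
    """Boolean species x sample grid of high-attention cells.

    ``zscore``: cell (i, s) is flagged iff score[i, s] > mean_i + thres * sd_i,
    with mean/sd over that species' scores across all samples; a species with
    zero spread flags nothing.
    ``ratio``: flagged iff score[i, s] > thres * m_i, where m_i is the species'
    mean attention over the samples where it occurs (nonzero scores). Zeros are
    structural absences, so excluding them separates presence from intensity;
    with a fold-change reading of the cutoff this keeps null flag counts small
    enough that the discrete hypergeometric tail stays conservative.
    """
    scores = attention.scores if isinstance(attention, AttentionMatrix) else np.asarray(attention)
    if np.any(scores < 0):
        raise ValidationError("attention scores must be non-negative")
    if mode == "zscore":
        mean = scores.mean(axis=1, keepdims=True)
        sd = scores.std(axis=1, keepdims=True)
        flags = scores > mean + thres * sd
        flags &= sd > 0
    elif mode == "ratio":
        pos = scores > 0
        npos = pos.sum(axis=1, keepdims=True)
        mean_present = np.divide(
            scores.sum(axis=1, keepdims=True), npos,
            out=np.zeros((scores.shape[0], 1)), where=npos > 0,
        )
        flags = scores > thres * mean_present
        flags &= mean_present > 0
    else:
        raise ValidationError(f"unknown high-attention mode {mode!r}")
    return flags


def enrichment_test(flags: np.ndarray, metadata: SampleMetadata, cancer_type: str,
                    sample_ids: list[str], test: str = "hypergeometric") -> np.ndarray:
    """Per-species upper-tail p-value for enrichment of flagged samples in
    ``cancer_type``: P(X >= k) with K flagged overall, n samples in the type,
    N samples total (drawn without replacement)."""
    labels = metadata.labels
    missing = [s for s in sample_ids if s not in labels]
    if missing:
        raise ValidationError(f"samples without metadata labels: {missing[:5]}")
    in_type = np.array([labels[s] == cancer_type for s in sample_ids], dtype=bool)
    if not in_type.any():
        raise ValidationError(f"cancer type {cancer_type!r} absent from metadata")
    N = flags.shape[1]
    n = int(in_type.sum())
    K = flags.sum(axis=1)
    k = flags[:, in_type].sum(axis=1)
    if test == "hypergeometric":
        return hypergeom.sf(k - 1, N, K, n)
    if test == "binomial":
        return np.array([
            binomtest(int(ki), n, Ki / N, alternative="greater").pvalue if Ki else 1.0
            for ki, Ki in zip(k, K)
        ])
    raise ValidationError(f"unknown enrichment test {test!r}")


@dataclass
class SignatureRecord:
    cancer_type: str
    taxid: int
    species_name: str
    normalized_attention: float
    n_high: int
    n_type: int
    p_value: float
    significant: bool


SIGNATURE_COLUMNS = ["cancer_type", "taxid", "species_name", "normalized_attention",
                     "n_high", "n_type", "p_value", "significant"]


def call_signatures(
    attention: AttentionMatrix,
    metadata: SampleMetadata,
    thres: float = 3.0,
    alpha: float = 0.05,
    correction: str = "none",
    taxonomy: TaxonomyTable | None = None,
    flag_mode: str = "ratio",
    test: str = "hypergeometric",
) -> pd.DataFrame:
    """Flag, count and test every (cancer type, species) pair.

    ``normalized_attention`` is the species' mean attention within the cancer
    type, min-max scaled to [0, 1] within that type. Cancer types with fewer
    than 2 samples are excluded. Rows are sorted by cancer type, then ascending
    p-value. ``correction='bh'`` applies Benjamini-Hochberg across all pairs.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValidationError(f"alpha must lie in (0, 1], got {alpha}")
    flags = flag_high_attention(attention, thres=thres, mode=flag_mode)
    labels = metadata.labels
    names = taxonomy.taxid_to_name() if taxonomy is not None else {}
    sample_ids = attention.sample_ids

    rows = []
    for ct in sorted({labels[s] for s in sample_ids if s in labels}):
        in_type = np.array([labels.get(s) == ct for s in sample_ids], dtype=bool)
        n_type = int(in_type.sum())
        if n_type < 2:
            logger.warning("cancer type %s has %d sample(s); excluded", ct, n_type)
            continue
        pvals = enrichment_test(flags, metadata, ct, sample_ids, test=test)
        mean_in_type = attention.scores[:, in_type].mean(axis=1)
        lo, hi = mean_in_type.min(), mean_in_type.max()
        norm = (mean_in_type - lo) / (hi - lo) if hi > lo else np.zeros_like(mean_in_type)
        k_in = flags[:, in_type].sum(axis=1)
        for i, taxid in enumerate(attention.species_ids):
            rows.append((ct, int(taxid), names.get(int(taxid), str(taxid)),
                         float(norm[i]), int(k_in[i]), n_type, float(pvals[i])))

    df = pd.DataFrame(rows, columns=SIGNATURE_COLUMNS[:-1])
    if df.empty:
        df["significant"] = pd.Series(dtype=bool)
        return df
    if correction == "bh":
        _, qvals, _, _ = multipletests(df["p_value"], alpha=alpha, method="fdr_bh")
        df["p_value"] = qvals
        df["significant"] = qvals < alpha
    elif correction == "none":
        df["significant"] = df["p_value"] < alpha
    else:
        raise ValidationError(f"unknown correction {correction!r}")
    df = df.sort_values(["cancer_type", "p_value", "taxid"],
                        kind="mergesort").reset_index(drop=True)
    return df


def write_signatures(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_signatures(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"species_name": str},
                     float_precision="round_trip")
    df["significant"] = df["significant"].astype(bool)
    return df
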