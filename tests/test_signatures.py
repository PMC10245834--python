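from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from microsig import io
from microsig.model import AttentionMatrix
from microsig.signatures import (
    call_signatures,
    enrichment_test,
    flag_high_attention,
    read_signatures,
    write_signatures,
)


def _attention(scores):
    scores = np.asarray(scores, dtype=float)
    return AttentionMatrix(
        scores=scores,
        species_ids=[1000 + i for i in range(scores.shape[0])],
        sample_ids=[f"S{j}" for j in range(scores.shape[1])],
        layer=0, heads_averaged=1,
    )


def _metadata(labels):
    return io.SampleMetadata(pd.DataFrame({
        "sample_id": [f"S{j}" for j in range(len(labels))],
        "cancer_type": list(labels)}))


class TestFlagHighAttention:
    def test_constant_row_flags_nothing(self):
        flags = flag_high_attention(_attention(np.full((1, 50), 0.3)), thres=3.0)
        assert not flags.any()

    def test_extreme_outlier_flagged_alone(self):
        rng = np.random.default_rng(0)
        row = 1.0 + 0.01 * rng.standard_normal(100)
        row[17] = row.mean() + 9 * row.std()
        flags = flag_high_attention(_attention(row[None, :]), thres=3.0, mode="zscore")
        assert flags[0, 17]
        assert flags.sum() == 1

    def test_thres_zero_flags_everything_above_mean(self):
        row = np.array([[0.1, 0.2, 0.3, 0.4]])
        flags = flag_high_attention(_attention(row), thres=0.0, mode="zscore")
        assert np.array_equal(flags[0], row[0] > row.mean())

    def test_ratio_mode_uses_present_sample_mean(self):
        # zeros are absences: present-sample mean is 1.5, so 3x flags the 5.0
        row = np.array([[0.0, 0.0, 1.0, 1.0, 1.0, 5.0, 0.5, 0.5]])
        flags = flag_high_attention(_attention(row), thres=3.0, mode="ratio")
        mean_present = row[row > 0].mean()
        assert np.array_equal(flags[0], row[0] > 3 * mean_present)
        assert flags[0, 5] and flags.sum() == 1

    def test_negative_scores_rejected(self):
        with pytest.raises(io.ValidationError, match="non-negative"):
            flag_high_attention(_attention([[-0.1, 0.2]]))


class TestEnrichmentTest:
    def test_all_flags_inside_small_type(self):
        # 10 flagged samples all inside a 10-sample type among N=100
        flags = np.zeros((1, 100), dtype=bool)
        flags[0, :10] = True
        meta = _metadata(["T"] * 10 + ["U"] * 90)
        p = enrichment_test(flags, meta, "T", meta.sample_ids)
        assert p[0] == pytest.approx(1.0 / comb(100, 10), rel=1e-9)

    def test_no_flags_gives_p_one(self):
        flags = np.zeros((3, 20), dtype=bool)
        meta = _metadata(["A"] * 10 + ["B"] * 10)
        assert np.all(enrichment_test(flags, meta, "A", meta.sample_ids) == 1.0)

    @pytest.mark.parametrize("N,n,K", [(8, 3, 2), (10, 4, 5), (12, 6, 3), (12, 5, 5)])
    def test_matches_exhaustive_enumeration(self, N, n, K):
        """Tail probability equals the exact count over all C(N, n) type layouts."""
        flags = np.zeros((1, N), dtype=bool)
        flags[0, :K] = True
        meta = _metadata(["T"] * n + ["U"] * (N - n))
        k_obs = flags[0, :n].sum()
        p = enrichment_test(flags, meta, "T", meta.sample_ids)[0]
        hits = sum(
            1 for type_set in combinations(range(N), n)
            if sum(1 for s in type_set if s < K) >= k_obs
        )
        assert p == pytest.approx(hits / comb(N, n), rel=1e-12)

    def test_monotone_decreasing_in_k(self):
        from scipy.stats import hypergeom

        N, K, n = 60, 12, 15
        ps = [hypergeom.sf(k - 1, N, K, n) for k in range(0, K + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_absent_cancer_type_rejected(self):
        flags = np.zeros((1, 4), dtype=bool)
        meta = _metadata(["A", "A", "B", "B"])
        with pytest.raises(io.ValidationError, match="absent"):
            enrichment_test(flags, meta, "Z", meta.sample_ids)


class TestCallSignatures:
    def _planted_attention(self, rng, n_species=40, n_samples=120, n_types=3):
        labels = [f"T{j % n_types}" for j in range(n_samples)]
        scores = rng.lognormal(0.0, 0.3, size=(n_species, n_samples))
        # species 0 strongly elevated in type T0
        t0 = np.array([l == "T0" for l in labels])
        scores[0, t0] *= 8
        return _attention(scores), _metadata(labels)

    def test_all_equal_attention_yields_no_signatures(self):
        att = _attention(np.full((5, 40), 0.2))
        sig = call_signatures(att, _metadata(["A"] * 20 + ["B"] * 20))
        assert not sig["significant"].any()

    def test_elevated_species_called_for_its_type(self):
        att, meta = self._planted_attention(np.random.default_rng(2))
        sig = call_signatures(att, meta)
        hits = sig[sig.significant]
        assert ("T0", 1000) in {(r.cancer_type, r.taxid) for r in hits.itertuples()}

    def test_significant_set_nests_across_alpha(self):
        att, meta = self._planted_attention(np.random.default_rng(3))
        s05 = call_signatures(att, meta, alpha=0.05)
        s01 = call_signatures(att, meta, alpha=0.01)
        set05 = {(r.cancer_type, r.taxid) for r in s05[s05.significant].itertuples()}
        set01 = {(r.cancer_type, r.taxid) for r in s01[s01.significant].itertuples()}
        assert set01 <= set05

    def test_output_contract(self):
        att, meta = self._planted_attention(np.random.default_rng(4))
        sig = call_signatures(att, meta)
        # sorted by cancer type then ascending p
        assert list(sig.cancer_type) == sorted(sig.cancer_type)
        for _, grp in sig.groupby("cancer_type"):
            assert grp.p_value.is_monotonic_increasing
        assert ((sig.n_high <= sig.n_type) & (sig.p_value.between(0, 1))).all()
        assert sig.normalized_attention.between(0, 1).all()
        assert ((sig.p_value < 0.05) == sig.significant).all()

    def test_small_cancer_type_excluded(self):
        att = _attention(np.random.default_rng(5).random((4, 11)))
        meta = _metadata(["A"] * 10 + ["B"])
        sig = call_signatures(att, meta)
        assert set(sig.cancer_type) == {"A"}

    def test_bh_correction_is_more_conservative(self):
        att, meta = self._planted_attention(np.random.default_rng(6))
        raw = call_signatures(att, meta, correction="none")
        bh = call_signatures(att, meta, correction="bh")
        raw_set = {(r.cancer_type, r.taxid) for r in raw[raw.significant].itertuples()}
        bh_set = {(r.cancer_type, r.taxid) for r in bh[bh.significant].itertuples()}
        assert bh_set <= raw_set

    def test_roundtrip_through_tsv(self, tmp_path):
        att, meta = self._planted_attention(np.random.default_rng(7))
        sig = call_signatures(att, meta)
        write_signatures(sig, tmp_path / "sig.tsv")
        back = read_signatures(tmp_path / "sig.tsv")
        pd.testing.assert_frame_equal(back, sig)


def test_permutation_null_is_calibrated():
    """With labels shuffled (no real association), few species reach p < 0.05."""
    rates = []
    for seed in (11, 12, 13):
        rng = np.random.default_rng(seed)
        scores = rng.lognormal(0.0, 0.5, size=(200, 120))
        scores[rng.random(scores.shape) < 0.4] = 0.0
        labels = rng.permutation([f"T{j % 4}" for j in range(120)])
        sig = call_signatures(_attention(scores), _metadata(labels))
        rates.append(sig.groupby("taxid").significant.any().mean())
    assert all(r <= 0.10 for r in rates)
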