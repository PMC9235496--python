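"""Synthetic generators: determinism, calibration, consumer invariants."""

import numpy as np
import pytest

from targetrepo.model import LabelMatrix
from targetrepo.simulate import (SyntheticSpec, simulate_disease_signatures,
                                 simulate_inverse_recovery,
                                 simulate_masked_tensor, simulate_snp_catalog,
                                 simulate_targets_and_labels,
                                 write_synthetic_dataset)


SMALL = dict(N=40, M=6, d=30, n_clusters=2, positives_per_disease=3)


class TestDiseaseSignatures:
    def test_deterministic_and_seed_sensitive(self):
        a = simulate_disease_signatures(SyntheticSpec(**SMALL, seed=1))
        b = simulate_disease_signatures(SyntheticSpec(**SMALL, seed=1))
        c = simulate_disease_signatures(SyntheticSpec(**SMALL, seed=2))
        np.testing.assert_array_equal(a.signatures[0].values, b.signatures[0].values)
        assert not np.array_equal(a.signatures[0].values, c.signatures[0].values)

    def test_perfect_similarity_gives_identical_cluster_members(self):
        spec = SyntheticSpec(**SMALL, within_cluster_similarity=1.0, seed=0)
        sim = simulate_disease_signatures(spec)
        same = np.flatnonzero(sim.cluster_labels == 0)
        v0 = sim.signatures[same[0]].values.to_numpy()
        v1 = sim.signatures[same[1]].values.to_numpy()
        np.testing.assert_allclose(v0, v1)

    def test_every_disease_own_cluster_when_m_clusters(self):
        spec = SyntheticSpec(N=10, M=4, d=20, n_clusters=4, seed=0)
        sim = simulate_disease_signatures(spec)
        assert len(set(sim.cluster_labels.tolist())) == 4

    def test_realized_within_cluster_cosine_near_target(self):
        cosines = []
        for seed in range(10):
            spec = SyntheticSpec(N=10, M=12, d=200, n_clusters=3,
                                 within_cluster_similarity=0.8, seed=seed)
            sim = simulate_disease_signatures(spec)
            Z = np.array([s.values.to_numpy() for s in sim.signatures])
            Zn = Z / np.linalg.norm(Z, axis=1, keepdims=True)
            S = Zn @ Zn.T
            for k in range(3):
                idx = np.flatnonzero(sim.cluster_labels == k)
                iu = np.triu_indices(len(idx), 1)
                cosines.append(S[np.ix_(idx, idx)][iu].mean())
        assert abs(np.mean(cosines) - 0.8) < 0.1

    def test_infeasible_similarity_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(**SMALL, within_cluster_similarity=1.5)


class TestTargetsAndLabels:
    def test_exact_positive_quota_and_mask_consistency(self):
        spec = SyntheticSpec(**SMALL, seed=3)
        sim = simulate_disease_signatures(spec)
        X, labels, W_true = simulate_targets_and_labels(spec, sim)
        assert X.shape == (40, 30) and W_true.shape == (30, 6)
        np.testing.assert_array_equal(labels.Y.sum(axis=0), 3)
        # thinned-out positives are unobserved, never negative-labelled
        assert np.all(labels.observed[labels.Y == 1] == 1)
        assert isinstance(labels, LabelMatrix)

    def test_true_weights_follow_cluster_directions(self):
        spec = SyntheticSpec(**SMALL, seed=0)
        sim = simulate_disease_signatures(spec)
        _, _, W_true = simulate_targets_and_labels(spec, sim)
        for m in range(spec.M):
            c = sim.centers[sim.cluster_labels[m]]
            cos = W_true[:, m] @ c / np.linalg.norm(W_true[:, m])
            assert cos == pytest.approx(1.0)
            assert np.linalg.norm(W_true[:, m]) == pytest.approx(spec.signal_strength)

    def test_zero_signal_half_rate_before_thinning(self):
        spec = SyntheticSpec(N=400, M=4, d=20, n_clusters=2, signal_strength=1e-9,
                             positives_per_disease=2, seed=0)
        sim = simulate_disease_signatures(spec)
        _, labels, _ = simulate_targets_and_labels(spec, sim)
        # at zero signal half the drawn labels are positive; the unobserved
        # fraction of pairs is therefore near 1/2 minus the kept quota
        unobserved = 1.0 - labels.observed.mean()
        assert unobserved == pytest.approx(0.5 - 2 / 400, abs=0.05)

    def test_deterministic(self):
        spec = SyntheticSpec(**SMALL, seed=9)
        sim = simulate_disease_signatures(spec)
        X1, l1, _ = simulate_targets_and_labels(spec, sim)
        X2, l2, _ = simulate_targets_and_labels(spec, sim)
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(l1.Y, l2.Y)


class TestMaskedTensor:
    def test_noiseless_fully_observed_is_exact_low_rank(self):
        spec = SyntheticSpec(**SMALL, noise_sd=0.0, missing_rate=0.0,
                             cp_rank=2, seed=0)
        tensor, (A, B, C) = simulate_masked_tensor(spec, shape=(8, 6, 3))
        from targetrepo.tensor import cp_reconstruct
        np.testing.assert_allclose(tensor.T, cp_reconstruct(A, B, C))
        assert tensor.mask.all()

    def test_observed_fraction_within_binomial_bounds(self):
        spec = SyntheticSpec(**SMALL, missing_rate=0.3, seed=1)
        tensor, _ = simulate_masked_tensor(spec, shape=(20, 15, 5))
        n = tensor.mask.size
        sd = np.sqrt(0.3 * 0.7 / n)
        assert abs(tensor.mask.mean() - 0.7) < 3 * sd


class TestSnpCatalog:
    def _labels(self, spec):
        sim = simulate_disease_signatures(spec)
        _, labels, _ = simulate_targets_and_labels(spec, sim)
        return labels

    def test_true_pairs_have_strong_pvalues(self):
        spec = SyntheticSpec(**SMALL, seed=2)
        labels = self._labels(spec)
        catalog = simulate_snp_catalog(spec, labels)
        true_pairs = {(labels.target_ids[i], labels.disease_ids[j])
                      for i, j in zip(*np.nonzero(labels.Y))}
        is_true = catalog.apply(lambda r: (r["gene"], r["disease_id"]) in true_pairs,
                                axis=1)
        assert catalog.loc[is_true, "p_value"].max() < 1e-3
        assert catalog.loc[~is_true, "p_value"].min() >= 0.05

    def test_duplicate_records_exist_for_aggregation_path(self):
        spec = SyntheticSpec(**SMALL, seed=0)
        catalog = simulate_snp_catalog(spec, self._labels(spec))
        counts = catalog.groupby(["gene", "disease_id"]).size()
        assert (counts > 1).any()


class TestInverseRecovery:
    def test_construction_is_anticorrelated(self):
        aligned, truth = simulate_inverse_recovery(n_targets=5, d=100, snr=5, seed=0)
        from targetrepo.inverse import pearson_correlation
        for dis, tgt in truth.items():
            i = aligned.target_ids.index(tgt)
            j = aligned.disease_ids.index(dis)
            assert pearson_correlation(aligned.X[i], aligned.Z[j]) < -0.9


def test_write_synthetic_dataset_round_trips(tmp_path):
    from targetrepo.io import read_profiles_tsv, read_disease_signatures_tsv, \
        read_associations_tsv, aggregate_perturbation_profiles
    spec = SyntheticSpec(N=6, M=3, d=8, n_clusters=2, positives_per_disease=2,
                         seed=4)
    paths = write_synthetic_dataset(spec, tmp_path)
    profiles = read_profiles_tsv(paths["profiles"])
    assert len(profiles) == 6 * spec.n_cell_lines * spec.replicates_per_profile
    sigs = aggregate_perturbation_profiles(profiles, "knockdown")
    assert len(sigs) == 6 * spec.n_cell_lines
    assert len(read_disease_signatures_tsv(paths["diseases"])) == 3
    assoc = read_associations_tsv(paths["associations"])
    assert len(assoc) == 3 * 2  # positives_per_disease per disease
    assert paths["truth"].exists()
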