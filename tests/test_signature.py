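import numpy as np
import pandas as pd
import pytest

from svzm.preprocess import MethylationMatrix, m_to_beta
from svzm.simulate import SimulationConfig, generate_cohort, linked_validation_config, POS
from svzm.signature import (
    differential_methylation,
    stability_subset,
    rf_rank,
    select_signature,
    classify_svzm,
    discover_signature,
    gene_cpg_count,
)


def _matrix_from_m(m_array, probe_ids, sample_ids):
    return MethylationMatrix(
        pd.DataFrame(m_to_beta(m_array), index=probe_ids, columns=sample_ids)
    )


class TestDifferentialMethylation:
    def test_planted_dmp_detected(self, small_cohort, mri_labels):
        res = differential_methylation(small_cohort.methylation, mri_labels)
        planted = set(small_cohort.truth["dmp_probes"])
        hits = res.loc[res["is_dmp"]].index
        assert len(set(hits) & planted) / len(planted) > 0.8

    def test_null_type_I_rate(self):
        cfg = SimulationConfig(seed=13, n_probes=10_000, n_dmp=0, effect_delta=0.0,
                               n_pos=50, n_neg=50, n_genes=5, n_coupled=0,
                               cnv_probes_per_chrom=10)
        b = generate_cohort(cfg)
        labels = b.samples.set_index("sample_id")["mri_label"]
        res = differential_methylation(b.methylation, labels, alpha=0.001)
        frac = res["is_dmp"].mean()
        sd = np.sqrt(0.001 * 0.999 / 10_000)
        assert frac < 0.001 + 4 * sd

    def test_zero_variance_probe_flagged(self):
        rng = np.random.default_rng(0)
        m = np.vstack([np.zeros(8), rng.normal(size=8)])
        mat = _matrix_from_m(m, ["flat", "ok"], [f"s{i}" for i in range(8)])
        labels = pd.Series([POS] * 4 + ["SVZ-"] * 4, index=mat.sample_ids)
        res = differential_methylation(mat, labels)
        assert res.loc["flat", "degenerate"]
        assert res.loc["flat", "p_value"] == 1.0

    def test_small_class_errors(self, small_cohort):
        labels = pd.Series(
            [POS] + ["SVZ-"] * (small_cohort.methylation.n_samples - 1),
            index=small_cohort.methylation.sample_ids,
        )
        with pytest.raises(ValueError):
            differential_methylation(small_cohort.methylation, labels)

    def test_alpha_one_calls_every_probe(self, small_cohort, mri_labels):
        res = differential_methylation(small_cohort.methylation, mri_labels, alpha=1.01)
        assert res["is_dmp"].all()

    def test_direction_matches_mean_difference(self, small_cohort, mri_labels):
        res = differential_methylation(small_cohort.methylation, mri_labels)
        hypo = res["direction"] == "hypo_in_pos"
        assert ((res["mean_pos"] < res["mean_neg"]) == hypo).all()


class TestStabilitySubset:
    def test_pure_signal_untouched(self):
        rng = np.random.default_rng(5)
        n_pos, n_neg = 10, 12
        m = np.vstack([
            np.concatenate([rng.normal(2, 0.3, n_pos), rng.normal(-2, 0.3, n_neg)])
            for _ in range(6)
        ])
        sids = [f"s{i}" for i in range(n_pos + n_neg)]
        mat = _matrix_from_m(m, [f"p{i}" for i in range(6)], sids)
        labels = pd.Series([POS] * n_pos + ["SVZ-"] * n_neg, index=sids)
        assert stability_subset(mat, labels) == [f"p{i}" for i in range(6)]

    def test_decoys_pruned(self):
        rng = np.random.default_rng(3)
        n_pos, n_neg = 12, 12
        n_signal, n_decoy = 8, 4
        signal = [
            np.concatenate([rng.normal(1.0, 0.6, n_pos), rng.normal(-1.0, 0.6, n_neg)])
            for _ in range(n_signal)
        ]
        # decoys: stronger separation along independently scrambled partitions,
        # enough to corrupt the clustering until pruned
        decoy = []
        for _ in range(n_decoy):
            v = np.concatenate([rng.normal(3.0, 0.6, 12), rng.normal(-3.0, 0.6, 12)])
            decoy.append(v[rng.permutation(n_pos + n_neg)])
        m = np.vstack(signal + decoy)
        pids = [f"sig{i:02d}" for i in range(n_signal)] + [f"dec{i}" for i in range(n_decoy)]
        sids = [f"s{i}" for i in range(n_pos + n_neg)]
        mat = _matrix_from_m(m, pids, sids)
        labels = pd.Series([POS] * n_pos + ["SVZ-"] * n_neg, index=sids)
        kept = stability_subset(mat, labels)
        removed_decoys = sum(1 for p in pids if p.startswith("dec") and p not in kept)
        assert removed_decoys >= n_decoy / 2

    def test_single_probe_returned_unchanged(self):
        mat = _matrix_from_m(np.zeros((1, 4)), ["only"], list("abcd"))
        labels = pd.Series([POS, POS, "SVZ-", "SVZ-"], index=list("abcd"))
        assert stability_subset(mat, labels) == ["only"]


class TestRfRank:
    def test_informative_probe_ranked_first(self):
        rng = np.random.default_rng(4)
        n = 30
        noise = rng.normal(size=(10, n))
        info = np.concatenate([rng.normal(2, 0.5, 15), rng.normal(-2, 0.5, 15)])
        m = np.vstack([noise[:5], info, noise[5:]])
        pids = [f"n{i}" for i in range(5)] + ["info"] + [f"m{i}" for i in range(5)]
        sids = [f"s{i}" for i in range(n)]
        mat = _matrix_from_m(m, pids, sids)
        labels = pd.Series([POS] * 15 + ["SVZ-"] * 15, index=sids)
        ranked = rf_rank(mat, labels, n_trees=500, seed=0)
        assert ranked.index[0] == "info"

    def test_deterministic_given_seed(self, small_cohort, mri_labels):
        sub = small_cohort.methylation.subset_probes(
            small_cohort.truth["dmp_probes"][:20]
        )
        r1 = rf_rank(sub, mri_labels, n_trees=100, seed=7)
        r2 = rf_rank(sub, mri_labels, n_trees=100, seed=7)
        assert list(r1.index) == list(r2.index)

    def test_constant_probes_tie_broken_by_id(self):
        mat = _matrix_from_m(np.zeros((4, 10)), ["d", "b", "a", "c"],
                             [f"s{i}" for i in range(10)])
        labels = pd.Series([POS] * 5 + ["SVZ-"] * 5, index=mat.sample_ids)
        ranked = rf_rank(mat, labels, n_trees=50, seed=0)
        assert list(ranked.index) == ["a", "b", "c", "d"]
        assert (ranked.values <= 1e-9).all()

    def test_zero_trees_errors(self, small_cohort, mri_labels):
        with pytest.raises(ValueError):
            rf_rank(small_cohort.methylation, mri_labels, n_trees=0)


@pytest.fixture(scope="module")
def discovered(small_cohort, mri_labels):
    return discover_signature(small_cohort.methylation, mri_labels, seed=42)


class TestSelectAndClassify:
    def test_signature_length_default_15(self, discovered):
        sig, _, _ = discovered
        assert len(sig.signature_probes) == 15
        assert len(set(sig.signature_probes)) == 15

    def test_centroid_mode_reproduces_training_clusters(self, small_cohort, discovered):
        sig, _, _ = discovered
        by_cluster = classify_svzm(small_cohort.methylation, sig, mode="train_clustering")
        by_centroid = classify_svzm(small_cohort.methylation, sig, mode="centroid")
        assert (by_cluster == by_centroid).all()

    def test_validation_recovery_at_strong_effect(self, small_cohort, discovered):
        sig, _, _ = discovered
        vcfg = linked_validation_config(small_cohort.truth, seed=101, n_pos=50, n_neg=50)
        bv = generate_cohort(vcfg)
        pred = classify_svzm(bv.methylation, sig, mode="validation_clustering")
        truth = pd.Series(bv.truth["labels"])
        assert (pred == truth.loc[pred.index]).mean() >= 0.9

    def test_identical_samples_get_identical_labels(self, small_cohort, discovered):
        sig, _, _ = discovered
        m = small_cohort.methylation
        dup = m.beta.copy()
        dup["S900"] = dup[m.sample_ids[0]]
        mat = MethylationMatrix(dup, m.annotation)
        pred = classify_svzm(mat, sig, mode="centroid")
        assert pred["S900"] == pred[m.sample_ids[0]]

    def test_invariant_under_sample_permutation(self, small_cohort, discovered):
        sig, _, _ = discovered
        m = small_cohort.methylation
        perm = list(m.sample_ids)[::-1]
        a = classify_svzm(m, sig, mode="validation_clustering")
        b = classify_svzm(m.subset_samples(perm), sig, mode="validation_clustering")
        assert (a.loc[perm] == b).all()

    def test_missing_probe_error_lists_ids(self, small_cohort, discovered):
        sig, _, _ = discovered
        keep = [p for p in small_cohort.methylation.probe_ids
                if p != sig.signature_probes[0]]
        sub = small_cohort.methylation.subset_probes(keep)
        with pytest.raises(KeyError, match=sig.signature_probes[0]):
            classify_svzm(sub, sig)

    def test_k_equal_ranking_length_keeps_all(self, small_cohort, mri_labels):
        probes = small_cohort.truth["dmp_probes"][:10]
        sub = small_cohort.methylation.subset_probes(probes)
        ranked = rf_rank(sub, mri_labels, n_trees=100, seed=1)
        sig = select_signature(ranked, sub, mri_labels, k=10)
        assert set(sig.signature_probes) == set(probes)

    def test_gene_cpg_count(self, small_cohort, discovered):
        sig, _, _ = discovered
        ann = small_cohort.methylation.annotation.copy()
        for p in sig.signature_probes[:5]:
            ann.loc[p, "gene"] = "LRBA_LIKE"
        counts = gene_cpg_count(sig, ann)
        assert counts["LRBA_LIKE"] >= 5

    def test_signature_json_roundtrip(self, tmp_path, discovered):
        from svzm.signature import SignatureModel
        sig, _, _ = discovered
        path = tmp_path / "sig.json"
        sig.to_json(path)
        back = SignatureModel.from_json(path)
        assert back.signature_probes == sig.signature_probes
        assert back.centroids.keys() == sig.centroids.keys()
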