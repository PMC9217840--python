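import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svzm.integration import (
    log_cpm,
    sam_test,
    consensus_dmp,
    differential_expression,
    meth_expr_correlation,
    gene_cpg_rank,
    co_alteration_intersect,
    negbin_expression_test,
    pathway_activity,
)
from svzm.simulate import SimulationConfig, generate_cohort, linked_validation_config, POS, NEG


def _labels(n_pos, n_neg, prefix="s"):
    idx = [f"{prefix}{i}" for i in range(n_pos + n_neg)]
    return pd.Series([POS] * n_pos + [NEG] * n_neg, index=idx)


@pytest.fixture(scope="module")
def sam_cohort():
    cfg = SimulationConfig(seed=55, n_probes=2000, n_dmp=100, n_genes=20,
                           n_coupled=10, cnv_probes_per_chrom=10)
    return generate_cohort(cfg)


class TestSam:
    def test_planted_effect_power(self, sam_cohort):
        labels = sam_cohort.samples.set_index("sample_id")["mri_label"]
        res = sam_test(sam_cohort.methylation.m_values(), labels, n_perm=100, seed=1)
        planted = set(sam_cohort.truth["dmp_probes"])
        recovered = sum(p in planted for p in res.called)
        assert recovered >= 70
        assert res.fdr <= 0.05

    def test_null_data_calls_almost_nothing(self):
        cfg = SimulationConfig(seed=66, n_probes=2000, n_dmp=0, effect_delta=0.0,
                               n_genes=5, n_coupled=0, cnv_probes_per_chrom=10)
        b = generate_cohort(cfg)
        labels = b.samples.set_index("sample_id")["mri_label"]
        res = sam_test(b.methylation.m_values(), labels, n_perm=100, seed=2)
        assert len(res.called) <= 2 * 0.05 * 2000

    def test_called_set_monotone_in_delta(self, sam_cohort):
        # raising the target FDR can only enlarge (or keep) the called set
        labels = sam_cohort.samples.set_index("sample_id")["mri_label"]
        mv = sam_cohort.methylation.m_values()
        strict = sam_test(mv, labels, n_perm=50, fdr_target=0.01, seed=3)
        loose = sam_test(mv, labels, n_perm=50, fdr_target=0.20, seed=3)
        assert set(strict.called) <= set(loose.called)

    def test_small_class_rejected(self, sam_cohort):
        mv = sam_cohort.methylation.m_values()
        labels = pd.Series([POS] * 2 + [NEG] * (mv.shape[1] - 2), index=mv.columns)
        with pytest.raises(ValueError):
            sam_test(mv, labels)

    def test_direction_tracks_sign_of_d(self, sam_cohort):
        labels = sam_cohort.samples.set_index("sample_id")["mri_label"]
        res = sam_test(sam_cohort.methylation.m_values(), labels, n_perm=50, seed=4)
        assert ((res.d < 0) == (res.direction == "hypo_in_pos")).all()


class TestConsensusDmp:
    def test_identical_inputs_idempotent(self, sam_cohort):
        labels = sam_cohort.samples.set_index("sample_id")["mri_label"]
        res = sam_test(sam_cohort.methylation.m_values(), labels, n_perm=50, seed=5)
        cons = consensus_dmp(res, res)
        assert set(cons.index) == set(res.called)

    def test_two_cohort_recovery(self, sam_cohort):
        labels_a = sam_cohort.samples.set_index("sample_id")["mri_label"]
        res_a = sam_test(sam_cohort.methylation.m_values(), labels_a, n_perm=100, seed=6)
        vcfg = linked_validation_config(sam_cohort.truth, seed=77, n_pos=40, n_neg=40)
        bv = generate_cohort(vcfg)
        labels_b = bv.samples.set_index("sample_id")["mri_label"]
        res_b = sam_test(bv.methylation.m_values(), labels_b, n_perm=100, seed=7)
        cons = consensus_dmp(res_a, res_b)
        planted = set(sam_cohort.truth["dmp_probes"])
        n_planted = sum(p in planted for p in cons.index)
        n_unplanted = len(cons) - n_planted
        assert n_planted >= 60
        assert n_unplanted <= 5

    def test_consensus_is_subset_of_both(self, sam_cohort):
        labels = sam_cohort.samples.set_index("sample_id")["mri_label"]
        mv = sam_cohort.methylation.m_values()
        a = sam_test(mv, labels, n_perm=50, seed=8)
        b = sam_test(mv, labels, n_perm=50, seed=9)
        cons = consensus_dmp(a, b)
        assert set(cons.index) <= set(a.called) and set(cons.index) <= set(b.called)

    def test_hypomethylation_pattern_reproduced(self, sam_cohort):
        # frac_hypo=0.98 planted: >90% of consensus CpGs hypomethylated in SVZM+
        labels = sam_cohort.samples.set_index("sample_id")["mri_label"]
        res = sam_test(sam_cohort.methylation.m_values(), labels, n_perm=100, seed=10)
        cons = consensus_dmp(res, res)
        frac_hypo = (cons["direction"] == "hypo_in_pos").mean()
        assert frac_hypo > 0.9


class TestDifferentialExpression:
    def test_planted_fold_change_power(self):
        rng = np.random.default_rng(31)
        n = 100
        labels = _labels(50, 50)
        counts = pd.DataFrame(
            rng.negative_binomial(10, 10 / (10 + 200), size=(80, n)),
            index=[f"g{i}" for i in range(80)], columns=labels.index,
        )
        # plant 2-fold up in positive class for 20 genes
        planted = [f"g{i}" for i in range(20)]
        counts.loc[planted, labels == POS] = rng.negative_binomial(
            10, 10 / (10 + 400), size=(20, 50))
        res = differential_expression(counts, labels)
        hits = res["deg"].index
        assert sum(g in set(hits) for g in planted) >= 16

    def test_permuted_labels_near_nominal(self):
        rng = np.random.default_rng(37)
        labels = _labels(30, 30)
        counts = pd.DataFrame(
            rng.negative_binomial(10, 10 / (10 + 200), size=(400, 60)),
            index=[f"g{i}" for i in range(400)], columns=labels.index,
        )
        res = differential_expression(counts, labels)
        raw_pos = (res["table"]["p"] < 0.05).mean()
        assert raw_pos < 0.10

    def test_empty_deg_set_handled(self):
        labels = _labels(3, 3)
        counts = pd.DataFrame(100, index=["g1", "g2"], columns=labels.index)
        res = differential_expression(counts, labels)
        assert len(res["deg"]) == 0
        assert np.isnan(res["mean_deg_contrast_pos_minus_neg"])
        assert res["table"]["constant"].all()


class TestMethExprCorrelation:
    def test_perfect_anticorrelation(self):
        labels_idx = [f"s{i}" for i in range(6)]
        counts = pd.DataFrame(
            [[600, 500, 400, 300, 200, 100], [100, 200, 300, 400, 500, 600]],
            index=["gA", "gB"], columns=labels_idx,
        )
        # M-values set to exactly minus the transformed expression
        m = pd.DataFrame([-log_cpm(counts).loc["gA"].values], index=["cg1"],
                         columns=labels_idx)
        gmap = pd.DataFrame({"cpg_id": ["cg1"], "gene": ["gA"]})
        res = meth_expr_correlation(m, counts, gmap)
        assert res.loc[0, "r"] == pytest.approx(-1.0, abs=1e-12)

    def test_null_pairs_mostly_small_r(self):
        rng = np.random.default_rng(41)
        n = 47
        sids = [f"s{i}" for i in range(n)]
        m = pd.DataFrame(rng.normal(size=(40, n)),
                         index=[f"cg{i}" for i in range(40)], columns=sids)
        counts = pd.DataFrame(rng.poisson(200, size=(40, n)),
                              index=[f"g{i}" for i in range(40)], columns=sids)
        gmap = pd.DataFrame({"cpg_id": [f"cg{i}" for i in range(40)],
                             "gene": [f"g{i}" for i in range(40)]})
        res = meth_expr_correlation(m, counts, gmap)
        # |r| < 0.29 is the ~95% null band at n=47
        assert (res["r"].abs() < 0.29).mean() >= 0.85

    def test_coupled_gene_recovery(self):
        cfg = SimulationConfig(seed=43, n_probes=300, n_dmp=20, n_genes=100,
                               n_coupled=10, coupling_rho=-0.76,
                               n_pos=24, n_neg=23, cnv_probes_per_chrom=10)
        b = generate_cohort(cfg)
        res = meth_expr_correlation(
            b.methylation.m_values(), b.expression, b.gene_cpg_map)
        coupled = res[res["gene"].isin(b.truth["coupled_genes"])]
        assert -0.9 < coupled["r"].mean() < -0.6

    def test_zero_variance_marked_undefined(self):
        sids = [f"s{i}" for i in range(5)]
        m = pd.DataFrame([[1.0] * 5], index=["cg1"], columns=sids)
        counts = pd.DataFrame([[100, 120, 90, 110, 105]], index=["gA"], columns=sids)
        gmap = pd.DataFrame({"cpg_id": ["cg1"], "gene": ["gA"]})
        res = meth_expr_correlation(m, counts, gmap)
        assert np.isnan(res.loc[0, "r"])


class TestGeneCpgRank:
    def _ann(self, mapping):
        return pd.DataFrame({"gene": pd.Series(mapping)})

    def test_top_gene_by_count(self):
        ann = self._ann({f"cg{i}": "MAB21L2_LIKE" for i in range(9)})
        rank = gene_cpg_rank([f"cg{i}" for i in range(9)], ann)
        assert rank.index[0] == "MAB21L2_LIKE"
        assert rank.iloc[0] == 9

    def test_nested_pair_counted_for_both(self):
        ann = self._ann({"cg1": "GENEA;GENEB"})
        rank = gene_cpg_rank(["cg1"], ann)
        assert rank["GENEA"] == 1 and rank["GENEB"] == 1

    def test_unannotated_bucket(self):
        ann = self._ann({"cg1": ""})
        rank = gene_cpg_rank(["cg1", "cg_missing"], ann)
        assert rank["unannotated"] == 2

    def test_empty_consensus(self):
        assert len(gene_cpg_rank([], self._ann({"cg1": "G"}))) == 0


class TestCoAlteration:
    def test_inverse_pair_and_symmetry(self):
        meth = {"A": "hypo", "B": "hyper"}
        expr = {"A": "up", "C": "down"}
        cnv = {"A": "loss", "C": "loss"}
        res = co_alteration_intersect(meth, expr, cnv)
        me = res["MxE"]
        assert list(me["gene"]) == ["A"]
        assert me.loc[0, "category"] == "hypo_M/up_E"
        assert list(res["ExCN"]["gene"]) == ["A", "C"]
        assert list(res["MxCN"]["gene"]) == ["A"]

    def test_disjoint_sets_empty(self):
        res = co_alteration_intersect({"A": "hypo"}, {"B": "up"}, {"C": "gain"})
        assert all(len(v) == 0 for v in res.values())


class TestNegbin:
    def test_planted_reduction_detected(self):
        rng = np.random.default_rng(51)
        labels = _labels(24, 23)
        # stable background keeps library totals class-independent
        background = pd.DataFrame(
            rng.negative_binomial(10, 10 / (10 + 300), size=(50, 47)),
            index=[f"bg{i}" for i in range(50)], columns=labels.index,
        )
        mu = np.where(labels.values == POS, 100, 200).astype(float)
        tested = pd.DataFrame(
            [rng.negative_binomial(10, 10 / (10 + mu)) for _ in range(5)],
            index=[f"g{i}" for i in range(5)], columns=labels.index,
        )
        counts = pd.concat([background, tested])
        res = negbin_expression_test(counts, labels, genes=list(tested.index))
        assert (res["one_sided_p"] < 0.05).mean() >= 0.8

    def test_null_one_sided_p_centered(self):
        rng = np.random.default_rng(53)
        labels = _labels(24, 23)
        counts = pd.DataFrame(
            rng.negative_binomial(10, 10 / (10 + 200), size=(200, 47)),
            index=[f"g{i}" for i in range(200)], columns=labels.index,
        )
        res = negbin_expression_test(counts, labels)
        assert abs(res["one_sided_p"].mean() - 0.5) < 0.1

    def test_offset_invariance(self):
        rng = np.random.default_rng(57)
        labels = _labels(20, 20)
        counts = pd.DataFrame(
            rng.negative_binomial(10, 10 / (10 + 150), size=(3, 40)),
            index=["g0", "g1", "g2"], columns=labels.index,
        )
        res1 = negbin_expression_test(counts, labels, genes=["g0"])
        res2 = negbin_expression_test(counts * 2, labels, genes=["g0"])
        # doubling every count doubles the offset; the class coefficient is
        # unchanged up to estimation noise of the dispersion
        assert res1.loc["g0", "coef"] == pytest.approx(res2.loc["g0", "coef"], abs=0.05)

    def test_all_zero_gene_skipped(self):
        labels = _labels(4, 4)
        counts = pd.DataFrame([[0] * 8, [100] * 8], index=["dead", "ok"],
                              columns=labels.index)
        res = negbin_expression_test(counts, labels)
        assert "dead" not in res.index


class TestPathwayActivity:
    def _counts(self, rng, labels, n_genes=30):
        return pd.DataFrame(
            rng.negative_binomial(10, 10 / (10 + 200), size=(n_genes, len(labels))),
            index=[f"g{i}" for i in range(n_genes)], columns=labels.index,
        )

    def test_zero_weights_zero_scores(self):
        rng = np.random.default_rng(61)
        labels = _labels(10, 10)
        counts = self._counts(rng, labels)
        w = pd.DataFrame({"pathway": ["P"] * 3, "gene": ["g0", "g1", "g2"],
                          "weight": [0.0, 0.0, 0.0]})
        res = pathway_activity(counts, w, labels)
        assert np.allclose(res.loc["P", "scores"].values, 0.0)
        assert np.isnan(res.loc["P", "p"])

    def test_single_gene_weight_one_is_zscore(self):
        rng = np.random.default_rng(63)
        labels = _labels(10, 10)
        counts = self._counts(rng, labels)
        w = pd.DataFrame({"pathway": ["P"], "gene": ["g5"], "weight": [1.0]})
        res = pathway_activity(counts, w, labels)
        vals = log_cpm(counts).loc["g5"]
        z = (vals - vals.mean()) / vals.std(ddof=1)
        assert np.allclose(res.loc["P", "scores"].values, z.values)

    def test_planted_coherent_upregulation_detected(self):
        rng = np.random.default_rng(67)
        labels = _labels(25, 25)
        counts = self._counts(rng, labels)
        members = [f"g{i}" for i in range(8)]
        boost = rng.negative_binomial(10, 10 / (10 + 150), size=(8, 25))
        counts.loc[members, labels == POS] = (
            counts.loc[members, labels == POS].values + boost)
        w = pd.DataFrame({"pathway": ["P"] * 8, "gene": members, "weight": [1.0] * 8})
        res = pathway_activity(counts, w, labels)
        assert res.loc["P", "p"] < 0.05
        assert res.loc["P", "mean_pos"] > res.loc["P", "mean_neg"]

    def test_no_overlap_skipped(self):
        rng = np.random.default_rng(69)
        labels = _labels(5, 5)
        counts = self._counts(rng, labels)
        w = pd.DataFrame({"pathway": ["P"], "gene": ["absent"], "weight": [1.0]})
        res = pathway_activity(counts, w, labels)
        assert len(res) == 0
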