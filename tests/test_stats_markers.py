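"""Gender-balanced testing procedure, ROC-AUC, marker panels, and PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hpglyco import (
    CohortConfig,
    PatientRecord,
    StatsConfig,
    combine_markers,
    differential_tests,
    gender_balanced_subsets,
    generate_cohort,
    pca_scores,
    roc_auc,
)
from hpglyco.synthetic import CIRRHOSIS, HCC


def _patients(spec):
    """spec: list of (group, gender, n) triples."""
    out = []
    i = 0
    for group, gender, n in spec:
        for _ in range(n):
            i += 1
            out.append(
                PatientRecord(
                    patient_id=f"P{i:02d}",
                    group=group,
                    gender=gender,
                    afp_ng_ml=5.0,
                    tnm_stage="NA" if group == CIRRHOSIS else "I",
                )
            )
    return out


class TestGenderBalancedSubsets:
    def test_study_cohort_balances_to_3m_8f_per_arm(self):
        patients = _patients([(CIRRHOSIS, "M", 3), (CIRRHOSIS, "F", 12), (HCC, "M", 7), (HCC, "F", 8)])
        subsets = gender_balanced_subsets(patients, StatsConfig())
        by_id = {p.patient_id: p for p in patients}
        for subset in subsets:
            assert len(subset) == 22
            for group in (CIRRHOSIS, HCC):
                males = sum(1 for pid in subset if by_id[pid].group == group and by_id[pid].gender == "M")
                females = sum(1 for pid in subset if by_id[pid].group == group and by_id[pid].gender == "F")
                assert (males, females) == (3, 8)

    def test_balanced_cohort_passes_through_identically(self):
        patients = _patients([(CIRRHOSIS, "M", 4), (CIRRHOSIS, "F", 6), (HCC, "M", 4), (HCC, "F", 6)])
        subsets = gender_balanced_subsets(patients, StatsConfig())
        assert all(subset == sorted(p.patient_id for p in patients) for subset in subsets)

    def test_three_seeded_subsets_differ(self):
        patients = _patients([(CIRRHOSIS, "M", 3), (CIRRHOSIS, "F", 12), (HCC, "M", 7), (HCC, "F", 8)])
        subsets = gender_balanced_subsets(patients, StatsConfig(subset_seed=1))
        assert len({tuple(s) for s in subsets}) == 3

    def test_missing_gender_raises_actionable_error(self):
        patients = _patients([(CIRRHOSIS, "F", 5), (HCC, "M", 3), (HCC, "F", 3)])
        with pytest.raises(ValueError, match="gender ratio"):
            gender_balanced_subsets(patients, StatsConfig())


class TestDifferentialTests:
    def _frame(self, rng, n=22, k=10, shift=0.0):
        ids = [f"P{i:02d}" for i in range(n)]
        groups = pd.Series([CIRRHOSIS] * (n // 2) + [HCC] * (n - n // 2), index=ids)
        data = pd.DataFrame(rng.normal(0, 1, (n, k)), index=ids, columns=[f"f{j}" for j in range(k)])
        data.loc[groups == HCC] += shift
        return data, groups

    def test_identical_group_values_not_significant(self):
        ids = [f"P{i}" for i in range(8)]
        groups = pd.Series([CIRRHOSIS] * 4 + [HCC] * 4, index=ids)
        rel = pd.DataFrame({"f": [0.3] * 8}, index=ids)
        res = differential_tests(rel, groups, [ids] * 3, StatsConfig())
        assert res[0].t_p == (1.0, 1.0, 1.0)
        assert not res[0].significant and res[0].flagged

    def test_null_features_false_positive_rate_below_alpha(self):
        rng = np.random.default_rng(2024)
        data, groups = self._frame(rng, n=22, k=200, shift=0.0)
        subsets = [list(data.index)] * 3
        res = differential_tests(data, groups, subsets, StatsConfig())
        raw_fp = np.mean([r.t_p[0] < 0.05 for r in res])
        assert 0.005 <= raw_fp <= 0.12  # raw tests reject near alpha
        assert np.mean([r.significant for r in res]) <= 0.05

    def test_strong_shift_is_detected(self):
        rng = np.random.default_rng(7)
        data, groups = self._frame(rng, n=22, k=5, shift=2.5)
        res = differential_tests(data, groups, [list(data.index)] * 3, StatsConfig())
        assert all(r.significant for r in res)

    def test_bonferroni_monotone_and_capped(self):
        rng = np.random.default_rng(11)
        data, groups = self._frame(rng, n=10, k=20)
        res = differential_tests(data, groups, [list(data.index)] * 3, StatsConfig())
        for r in res:
            for raw, corr in zip(r.t_p, r.corrected_p):
                assert corr >= raw and corr <= 1.0


class TestRocAuc:
    def test_exhaustive_pair_counting_example(self):
        # pairs: (0.9,0.5)+ (0.9,0.1)+ (0.4,0.5)- (0.4,0.1)+ -> 3/4
        r = roc_auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.75)

    def test_perfect_separation_gives_one(self):
        r = roc_auc([3, 4, 5, 1, 2], [1, 1, 1, 0, 0])
        assert r.auc == 1.0 and r.ci_high == 1.0

    def test_all_ties_give_half(self):
        r = roc_auc([2.0] * 6, [1, 1, 1, 0, 0, 0])
        assert r.auc == pytest.approx(0.5)

    @given(st.lists(st.integers(-50, 50), min_size=4, max_size=20, unique=True))
    def test_monotone_transform_invariance_and_flip_symmetry(self, scores):
        scores = [s / 10 for s in scores]
        labels = [i % 2 for i in range(len(scores))]
        a = roc_auc(scores, labels, auto_flip=False).auc
        b = roc_auc(np.exp(scores), labels, auto_flip=False).auc
        assert a == pytest.approx(b)
        assert roc_auc([-s for s in scores], labels, auto_flip=False).auc == pytest.approx(1 - a)

    def test_auto_flip_reports_flipped_marker(self):
        r = roc_auc([1, 2, 8, 9], [1, 1, 0, 0])
        assert r.flipped and r.auc == 1.0

    def test_delong_ci_matches_pair_count_oracle_on_random_data(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(1, 1, 15)
        neg = rng.normal(0, 1, 15)
        r = roc_auc(np.r_[pos, neg], [1] * 15 + [0] * 15, auto_flip=False)
        brute = np.mean([(p > q) + 0.5 * (p == q) for p, q in itertools.product(pos, neg)])
        assert r.auc == pytest.approx(brute)
        assert r.ci_low <= r.auc <= r.ci_high

    def test_bootstrap_ci_available(self):
        rng = np.random.default_rng(4)
        scores = np.r_[rng.normal(1, 1, 12), rng.normal(0, 1, 12)]
        cfg = StatsConfig(roc_ci_method="bootstrap", n_bootstrap=200)
        r = roc_auc(scores, [1] * 12 + [0] * 12, cfg, auto_flip=False)
        assert 0.0 <= r.ci_low <= r.auc <= r.ci_high <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestCombineMarkers:
    def test_single_feature_panel_equals_marker_auc(self):
        rng = np.random.default_rng(5)
        labels = np.array([0] * 12 + [1] * 12)
        x = rng.normal(0, 1, 24) + labels
        features = pd.DataFrame({"m": x})
        _, combined = combine_markers(features, labels)
        single = roc_auc(x, labels, auto_flip=False)
        assert combined.auc == pytest.approx(single.auc)

    def test_added_noise_feature_changes_auc_little(self):
        rng = np.random.default_rng(6)
        deltas = []
        for _ in range(20):
            labels = np.array([0] * 12 + [1] * 12)
            signal = rng.normal(0, 1, 24) + 1.5 * labels
            base = pd.DataFrame({"m": signal})
            noisy = base.assign(junk=rng.normal(0, 1, 24))
            _, a = combine_markers(base, labels)
            _, b = combine_markers(noisy, labels)
            deltas.append(abs(b.auc - a.auc))
        assert np.median(deltas) < 0.05

    def test_separable_panel_falls_back_to_ridge(self):
        labels = np.array([0] * 6 + [1] * 6)
        features = pd.DataFrame({"m": labels.astype(float)})
        _, r = combine_markers(features, labels)
        assert r.auc == 1.0


class TestPca:
    def test_single_axis_variance_loads_on_pc1(self):
        rng = np.random.default_rng(8)
        t = rng.normal(0, 2, 20)
        rel = pd.DataFrame({"a": t, "b": 0.5 * t, "c": np.full(20, 0.1)})
        _, _, ev = pca_scores(rel)
        assert ev[0] > 0.999

    def test_scores_covariance_is_diagonal(self):
        rng = np.random.default_rng(9)
        rel = pd.DataFrame(rng.normal(0, 1, (25, 6)))
        scores, loadings, _ = pca_scores(rel)
        cov = np.cov(scores.to_numpy().T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-10
        assert np.allclose(loadings.T @ loadings, np.eye(loadings.shape[1]), atol=1e-10)

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(10)
        rel = pd.DataFrame(rng.normal(0, 1, (15, 5)))
        _, _, ev = pca_scores(rel)
        assert all(a >= b for a, b in zip(ev, ev[1:]))

    def test_group_separation_at_asn207_not_asn184(self, targets):
        from sklearn.metrics import silhouette_score

        hits_207, sils_184 = 0, []
        for seed in range(10):
            ds = generate_cohort(CohortConfig(seed=300 + seed), targets)
            rel = ds.true_abundances
            labels = (pd.Series(ds.groups).loc[rel.index] == HCC).to_numpy()
            for site, bucket in (("Asn207", None), ("Asn184", sils_184)):
                cols = [c for c in rel.columns if c.startswith(site)]
                scores, _, _ = pca_scores(rel[cols])
                sil = silhouette_score(scores.iloc[:, :2], labels)
                if site == "Asn207":
                    hits_207 += sil > 0
                else:
                    bucket.append(sil)
        assert hits_207 >= 8
        assert np.median(sils_184) < 0.1
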