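"""Group-difference tests, Tukey HSD and multiple-testing correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nrrnet import (
    FeatureTable,
    SampleMetadata,
    ValidationError,
    adjust_pvalues,
    confounder_scan,
    per_feature_group_test,
    tukey_hsd,
)


class TestTukey:
    def test_identical_groups_p_one(self):
        p = tukey_hsd([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert p[0, 1] == pytest.approx(1.0)

    def test_two_group_hand_example(self):
        # pooled t = -1.2247, df = 4
        p = tukey_hsd([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
        t_ref = stats.ttest_ind([1, 2, 3], [2, 3, 4])
        assert t_ref.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert p[0, 1] == pytest.approx(t_ref.pvalue, abs=1e-8)

    def test_k2_equals_pooled_t_over_random_data(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(100):
            a = rng.standard_normal(rng.integers(3, 12))
            b = rng.standard_normal(rng.integers(3, 12)) + rng.normal()
            p = tukey_hsd([a, b])[0, 1]
            worst = max(worst, abs(p - stats.ttest_ind(a, b).pvalue))
        assert worst < 1e-8

    def test_k3_matches_scipy_reference(self):
        rng = np.random.default_rng(5)
        groups = [rng.standard_normal(8) + d for d in (0.0, 0.5, 1.5)]
        ours = tukey_hsd(groups)
        ref = stats.tukey_hsd(*groups).pvalue
        np.testing.assert_allclose(ours, ref, atol=1e-6)

    def test_zero_variance_unequal_means(self, caplog):
        with caplog.at_level("WARNING"):
            p = tukey_hsd([[1.0, 1.0], [2.0, 2.0]])
        assert p[0, 1] == 0.0
        assert "zero within-group variance" in caplog.text

    def test_needs_two_values_per_group(self):
        with pytest.raises(ValidationError):
            tukey_hsd([[1.0], [2.0, 3.0]])


class TestAdjust:
    def test_single_p_unchanged(self):
        for method in ("bh", "bonferroni"):
            assert adjust_pvalues([0.03], method)[0] == pytest.approx(0.03)

    def test_bonferroni_hand_example(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.04], "bonferroni"), [0.02, 0.08])

    def test_bh_step_up_hand_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh"), [0.04, 0.04, 0.04, 0.04]
        )

    def test_order_restored(self):
        p = [0.04, 0.01, 0.03, 0.02]
        adj = adjust_pvalues(p, "bonferroni")
        np.testing.assert_allclose(adj, [0.16, 0.04, 0.12, 0.08])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_pvalues([0.5, 1.2], "bh")

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_bonferroni_dominates_bh_and_monotone(self, p):
        bh = adjust_pvalues(p, "bh")
        bonf = adjust_pvalues(p, "bonferroni")
        assert (bonf >= bh - 1e-12).all()
        assert (bh <= 1).all() and (bonf <= 1).all()
        # pointwise larger inputs never yield smaller adjusted values
        bumped = np.minimum(1.0, np.asarray(p) + 0.05)
        assert (adjust_pvalues(bumped, "bonferroni") >= bonf - 1e-12).all()


def _cohort(rng, n_pairs=20, n_features=4, shift=0.0):
    meta, sids = [], []
    for k in range(n_pairs):
        meta.append(SampleMetadata(f"pt{k}", "patient", f"pr{k}", k % 2 == 0))
        meta.append(SampleMetadata(f"ct{k}", "control", f"pr{k}", False))
        sids += [f"pt{k}", f"ct{k}"]
    log_vals = rng.normal(5.0, 1.0, size=(2 * n_pairs, n_features))
    log_vals[0::2, 0] += shift  # patients are even rows
    return FeatureTable(sids, [f"f{j}" for j in range(n_features)], 2.0 ** log_vals), meta


class TestGroupTest:
    def test_identical_groups_all_p_one(self):
        meta = [
            SampleMetadata("pt0", "patient", "pr0"),
            SampleMetadata("ct0", "control", "pr0"),
            SampleMetadata("pt1", "patient", "pr1"),
            SampleMetadata("ct1", "control", "pr1"),
        ]
        vals = np.array([[1.0, 4.0], [1.0, 4.0], [2.0, 8.0], [2.0, 8.0]])
        table = FeatureTable(["pt0", "ct0", "pt1", "ct1"], ["a", "b"], vals)
        results = per_feature_group_test(table, meta)
        assert all(r.p_value == pytest.approx(1.0) for r in results)
        assert not any(r.significant for r in results)

    def test_label_symmetry(self, rng):
        table, meta = _cohort(rng, shift=0.8)
        res = {r.feature_id: r for r in per_feature_group_test(table, meta)}
        swapped = [
            SampleMetadata(m.sample_id, "control" if m.group == "patient" else "patient",
                           m.pair_id, m.antipsychotic_flag)
            for m in meta
        ]
        res_sw = {r.feature_id: r for r in per_feature_group_test(table, swapped)}
        for fid in res:
            assert res[fid].p_value == pytest.approx(res_sw[fid].p_value, abs=1e-12)
            assert res[fid].mean_patient == pytest.approx(res_sw[fid].mean_control)

    def test_planted_shift_detected(self):
        hits = 0
        for s in range(10):
            table, meta = _cohort(np.random.default_rng(200 + s), n_pairs=39, shift=1.5)
            res = {r.feature_id: r for r in per_feature_group_test(table, meta)}
            hits += res["f0"].significant
        assert hits >= 9

    def test_null_type_one_error_controlled(self):
        sig = total = 0
        for s in range(10):
            table, meta = _cohort(np.random.default_rng(300 + s), n_pairs=39, n_features=8)
            res = per_feature_group_test(table, meta)
            sig += sum(r.significant for r in res)
            total += len(res)
        assert sig / total < 0.15

    def test_concentration_scale_reports_raw_means(self, rng):
        table, meta = _cohort(rng)
        res = per_feature_group_test(table, meta, scale="concentration")
        assert all(r.mean_patient > 0 and r.mean_control > 0 for r in res)


class TestConfounderScan:
    def test_coefficient_equals_t_test(self, rng):
        table, meta = _cohort(rng, n_pairs=16)
        res = confounder_scan(table, meta)
        # flagged vs unflagged patients, log2 scale
        patients = [m for m in meta if m.group == "patient"]
        idx = {s: i for i, s in enumerate(table.sample_ids)}
        log_vals = np.log2(table.values)
        for r in res:
            c = table.feature_ids.index(r.feature_id)
            a = [log_vals[idx[m.sample_id], c] for m in patients if m.antipsychotic_flag]
            b = [log_vals[idx[m.sample_id], c] for m in patients if not m.antipsychotic_flag]
            t = stats.ttest_ind(a, b)
            assert r.coefficient == pytest.approx(np.mean(a) - np.mean(b), abs=1e-10)
            assert r.p_raw == pytest.approx(t.pvalue, abs=1e-10)

    def test_null_scan_rarely_flags(self):
        flagged = 0
        for s in range(5):
            table, meta = _cohort(np.random.default_rng(400 + s), n_pairs=39, n_features=10)
            flagged += sum(r.flagged for r in confounder_scan(table, meta))
        assert flagged == 0

    def test_adjustment_ordering(self, rng):
        table, meta = _cohort(rng)
        for r in confounder_scan(table, meta):
            assert r.p_bonferroni >= r.p_bh >= r.p_raw - 1e-12

    def test_constant_flag_errors(self, rng):
        table, meta = _cohort(rng)
        meta = [
            SampleMetadata(m.sample_id, m.group, m.pair_id, False) for m in meta
        ]
        with pytest.raises(ValidationError, match="flag constant"):
            confounder_scan(table, meta)

    def test_single_feature_corrections_coincide(self, rng):
        table, meta = _cohort(rng, n_features=1)
        (r,) = confounder_scan(table, meta)
        assert r.p_bh == pytest.approx(r.p_raw)
        assert r.p_bonferroni == pytest.approx(r.p_raw)
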