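import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

import mitograde as mg
from mitograde.agreement import NO_ZONE

HAND_MATRIX = np.array([[20, 3, 0], [4, 10, 2], [0, 3, 8]])
# hand calculation with w_ij = |i-j|/2: observed weighted disagreement
# 6/50 = 0.12, expected 1038/2500 = 0.4152, kappa = 1 - 0.12/0.4152
HAND_KAPPA = 0.7109826589595376


def pairs_from_matrix(m):
    a, b = [], []
    for i in range(3):
        for j in range(3):
            a += [i + 1] * m[i][j]
            b += [j + 1] * m[i][j]
    return a, b


class TestAccuracy:
    def test_diagonal_and_off_diagonal_extremes(self):
        assert mg.accuracy(np.diag([10, 10, 10])) == 1.0
        assert mg.accuracy([[0, 5, 0], [5, 0, 5], [0, 5, 0]]) == 0.0

    def test_hand_arithmetic_matrix(self):
        assert mg.accuracy(HAND_MATRIX) == pytest.approx(38 / 50)

    def test_accepts_score_pairs(self):
        assert mg.accuracy(([1, 2, 3, 1], [1, 2, 1, 1])) == 0.75

    def test_empty_matrix_is_an_error(self):
        with pytest.raises(ValueError):
            mg.accuracy(np.zeros((3, 3)))


class TestKappaLinear:
    def test_perfect_agreement(self):
        assert mg.kappa_linear(np.diag([5, 7, 3])).kappa == pytest.approx(1.0)

    def test_marginal_product_matrix_is_chance_level(self):
        cm = np.outer([2, 3, 5], [1, 4, 5])
        assert mg.kappa_linear(cm).kappa == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_hand_calculation(self):
        res = mg.kappa_linear(HAND_MATRIX)
        assert res.kappa == pytest.approx(HAND_KAPPA, rel=1e-12)
        assert res.ci_low < res.kappa < res.ci_high

    def test_transpose_symmetric(self):
        cm = mg.ConfusionMatrix3(HAND_MATRIX)
        assert mg.kappa_linear(cm).kappa == pytest.approx(
            mg.kappa_linear(cm.transpose).kappa
        )

    def test_count_scaling_leaves_kappa_but_narrows_ci(self):
        r1 = mg.kappa_linear(HAND_MATRIX)
        r5 = mg.kappa_linear(HAND_MATRIX * 5)
        assert r5.kappa == pytest.approx(r1.kappa)
        assert (r5.ci_high - r5.ci_low) < (r1.ci_high - r1.ci_low)

    def test_two_category_collapse_equals_unweighted_kappa(self):
        # with only two categories in use, linear weights are 0/1
        rng = np.random.default_rng(23)
        a = rng.choice([1, 2], 200)
        b = np.where(rng.random(200) < 0.7, a, rng.choice([1, 2], 200))
        ours = mg.kappa_linear(mg.ConfusionMatrix3.from_pairs(a, b)).kappa
        unweighted = cohen_kappa_score(a, b)
        assert ours == pytest.approx(unweighted, rel=1e-9)

    def test_cross_check_against_sklearn_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            m = rng.integers(1, 30, (3, 3))
            a, b = pairs_from_matrix(m)
            assert mg.kappa_linear(m).kappa == pytest.approx(
                cohen_kappa_score(a, b, weights="linear"), rel=1e-9
            )

    def test_degenerate_marginal_raises_not_silent_zero(self):
        with pytest.raises(ValueError, match="degenerate"):
            mg.kappa_linear(np.array([[5, 0, 0], [3, 0, 0], [2, 0, 0]]))

    def test_bootstrap_ci_brackets_estimate(self):
        res = mg.kappa_linear(HAND_MATRIX, ci="bootstrap", n_boot=200, seed=0)
        assert res.kappa == pytest.approx(HAND_KAPPA)
        assert res.ci_low < res.kappa < res.ci_high


class TestICC:
    def test_identical_nonconstant_vectors(self):
        v = [1, 2, 3, 1, 2, 3, 2, 1]
        assert mg.icc_scores(v, v).icc == pytest.approx(1.0)

    def test_broken_pairing_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=2000)
        y = rng.permutation(rng.normal(size=2000))
        assert abs(mg.icc_scores(x, y).icc) < 0.08

    def test_parameter_recovery_rho_07(self):
        rng = np.random.default_rng(5)
        rho, n = 0.7, 500
        subj = rng.normal(0, np.sqrt(rho), n)
        a = subj + rng.normal(0, np.sqrt(1 - rho), n)
        b = subj + rng.normal(0, np.sqrt(1 - rho), n)
        res = mg.icc_scores(a, b)
        assert res.icc == pytest.approx(rho, abs=0.05)
        assert res.ci_low < res.icc < res.ci_high

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            mg.icc_scores([2, 2, 2, 2], [2, 2, 2, 2])

    def test_alternate_forms_accepted(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=50), rng.normal(size=50)
        forms = {f: mg.icc_scores(a, b, form=f).icc
                 for f in ("ICC1", "ICC2", "ICC3", "ICC2k")}
        assert len(forms) == 4
        with pytest.raises(ValueError):
            mg.icc_scores(a, b, form="ICC9")


def zone(x, y, area=2.0):
    return mg.CircleZone.from_area(mg.PointUm(x, y), area)


class TestZoneIntersection:
    def test_identical_zones_rate_one(self):
        za = {f"s{i}": zone(i * 100.0, 0.0) for i in range(5)}
        rate, flags, excluded = mg.zone_intersection_rate(za, dict(za))
        assert rate == 1.0 and all(flags.values()) and excluded == []

    def test_distant_zones_rate_zero(self):
        za = {f"s{i}": zone(0, 0) for i in range(4)}
        zb = {f"s{i}": zone(50000, 50000) for i in range(4)}
        rate, _, _ = mg.zone_intersection_rate(za, zb)
        assert rate == 0.0

    def test_mixed_pattern_matches_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        za, zb, expected = {}, {}, {}
        for i in range(30):
            ax, ay = rng.uniform(0, 10000, 2)
            bx, by = rng.uniform(0, 10000, 2)
            za[f"s{i}"], zb[f"s{i}"] = zone(ax, ay), zone(bx, by)
            r = mg.area_to_radius(2.0)
            expected[f"s{i}"] = np.hypot(ax - bx, ay - by) <= 2 * r
        rate, flags, _ = mg.zone_intersection_rate(za, zb)
        assert flags == expected
        assert rate == pytest.approx(sum(expected.values()) / 30)

    def test_missing_slide_excluded_and_no_zone_counts_false(self):
        za = {"s0": zone(0, 0), "s1": zone(0, 0), "s2": zone(0, 0)}
        zb = {"s0": zone(10, 10), "s1": NO_ZONE}
        rate, flags, excluded = mg.zone_intersection_rate(za, zb)
        assert excluded == ["s2"]
        assert flags == {"s0": True, "s1": False}
        assert rate == 0.5

    def test_ai_variant_any_selected_zone_counts(self):
        ai = {"s0": [zone(0, 0), zone(9000, 9000)], "s1": []}
        rd = {"s0": zone(9100, 9100), "s1": zone(0, 0)}
        rate, flags, _ = mg.ai_zone_intersection_rate(ai, rd)
        assert flags == {"s0": True, "s1": False}
        assert rate == 0.5


def make_records(scores_by_reader, condition="with_AI", specimen=None, zones=None):
    rows = []
    for rid, scores in scores_by_reader.items():
        for i, s in enumerate(scores):
            row = {"slide_id": f"s{i}", "reader_id": rid,
                   "condition": condition, "score": s}
            if specimen is not None:
                row["specimen_type"] = specimen[i]
            if zones is not None:
                zx, zy = zones[(rid, i)]
                row.update(zone_x=zx, zone_y=zy,
                           zone_radius_um=mg.area_to_radius(2.0))
            rows.append(row)
    return pd.DataFrame(rows)


class TestSubgroupReport:
    def test_single_stratum_equals_global(self):
        rng = np.random.default_rng(3)
        truth = rng.choice([1, 2, 3], 30)
        noisy = np.where(rng.random(30) < 0.8, truth,
                         rng.choice([1, 2, 3], 30))
        records = make_records({"R1": truth, "R2": noisy})
        consensus = {f"s{i}": int(t) for i, t in enumerate(truth)}
        reports = {r.stratum: r for r in mg.subgroup_report(records, consensus)}
        global_r = reports["all"]
        expected_kappa = mg.kappa_linear(
            mg.ConfusionMatrix3.from_pairs(truth, noisy)
        ).kappa
        assert global_r.kappa.kappa == pytest.approx(expected_kappa)
        assert global_r.accuracy_by_reader["R1"] == 1.0

    def test_perfect_agreement_stratum(self):
        truth = [1, 2, 3, 1, 2, 3, 2, 1]
        records = make_records({"R1": truth, "R2": truth})
        consensus = {f"s{i}": t for i, t in enumerate(truth)}
        rep = [r for r in mg.subgroup_report(records, consensus)
               if r.stratum == "all"][0]
        assert rep.accuracy == 1.0
        assert rep.kappa.kappa == pytest.approx(1.0)

    def test_strata_match_manual_subsetting(self):
        rng = np.random.default_rng(14)
        truth = rng.choice([1, 2, 3], 60)
        specimen = ["biopsy" if i % 2 else "surgical" for i in range(60)]
        r1 = np.where(rng.random(60) < 0.7, truth, rng.choice([1, 2, 3], 60))
        r2 = np.where(rng.random(60) < 0.7, truth, rng.choice([1, 2, 3], 60))
        records = make_records({"R1": r1, "R2": r2}, specimen=specimen)
        consensus = {f"s{i}": int(t) for i, t in enumerate(truth)}
        reports = {r.stratum: r for r in mg.subgroup_report(records, consensus)}
        mask = truth == 1
        manual_acc = np.mean(
            np.concatenate([r1[mask] == truth[mask], r2[mask] == truth[mask]])
        )
        assert reports["score=1"].accuracy == pytest.approx(manual_acc)
        bio = [i % 2 == 1 for i in range(60)]
        manual_bio = np.mean(
            np.concatenate([(r1 == truth)[bio], (r2 == truth)[bio]])
        )
        assert reports["specimen=biopsy"].accuracy == pytest.approx(manual_bio)

    def test_small_stratum_reports_n_without_statistics(self):
        records = make_records({"R1": [3], "R2": [3]})
        consensus = {"s0": 3}
        rep = [r for r in mg.subgroup_report(records, consensus)
               if r.stratum == "score=3"][0]
        assert rep.n_slides == 1
        assert rep.accuracy is None and rep.kappa is None

    def test_zone_columns_feed_intersection_rate(self):
        zones = {("R1", 0): (0, 0), ("R1", 1): (0, 0),
                 ("R2", 0): (100, 100), ("R2", 1): (30000, 30000)}
        records = make_records({"R1": [1, 2], "R2": [1, 2]}, zones=zones)
        consensus = {"s0": 1, "s1": 2}
        rep = [r for r in mg.subgroup_report(records, consensus)
               if r.stratum == "all"][0]
        assert rep.zone_intersection_rate == 0.5
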