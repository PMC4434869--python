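"""HK/LK median-split stratification, group comparisons and survival."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ctcemt.cohort import (
    CohortError,
    associate_group_with_covariate,
    compare_cell_populations,
    compare_keratin_by_group,
    label_patients,
    one_year_os,
    pooled_median,
)
from ctcemt.records import PatientRecord


def patient(values, pid="p0", tn=False, os_months=24.0, os_event=False, **kw):
    defaults = dict(er_status="positive", pr_status="positive", her2_status="negative")
    if tn:
        defaults = dict(
            er_status="negative", pr_status="negative", her2_status="negative"
        )
    defaults.update(kw)
    return PatientRecord(
        patient_id=pid,
        ctc_keratin_values=list(values),
        triple_negative=tn,
        os_months=os_months,
        os_event=os_event,
        **defaults,
    )


class TestMedianSplit:
    def test_odd_pool(self):
        assert pooled_median([patient([1.0, 2.0, 3.0])]) == 2.0

    def test_even_pool_midpoint(self):
        assert pooled_median([patient([1.0, 2.0]), patient([3.0, 4.0], "p1")]) == 2.5

    def test_matches_brute_force_sort(self):
        from ctcemt.synthetic import CohortGenConfig, generate_cohort

        patients = generate_cohort(CohortGenConfig(seed=5))
        pool = sorted(v for p in patients for v in p.ctc_keratin_values)
        n = len(pool)
        brute = pool[n // 2] if n % 2 else (pool[n // 2 - 1] + pool[n // 2]) / 2
        assert pooled_median(patients) == pytest.approx(brute)

    def test_empty_pool_is_an_error(self):
        with pytest.raises(CohortError):
            pooled_median([])

    def test_minority_high_is_lk(self):
        (p,) = label_patients([patient([10.0, 10.0, 30.0])], median=20.0)
        assert p.fraction_high == pytest.approx(1 / 3)
        assert p.keratin_group == "LK"

    def test_majority_high_is_hk(self):
        (p,) = label_patients([patient([30.0, 30.0, 10.0])], median=20.0)
        assert p.keratin_group == "HK"

    def test_exact_half_is_lk(self):
        (p,) = label_patients([patient([30.0, 30.0, 10.0, 10.0])], median=20.0)
        assert p.fraction_high == 0.5
        assert p.keratin_group == "LK"

    def test_values_at_the_median_are_not_high(self):
        (p,) = label_patients([patient([20.0, 20.0, 20.0])], median=20.0)
        assert p.fraction_high == 0.0
        assert p.keratin_group == "LK"

    @given(
        data=st.lists(
            st.lists(st.floats(1.0, 300.0), min_size=2, max_size=8),
            min_size=2,
            max_size=10,
        ),
        seed=st.integers(0, 2**16),
    )
    @settings(derandomize=True, max_examples=100)
    def test_partition_and_permutation_invariance(self, data, seed):
        patients = [patient(v, f"p{i}") for i, v in enumerate(data)]
        med = pooled_median(patients)
        label_patients(patients, med)
        labels = {p.patient_id: p.keratin_group for p in patients}
        assert all(g in ("HK", "LK") for g in labels.values())
        rng = np.random.default_rng(seed)
        shuffled = [
            patient(list(rng.permutation(v)), f"p{i}") for i, v in enumerate(data)
        ]
        order = rng.permutation(len(shuffled))
        shuffled = [shuffled[i] for i in order]
        med2 = pooled_median(shuffled)
        assert med2 == pytest.approx(med)
        label_patients(shuffled, med2)
        assert {p.patient_id: p.keratin_group for p in shuffled} == labels


class TestGroupComparison:
    def test_identical_groups(self):
        patients = [
            patient([5.0, 5.0], "a", tn=True),
            patient([5.0, 5.0], "b", tn=False),
        ]
        res = compare_keratin_by_group(patients)
        assert res.mean_difference == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_separation(self):
        patients = [
            patient([0.0, 0.0, 0.0, 0.0], "a", tn=True),
            patient([1.0, 1.0, 1.0, 1.0], "b"),
        ]
        res = compare_keratin_by_group(patients)
        assert res.mean_difference == pytest.approx(-1.0)
        assert res.p_value < 0.01

    def test_matches_scipy_on_pooled_values(self):
        rng = np.random.default_rng(3)
        tn = [patient(rng.uniform(50, 150, 5), f"t{i}", tn=True) for i in range(4)]
        other = [patient(rng.uniform(100, 250, 5), f"o{i}") for i in range(6)]
        res = compare_keratin_by_group(tn + other)
        a = np.concatenate([p.ctc_keratin_values for p in tn])
        b = np.concatenate([p.ctc_keratin_values for p in other])
        ref = stats.ttest_ind(a, b)
        assert res.t_statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_single_group_is_an_error(self):
        with pytest.raises(CohortError):
            compare_keratin_by_group([patient([1.0, 2.0], tn=True)])


class TestAssociation:
    def label(self, patients, groups):
        for p, g in zip(patients, groups):
            p.keratin_group = g
        return patients

    def test_independent_table(self):
        patients = self.label(
            [patient([1.0, 1.0], f"t{i}", tn=True) for i in range(10)]
            + [patient([1.0, 1.0], f"o{i}") for i in range(10)],
            ["LK"] * 5 + ["HK"] * 5 + ["LK"] * 5 + ["HK"] * 5,
        )
        res = associate_group_with_covariate(patients)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association(self):
        patients = self.label(
            [patient([1.0, 1.0], f"t{i}", tn=True) for i in range(10)]
            + [patient([1.0, 1.0], f"o{i}") for i in range(10)],
            ["LK"] * 10 + ["HK"] * 10,
        )
        res = associate_group_with_covariate(patients)
        assert res.lk_fraction_in_positive == 1.0
        assert res.p_value < 0.01

    def test_eight_of_eleven_stratum_percentage(self):
        patients = self.label(
            [patient([1.0, 1.0], f"t{i}", tn=True) for i in range(11)]
            + [patient([1.0, 1.0], f"o{i}") for i in range(50)],
            ["LK"] * 8 + ["HK"] * 3 + ["LK"] * 19 + ["HK"] * 31,
        )
        res = associate_group_with_covariate(patients)
        assert res.lk_fraction_in_positive == pytest.approx(8 / 11)
        assert round(100 * res.lk_fraction_in_positive, 1) == 72.7

    def test_unknown_status_excluded(self):
        patients = self.label(
            [patient([1.0, 1.0], f"a{i}", er_status="negative") for i in range(4)]
            + [patient([1.0, 1.0], f"b{i}", er_status="positive") for i in range(4)]
            + [patient([1.0, 1.0], "u", er_status="unknown")],
            ["LK", "LK", "HK", "HK"] * 2 + ["LK"],
        )
        res = associate_group_with_covariate(patients, "er_status")
        assert res.n_excluded_unknown == 1
        assert sum(sum(row) for row in res.table) == 8

    def test_degenerate_margin_is_an_error(self):
        patients = self.label(
            [patient([1.0, 1.0], f"t{i}", tn=True) for i in range(4)],
            ["LK"] * 4,
        )
        with pytest.raises(CohortError):
            associate_group_with_covariate(patients)


class TestSurvival:
    def group(self, specs, label, prefix):
        out = []
        for i, (months, event) in enumerate(specs):
            p = patient([1.0, 1.0], f"{prefix}{i}", os_months=months, os_event=event)
            p.keratin_group = label
            out.append(p)
        return out

    def test_no_deaths_before_horizon(self):
        patients = self.group([(24.0, False)] * 5, "HK", "h") + self.group(
            [(24.0, True)] * 5, "LK", "l"
        )
        res = one_year_os(patients)
        assert res.survival["HK"] == pytest.approx(1.0)

    def test_all_deaths_at_six_months(self):
        patients = self.group([(6.0, True)] * 5, "HK", "h") + self.group(
            [(24.0, False)] * 5, "LK", "l"
        )
        res = one_year_os(patients)
        assert res.survival["HK"] == pytest.approx(0.0)

    def test_km_without_censoring_equals_empirical_fraction(self):
        times = [3.0, 8.0, 14.0, 20.0, 30.0, 5.0]
        patients = self.group([(t, True) for t in times], "HK", "h") + self.group(
            [(40.0, False)] * 3, "LK", "l"
        )
        res = one_year_os(patients, horizon_months=12.0)
        assert res.survival["HK"] == pytest.approx(np.mean(np.array(times) > 12.0))

    def test_missing_group_is_an_error(self):
        patients = self.group([(10.0, True)] * 3, "HK", "h")
        with pytest.raises(CohortError):
            one_year_os(patients)


class TestMultiGroup:
    def test_identical_groups(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        res = compare_cell_populations(g)
        assert res.h_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_separated_groups_all_pairs_significant(self):
        rng = np.random.default_rng(0)
        g = {
            "epi": list(rng.normal(0.2, 0.05, 30)),
            "mid": list(rng.normal(2.0, 0.3, 30)),
            "mes": list(rng.normal(13.0, 2.0, 30)),
        }
        res = compare_cell_populations(g)
        assert res.p_value < 1e-6
        assert all(p < 0.05 for p in res.dunn_p.values())

    def test_h_matches_hand_computed_ranks(self):
        g = {
            "a": [1.0, 3.0, 5.0, 7.0],
            "b": [2.0, 4.0, 6.0, 8.0],
            "c": [9.0, 10.0, 11.0, 12.0],
        }
        pooled = np.concatenate(list(g.values()))
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        rank_sums = [ranks[:4].sum(), ranks[4:8].sum(), ranks[8:].sum()]
        h = 12.0 / (n * (n + 1)) * sum(r**2 / 4 for r in rank_sums) - 3 * (n + 1)
        res = compare_cell_populations(g)
        assert res.h_statistic == pytest.approx(h)

    def test_dunn_z_matches_direct_formula(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0], "c": [7.0, 8.0, 9.0]}
        res = compare_cell_populations(g)
        # no ties: variance term is N(N+1)/12
        n = 9
        sd = np.sqrt(n * (n + 1) / 12.0 * (2 / 3))
        assert res.dunn_z[("a", "b")] == pytest.approx((2.0 - 5.0) / sd)
        expected_p = min(2 * stats.norm.sf(abs((2.0 - 5.0) / sd)) * 3, 1.0)
        assert res.dunn_p[("a", "b")] == pytest.approx(expected_p)

    def test_two_groups_is_an_error(self):
        with pytest.raises(CohortError):
            compare_cell_populations({"a": [1.0, 2.0], "b": [3.0, 4.0]})
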