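"""Group tests, paired comparisons and washout summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from spheroscreen.clinical import (
    association_report,
    drug_dss_per_sample,
    effective_counts_per_sample,
    group_dss_by_clinical,
    mann_whitney,
    paired_format_comparison,
    per_drug_format_difference,
    summarize_longterm,
)
from spheroscreen.plate import ClinicalRecord
from spheroscreen.simulate import (
    LongTermConfig,
    ScreenConfig,
    generate_cohort_dss,
    generate_longterm,
)


def brute_force_mwu_p(a, b):
    """Exact two-tailed p by enumerating every assignment of the pooled
    values to group labels (independent oracle for small untied inputs)."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(group_a, group_b):
        return sum(1.0 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(a, b)
    mid = n_a * len(b) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(ga, gb)
        # tail as extreme as observed, in the observed direction
        if u_obs <= mid:
            count += u <= u_obs
        else:
            count += u >= u_obs
        total += 1
    return min(1.0, 2.0 * count / total)


class TestMannWhitney:
    def test_separated_groups_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_groups_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 7, size=2)
        pool = rng.permutation(np.arange(1.0, 20.0))[: n_a + n_b]
        a, b = pool[:n_a], pool[n_a:]
        res = mann_whitney(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_mwu_p(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])

    def test_ties_fall_back_to_asymptotic(self):
        res = mann_whitney([1, 1, 2, 3], [2, 2, 3, 4])
        assert res.method == "asymptotic"
        assert 0 < res.p_value <= 1


def table1_style_cohort(excluded=False):
    """16 patients: 11 CR / 4 PR / 1 P, one value-bearing sample each."""
    records = []
    labels = ["CR"] * 11 + ["PR"] * 4 + ["P"]
    for i, lab in enumerate(labels):
        records.append(ClinicalRecord(
            patient_id=f"PT{i+1:02d}", sample_ids=[f"PT{i+1:02d}-T"],
            recist=lab, pfi_months=6.0 if i % 2 else 24.0,
            excluded=excluded and i == 0))
    return records


class TestGrouping:
    def test_recist_group_sizes_match_cohort(self):
        clinical = table1_style_cohort()
        values = pd.Series({r.sample_ids[0]: float(i)
                            for i, r in enumerate(clinical)})
        cr, prp = group_dss_by_clinical(values, clinical, "RECIST_CRvsPRP")
        assert (len(cr), len(prp)) == (11, 5)

    def test_excluded_patient_omitted(self):
        clinical = table1_style_cohort(excluded=True)
        values = pd.Series({r.sample_ids[0]: 1.0 for r in clinical})
        cr, prp = group_dss_by_clinical(values, clinical, "RECIST_CRvsPRP")
        assert len(cr) + len(prp) == 15

    def test_all_excluded_raises(self):
        clinical = [ClinicalRecord(patient_id="A", sample_ids=["A-T"],
                                   recist="CR", excluded=True)]
        with pytest.raises(ValueError):
            group_dss_by_clinical(pd.Series({"A-T": 1.0}), clinical,
                                  "RECIST_CRvsPRP")

    def test_multi_sample_patients_contribute_one_value(self):
        rec = ClinicalRecord(patient_id="A", sample_ids=["A-T", "A-A"],
                             recist="CR", pfi_months=20.0)
        other = ClinicalRecord(patient_id="B", sample_ids=["B-T"],
                               recist="PR", pfi_months=5.0)
        values = pd.Series({"A-T": 10.0, "A-A": 20.0, "B-T": 7.0})
        cr, prp = group_dss_by_clinical(values, [rec, other], "RECIST_CRvsPRP")
        assert cr == [15.0]  # mean of the patient's two samples
        assert prp == [7.0]

    def test_order_independence(self):
        clinical = table1_style_cohort()
        values = pd.Series({r.sample_ids[0]: float(i)
                            for i, r in enumerate(clinical)})
        a1, b1 = group_dss_by_clinical(values, clinical, "PFI_le12_vs_gt12")
        a2, b2 = group_dss_by_clinical(values, clinical[::-1], "PFI_le12_vs_gt12")
        assert sorted(a1) == sorted(a2) and sorted(b1) == sorted(b2)

    def test_configured_pfi_effect_direction_recovered(self):
        df, clinical, _ = generate_cohort_dss(ScreenConfig(), seed=2)
        vals = drug_dss_per_sample(df, "carboplatin")
        le12, gt12 = group_dss_by_clinical(vals, clinical, "PFI_le12_vs_gt12")
        assert (len(le12), len(gt12)) == (7, 7)
        assert np.mean(gt12) > np.mean(le12)  # long PFI = platinum sensitive


class TestPairedComparison:
    def test_identical_pairs(self):
        res = paired_format_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_difference_degenerate(self):
        res = paired_format_comparison([2.0] * 11, [1.0] * 11)
        assert res.degenerate
        assert res.p_value == 0.0
        assert res.mean_difference == pytest.approx(1.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_format_comparison([1.0], [2.0])

    def test_configured_growth_difference_recovered(self, small_screen):
        from spheroscreen.readout import sample_fold_growth

        dataset, _ = small_screen
        growth = sample_fold_growth(dataset.wells_frame())
        wide = growth.pivot(index="sample_id", columns="format",
                            values="fold_growth").dropna()
        res = paired_format_comparison(wide["3D"], wide["2D"])
        assert res.mean_difference > 0

    def test_per_drug_difference_report_threshold(self):
        d2 = pd.DataFrame({"drug_id": ["a", "b"], "dss": [10.0, 5.0]})
        d3 = pd.DataFrame({"drug_id": ["a", "b"], "dss": [8.5, 4.8]})
        out = per_drug_format_difference(d2, d3).set_index("drug_id")
        assert bool(out.loc["a", "reported"])       # |1.5| > 1
        assert not bool(out.loc["b", "reported"])   # |0.2| <= 1


@pytest.fixture(scope="module")
def summaries():
    series, _ = generate_longterm(LongTermConfig(noise_cv=0.0), seed=5)
    return {(s.arm, s.dose_level, s.washout_day): s
            for s in summarize_longterm(series)}


class TestLongTerm:
    def test_control_grows(self, summaries):
        s = summaries[("control", "none", 3)]
        assert s.fold_change_day14 > 1.0

    def test_combination_is_cytotoxic(self, summaries):
        s = summaries[("combination", "high", 5)]
        assert s.fold_change_day14 < 0.1
        assert not s.regrowth

    def test_monotherapy_regrows_after_washout(self, summaries):
        s = summaries[("drug2", "high", 3)]
        assert s.regrowth

    def test_gap_flagging(self):
        series, _ = generate_longterm(LongTermConfig(noise_cv=0.0), seed=5)
        gappy = series[~series["time_h"].between(100, 140)]
        flags = {(s.arm, s.dose_level, s.washout_day): s.flagged
                 for s in summarize_longterm(gappy)}
        assert all(flags.values())


class TestAssociationReport:
    def test_battery_on_synthetic_cohort(self):
        df, clinical, _ = generate_cohort_dss(ScreenConfig(), seed=4)
        report = association_report(df, clinical)
        assert set(report["endpoint"]) == {"RECIST_CRvsPRP", "PFI_le12_vs_gt12"}
        carbo_pfi = report[(report.variable == "carboplatin_dss")
                           & (report.endpoint == "PFI_le12_vs_gt12")].iloc[0]
        assert carbo_pfi.n_a == 7 and carbo_pfi.n_b == 7
        assert carbo_pfi.p_value < 0.05
        assert carbo_pfi.direction == "A<B"

    def test_effective_counts_per_sample(self):
        df = pd.DataFrame({
            "sample_id": ["S1"] * 3 + ["S2"] * 3,
            "drug_id": ["a", "b", "c"] * 2,
            "parameter": ["TMRM"] * 6,
            "dss": [10.0, 7.9, 8.1, 1.0, 2.0, 30.0],
        })
        counts = effective_counts_per_sample(df)
        assert counts["S1"] == 2 and counts["S2"] == 1
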