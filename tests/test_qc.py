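"""Z'-factor gating and percent-inhibition normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spheroscreen.qc import normalize_responses, percent_inhibition, qc_gate, zprime
from spheroscreen.simulate import ScreenConfig, generate_screen


class TestZPrime:
    def test_zero_variance_distinct_means_is_one(self):
        assert zprime([1.0, 1.0, 1.0], [0.1, 0.1, 0.1]) == pytest.approx(1.0)

    def test_closed_form(self):
        # mu_n=1.0 sd_n=0.05, mu_p=0.1 sd_p=0.05 -> 1 - 3*0.1/0.9
        neg = [0.95, 1.05, 0.95, 1.05]
        pos = [0.05, 0.15, 0.05, 0.15]
        sd = np.std(neg, ddof=1)
        expected = 1 - 3 * (2 * sd) / 0.9
        assert zprime(neg, pos) == pytest.approx(expected)
        assert zprime([1 - 0.05, 1 + 0.05], [0.1 - 0.05, 0.1 + 0.05]) == \
            pytest.approx(1 - 3 * (0.05 * np.sqrt(2) * 2) / 0.9)

    def test_monotone_in_spread(self):
        tight = zprime([0.99, 1.01], [0.09, 0.11])
        loose = zprime([0.8, 1.2], [0.0, 0.3])
        assert loose < tight <= 1.0

    def test_equal_means_sentinel(self):
        with pytest.warns(UserWarning, match="coincide"):
            assert zprime([1.0, 2.0], [1.2, 1.8]) == float("-inf")

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            zprime([1.0], [0.1, 0.2])


class TestPercentInhibition:
    def test_anchors(self):
        assert percent_inhibition(1.0, 1.0, 0.1, "viability_decreases") == 0.0
        assert percent_inhibition(0.1, 1.0, 0.1, "viability_decreases") == \
            pytest.approx(100.0)
        assert percent_inhibition(0.05, 0.05, 0.95, "death_increases") == 0.0
        assert percent_inhibition(0.95, 0.05, 0.95, "death_increases") == \
            pytest.approx(100.0)

    def test_midpoint_closed_form(self):
        assert percent_inhibition(0.55, 1.0, 0.1, "viability_decreases") == \
            pytest.approx(50.0)

    def test_degenerate_controls_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            percent_inhibition(0.5, 1.0, 1.0, "viability_decreases")

    def test_not_clamped(self):
        assert percent_inhibition(1.2, 1.0, 0.1, "viability_decreases") < 0
        assert percent_inhibition(-0.1, 1.0, 0.1, "viability_decreases") > 100

    @given(st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance(self, a, b):
        """Applying x -> a*x + b (a > 0) to raw values and both control
        means leaves percent inhibition unchanged."""
        raw, neg, pos = 0.62, 1.0, 0.1
        before = percent_inhibition(raw, neg, pos, "viability_decreases")
        after = percent_inhibition(a * raw + b, a * neg + b, a * pos + b,
                                   "viability_decreases")
        assert after == pytest.approx(before, rel=1e-7, abs=1e-7)


class TestQCGate:
    def test_degraded_sample_fails_exactly(self):
        cfg = ScreenConfig(n_patients=3, n_paired_samples=0, n_drugs=4,
                           n_2d_samples=0, degraded_samples=("PT02-A",))
        dataset, _ = generate_screen(cfg, seed=21)
        from spheroscreen.readout import well_readouts
        report = qc_gate(well_readouts(dataset.wells))
        tmrm = report[report.parameter == "TMRM"].set_index("sample_id")
        assert not tmrm.loc["PT02-A", "passed"]
        others = tmrm.drop("PT02-A")
        assert others["passed"].all()

    def test_gate_is_strictly_greater(self, small_screen_tables):
        report = small_screen_tables["qc"]
        assert (report["passed"] == (report["zprime"] > 0.4)).all()

    def test_matches_brute_force_recomputation(self, small_screen_tables):
        from spheroscreen.readout import substitute_popo1_positive_control

        readouts = small_screen_tables["readouts"]
        report = small_screen_tables["qc"].set_index(["sample_id", "parameter"])
        sample = readouts["sample_id"].iloc[0]
        ctrl = readouts[(readouts.sample_id == sample)
                        & (readouts.timepoint_h == 72)]
        neg = ctrl[ctrl.role == "neg_control"]["tmrm_ratio"].to_numpy()
        pos = ctrl[ctrl.role == "pos_control"]["tmrm_ratio"].to_numpy()
        assert report.loc[(sample, "TMRM"), "zprime"] == \
            pytest.approx(zprime(neg, pos))
        negp = ctrl[ctrl.role == "neg_control"]["popo1_ratio"].to_numpy()
        posp = np.asarray(substitute_popo1_positive_control(
            ctrl[ctrl.role == "pos_control"]["popo1_ratio"].to_numpy()))
        assert report.loc[(sample, "POPO1"), "zprime"] == \
            pytest.approx(zprime(negp, posp))

    def test_missing_controls_flagged_unevaluable(self, small_screen_tables):
        readouts = small_screen_tables["readouts"]
        broken = readouts[~((readouts.role == "pos_control")
                            & (readouts.sample_id == "PT01-T"))]
        report = qc_gate(broken).set_index(["sample_id", "parameter"])
        assert not report.loc[("PT01-T", "TMRM"), "evaluable"]
        assert not report.loc[("PT01-T", "TMRM"), "passed"]

    def test_substitutions_counted(self):
        cfg = ScreenConfig(n_patients=2, n_paired_samples=0, n_drugs=4,
                           n_2d_samples=0, popo1_pos_dropout_rate=1.0)
        dataset, _ = generate_screen(cfg, seed=5)
        from spheroscreen.readout import well_readouts
        report = qc_gate(well_readouts(dataset.wells))
        popo = report[report.parameter == "POPO1"]
        assert (popo["n_substituted"] == 10).all()


class TestNormalization:
    def test_control_anchors_map_to_0_and_100(self, small_screen_tables):
        """Feeding a synthetic treatment value equal to a control mean hits
        the normalization anchor exactly."""
        readouts = small_screen_tables["readouts"]
        sample = "PT01-T"
        ctrl = readouts[(readouts.sample_id == sample)
                        & (readouts.timepoint_h == 72)]
        neg_mean = ctrl[ctrl.role == "neg_control"]["tmrm_ratio"].mean()
        pos_mean = ctrl[ctrl.role == "pos_control"]["tmrm_ratio"].mean()
        assert percent_inhibition(neg_mean, neg_mean, pos_mean,
                                  "viability_decreases") == 0.0
        assert percent_inhibition(pos_mean, neg_mean, pos_mean,
                                  "viability_decreases") == pytest.approx(100.0)

    def test_normalized_table_covers_all_treatment_wells(self, small_screen_tables):
        readouts = small_screen_tables["readouts"]
        normalized = small_screen_tables["normalized"]
        n_treat = len(readouts[(readouts.role == "treatment")
                               & (readouts.timepoint_h == 72)])
        assert len(normalized) == 2 * n_treat  # TMRM + POPO1

    def test_inhibition_recovers_truth_curve(self, small_screen_tables):
        """Mean normalized inhibition at each dose tracks the generating
        curve (low noise, TMRM)."""
        from spheroscreen.dose_response import fourpl
        from spheroscreen.simulate import TruthModel

        truth = small_screen_tables["truth"]
        normalized = small_screen_tables["normalized"]
        sub = normalized[(normalized.parameter == "TMRM")
                         & (normalized.format == "3D")
                         & (normalized.sample_id == "PT02-A")]
        drug = sub["drug_id"].iloc[0]
        params = truth.curves[TruthModel.curve_key("PT02-A", "3D", drug)]
        g = sub[sub.drug_id == drug]
        for row in g.itertuples(index=False):
            expected = fourpl(np.log10(row.conc_nM), params["a"], params["d"],
                              params["b"], params["c"])
            assert row.percent_inhibition == pytest.approx(expected, abs=12.0)
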