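"""Stepwise detector: SD cutoffs, glucose floor, dilution rule, two passes."""

import numpy as np
import pandas as pd
import pytest

import pulseqc as pq
from conftest import make_panel


class TestFlagWithin:
    def test_asymmetric_cutoffs(self):
        z = [-3.5, 0.0, 4.2, 3.9, -2.9]
        np.testing.assert_array_equal(
            pq.flag_within(z), [True, False, True, False, False]
        )

    def test_boundaries_are_strict(self):
        assert not pq.flag_within([-3.0]).any()
        assert not pq.flag_within([4.0]).any()

    def test_interior_never_flagged(self):
        z = np.linspace(-2.99, 3.99, 50)
        assert not pq.flag_within(z).any()

    def test_missing_never_flagged(self):
        assert not pq.flag_within([np.nan, -10.0])[0]


class TestGlucoseFloor:
    def test_below_floor_flagged_strictly(self):
        panel = make_panel({"P1": {"glucose": [2.7, 2.8, 5.0], "TSH": [1.0, 1.0, 1.0]}})
        flags = pq.flag_glucose_floor(panel)
        assert flags.loc[("P1", 0), "glucose"]
        assert not flags.loc[("P1", 1), "glucose"]  # exactly 2.8: not flagged
        assert not flags["TSH"].any()  # rule touches glucose only

    def test_panel_without_glucose_warns_empty(self, caplog):
        panel = make_panel({"P1": {"TSH": [1.0, 1.1]}})
        with caplog.at_level("WARNING"):
            flags = pq.flag_glucose_floor(panel)
        assert not flags.any().any()
        assert "glucose" in caplog.text


class TestFlagCross:
    def _block(self, rows, hormones=("a", "b", "c", "d", "e")):
        return pd.DataFrame(rows, columns=list(hormones))

    def test_sum_below_threshold_flags_whole_tube(self):
        block = self._block([[-1.8] * 5, [0.0] * 5])
        flags = pq.flag_cross(block)
        assert flags.iloc[0].all()  # sum −9 < −8
        assert not flags.iloc[1].any()

    def test_threshold_is_strict(self):
        block = self._block([[-1.58] * 5])  # sum −7.9
        assert not pq.flag_cross(block).any().any()

    def test_missing_contributes_zero_and_rest_flagged(self):
        block = self._block([[np.nan, -2.125, -2.125, -2.125, -2.125]])  # sum −8.5
        flags = pq.flag_cross(block)
        assert not flags.iloc[0, 0]  # missing point cannot be flagged
        assert flags.iloc[0, 1:].all()

    def test_permutation_symmetric(self):
        rng = np.random.default_rng(0)
        block = self._block(rng.normal(-1.2, 1.0, size=(30, 5)))
        base = pq.flag_cross(block)
        perm = ["d", "b", "e", "a", "c"]
        flags_perm = pq.flag_cross(block[perm])
        pd.testing.assert_frame_equal(flags_perm[base.columns], base)

    def test_needs_two_hormones(self):
        with pytest.raises(ValueError):
            pq.flag_cross(self._block([[0.0]], hormones=("a",)), ["a"])


class TestDetectStepwise:
    def test_dilution_tube_flagged_by_cross_rule(self):
        cfg = pq.SimulationConfig(
            n_participants=1,
            errors=pq.ErrorSpec(spike_rate=0, drop_rate=0, dilution_rate=0),
        )
        panel = pq.simulate_clean_panel(cfg, seed=3)
        diluted = panel.copy()
        diluted.values.loc[("P01", 70)] *= 0.3
        res = pq.detect_stepwise(diluted)
        assert res.flags.loc[("P01", 70)].all()
        labels = res.step_labels.loc[("P01", 70)]
        assert labels.isin(["cross", "cross_pass2", "within", "glucose"]).all()

    def test_clean_low_noise_panel_unflagged(self):
        profiles = {
            "glucose": pq.HormoneProfile(baseline=5.0, circadian_amplitude=0.02,
                                         cv=0.005),
            "TSH": pq.HormoneProfile(baseline=1.5, circadian_amplitude=0.1,
                                     acrophase_hour=2.0, cv=0.005),
        }
        cfg = pq.SimulationConfig(n_participants=1, profiles=profiles,
                                  meal_times_min=())
        panel = pq.simulate_clean_panel(cfg, seed=1)
        res = pq.detect_stepwise(panel)
        assert res.n_flagged() == 0

    def test_union_contains_pass1(self, sim_panel_truth):
        panel, _ = sim_panel_truth
        once = pq.detect_stepwise(panel, pq.StepwiseParams(iterate=False))
        twice = pq.detect_stepwise(panel, pq.StepwiseParams(iterate=True))
        assert once.flagged_keys() <= twice.flagged_keys()

    def test_null_configuration_flags_nothing(self, sim_panel_truth):
        panel, _ = sim_panel_truth
        params = pq.StepwiseParams(
            lower_z=-1e12, upper_z=1e12, glucose_floor=0.0,
            cross_sum_threshold=-1e12,
        )
        assert pq.detect_stepwise(panel, params).n_flagged() == 0

    def test_masked_dilution_caught_in_second_pass(self):
        # A large shared pulse inflates every residual SD in pass 1, hiding
        # a moderate dilution elsewhere in the series; removing the pulse and
        # refitting shrinks the SD and the cross rule catches the dilution.
        rng = np.random.default_rng(8)
        n = 60
        data = {}
        for h in ["a", "b", "c", "d", "e"]:
            base = 10 + 0.5 * rng.standard_normal(n)
            base[29] += 30  # large shared pulse
            base[35] *= 0.75  # mild dilution, outside the pulse's window
            data[h] = base
        panel = make_panel({"P1": data})
        once = pq.detect_stepwise(panel, pq.StepwiseParams(iterate=False,
                                                           glucose_floor=0.0))
        twice = pq.detect_stepwise(panel, pq.StepwiseParams(glucose_floor=0.0))
        key = ("P1", 35)
        assert not once.flags.loc[key].any()  # masked in pass 1
        assert twice.flags.loc[key].all()  # rescued by the refit
        assert (twice.step_labels.loc[key] == "cross_pass2").all()

    def test_glucose_floor_points_labeled(self):
        vals = {"glucose": [5.0] * 20, "TSH": [1.5] * 20}
        vals["glucose"][7] = 2.5
        panel = make_panel({"P1": vals})
        res = pq.detect_stepwise(panel)
        assert res.flags.loc[("P1", 7), "glucose"]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            pq.StepwiseParams(lower_z=1.0)
        with pytest.raises(ValueError):
            pq.StepwiseParams(cross_sum_threshold=2.0)
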