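"""RFI computation and EC150/EC200 interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hclat import (ConcentrationResult, HillInduction, TruthModel,
                   ec_from_run, final_ec, main_series, marker_positive, rfi,
                   round_half_away, truth_ec, truth_rfi)


class TestRfi:
    @pytest.mark.parametrize("args, expected", [
        ((500, 50, 350, 50), 150.0),
        ((350, 50, 350, 50), 100.0),     # test tube equals vehicle tube
        ((60, 50, 350, 50), pytest.approx(100 * 10 / 300)),
    ])
    def test_worked_values(self, args, expected):
        assert rfi(*args) == expected

    def test_rescaling_invariance(self):
        base = rfi(500, 50, 350, 50)
        for k in (0.1, 3.0, 1000.0):
            assert rfi(500 * k, 50 * k, 350 * k, 50 * k) == pytest.approx(base)

    def test_nonpositive_denominator_is_undefined(self):
        assert rfi(500, 50, 50, 50) is None
        assert rfi(500, 50, 40, 50) is None

    def test_negative_numerator_clamped_to_zero(self):
        assert rfi(40, 50, 350, 50) == 0.0

    def test_negative_mfi_rejected(self):
        with pytest.raises(ValueError):
            rfi(-1, 50, 350, 50)


class TestEcFromRun:
    def cv_ok(self, concs):
        return {c: 90.0 for c in concs}

    def test_midpoint_interpolation(self):
        ec = ec_from_run({10: 100, 20: 200}, self.cv_ok([10, 20]), 150)
        assert ec.value == pytest.approx(15.0)

    def test_all_below_threshold_undefined(self):
        ec = ec_from_run({10: 110, 20: 140}, self.cv_ok([10, 20]), 150)
        assert ec.value is None
        assert not ec.no_eligible

    def test_lowest_dose_already_positive_is_censored(self):
        ec = ec_from_run({10: 180, 20: 250}, self.cv_ok([10, 20]), 150)
        assert ec.value == 10
        assert ec.below_lowest

    def test_cv_gate_excludes_cytotoxic_doses(self):
        # the only dose above threshold fails the viability gate
        ec = ec_from_run({10: 120, 20: 300}, {10: 90.0, 20: 40.0}, 150)
        assert ec.value is None

    def test_all_doses_fail_gate(self):
        ec = ec_from_run({10: 300, 20: 300}, {10: 30.0, 20: 30.0}, 150)
        assert ec.value is None
        assert ec.no_eligible

    def test_recovers_hill_truth_on_main_series(self):
        truth = TruthModel(markers={
            "CD86": HillInduction(rmax=300.0, k=10.0, hill=1.0),
            "CD54": HillInduction(rmax=300.0, k=10.0, hill=1.0)})
        series = main_series(10.0).concentrations
        dose_rfi = {c: truth_rfi(truth, "CD86", c) for c in series}
        ec = ec_from_run(dose_rfi, self.cv_ok(series), 150)
        expected = truth_ec(truth, "CD86", 150)
        assert expected == pytest.approx(10 / 3)
        # truth EC sits just below the lowest tested dose: censored there
        assert ec.below_lowest
        assert ec.value == pytest.approx(expected, rel=0.15)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_agrees_with_dense_grid_oracle(self, seed):
        """EC matches a 1e5-point scan of the piecewise-linear RFI curve
        within 0.5% on monotone profiles."""
        rng = np.random.default_rng(seed)
        concs = np.sort(rng.uniform(1, 50, 8))
        rfis = np.sort(rng.uniform(80, 400, 8))
        threshold = 150.0
        if rfis.max() < threshold or rfis.min() >= threshold:
            rfis = np.linspace(90, 350, 8)
        ec = ec_from_run(dict(zip(concs, rfis)), self.cv_ok(concs), threshold)

        grid = np.linspace(concs[0], concs[-1], 100_000)
        rgrid = np.interp(grid, concs, rfis)
        at = np.nonzero(rgrid >= threshold)[0]
        oracle = grid[at[0]]
        if ec.below_lowest:
            assert oracle == pytest.approx(concs[0], rel=5e-3)
        else:
            assert ec.value == pytest.approx(oracle, rel=5e-3)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_defined_ec_iff_marker_positive(self, seed):
        """Over randomized gated 8-point profiles, an EC exists (possibly
        censored) exactly when the run's marker criterion is met."""
        rng = np.random.default_rng(seed)
        concs = main_series(20.0).concentrations[::-1]
        rfis = rng.uniform(50, 260, 8)
        cvs = rng.uniform(30, 100, 8)
        ec = ec_from_run(dict(zip(concs, rfis)), dict(zip(concs, cvs)), 150)
        results = [ConcentrationResult(c, cv, r, r)
                   for c, cv, r in zip(concs, cvs, rfis)]
        positive = marker_positive(results, "CD86", 150)
        assert (ec.value is not None) == positive


class TestFinalEc:
    @pytest.mark.parametrize("ecs, flags, expected, printed", [
        ((17.0, 11.0, None), (True, True, False), 14.0, 14),
        ((8.0, None, 6.0), (True, False, True), 7.0, 7),
        ((8.0, 25.0, 8.0), (True, True, True), 41 / 3, 14),
    ])
    def test_averaged_over_positive_runs(self, ecs, flags, expected, printed):
        value = final_ec(ecs, flags)
        assert value == pytest.approx(expected)
        assert round_half_away(value) == printed

    def test_marker_negative_runs_excluded_even_if_run_positive(self):
        # run 2 positive only via the other marker: contributes nothing here
        assert final_ec([10.0, 20.0], [True, False]) == 10.0

    def test_no_positive_run_gives_undefined(self):
        assert final_ec([None, None], [True, True]) is None
        assert final_ec([10.0], [False]) is None

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            final_ec([1.0], [True, False])


def test_round_half_away_from_zero():
    assert round_half_away(13.5) == 14
    assert round_half_away(10.666666) == 11
    assert round_half_away(-2.5) == -3
    assert round_half_away(0.163, 3) == 0.163
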