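"""Run acceptance, positivity rules, the 2-of-3 model and proficiency checks."""

import itertools

import pytest

from hclat import (ConcentrationResult, EcRunResult,
                   InsufficientRunsError, ProficiencyReference, RunResult,
                   ThirdRunRequiredError, classify_substance,
                   evaluate_proficiency, final_call, marker_positive,
                   run_acceptance)
from hclat.prediction_engine import ProficiencyResult, score_run


def conc_result(rfi_cd86=100.0, rfi_cd54=100.0, cv=90.0, conc=10.0):
    return ConcentrationResult(concentration=conc, cv_pct=cv,
                               rfi_cd86=rfi_cd86, rfi_cd54=rfi_cd54)


class TestMarkerPositive:
    def test_high_rfi_is_positive(self):
        assert marker_positive([conc_result(rfi_cd86=371.0)], "CD86")

    def test_below_threshold_negative(self):
        assert not marker_positive([conc_result(rfi_cd54=169.0)], "CD54")

    def test_inclusive_threshold_and_cv_gate(self):
        assert marker_positive([conc_result(rfi_cd86=150.0)], "CD86")
        assert not marker_positive([conc_result(rfi_cd54=200.0, cv=49.0)],
                                   "CD54")
        assert marker_positive([conc_result(rfi_cd54=200.0, cv=50.0)], "CD54")

    def test_undefined_rfi_cannot_be_positive(self):
        assert not marker_positive([conc_result(rfi_cd86=None)], "CD86")

    def test_exhaustive_against_brute_force(self):
        """Over a grid of RFI/CV combinations, positivity equals a literal
        any() over gated concentrations at the inclusive threshold."""
        levels = [None, 100.0, 149.9, 150.0, 371.0]
        cvs = [40.0, 50.0, 95.0]
        for rfis in itertools.product(levels, repeat=3):
            for cv in cvs:
                results = [conc_result(rfi_cd86=r, cv=cv, conc=i + 1.0)
                           for i, r in enumerate(rfis)]
                expected = any(r is not None and r >= 150.0 and cv >= 50.0
                               for r in rfis)
                assert marker_positive(results, "CD86") == expected


class TestRunAcceptance:
    def test_observed_control_values_pass(self):
        acc = run_acceptance(611.0, 426.0, 83.0, 97.0, [90.0] * 8)
        assert acc.accepted and not acc.reasons

    def test_dncb_failure_rejects(self):
        acc = run_acceptance(120.0, 426.0, 83.0, 97.0, [90.0] * 8)
        assert not acc.accepted
        assert any("DNCB CD86" in r for r in acc.reasons)

    def test_dncb_checks_are_strict(self):
        acc = run_acceptance(150.0, 200.0, 83.0, 97.0, [90.0] * 8)
        assert not acc.dncb_cd86_ok and not acc.dncb_cd54_ok

    def test_too_few_eligible_concentrations(self):
        acc = run_acceptance(611.0, 426.0, 83.0, 97.0,
                             [90.0, 80.0] + [30.0] * 6)
        assert not acc.accepted
        assert acc.n_eligible_concentrations == 2

    def test_missing_controls_rejected(self):
        with pytest.raises(ValueError):
            run_acceptance(None, 426.0, 83.0, 97.0, [90.0] * 8)


class TestFinalCall:
    @pytest.mark.parametrize("calls, expected", [
        ((True, False, True), True),
        ((False, False, False), False),
        ((True, True, True), True),
    ])
    def test_majority_of_three(self, calls, expected):
        call, n = final_call(calls)
        assert call is expected and n == 3

    def test_two_concordant_with_early_stop(self):
        assert final_call((True, True), allow_early_stop=True) == (True, 2)
        assert final_call((False, False), allow_early_stop=True) == (False, 2)

    def test_two_discordant_requires_third(self):
        with pytest.raises(ThirdRunRequiredError):
            final_call((True, False), allow_early_stop=True)

    def test_exhaustive_against_brute_force(self):
        """All 2^3 call patterns match a literal >= 2-of-3 vote; all 2^2
        marker-flag patterns give run_call = CD86 OR CD54."""
        for calls in itertools.product([False, True], repeat=3):
            assert final_call(calls)[0] == (sum(calls) >= 2)
        for cd86, cd54 in itertools.product([False, True], repeat=2):
            results = [conc_result(rfi_cd86=300.0 if cd86 else 100.0,
                                   rfi_cd54=300.0 if cd54 else 100.0)]
            run = score_run(1, results)
            assert run.run_call == (cd86 or cd54)
            assert run.cd86_positive == cd86 and run.cd54_positive == cd54

    def test_raising_rfi_never_flips_positive_to_negative(self):
        """Monotonicity of the decision rule in any single RFI value."""
        base = [[conc_result(rfi_cd86=160.0, conc=5.0),
                 conc_result(rfi_cd86=120.0, conc=10.0)]
                for _ in range(3)]
        runs = [score_run(i + 1, r) for i, r in enumerate(base)]
        before = final_call([r.run_call for r in runs])[0]
        assert before
        raised = [[ConcentrationResult(c.concentration, c.cv_pct,
                                       (c.rfi_cd86 or 0) + 500.0, c.rfi_cd54)
                   for c in run] for run in base]
        runs2 = [score_run(i + 1, r) for i, r in enumerate(raised)]
        assert final_call([r.run_call for r in runs2])[0]


class TestClassifySubstance:
    def make_run(self, run_id, cd86_rfi, cd54_rfi, ec150=None, ec200=None,
                 accepted=True):
        results = [conc_result(rfi_cd86=cd86_rfi, rfi_cd54=cd54_rfi)]
        acc = run_acceptance(611.0, 426.0, 83.0, 97.0,
                             [90.0] * (8 if accepted else 2))
        return RunResult(
            run_id=run_id, concentration_results=tuple(results),
            cd86_positive=cd86_rfi is not None and cd86_rfi >= 150,
            cd54_positive=cd54_rfi is not None and cd54_rfi >= 200,
            run_call=(cd86_rfi is not None and cd86_rfi >= 150)
            or (cd54_rfi is not None and cd54_rfi >= 200),
            acceptance=acc,
            ec150=EcRunResult(ec150), ec200=EcRunResult(ec200),
        )

    def test_all_positive_runs(self):
        runs = [self.make_run(1, 217.0, 3922.0, 12.0, 10.0),
                self.make_run(2, 263.0, 4622.0, 13.0, 11.0),
                self.make_run(3, 360.0, 4721.0, 9.0, 11.0)]
        pred = classify_substance("zinc oxide", runs)
        assert pred.final_call == "Positive"
        assert pred.final_ec150 == pytest.approx(34 / 3)
        assert pred.final_ec200 == pytest.approx(32 / 3)

    def test_just_below_thresholds_negative_without_ecs(self):
        runs = [self.make_run(i, 149.0, 199.0) for i in (1, 2, 3)]
        pred = classify_substance("borderline", runs)
        assert pred.final_call == "Negative"
        assert pred.final_ec150 is None and pred.final_ec200 is None

    def test_rejected_runs_are_excluded(self):
        runs = [self.make_run(1, 300.0, 300.0, ec150=5.0, accepted=False),
                self.make_run(2, 100.0, 100.0),
                self.make_run(3, 100.0, 100.0)]
        with pytest.raises(ThirdRunRequiredError):
            # two accepted discordant... here both negative and concordant,
            # but early stop is off by default
            classify_substance("x", runs)
        pred = classify_substance("x", runs, allow_early_stop=True)
        assert pred.final_call == "Negative"
        assert pred.excluded_runs == (1,)

    def test_fewer_than_two_usable_runs(self):
        runs = [self.make_run(1, 300.0, 300.0, accepted=False),
                self.make_run(2, 300.0, 300.0, accepted=False),
                self.make_run(3, 300.0, 300.0)]
        with pytest.raises(InsufficientRunsError):
            classify_substance("x", runs)


class TestProficiency:
    def test_in_range_sensitizers_pass(self):
        refs = [ProficiencyReference("nickel sulfate", "Positive",
                                     cv75_range=(30.0, 500.0)),
                ProficiencyReference("imidazolidinyl urea", "Positive",
                                     cv75_range=(25.0, 100.0))]
        results = [ProficiencyResult("nickel sulfate", "Positive",
                                     cv75=(218 + 162) / 2),
                   ProficiencyResult("imidazolidinyl urea", "Positive",
                                     cv75=(37 + 42) / 2)]
        outcomes = evaluate_proficiency(results, refs)
        assert all(o.passed for o in outcomes)
        assert outcomes[0].cv75_in_range and outcomes[1].cv75_in_range

    def test_mispredicted_sensitizer_fails_on_call(self):
        refs = [ProficiencyReference("nickel sulfate", "Positive")]
        outcomes = evaluate_proficiency(
            [ProficiencyResult("nickel sulfate", "Negative")], refs)
        assert not outcomes[0].passed and not outcomes[0].call_match

    def test_censored_cv75_skips_range_check(self):
        refs = [ProficiencyReference("lactic acid", "Negative",
                                     cv75_range=(1500.0, 5000.0))]
        outcomes = evaluate_proficiency(
            [ProficiencyResult("lactic acid", "Negative", cv75=1000.0,
                               cv75_censored=True)], refs)
        assert outcomes[0].passed
        assert outcomes[0].cv75_in_range is None

    def test_historically_negative_marker_is_non_gating(self):
        refs = [ProficiencyReference("r-limonene", "Positive",
                                     ec150_range=(5.0, None),
                                     ec150_historically_negative=True,
                                     ec200_range=(None, 250.0))]
        outcomes = evaluate_proficiency(
            [ProficiencyResult("r-limonene", "Positive", ec150=239.0,
                               ec200=121.0)], refs)
        assert outcomes[0].passed
        assert outcomes[0].ec150_in_range is None
        assert outcomes[0].ec200_in_range is True

    def test_unknown_substance_reported_unmatched(self):
        outcomes = evaluate_proficiency(
            [ProficiencyResult("mystery", "Positive")], [])
        assert not outcomes[0].passed
        assert "no reference" in outcomes[0].notes[0]
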