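"""Dose-response IC50, sensitization, and apoptosis quadrant statistics."""
import numpy as np
import pandas as pd
import pytest

from kinomeflow import (
    DoseResponseCurve,
    InvalidParameterError,
    UndefinedIC50Error,
    classify_events,
    estimate_ic50,
    sensitization_test,
)
from kinomeflow.pharm import fit_four_param_logistic
from kinomeflow.synthetic_data import (
    DEFAULT_FLOW_GATES,
    simulate_dose_response,
    simulate_flow_events,
)


def test_ic50_exact_for_linear_in_log_data():
    curve = DoseResponseCurve(np.array([1.0, 10.0, 100.0]),
                              np.array([[100.0], [50.0], [0.0]]))
    fit = estimate_ic50(curve)
    assert fit.ic50 == pytest.approx(10.0, rel=1e-9)
    assert not fit.extrapolated


def test_ic50_recovery_from_logistic_curve():
    curve = simulate_dose_response(10.0, 1.0,
                                   [1, 2.15, 4.64, 10, 21.5, 46.4, 100],
                                   n_reps=3, noise_sd=0.0)
    fit = estimate_ic50(curve)
    assert fit.ic50 == pytest.approx(10.0, rel=0.05)
    # the 4PL alternative recovers the midpoint essentially exactly
    assert fit_four_param_logistic(curve)["ic50"] == pytest.approx(10.0, rel=1e-3)


def test_ic50_undefined_for_flat_or_rising_curves():
    flat = DoseResponseCurve(np.array([1.0, 10.0]), np.array([[100.0], [100.0]]))
    with pytest.raises(UndefinedIC50Error):
        estimate_ic50(flat)
    rising = DoseResponseCurve(np.array([1.0, 10.0]), np.array([[40.0], [80.0]]))
    with pytest.raises(UndefinedIC50Error):
        estimate_ic50(rising)


def test_ic50_extrapolation_flag():
    # midpoint far above the tested range
    curve = simulate_dose_response(500.0, 1.0, [1, 3, 10, 30], n_reps=2,
                                   noise_sd=0.0)
    fit = estimate_ic50(curve, allow_extrapolation=True)
    assert fit.extrapolated
    with pytest.raises(UndefinedIC50Error):
        estimate_ic50(curve, allow_extrapolation=False)


def test_ic50_unit_rescaling_consistency():
    conc = np.array([1, 3.16, 10, 31.6, 100.0])
    curve = simulate_dose_response(10.0, 1.2, conc, n_reps=2, noise_sd=0.0)
    fit_um = estimate_ic50(curve)
    nm = DoseResponseCurve(conc * 1000.0, curve.viabilities)
    fit_nm = estimate_ic50(nm)
    assert fit_nm.ic50 == pytest.approx(fit_um.ic50 * 1000.0, rel=1e-9)


def test_ic50_median_recovery_under_noise():
    recovered = []
    for seed in range(25):
        curve = simulate_dose_response(
            10.0, 1.0, [1, 2.15, 4.64, 10, 21.5, 46.4, 100],
            n_reps=3, noise_sd=0.05, seed=seed,
        )
        recovered.append(estimate_ic50(curve).ic50)
    assert np.median(recovered) == pytest.approx(10.0, rel=0.15)


def test_dose_response_tsv_round_trip(tmp_path):
    curve = simulate_dose_response(5.0, 1.0, [1, 5, 25], n_reps=3,
                                   noise_sd=0.02, seed=4)
    curve.to_tsv(tmp_path / "dr.tsv")
    back = DoseResponseCurve.from_tsv(tmp_path / "dr.tsv")
    assert np.allclose(back.concentrations, curve.concentrations)
    assert np.allclose(back.viabilities, curve.viabilities)


def test_sensitization_detected():
    res = sensitization_test((80, 82, 78), (40, 42, 38))
    assert res.sensitized and res.p_value < 0.001
    assert res.mean_difference == pytest.approx(40.0)


def test_sensitization_requires_direction_and_significance():
    same = sensitization_test((50, 50, 50), (50, 50, 50))
    assert not same.sensitized and same.p_value == 1.0
    higher = sensitization_test((40, 42, 38), (80, 82, 78))
    assert not higher.sensitized and higher.p_value < 0.001


def test_quadrant_definitions():
    events = pd.DataFrame({
        "annexin": [0.5, 2.0, 2.0, 0.5],
        "aad7":    [0.5, 0.5, 2.0, 2.0],
    })
    res = classify_events(events, (1.0, 1.0))
    assert res.counts == {"live": 1, "early_apoptosis": 1,
                          "late_apoptosis": 1, "non_apoptotic_death": 1}
    assert sum(res.percentages.values()) == pytest.approx(100.0)


def test_events_at_gate_are_negative():
    events = pd.DataFrame({"annexin": [1.0, 1.0], "aad7": [1.0, 0.0]})
    res = classify_events(events, (1.0, 1.0))
    assert res.counts["live"] == 2  # strict positivity: at-gate is negative


def test_quadrant_partition_and_empty_table(rng):
    events = pd.DataFrame({"annexin": rng.normal(1, 1, 500),
                           "aad7": rng.normal(1, 1, 500)})
    res = classify_events(events, (0.7, 1.3))
    assert res.total == 500
    empty = classify_events(pd.DataFrame({"annexin": [], "aad7": []}), (1, 1))
    assert empty.total == 0 and empty.percentages is None


def test_exact_counts_round_trip():
    events = simulate_flow_events(10000, (0.6, 0.1, 0.2, 0.1), seed=9,
                                  exact_counts=True)
    res = classify_events(events, DEFAULT_FLOW_GATES)
    assert res.percentages == {
        "live": 60.0, "early_apoptosis": 10.0,
        "late_apoptosis": 20.0, "non_apoptotic_death": 10.0,
    }
    # classification agrees with the generator's planted labels
    assert (events["true_quadrant"].value_counts().to_dict()
            == res.counts)
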