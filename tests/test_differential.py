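"""Differential calling: Welch test, fold-change classes, invariances."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kinomeflow import (
    DifferentialParams,
    InvalidParameterError,
    call_differential,
    export_volcano_table,
    welch_t_test,
)
from kinomeflow.differential import (
    CLASS_DOWN,
    CLASS_NOT_SIGNIFICANT,
    CLASS_UP,
    VOLCANO_REFERENCE_FCS,
)
from kinomeflow.reliability_qc import apply_filter
from kinomeflow.synthetic_data import make_layout


def _all_pass_verdicts(substrates, reps=(10.0, 10.0, 10.0)):
    frame = pd.DataFrame.from_dict({s: reps for s in substrates}, orient="index")
    return apply_filter({"chip": frame})


def test_welch_identical_groups():
    t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
    assert t == 0.0 and p == 1.0


def test_welch_known_example():
    t, df, p = welch_t_test([1, 2, 3], [4, 5, 6])
    assert t == pytest.approx(-3.674, abs=1e-3)
    assert df == pytest.approx(4.0)
    assert p == pytest.approx(0.0212, abs=2e-4)


def test_welch_antisymmetry():
    t1, df1, p1 = welch_t_test([1.0, 4.0, 5.0], [2.0, 9.0])
    t2, df2, p2 = welch_t_test([2.0, 9.0], [1.0, 4.0, 5.0])
    assert t1 == pytest.approx(-t2)
    assert df1 == pytest.approx(df2)
    assert p1 == pytest.approx(p2)


def test_welch_matches_scipy_on_random_groups(rng):
    for _ in range(50):
        a = rng.lognormal(0, 0.5, rng.integers(2, 8))
        b = rng.lognormal(0.3, 0.8, rng.integers(2, 8))
        t, df, p = welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)


def test_welch_zero_variance_conventions():
    assert welch_t_test([5, 5], [5, 5])[2] == 1.0
    t, _, p = welch_t_test([5, 5], [7, 7])
    assert p == 0.0 and t == -math.inf
    with pytest.raises(InvalidParameterError):
        welch_t_test([1], [1, 2])


@pytest.mark.parametrize(
    "ctrl, expt, fc, cls",
    [
        ((1, 2, 3), (4, 5, 6), 2.5, CLASS_UP),
        ((1, 2, 3), (1, 2, 3), 1.0, CLASS_NOT_SIGNIFICANT),
        ((4, 5, 6), (1, 2, 3), 0.4, CLASS_DOWN),
    ],
)
def test_call_differential_examples(ctrl, expt, fc, cls):
    verdicts = _all_pass_verdicts(["s1"])
    result = call_differential({"s1": ctrl}, {"s1": expt}, verdicts)
    (rec,) = result.records
    assert rec.fold_change == pytest.approx(fc)
    assert rec.class_label == cls
    if cls != CLASS_NOT_SIGNIFICANT:
        assert rec.p_value == pytest.approx(0.0212, abs=2e-4)


def test_rejected_substrates_carry_no_class():
    verdicts = apply_filter(
        {"chip": pd.DataFrame.from_dict(
            {"good": (10.0, 10.0, 10.0), "bad": (1.0, 1.0, 10.0)}, orient="index")}
    )
    result = call_differential(
        {"good": (1, 2, 3), "bad": (1, 2, 3)},
        {"good": (4, 5, 6), "bad": (4, 5, 6)},
        verdicts,
    )
    assert [r.substrate_id for r in result.records] == ["good"]
    assert result.excluded == {"bad": "rejected_qc"}


def test_zero_control_median_excluded():
    verdicts = _all_pass_verdicts(["s1"])
    result = call_differential({"s1": (-1.0, 0.0, 1.0)}, {"s1": (4, 5, 6)}, verdicts)
    assert not result.records
    assert result.excluded == {"s1": "zero_median"}


def test_scale_invariance(rng):
    ctrl = {"s1": rng.lognormal(0, 0.1, 3)}
    expt = {"s1": rng.lognormal(1.0, 0.1, 3)}
    verdicts = _all_pass_verdicts(["s1"])
    r1 = call_differential(ctrl, expt, verdicts).records[0]
    k = 37.5
    r2 = call_differential({"s1": ctrl["s1"] * k}, {"s1": expt["s1"] * k},
                           verdicts).records[0]
    assert r2.fold_change == pytest.approx(r1.fold_change)
    assert r2.p_value == pytest.approx(r1.p_value)
    assert r2.class_label == r1.class_label


def test_reciprocity_under_label_swap(rng):
    ctrl = {"s1": rng.lognormal(0, 0.05, 3)}
    expt = {"s1": rng.lognormal(1.0, 0.05, 3)}
    verdicts = _all_pass_verdicts(["s1"])
    fwd = call_differential(ctrl, expt, verdicts).records[0]
    rev = call_differential(expt, ctrl, verdicts).records[0]
    assert rev.fold_change == pytest.approx(1.0 / fwd.fold_change)
    assert rev.p_value == pytest.approx(fwd.p_value)
    assert {fwd.class_label, rev.class_label} == {CLASS_UP, CLASS_DOWN}


def test_invalid_params_rejected():
    with pytest.raises(InvalidParameterError):
        DifferentialParams(fc_up=0.5, fc_down=0.75)
    with pytest.raises(InvalidParameterError):
        DifferentialParams(alpha=0.0)


def test_bh_qvalues_opt_in(rng):
    subs = [f"s{i}" for i in range(20)]
    ctrl = {s: rng.lognormal(0, 0.1, 3) for s in subs}
    expt = {s: rng.lognormal(0, 0.1, 3) for s in subs}
    verdicts = _all_pass_verdicts(subs)
    plain = call_differential(ctrl, expt, verdicts)
    assert all(r.q_value is None for r in plain.records)
    with_q = call_differential(ctrl, expt, verdicts,
                               DifferentialParams(bh_qvalues=True))
    from statsmodels.stats.multitest import multipletests

    expected = multipletests([r.p_value for r in with_q.records],
                             method="fdr_bh")[1]
    assert np.allclose([r.q_value for r in with_q.records], expected)


def test_volcano_table_contents():
    layout = make_layout(2, 3, 1.0, seed=0)
    verdicts = _all_pass_verdicts(["pep0000", "pep0001"])
    result = call_differential(
        {"pep0000": (1, 2, 3), "pep0001": (1, 2, 3)},
        {"pep0000": (4, 5, 6), "pep0001": (1.0, 2.0, 3.1)},
        verdicts,
    )
    table = export_volcano_table(result.records, layout)
    assert list(table["p_value"]) == sorted(table["p_value"])
    up = table.set_index("substrate_id").loc["pep0000"]
    assert up["log2_fc"] == pytest.approx(math.log2(2.5), abs=1e-4)
    assert up["kinase"] != ""
    assert VOLCANO_REFERENCE_FCS == (0.5, 1.0, 2.0)
    assert export_volcano_table([]).empty
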