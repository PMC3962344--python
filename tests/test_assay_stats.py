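"""Condition summaries, t-tests, drug categories, dosing and dose-response shape."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from larvatrack.assay_stats import (
    AssayDesign,
    ConditionSummary,
    classify_drug,
    dose_response_table,
    final_concentration,
    summarize_condition,
    two_sided_t_test,
)
from larvatrack.errors import AnalysisError, ConfigError, InputError
from larvatrack.tracking import DishSeries


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t statistic, written independently."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))


def test_t_test_identical_samples():
    t, df, p = two_sided_t_test([1, 2, 3], [1, 2, 3])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_t_test_closed_form():
    t, df, p = two_sided_t_test([1, 2, 3], [4, 5, 6])
    assert t == pytest.approx(pooled_t_oracle([1, 2, 3], [4, 5, 6]), rel=1e-12)
    assert t == pytest.approx(-3.674, abs=5e-4)
    assert df == 4
    assert p == pytest.approx(0.0213, abs=5e-5)


def test_t_test_zero_variance_rules():
    assert two_sided_t_test([0, 0], [1, 1])[2] == 0.0
    assert two_sided_t_test([2, 2], [2, 2])[2] == 1.0


@given(
    a=st.lists(st.floats(-100, 100), min_size=2, max_size=8),
    b=st.lists(st.floats(-100, 100), min_size=2, max_size=8),
)
def test_t_test_symmetry(a, b):
    t1, df1, p1 = two_sided_t_test(a, b)
    t2, df2, p2 = two_sided_t_test(b, a)
    assert df1 == df2
    assert t1 == pytest.approx(-t2, rel=1e-9, abs=1e-12) or (t1 == 0 and t2 == 0)
    if math.isfinite(t1):
        assert p1 == pytest.approx(p2, rel=1e-9, abs=1e-12)


def one_point_series(label, value, rep):
    """A replicate whose whole analysis-window cumulative distance is `value`."""
    return DishSeries(
        dish_id=f"{label}-{rep}",
        condition_label=label,
        time_s=np.array([1.0]),
        distance_px=np.array([float(value)]),
        n_fish_moved=np.array([1]),
    )


def design():
    return AssayDesign(stimulus_label="stim", analysis_window_s=(0.0, 10.0))


def test_summary_hand_arithmetic():
    """Drug {50,60,70} vs stimulus {100,110,120}: percent = 100*60/110."""
    series = [one_point_series("drug", v, i) for i, v in enumerate([50, 60, 70])]
    series += [one_point_series("stim", v, i) for i, v in enumerate([100, 110, 120])]
    s = summarize_condition(series, design(), "drug")
    assert s.percent_of_stimulus == pytest.approx(100 * 60 / 110)
    assert s.n_replicates == 3
    assert s.se_cumulative_px == pytest.approx(10 / math.sqrt(3))
    t, df, p = two_sided_t_test([50, 60, 70], [100, 110, 120])
    assert s.t_stat == pytest.approx(t) and s.p_value == pytest.approx(p)


def test_summary_stimulus_vs_itself():
    series = [one_point_series("stim", v, i) for i, v in enumerate([100, 110, 120])]
    s = summarize_condition(series, design(), "stim")
    assert s.percent_of_stimulus == 100.0
    assert s.p_value is None  # degenerate self-comparison is reported absent


def test_summary_zero_drug_and_zero_stimulus():
    series = [one_point_series("drug", 0, i) for i in range(3)]
    series += [one_point_series("stim", v, i) for i, v in enumerate([100, 110, 120])]
    assert summarize_condition(series, design(), "drug").percent_of_stimulus == 0.0
    zeros = [one_point_series("stim", 0, i) for i in range(3)]
    with pytest.raises(AnalysisError):
        summarize_condition(zeros + series[:3], design(), "drug")


def test_summary_single_replicate_warns_no_p():
    series = [one_point_series("drug", 50, 0)]
    series += [one_point_series("stim", v, i) for i, v in enumerate([100, 110, 120])]
    with pytest.warns(UserWarning):
        s = summarize_condition(series, design(), "drug")
    assert s.p_value is None


@given(k=st.floats(min_value=1e-3, max_value=1e3))
def test_percent_and_t_are_scale_invariant(k):
    base_drug, base_stim = [50, 60, 70], [100, 110, 120]
    series = [one_point_series("drug", v * k, i) for i, v in enumerate(base_drug)]
    series += [one_point_series("stim", v * k, i) for i, v in enumerate(base_stim)]
    s = summarize_condition(series, design(), "drug")
    assert s.percent_of_stimulus == pytest.approx(100 * 60 / 110, rel=1e-9)
    assert s.t_stat == pytest.approx(two_sided_t_test(base_drug, base_stim)[0], rel=1e-9)


def summary(label, percent, p):
    return ConditionSummary(
        condition_label=label, n_replicates=3, mean_cumulative_px=percent,
        se_cumulative_px=1.0, percent_of_stimulus=percent, t_stat=0.0, df=4.0, p_value=p,
    )


def test_classify_category_iv():
    """Significant nicotine-only attenuation with quiet oil controls."""
    cat = classify_drug(summary("nic", 40, 0.01), summary("cin", 95, 0.4),
                        summary("mus", 102, 0.7))
    assert cat.label == "iv"
    assert cat.nicotine_attenuated and not cat.control_attenuated


def test_classify_category_iii():
    cat = classify_drug(summary("nic", 35, 0.01), summary("cin", 50, 0.02),
                        summary("mus", 90, 0.5))
    assert cat.label == "iii"


def test_classify_categories_i_and_ii():
    assert classify_drug(summary("nic", 90, 0.6), summary("cin", 100, 0.9),
                         summary("mus", 100, 0.9), toxicity_observed=False).label == "i"
    assert classify_drug(summary("nic", 90, 0.6), summary("cin", 100, 0.9),
                         summary("mus", 100, 0.9), toxicity_observed=True).label == "ii"


def test_classify_potentiation_never_attenuation():
    cat = classify_drug(summary("nic", 150, 0.01), summary("cin", 100, 0.9),
                        summary("mus", 100, 0.9))
    assert cat.label == "i" and cat.potentiation and not cat.nicotine_attenuated


def test_classify_provisional_without_controls():
    with pytest.warns(UserWarning):
        cat = classify_drug(summary("nic", 40, 0.01))
    assert cat.label == "iv" and cat.provisional


@given(
    nic_pct=st.floats(1, 200), nic_p=st.floats(0.0001, 1),
    cin_pct=st.floats(1, 200), cin_p=st.floats(0.0001, 1),
    tox=st.booleans(),
)
def test_classification_exhaustive_and_exclusive(nic_pct, nic_p, cin_pct, cin_p, tox):
    cat = classify_drug(summary("nic", nic_pct, nic_p), summary("cin", cin_pct, cin_p),
                        summary("mus", 100, 0.9), toxicity_observed=tox)
    assert cat.label in {"i", "ii", "iii", "iv"}
    if cat.label == "iv":
        assert cat.nicotine_attenuated and not cat.control_attenuated
    if cat.label == "iii":
        assert cat.nicotine_attenuated and cat.control_attenuated
    if cat.label in {"i", "ii"}:
        assert not cat.nicotine_attenuated
        assert (cat.label == "ii") == tox


def test_final_concentration_cases():
    assert final_concentration(400.0, 0.5, 10.0) == 20.0
    assert final_concentration(123.0, 4.0, 4.0) == 123.0
    assert final_concentration(100.0, 1.0, 4.0) == 25.0
    with pytest.raises(InputError):
        final_concentration(100.0, -1.0, 4.0)
    with pytest.raises(InputError):
        final_concentration(100.0, 5.0, 4.0)


@given(c=st.floats(0, 1e4), v=st.floats(0.01, 10.0), k=st.floats(0.1, 10.0))
def test_final_concentration_linear(c, v, k):
    total = 20.0
    if k * v > total:
        return
    assert final_concentration(k * c, v, total) == pytest.approx(
        k * final_concentration(c, v, total), rel=1e-12, abs=1e-12
    )
    assert final_concentration(c, k * v, total) == pytest.approx(
        k * final_concentration(c, v, total), rel=1e-12, abs=1e-12
    )


def mean_summary(label, mean):
    return ConditionSummary(condition_label=label, n_replicates=3,
                            mean_cumulative_px=mean, se_cumulative_px=1.0,
                            percent_of_stimulus=100.0)


def test_dose_response_shapes():
    table, peak, inv_u = dose_response_table(
        [(10, mean_summary("a", 50)), (100, mean_summary("c", 40)),
         (30, mean_summary("b", 120))]
    )
    assert peak == 30 and inv_u
    assert list(table["dose"]) == [10, 30, 100]
    _, peak2, inv2 = dose_response_table(
        [(1, mean_summary("a", 10)), (2, mean_summary("b", 20)),
         (3, mean_summary("c", 30))]
    )
    assert peak2 == 3 and not inv2
    with pytest.raises(InputError):
        dose_response_table([(1, mean_summary("a", 1)), (1, mean_summary("b", 2)),
                             (2, mean_summary("c", 3))])


def test_design_validation():
    with pytest.raises(ConfigError):
        AssayDesign(analysis_window_s=(-10.0, 240.0))
    with pytest.raises(ConfigError):
        AssayDesign(baseline_window_s=(0.0, 100.0), analysis_window_s=(50.0, 240.0))
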