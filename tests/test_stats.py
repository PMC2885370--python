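"""ANOVA, Cochran's C, SNK, decay and linear fits, FDR correction."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodeid import (
    anova_2way_mixed,
    cochran_c,
    compare_decay_curves,
    fdr_correct,
    fit_exp_decay,
    fit_linear,
    pairwise_f_test,
    snk_test,
)
from barcodeid.stats import cell_variances


def _table(values):
    """values: array (criteria, orders, replicates) -> long frame."""
    values = np.asarray(values, float)
    rows = []
    for (i, j, k) in itertools.product(*(range(s) for s in values.shape)):
        rows.append(
            {
                "criterion": f"C{i}",
                "order": f"O{j}",
                "replicate": k + 1,
                "proportion_correct": values[i, j, k],
            }
        )
    return pd.DataFrame(rows)


def test_anova_df_and_partition_identity():
    rng = np.random.default_rng(0)
    tab = _table(rng.uniform(0.5, 1.0, size=(3, 6, 3)))
    res = anova_2way_mixed(tab)
    assert res["df"].tolist() == [2, 5, 10, 36, 53]
    parts = res.loc[["Cr", "Or", "Cr x Or", "Residual"], "SS"].sum()
    assert parts == pytest.approx(res.at["Total", "SS"], rel=1e-10)
    assert res.at["Cr", "denominator"] == "Cr x Or"
    assert res.at["Or", "denominator"] == "Residual"


def test_anova_constant_input_degenerates_cleanly():
    res = anova_2way_mixed(_table(np.full((3, 6, 3), 0.7)))
    assert res.at["Total", "SS"] == pytest.approx(0.0, abs=1e-24)
    assert math.isnan(res.at["Cr", "F"])


def test_anova_detects_planted_criterion_effect():
    rng = np.random.default_rng(1)
    base = rng.normal(0, 0.01, size=(3, 6, 3))
    effects = np.array([-0.15, 0.0, 0.15])[:, None, None]
    res = anova_2way_mixed(_table(0.8 + effects + base))
    assert res.at["Cr", "p"] < 0.001
    assert res.at["Cr", "stars"] == "***"


def test_anova_rejects_unbalanced_design():
    tab = _table(np.zeros((3, 6, 3))).iloc[:-1]
    with pytest.raises(ValueError, match="balanced"):
        anova_2way_mixed(tab)


def test_cochran_c_arithmetic():
    C, _, _ = cochran_c(np.ones(18), df=2)
    assert C == pytest.approx(1 / 18)
    C, _, sig = cochran_c(np.array([1.0] + [0.0] * 17), df=2)
    assert C == pytest.approx(1.0) and sig
    C, _, _ = cochran_c(np.array([4.0] + [1.0] * 17), df=2)
    assert C == pytest.approx(4 / 21)
    C, crit, sig = cochran_c(np.zeros(18), df=2)
    assert math.isnan(C) and not sig


def test_cell_variances_shape():
    tab = _table(np.random.default_rng(3).uniform(size=(3, 6, 3)))
    assert cell_variances(tab).shape == (18,)


def test_snk_separates_distant_mean_and_merges_close_ones():
    res = snk_test({"BM": 0.95, "BCM": 0.95, "NJT": 0.65},
                   ms_error=0.001, df_error=10, n_per_mean=18)
    assert res.relation in ("BM = BCM > NJT", "BCM = BM > NJT")
    res = snk_test({"A": 0.9, "B": 0.9, "C": 0.9},
                   ms_error=0.01, df_error=10, n_per_mean=6)
    assert len(res.subsets) == 1
    with pytest.raises(ValueError):
        snk_test({"A": 1.0, "B": 0.5}, 0.1, 0, 3)


def test_decay_fit_exact_recovery_on_noiseless_data():
    x = np.array([22.0, 55.0, 110.0, 164.0, 220.0, 658.0])
    y = 0.92 + (-1.2) * np.exp(-x / 50.0)
    fit = fit_exp_decay(x, y)
    assert fit.y0 == pytest.approx(0.92, abs=1e-6)
    assert fit.a == pytest.approx(-1.2, abs=1e-6)
    assert fit.t == pytest.approx(50.0, abs=1e-4)
    assert fit.rss < 1e-12
    assert fit.r2 == pytest.approx(1.0)


def test_decay_fit_constant_input_degenerates_cleanly():
    x = np.array([10.0, 20.0, 40.0, 80.0])
    fit = fit_exp_decay(x, np.full(4, 0.8))
    assert fit.y0 + fit.a * math.exp(-x[0] / fit.t) == pytest.approx(0.8, abs=1e-6)
    assert fit.r2 == 0.0


def test_decay_fit_input_validation():
    with pytest.raises(ValueError):
        fit_exp_decay([1.0, 2.0, 3.0], [1, 2, 3])
    with pytest.raises(ValueError):
        fit_exp_decay([0.0, 1.0, 2.0, 3.0], [1, 2, 3, 4])


def test_pairwise_f_test_identical_symmetric_and_sensitive():
    x = np.array([22.0, 55.0, 110.0, 164.0, 220.0, 658.0])
    rng = np.random.default_rng(2)
    y = 0.9 - 1.0 * np.exp(-x / 60.0) + rng.normal(0, 0.005, x.size)
    F, p = compare_decay_curves(x, y, x, y)
    assert F == pytest.approx(0.0, abs=1e-6)
    assert p > 0.99
    y2 = 0.7 - 0.8 * np.exp(-x / 300.0) + rng.normal(0, 0.005, x.size)
    F_ab, p_ab = compare_decay_curves(x, y, x, y2)
    F_ba, p_ba = compare_decay_curves(x, y2, x, y)
    assert F_ab == pytest.approx(F_ba, rel=1e-9)
    assert p_ab < 0.01


def test_fdr_bh_arithmetic():
    np.testing.assert_allclose(fdr_correct([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert fdr_correct([0.2]) == pytest.approx([0.2])
    np.testing.assert_allclose(fdr_correct([1.0, 1.0, 1.0]), [1.0] * 3)
    with pytest.raises(ValueError):
        fdr_correct([0.5, 1.5])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
def test_fdr_bh_is_monotone_and_bounded(p):
    adj = fdr_correct(p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
    assert np.all((adj >= np.asarray(p) - 1e-12) & (adj <= 1.0))


def test_linear_fit_exact_line_and_residual_identity():
    x = np.array([100.0, 500.0, 1000.0, 1500.0, 1995.0])
    y = 1.0 - 2e-5 * x
    fit = fit_linear(x, y)
    assert fit.b == pytest.approx(-2e-5, rel=1e-9)
    assert fit.a == pytest.approx(1.0, rel=1e-9)
    rng = np.random.default_rng(4)
    y_noisy = y + rng.normal(0, 0.01, x.size)
    fit2 = fit_linear(x, y_noisy)
    residuals = y_noisy - (fit2.a + fit2.b * x)
    assert residuals.sum() == pytest.approx(0.0, abs=1e-10)
    assert 0 <= fit2.r2 <= 1
    with pytest.raises(ValueError):
        fit_linear([1.0, 1.0, 1.0], [1, 2, 3])
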