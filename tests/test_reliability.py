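"""ICC, COR, Bland-Altman, paired t, and the tabulated report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from octlayers.errors import (
    DegenerateTestError,
    IncompleteDesignError,
    InvalidInputError,
    SampleSizeError,
)
from octlayers.phantom import simulate_study
from octlayers.reliability import (
    bland_altman,
    cor_percent,
    icc,
    paired_t,
    reliability_report,
    validate_table,
)


def icc_oracle(x, form="consistency"):
    """Two-way ANOVA by the definitional sums of squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ssr = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if form == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_icc_identical_columns_is_one():
    x = np.array([[10.0, 10.0], [20.0, 20.0], [30.0, 30.0]])
    assert icc(x) == pytest.approx(1.0)


def test_icc_degenerate_all_equal_warns_nan():
    with pytest.warns(RuntimeWarning):
        out = icc(np.full((4, 2), 7.0))
    assert np.isnan(out)


def test_icc_against_anova_oracle_small_matrix():
    x = np.array([[10.0, 12.0], [20.0, 19.0], [30.0, 31.0]])
    assert icc(x) == pytest.approx(icc_oracle(x), abs=1e-12)


def test_icc_matches_oracle_random(rng):
    for _ in range(100):
        n = int(rng.integers(3, 9))
        k = int(rng.integers(2, 5))
        x = rng.normal(50, 10, size=(n, k)) + rng.normal(0, 5, size=(n, 1))
        for form in ("consistency", "agreement"):
            assert icc(x, form) == pytest.approx(icc_oracle(x, form), abs=1e-10)


def test_icc_against_pingouin(rng):
    """Independent cross-check of both forms against pingouin's ICC3/ICC2."""
    pingouin = pytest.importorskip("pingouin")
    x = rng.normal(100, 15, size=(12, 3)) + rng.normal(0, 4, size=(12, 1))
    frame = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(12), 3),
            "rater": np.tile(np.arange(3), 12),
            "score": x.ravel(),
        }
    )
    table = pingouin.intraclass_corr(
        frame, targets="subject", raters="rater", ratings="score"
    ).set_index("Type")["ICC"]
    assert icc(x, "consistency") == pytest.approx(table["ICC(C,1)"], abs=1e-6)
    assert icc(x, "agreement") == pytest.approx(table["ICC(A,1)"], abs=1e-6)


def test_icc_invariances(rng):
    x = rng.normal(40, 8, size=(10, 2)) + rng.normal(0, 6, size=(10, 1))
    base = icc(x)
    assert icc(x + 100.0) == pytest.approx(base, abs=1e-9)
    assert icc(x * 3.7) == pytest.approx(base, abs=1e-9)


def test_icc_input_validation():
    with pytest.raises(SampleSizeError):
        icc(np.ones((2, 2)))
    with pytest.raises(SampleSizeError):
        icc(np.ones((5, 1)))
    bad = np.ones((4, 2))
    bad[1, 1] = np.nan
    with pytest.raises(IncompleteDesignError):
        icc(bad)


def test_icc_parameter_recovery():
    """n=20, k=2, sigma_b=15, sigma_w=1: mean estimate near 225/226."""
    rng = np.random.default_rng(3)
    estimates = []
    for _ in range(500):
        subj = rng.normal(0, 15, size=(20, 1))
        x = 292.0 + subj + rng.normal(0, 1, size=(20, 2))
        estimates.append(icc(x))
    assert np.mean(estimates) == pytest.approx(225 / 226, abs=0.002)


def test_cor_identical_measurements_zero():
    t = np.array([10.0, 20.0, 30.0])
    assert cor_percent(t, t) == 0.0


def test_cor_hand_arithmetic():
    t1 = np.array([10.0, 20.0, 30.0])
    t2 = np.array([12.0, 18.0, 33.0])
    # diffs (-2, 2, -3): SD 2.6458; pooled mean 20.5 -> 12.906%
    assert cor_percent(t1, t2) == pytest.approx(12.906, abs=0.001)


def test_cor_scale_invariant_and_symmetric(rng):
    t1 = rng.uniform(10, 50, size=8)
    t2 = t1 + rng.normal(0, 2, size=8)
    assert cor_percent(3 * t1, 3 * t2) == pytest.approx(cor_percent(t1, t2), abs=1e-9)
    assert cor_percent(t2, t1) == pytest.approx(cor_percent(t1, t2), abs=1e-12)


def test_cor_rejects_nonpositive_mean():
    with pytest.raises(InvalidInputError):
        cor_percent(np.array([-5.0, 5.0]), np.array([5.0, -5.0]))


def test_bland_altman_constant_difference():
    a = np.array([10.0, 20.0, 30.0])
    out = bland_altman(a + 2.0, a)
    assert (out.mean_diff, out.loa_low, out.loa_high) == (2.0, 2.0, 2.0)
    same = bland_altman(a, a)
    assert (same.mean_diff, same.loa_low, same.loa_high) == (0.0, 0.0, 0.0)


@given(
    st.lists(st.floats(-100, 100), min_size=2, max_size=30),
    st.lists(st.floats(-100, 100), min_size=2, max_size=30),
)
def test_bland_altman_algebra(a, b):
    n = min(len(a), len(b))
    a = np.asarray(a[:n])
    b = np.asarray(b[:n])
    out = bland_altman(a, b)
    assert (out.loa_low + out.loa_high) / 2 == pytest.approx(out.mean_diff, abs=1e-9)
    sd = np.std(a - b, ddof=1)
    assert out.loa_high - out.loa_low == pytest.approx(2 * 1.96 * sd, rel=1e-9, abs=1e-9)


def test_paired_t_zero_offset():
    a = np.array([10.0, 20.0, 30.0, 40.0])
    t, df, p = paired_t(a, a + np.array([1.0, -1.0, 1.0, -1.0]))
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_paired_t_hand_arithmetic():
    t, df, p = paired_t(np.array([1.0, 3.0]), np.array([0.0, 0.0]))
    assert t == pytest.approx(2.0)
    assert df == 1


def test_paired_t_degenerate():
    a = np.array([1.0, 2.0, 3.0])
    with pytest.raises(DegenerateTestError):
        paired_t(a, a + 5.0)


def test_paired_t_p_matches_quadrature(rng):
    """Two-sided p equals the numerically integrated t-density tail."""
    from math import lgamma

    from scipy.integrate import quad

    def t_pdf(x, df):
        return np.exp(
            lgamma((df + 1) / 2)
            - lgamma(df / 2)
            - 0.5 * np.log(df * np.pi)
            - (df + 1) / 2 * np.log1p(x * x / df)
        )

    for _ in range(10):
        n = int(rng.integers(3, 12))
        a = rng.normal(10, 2, size=n)
        b = a + rng.normal(0.5, 1, size=n)
        t, df, p = paired_t(a, b)
        tail, _ = quad(t_pdf, abs(t), np.inf, args=(df,))
        assert p == pytest.approx(2 * tail, abs=1e-6)


def make_table(n=6, sigma=0.0, seed=0, offset_b=0.0):
    rng = np.random.default_rng(seed)
    base = rng.uniform(200, 300, size=n)
    rows = []
    for inst in ("uhr", "rtvue100"):
        for s in range(n):
            for examiner, repeats in ((1, (1, 2)), (2, (1,))):
                for rep in repeats:
                    value = base[s] + rng.normal(0, sigma)
                    if inst == "rtvue100":
                        value += offset_b
                    rows.append(
                        dict(
                            subject=s,
                            layer="Total",
                            meridian="horizontal",
                            instrument=inst,
                            examiner=examiner,
                            repeat=rep,
                            thickness_um=value,
                        )
                    )
    return pd.DataFrame(rows)


def test_report_duplicate_repeats_give_perfect_reliability():
    table = make_table(sigma=0.0)
    rep = reliability_report(table, "repeatability")
    assert np.allclose(rep["icc"], 1.0)
    assert np.allclose(rep["cor_percent"], 0.0)


def test_report_reproducibility_design():
    table = make_table(sigma=1.0, seed=4)
    rep = reliability_report(table, "reproducibility")
    assert set(rep["instrument"]) == {"uhr", "rtvue100"}
    assert (rep["icc"] > 0.9).all()


def test_report_agreement_recovers_injected_offset():
    """Instrument B = A + 13 µm exactly: mean_diff -13, zero-width LoA,
    degenerate paired t reported as NaN."""
    table = make_table(sigma=0.0, offset_b=13.0)
    rep = reliability_report(table, "agreement")
    row = rep.iloc[0]
    assert row.instrument == "rtvue100 - uhr"
    assert row.mean_diff_um == pytest.approx(13.0)
    assert row.loa_high_um - row.loa_low_um == pytest.approx(0.0)
    assert np.isnan(row.t_stat) and np.isnan(row.p_value)


def test_report_missing_cells_named():
    table = make_table()
    table = table[~((table.subject == 2) & (table.repeat == 2))]
    with pytest.raises(IncompleteDesignError):
        reliability_report(table, "repeatability")


def test_validate_table_rejects_duplicates_and_nonpositive():
    table = make_table()
    with pytest.raises(InvalidInputError):
        validate_table(pd.concat([table, table.iloc[[0]]]))
    bad = table.copy()
    bad.loc[0, "thickness_um"] = -1.0
    with pytest.raises(InvalidInputError):
        validate_table(bad)


def test_simulated_study_reliability_pattern():
    """Phantom study: total-retina reliability far above thin-layer reliability."""
    table = simulate_study(n_subjects=12, instruments=("uhr",), seed=9)
    rep = reliability_report(table, "repeatability").set_index("layer")
    assert rep.loc["Total", "icc"] > 0.97
    assert rep.loc["Total", "cor_percent"] < 2.0
    # a ~20 µm layer with the same 1 µm read noise is necessarily less reliable
    assert rep.loc["OPL", "icc"] < rep.loc["Total", "icc"]
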