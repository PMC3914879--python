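"""Reliability statistics: ICC, COR, Bland-Altman, paired t.

Implements the statistics used to judge repeatability (same examiner,
repeated scans), reproducibility (different examiners) and
between-instrument agreement of layer-thickness measurements:

* **ICC** from a two-way (subjects x ratings) analysis of variance. The
  default is the single-measure consistency form, ICC(3,1) =
  (MSR - MSE) / (MSR + (k-1) MSE); the absolute-agreement form ICC(2,1)
  is available via ``form="agreement"``. Which of the two a given study
  used is often unstated; both are standard.
* **COR**, the coefficient of repeatability/reproducibility: the SD of
  the paired differences expressed as a percentage of the pooled mean of
  the two measurements.
* **Bland-Altman 95% limits of agreement**: mean difference +/- 1.96 SD
  of the differences, with the per-subject (mean, difference) pairs for
  plotting.
* **Paired t-test** for a systematic offset between two measurements.

Sample SDs use the n-1 denominator throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateTestError,
    IncompleteDesignError,
    InvalidInputError,
    InvalidParameterError,
    SampleSizeError,
)

TABLE_COLUMNS = ("subject", "layer", "meridian", "instrument", "examiner", "repeat", "thickness_um")

DESIGNS = ("repeatability", "reproducibility", "agreement")


def icc(values: np.ndarray, form: str = "consistency") -> float:
    """Single-measure intraclass correlation from a two-way ANOVA.

    Parameters
    ----------
    values : (n, k) array
        One row per subject, one column per rating/measurement. Requires
        n >= 3 subjects, k >= 2 ratings and no missing cells.
    form : {"consistency", "agreement"}
        ``consistency`` gives ICC(3,1) — raters fixed, column offsets not
        penalized; ``agreement`` gives ICC(2,1) which charges systematic
        rater differences to the error.

    Returns NaN (with a warning) when the data carry no variance at all.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise InvalidInputError(f"expected an (n, k) matrix, got shape {x.shape}")
    n, k = x.shape
    if n < 3:
        raise SampleSizeError(f"ICC requires at least 3 subjects, got {n}")
    if k < 2:
        raise SampleSizeError(f"ICC requires at least 2 ratings, got {k}")
    if np.any(~np.isfinite(x)):
        raise IncompleteDesignError("ICC requires a complete matrix without missing cells")
    if form not in ("consistency", "agreement"):
        raise InvalidParameterError(f"unknown ICC form {form!r}")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if msr == 0 and mse == 0:
        warnings.warn("ICC undefined: no variance in the data", RuntimeWarning, stacklevel=2)
        return float("nan")
    if form == "consistency":
        return float((msr - mse) / (msr + (k - 1) * mse))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def cor_percent(t1: np.ndarray, t2: np.ndarray) -> float:
    """Coefficient of repeatability/reproducibility, in percent.

    100 x SD(t1 - t2) / mean of all pooled values. Scale-invariant and
    symmetric in its arguments.
    """
    a = np.asarray(t1, dtype=float)
    b = np.asarray(t2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("t1 and t2 must be 1-D arrays of equal length")
    if a.size < 2:
        raise InvalidInputError("COR requires at least 2 paired values")
    pooled_mean = float(np.concatenate([a, b]).mean())
    if pooled_mean <= 0:
        raise InvalidInputError(f"pooled mean must be positive, got {pooled_mean}")
    return float(100.0 * np.std(a - b, ddof=1) / pooled_mean)


@dataclass
class BlandAltman:
    """Bland-Altman agreement summary plus per-subject plotting pairs."""

    mean_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray

    def __post_init__(self) -> None:
        # algebraic identity: the LoA midpoint is the mean difference
        assert abs((self.loa_low + self.loa_high) / 2.0 - self.mean_diff) <= 1e-9 * max(
            1.0, abs(self.mean_diff)
        )


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltman:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 SD)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("a and b must be 1-D arrays of equal length")
    if a.size < 2:
        raise InvalidInputError("Bland-Altman requires at least 2 paired values")
    d = a - b
    mean_diff = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return BlandAltman(
        mean_diff=mean_diff,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        means=(a + b) / 2.0,
        diffs=d,
    )


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p).

    Raises :class:`DegenerateTestError` when the differences have zero
    variance (the statistic is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("a and b must be 1-D arrays of equal length")
    n = a.size
    if n < 2:
        raise InvalidInputError("paired t-test requires at least 2 pairs")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise DegenerateTestError("zero-variance differences: paired t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format measurement table against its invariants."""
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise InvalidInputError(f"measurement table missing columns: {sorted(missing)}")
    keys = ["subject", "layer", "meridian", "instrument", "examiner", "repeat"]
    if table.duplicated(subset=keys).any():
        dup = table[table.duplicated(subset=keys)].iloc[0]
        raise InvalidInputError(
            f"duplicate measurement key: {tuple(dup[k] for k in keys)}"
        )
    if (table["thickness_um"] <= 0).any():
        raise InvalidInputError("thickness_um values must be positive")
    return table


def _paired_values(
    group: pd.DataFrame, sel_a: dict, sel_b: dict, label_a: str, label_b: str
) -> tuple[np.ndarray, np.ndarray]:
    def pick(sel: dict, label: str) -> pd.Series:
        mask = np.ones(len(group), dtype=bool)
        for key, value in sel.items():
            mask &= group[key] == value
        sub = group[mask].set_index("subject")["thickness_um"]
        if sub.empty:
            raise IncompleteDesignError(f"no measurements for {label} ({sel})")
        return sub

    a = pick(sel_a, label_a)
    b = pick(sel_b, label_b)
    subjects = sorted(set(a.index) | set(b.index))
    missing_a = set(subjects) - set(a.index)
    missing_b = set(subjects) - set(b.index)
    if missing_a or missing_b:
        raise IncompleteDesignError(
            f"missing cells: {label_a} lacks subjects {sorted(missing_a)}, "
            f"{label_b} lacks subjects {sorted(missing_b)}"
        )
    return a.loc[subjects].to_numpy(), b.loc[subjects].to_numpy()


def reliability_report(
    table: pd.DataFrame,
    design: str,
    icc_form: str = "consistency",
) -> pd.DataFrame:
    """Per layer x meridian reliability statistics for one study design.

    ``repeatability`` pairs examiner-1 repeat 1 against repeat 2 within
    each instrument; ``reproducibility`` pairs examiner-1 repeat 1 against
    examiner-2 repeat 1; ``agreement`` pairs the two instruments, each
    represented by the mean of examiner-1's repeats. The paired t-test is
    reported as NaN when its statistic is undefined (zero-variance
    differences).
    """
    if design not in DESIGNS:
        raise InvalidParameterError(f"design must be one of {DESIGNS}, got {design!r}")
    validate_table(table)
    records = []
    if design in ("repeatability", "reproducibility"):
        group_keys = ["instrument", "layer", "meridian"]
        for (inst, layer, meridian), group in table.groupby(group_keys, sort=True):
            if design == "repeatability":
                sel_a = {"examiner": 1, "repeat": 1}
                sel_b = {"examiner": 1, "repeat": 2}
                labels = ("examiner 1 / repeat 1", "examiner 1 / repeat 2")
            else:
                sel_a = {"examiner": 1, "repeat": 1}
                sel_b = {"examiner": 2, "repeat": 1}
                labels = ("examiner 1 / repeat 1", "examiner 2 / repeat 1")
            a, b = _paired_values(group, sel_a, sel_b, *labels)
            records.append(
                _result_row(design, inst, layer, meridian, a, b, icc_form)
            )
    else:
        instruments = sorted(table["instrument"].unique())
        if len(instruments) != 2:
            raise IncompleteDesignError(
                f"agreement design requires exactly 2 instruments, got {instruments}"
            )
        inst_a, inst_b = instruments
        ex1 = table[table["examiner"] == 1]
        if ex1.empty:
            raise IncompleteDesignError("agreement design requires examiner-1 measurements")
        averaged = (
            ex1.groupby(["subject", "layer", "meridian", "instrument"], sort=True)[
                "thickness_um"
            ]
            .mean()
            .reset_index()
        )
        for (layer, meridian), group in averaged.groupby(["layer", "meridian"], sort=True):
            a, b = _paired_values(
                group,
                {"instrument": inst_a},
                {"instrument": inst_b},
                f"instrument {inst_a}",
                f"instrument {inst_b}",
            )
            records.append(
                _result_row(design, f"{inst_a} - {inst_b}", layer, meridian, a, b, icc_form)
            )
    return pd.DataFrame.from_records(records)


def _result_row(
    design: str,
    instrument: str,
    layer: str,
    meridian: str,
    a: np.ndarray,
    b: np.ndarray,
    icc_form: str,
) -> dict:
    ba = bland_altman(a, b)
    try:
        t, df, p = paired_t(a, b)
    except DegenerateTestError:
        t, df, p = float("nan"), a.size - 1, float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        icc_value = icc(np.column_stack([a, b]), form=icc_form)
    return {
        "design": design,
        "instrument": instrument,
        "layer": layer,
        "meridian": meridian,
        "n": int(a.size),
        "mean_a_um": float(a.mean()),
        "sd_a_um": float(np.std(a, ddof=1)),
        "mean_b_um": float(b.mean()),
        "sd_b_um": float(np.std(b, ddof=1)),
        "mean_diff_um": ba.mean_diff,
        "sd_diff_um": float(np.std(a - b, ddof=1)),
        "icc": icc_value,
        "cor_percent": cor_percent(a, b),
        "loa_low_um": ba.loa_low,
        "loa_high_um": ba.loa_high,
        "t_stat": t,
        "df": df,
        "p_value": p,
    }
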