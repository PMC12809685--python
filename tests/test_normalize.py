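"""Size factors, log transform, outlier screen, particle arithmetic and the
repeated-measures ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uevabt.normalize import (
    compute_size_factors,
    log_transform,
    normalize_counts,
    normalize_particle_concentration,
    screen_outliers,
)
from uevabt.stats import rm_anova_timepoints


def brute_force_size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Independent median-of-ratios oracle, written straight from the
    definition with explicit loops."""
    rows = []
    for mirna in counts.index:
        row = counts.loc[mirna].to_numpy(dtype=float)
        if (row > 0).all():
            rows.append(row)
    assert rows, "no reference-eligible miRNA"
    out = []
    for j in range(counts.shape[1]):
        ratios = []
        for row in rows:
            geomean = np.exp(np.mean([np.log(v) for v in row]))
            ratios.append(row[j] / geomean)
        out.append(np.median(ratios))
    return np.array(out)


def test_size_factors_worked_example():
    counts = pd.DataFrame([[10, 20], [30, 60]], index=["a", "b"],
                          columns=["s1", "s2"])
    s = compute_size_factors(counts)
    assert np.allclose(s.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], atol=1e-4)
    norm = normalize_counts(counts, s)
    assert np.allclose(norm["s1"], norm["s2"])
    assert np.allclose(norm["s1"], [10 * np.sqrt(2), 30 * np.sqrt(2)], atol=1e-3)


def test_size_factors_identical_columns_are_one():
    counts = pd.DataFrame([[5, 5, 5], [9, 9, 9]], columns=list("xyz"))
    assert np.allclose(compute_size_factors(counts), 1.0)


def test_zero_row_excluded_from_reference():
    counts = pd.DataFrame([[0, 5], [4, 4]], columns=["s1", "s2"])
    s = compute_size_factors(counts)
    assert np.allclose(s.to_numpy(), [1.0, 1.0])


def test_no_reference_mirna_raises():
    counts = pd.DataFrame([[0, 5], [4, 0]], columns=["s1", "s2"])
    with pytest.raises(ValueError, match="prevalence"):
        compute_size_factors(counts)


def test_size_factors_match_brute_force_oracle(rng):
    for _ in range(50):
        counts = pd.DataFrame(rng.integers(1, 200, size=(3, 4)))
        s = compute_size_factors(counts)
        assert np.allclose(s.to_numpy(), brute_force_size_factors(counts),
                           rtol=1e-12)


@given(scale=st.floats(min_value=0.1, max_value=50.0), col=st.integers(0, 3))
@settings(max_examples=25, deadline=None)
def test_column_scaling_equivariance(scale, col):
    """Scaling one raw column by c scales its size factor relative to every
    other sample by c, and changes the normalized matrix only by one global
    scalar (the reference geometric mean absorbs c^(1/n))."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(rng.integers(1, 100, size=(5, 4)).astype(float))
    s = compute_size_factors(counts)
    scaled = counts.copy()
    scaled[col] = scaled[col] * scale
    s2 = compute_size_factors(scaled)
    ratio = (s2 / s).to_numpy()
    others = [j for j in range(4) if j != col]
    assert np.allclose(ratio[others], ratio[others][0], rtol=1e-9)
    assert np.isclose(ratio[col] / ratio[others][0], scale, rtol=1e-9)
    n1 = normalize_counts(counts, s).to_numpy()
    n2 = normalize_counts(scaled, s2).to_numpy()
    global_factor = n2 / n1
    assert np.allclose(global_factor, global_factor.flat[0], rtol=1e-9)


def test_normalize_requires_all_samples():
    counts = pd.DataFrame([[1, 2]], columns=["s1", "s2"])
    with pytest.raises(ValueError, match="s2"):
        normalize_counts(counts, pd.Series({"s1": 1.0}))


@pytest.mark.parametrize("value,expected", [(0, 0), (1, 1), (7, 3)])
def test_log_transform_values(value, expected):
    df = pd.DataFrame([[value]], dtype=float)
    assert log_transform(df).iloc[0, 0] == expected


def test_outlier_screen_flags_the_shifted_column(rng):
    base = rng.normal(0, 1, size=(50, 21))
    base[:, 7] += 10.0
    df = pd.DataFrame(base, columns=[f"s{i}" for i in range(21)])
    assert screen_outliers(df) == ["s7"]


def test_outlier_screen_clean_and_permutation_invariant(rng):
    base = rng.normal(0, 1, size=(50, 20))
    df = pd.DataFrame(base, columns=[f"s{i}" for i in range(20)])
    flags = screen_outliers(df)
    perm = rng.permutation(20)
    flags_perm = screen_outliers(df.iloc[:, perm])
    assert sorted(flags) == sorted(flags_perm)
    const = pd.DataFrame(np.ones((10, 5)))
    assert screen_outliers(const) == []


def test_particle_normalization_unit_arithmetic():
    # 1e8/mL diluted x10, 50 uL eluate from 10 mL urine at 1 g/L creatinine
    out = normalize_particle_concentration(1e8, 10, 0.05, 10.0, 1.0)
    assert np.isclose(out, 5e9)
    # identity configuration: 1 L urine at 1 g/L -> exactly measured_conc
    assert np.isclose(
        normalize_particle_concentration(3.3e7, 1, 1.0, 1000.0, 1.0), 3.3e7
    )


@given(c=st.floats(min_value=0.5, max_value=8.0))
@settings(max_examples=25, deadline=None)
def test_particle_normalization_linearity(c):
    base = normalize_particle_concentration(1e8, 10, 0.05, 10.0, 0.9)
    assert np.isclose(
        normalize_particle_concentration(1e8, 10 * c, 0.05, 10.0, 0.9), base * c
    )
    assert np.isclose(
        normalize_particle_concentration(1e8, 10, 0.05, 10.0, 0.9 * c), base / c
    )


def test_rm_anova_constant_values():
    wide = pd.DataFrame(np.full((4, 5), 3.0),
                        columns=["-9w", "-8w", "-7w", "t0", "+3h"])
    res = rm_anova_timepoints(wide)
    assert res.f == 0.0 and res.p == 1.0


def test_rm_anova_two_timepoints_equals_paired_t():
    """With two time points the repeated-measures F equals t^2."""
    from scipy import stats as sps

    wide = pd.DataFrame({"-9w": [1.0, 4.0, 3.0], "t0": [2.0, 7.0, 3.5]})
    res = rm_anova_timepoints(wide)
    t, p = sps.ttest_rel(wide["t0"], wide["-9w"])
    assert np.isclose(res.f, t**2, rtol=1e-10)
    assert np.isclose(res.p, p, rtol=1e-10)


def test_rm_anova_matches_pingouin():
    rng = np.random.default_rng(3)
    wide = pd.DataFrame(rng.normal(size=(8, 5)),
                        columns=["-9w", "-8w", "-7w", "t0", "+3h"])
    res = rm_anova_timepoints(wide)
    import pingouin as pg

    long = wide.reset_index().melt(id_vars="index", var_name="time",
                                   value_name="value")
    pg_res = pg.rm_anova(data=long, dv="value", within="time", subject="index",
                         correction=False)
    assert np.isclose(res.f, pg_res["F"].iloc[0], rtol=1e-8)
    assert np.isclose(res.p, pg_res["p_unc"].iloc[0], rtol=1e-6)


def test_rm_anova_null_calibration():
    """i.i.d. normal data rejects at about the nominal 5% level."""
    rng = np.random.default_rng(0)
    hits = 0
    reps = 1000
    for _ in range(reps):
        wide = pd.DataFrame(rng.normal(size=(10, 11)))
        if rm_anova_timepoints(wide).p < 0.05:
            hits += 1
    assert 0.03 <= hits / reps <= 0.07


def test_rm_anova_needs_two_subjects():
    with pytest.raises(ValueError, match=">= 2"):
        rm_anova_timepoints(pd.DataFrame([[1.0, 2.0]]))
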