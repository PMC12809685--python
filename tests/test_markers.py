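"""Surface-marker processing order, log2FC, clustering and ANOVA."""

import numpy as np
import pandas as pd
import pytest

from uevabt.markers import (
    apply_isotype_threshold,
    cluster_separation,
    compare_markers_over_time,
    detection_frequency,
    marker_log2fc,
    normalize_rmfi,
    subtract_background,
)

from conftest import make_design


def test_background_subtraction_clamps_and_propagates_missing():
    mfi = pd.DataFrame({"s1": [100.0, 20.0, np.nan]},
                       index=["mA", "mB", "mC"])
    bg = pd.Series({"mA": 30.0, "mB": 30.0, "mC": 30.0})
    out = subtract_background(mfi, bg)
    assert out.loc["mA", "s1"] == 70.0
    assert out.loc["mB", "s1"] == 0.0
    assert np.isnan(out.loc["mC", "s1"])


def test_isotype_threshold_is_strict():
    corrected = pd.DataFrame({"s1": [120.0, 40.0, 50.0]},
                             index=["mA", "mB", "mC"])
    iso = pd.Series({"s1": 50.0})
    out = apply_isotype_threshold(corrected, iso)
    assert out.loc["mA", "s1"] == 120.0
    assert np.isnan(out.loc["mB", "s1"])
    assert np.isnan(out.loc["mC", "s1"])  # tie disregarded


def test_missing_isotype_drops_sample_with_warning():
    corrected = pd.DataFrame({"s1": [120.0], "s2": [120.0]}, index=["mA"])
    iso = pd.Series({"s1": 50.0})
    with pytest.warns(UserWarning, match="missing isotype"):
        out = apply_isotype_threshold(corrected, iso)
    assert out.loc["mA", "s1"] == 120.0
    assert np.isnan(out.loc["mA", "s2"])


def test_rmfi_division_and_frequency():
    thresholded = pd.DataFrame({"s1": [500.0, np.nan], "s2": [200.0, 80.0]},
                               index=["mA", "mB"])
    rmfi = normalize_rmfi(thresholded, pd.Series({"s1": 0.5, "s2": 1.0}))
    assert rmfi.loc["mA", "s1"] == 1000.0
    assert rmfi.loc["mA", "s2"] == 200.0
    freq = detection_frequency(thresholded)
    assert freq["mA"] == 100.0 and freq["mB"] == 50.0


def test_processing_order_matters():
    """Background-then-isotype differs from isotype-then-background on a
    value between the raw and corrected isotype levels (guards the
    documented order)."""
    from uevabt.design import SampleRecord, StudyDesign
    from uevabt.io import MFIMatrix
    from uevabt.markers import process_mfi

    design = StudyDesign([SampleRecord("s1", "x", "control", "-9w", 1.0)])
    panel = pd.DataFrame({"s1": [55.0]}, index=["mA"])
    background = pd.Series({"mA": 20.0, "iso": 0.0})
    isotype = pd.DataFrame({"s1": [50.0]}, index=["iso"])
    mfi = MFIMatrix(panel=panel, background=background, isotype=isotype)
    default_order = process_mfi(mfi, design)
    swapped = process_mfi(mfi, design, isotype_before_background=True)
    # corrected 35 < corrected isotype 50 -> invalid under the default order
    assert np.isnan(default_order.loc["mA", "s1"])
    # raw 55 > raw isotype 50 -> kept, then background-corrected
    assert swapped.loc["mA", "s1"] == 35.0


def test_marker_log2fc_examples():
    design = make_design(n_per_group=1, time_points=("-9w", "-8w", "+6h"))
    cols = design.sample_ids
    rmfi = pd.DataFrame(np.nan, index=["mA", "mB"], columns=cols)
    rmfi.loc["mA", ["control_01_-9w", "control_01_-8w"]] = [2.0, 2.0]
    rmfi.loc["mA", "control_01_+6h"] = 8.0
    rmfi.loc["mB", "control_01_+6h"] = 5.0  # no baseline -> missing
    out = marker_log2fc(rmfi, design)
    assert out.loc["mA", "control_01_+6h"] == 2.0
    assert out.loc["mA", "control_01_-9w"] == 0.0
    assert np.isnan(out.loc["mB", "control_01_+6h"])


def test_marker_log2fc_zero_baseline_warns():
    design = make_design(n_per_group=1, time_points=("-9w", "+6h"))
    rmfi = pd.DataFrame(
        [[0.0, 4.0]], index=["mA"],
        columns=["control_01_-9w", "control_01_+6h"],
    ).reindex(columns=design.sample_ids)
    with pytest.warns(UserWarning, match="zero baseline"):
        out = marker_log2fc(rmfi, design)
    assert np.isnan(out.loc["mA", "control_01_+6h"])


def _opposite_pattern_fixture(n_per_group=6, n_markers=10, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    pattern = np.resize([1.0, -1.0], n_markers)
    cols, labels = [], {}
    data = []
    for g, sign in (("control", 1.0), ("group2", -1.0)):
        for i in range(n_per_group):
            sid = f"{g}_{i}"
            cols.append(sid)
            labels[sid] = g
            data.append(sign * pattern + rng.normal(0, noise, n_markers))
    table = pd.DataFrame(np.array(data).T,
                         index=[f"mk{i}" for i in range(n_markers)],
                         columns=cols)
    return table, pd.Series(labels)


def test_cluster_separation_opposite_patterns():
    table, labels = _opposite_pattern_fixture()
    res = cluster_separation(table, labels, k=2)
    assert res.ari == 1.0
    assert res.excluded == []


def test_cluster_separation_label_permutation_null(rng):
    table, labels = _opposite_pattern_fixture()
    res = cluster_separation(table, labels, k=2)
    from sklearn.metrics import adjusted_rand_score

    aris = []
    values = labels.reindex(res.labels.index).to_numpy()
    for _ in range(1000):
        aris.append(
            adjusted_rand_score(rng.permutation(values), res.labels.to_numpy())
        )
    assert abs(np.mean(aris)) < 0.05


def test_cluster_separation_k1_rejected():
    table, labels = _opposite_pattern_fixture()
    with pytest.raises(ValueError, match="k >= 2"):
        cluster_separation(table, labels, k=1)


def test_cluster_distance_invariant_to_global_affine():
    """A global (non-row-specific) affine map of the table leaves the
    cluster assignment and ARI unchanged."""
    table, labels = _opposite_pattern_fixture(seed=3)
    res = cluster_separation(table, labels, k=2)
    res2 = cluster_separation(table * 3.7 + 11.0, labels, k=2)
    from sklearn.metrics import adjusted_rand_score

    assert res.ari == res2.ari
    # same partition up to cluster renumbering
    assert adjusted_rand_score(res.labels, res2.labels.reindex(res.labels.index)) == 1.0


def test_sample_sharing_too_few_markers_excluded():
    table, labels = _opposite_pattern_fixture()
    lonely = pd.Series(np.nan, index=table.index, name="control_lonely")
    lonely.iloc[:2] = [1.0, -1.0]  # only 2 non-missing markers
    table = pd.concat([table, lonely.to_frame()], axis=1)
    labels = pd.concat([labels, pd.Series({"control_lonely": "control"})])
    res = cluster_separation(table, labels, k=2)
    assert res.excluded == ["control_lonely"]
    assert res.ari == 1.0


def test_marker_drift_separates_groups(default_cohort):
    """With the planted treatment drift, cross-group profile distances
    exceed within-group distances and the ARI beats the no-drift null."""
    from uevabt.markers import _pairwise_pearson_distance, _row_scale, process_mfi
    from uevabt.simulate import SimulationConfig, simulate_cohort

    def _post_table(cohort):
        design, _, mfi, *_ = cohort
        rmfi = process_mfi(mfi, design)
        l2 = marker_log2fc(rmfi, design)
        meta = design.to_frame().set_index("sample_id")
        post = meta.loc[design.select(phase="post")]
        post = post[post["group"].isin(["control", "group2"])]
        return l2[post.index.tolist()], post["group"]

    table, labels = _post_table(default_cohort)
    dist = _pairwise_pearson_distance(_row_scale(table), 3)
    same = []
    cross = []
    for i, si in enumerate(dist.index):
        for sj in dist.index[i + 1:]:
            d = dist.loc[si, sj]
            if np.isnan(d):
                continue
            (same if labels[si] == labels[sj] else cross).append(d)
    assert np.mean(cross) > np.mean(same) + 0.2
    drift_ari = cluster_separation(table, labels, k=2).ari
    null_cohort = simulate_cohort(SimulationConfig(seed=1,
                                                   marker_drift_enabled=False))
    null_table, null_labels = _post_table(null_cohort)
    null_ari = cluster_separation(null_table, null_labels, k=2).ari
    assert drift_ari > null_ari
    assert abs(null_ari) < 0.12


def test_compare_markers_null_simulation_finds_nothing():
    """Without planted drift the per-marker ANOVA yields (almost) no
    BH-significant effects."""
    from uevabt.markers import process_mfi
    from uevabt.simulate import SimulationConfig, simulate_cohort

    design, _, mfi, *_ = simulate_cohort(
        SimulationConfig(seed=6, marker_drift_enabled=False)
    )
    l2 = marker_log2fc(process_mfi(mfi, design), design)
    out = compare_markers_over_time(l2, design)
    assert len(out) > 0
    n_sig = int((out[["padj_group", "padj_time", "padj_interaction"]] < 0.05)
                .to_numpy().sum())
    assert n_sig <= 1


def test_compare_markers_over_time_constant_and_cardinality(default_cohort):
    design, *_ = default_cohort
    cols = design.sample_ids
    l2 = pd.DataFrame(np.zeros((2, len(cols))), index=["mA", "mB"],
                      columns=cols)
    out = compare_markers_over_time(l2, design)
    assert len(out) == 2
    assert (out["p_group"] == 1.0).all() and (out["f_group"] == 0.0).all()
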