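"""Generator contracts: determinism, design shape, count moments, planted
effects, marker detection and particle levels."""

import numpy as np
import pandas as pd
import pytest

from uevabt.design import TREATMENT_GROUPS
from uevabt.normalize import normalize_particle_table
from uevabt.simulate import (
    MARKER_PANEL,
    SimulationConfig,
    _nb_draw,
    simulate_cohort,
    simulate_counts,
    simulate_markers,
)

from conftest import make_design


def test_same_seed_is_bit_identical():
    a = simulate_cohort(SimulationConfig(seed=11))
    b = simulate_cohort(SimulationConfig(seed=11))
    pd.testing.assert_frame_equal(a[1], b[1])
    pd.testing.assert_frame_equal(a[2].panel, b[2].panel)
    pd.testing.assert_frame_equal(a[3], b[3])
    assert a[0].sample_ids == b[0].sample_ids
    assert a[4].planted_mirnas == b[4].planted_mirnas
    assert [s.u_crea for s in a[0].samples] == [s.u_crea for s in b[0].samples]


def test_default_design_grid(default_cohort):
    design, counts, *_ = default_cohort
    assert design.expected_grid_size() == 330
    assert len(design.groups_present) == 3
    assert counts.shape[0] == 600
    assert counts.shape[1] == len(design.samples) <= 330
    # expected 9/330 missing: allow generous Binomial slack
    assert 320 - 15 <= len(design.samples) <= 330


def test_counts_match_depth_and_are_integers(default_cohort):
    _, counts, *_ = default_cohort
    assert (counts.to_numpy() >= 0).all()
    assert np.issubdtype(counts.to_numpy().dtype, np.integer)
    totals = counts.sum(axis=0)
    assert abs(totals.mean() / 2.89e5 - 1) < 0.15


def test_nb_draw_poisson_limit(rng):
    """alpha -> 0 with fixed mean gives Poisson-like variance (var ~ mean)."""
    mean = np.full(10_000, 50.0)
    draws = _nb_draw(rng, mean, 0.0)
    assert abs(draws.var() / draws.mean() - 1) < 0.1


def test_nb_draw_overdispersed_variance(rng):
    """Variance tracks mu + alpha mu^2 at alpha = 0.4."""
    mu, alpha = 50.0, 0.4
    draws = _nb_draw(rng, np.full(10_000, mu), alpha)
    expected = mu + alpha * mu**2
    assert abs(draws.var() / expected - 1) < 0.1


def test_planted_fold_recovered_at_peak(rng):
    """Group-2 mean at +6h over baseline mean approaches the planted 2.5."""
    config = SimulationConfig(seed=5, n_per_group=150, n_mirna=60,
                              planted_mirnas=5, missingness=0.0)
    design = make_design(n_per_group=150)
    counts, planted = simulate_counts(design, config, rng)
    rel = counts  # effects act on absolute expected counts
    meta = design.to_frame().set_index("sample_id")
    g2_peak = meta[(meta.group == "group2") & (meta.time_point == "+6h")].index
    g2_base = meta[(meta.group == "group2") & (meta.phase == "baseline")].index
    ratio = rel.loc[planted, g2_peak].mean(axis=1) / rel.loc[
        planted, g2_base].mean(axis=1)
    assert np.allclose(ratio, 2.5, rtol=0.2)
    ctl_peak = meta[(meta.group == "control") & (meta.time_point == "+6h")].index
    ctl_base = meta[(meta.group == "control") & (meta.phase == "baseline")].index
    ctl_ratio = rel.loc[planted, ctl_peak].mean(axis=1) / rel.loc[
        planted, ctl_base].mean(axis=1)
    assert np.allclose(ctl_ratio, 1.0, atol=0.15)


def test_null_effect_profile_plants_nothing(rng):
    config = SimulationConfig(
        seed=5, effect_profile={tp: 1.0 for tp in ("+3h", "+6h", "+1d")}
    )
    design, counts, *_ , truth = simulate_cohort(config)
    meta = design.to_frame().set_index("sample_id")
    rel = counts / counts.sum(axis=0)
    planted = truth.planted_mirnas
    post = meta[(meta.group.isin(TREATMENT_GROUPS)) & (meta.phase == "post")].index
    base = meta[meta.phase == "baseline"].index
    ratio = rel.loc[planted, post].mean(axis=1) / rel.loc[planted, base].mean(axis=1)
    assert np.allclose(ratio, 1.0, atol=0.2)


def test_marker_detection_frequency_matches_panel(default_cohort):
    """CD63 should be detected (above isotype) in about 97% of samples."""
    from uevabt.markers import detection_frequency, process_mfi

    design, _, mfi, *_ = default_cohort
    freq = detection_frequency(process_mfi(mfi, design))
    assert abs(freq["CD63"] - 97.0) < 4.0
    assert abs(freq["CD9"] - 93.0) < 5.0


def test_zero_detection_probability_marker_missing(rng):
    design = make_design(n_per_group=2)
    config = SimulationConfig(seed=0)
    config.marker_panel = config.marker_panel.copy()
    config.marker_panel.loc["CD63", "detection_p"] = 0.0
    mfi = simulate_markers(design, config, rng)
    from uevabt.markers import process_mfi

    rmfi = process_mfi(mfi, design)
    assert rmfi.loc["CD63"].isna().all()


def test_marker_panel_has_37_entries():
    assert len(MARKER_PANEL) == 37


def test_particle_baseline_level_and_null_effect():
    design, _, _, particles, truth = simulate_cohort(SimulationConfig(seed=2))
    table = normalize_particle_table(particles, design)
    base = table[table.phase == "baseline"]["particles_per_g_crea"]
    assert abs(base.mean() / 8.79e10 - 1) < 0.25
    # null particle effect: post/baseline ratio ~ 1
    cfg = SimulationConfig(seed=2, particle_effect=1.0)
    design2, _, _, particles2, _ = simulate_cohort(cfg)
    t2 = normalize_particle_table(particles2, design2)
    b2 = t2[t2.phase == "baseline"]["particles_per_g_crea"].mean()
    w2 = t2[
        t2.time_point.isin(truth.particle_effect_window)
        & t2.group.isin(TREATMENT_GROUPS)
    ]["particles_per_g_crea"].mean()
    assert abs(w2 / b2 - 1) < 0.25


def test_particle_effect_round_trip():
    """The normalizer recovers the generator's two-fold window increase."""
    design, _, _, particles, truth = simulate_cohort(SimulationConfig(seed=3))
    table = normalize_particle_table(particles, design)
    base = table[table.phase == "baseline"]["particles_per_g_crea"].mean()
    window = table[
        table.time_point.isin(truth.particle_effect_window)
        & table.group.isin(TREATMENT_GROUPS)
    ]["particles_per_g_crea"].mean()
    assert abs(window / base - truth.particle_effect) < 0.1 * truth.particle_effect


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(planted_mirnas=700)
    with pytest.raises(ValueError):
        SimulationConfig(dispersion=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(effect_profile={"-9w": 2.0})
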