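"""Cohort generator: determinism, support constraints, planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mscmorph.synth import (DEFAULT_EFFECTS, OUTCOME_COLUMNS,
                            PREDICTOR_COLUMNS, ConfigError, EffectConfig,
                            generate_cohort, generate_feature_table,
                            simulate_assays, simulate_cohort, with_effects)

NULL = EffectConfig(effects={})


def test_cohort_respects_support_constraints():
    for donor in generate_cohort(EffectConfig(n_donors=40, seed=7)):
        assert 0 < donor.cell_wl_ratio <= 1
        assert 0 < donor.nucleus_wl_ratio <= 1
        assert donor.mean_nucleus_area < donor.mean_cell_area
        assert donor.texture_intensity >= 0


def test_single_donor_cohort_is_valid():
    cohort = generate_cohort(EffectConfig(n_donors=1, seed=0))
    assert len(cohort) == 1


def test_invalid_effect_magnitude_rejected():
    with pytest.raises(ConfigError):
        EffectConfig(effects={("nucleus_wl_ratio", "osteo_au"): 1.0}).validate()
    with pytest.raises(ConfigError):
        EffectConfig(effects={("no_such_trait", "osteo_au"): 0.3}).validate()


def test_cohort_determinism():
    a = generate_cohort(EffectConfig(seed=42))
    b = generate_cohort(EffectConfig(seed=42))
    assert all(x == y for x, y in zip(a, b))


def test_feature_table_determinism_and_completeness():
    cfg = EffectConfig(n_donors=56, seed=9)
    t1 = generate_feature_table(cfg)
    t2 = generate_feature_table(cfg)
    pd.testing.assert_frame_equal(t1, t2)
    assert len(t1) == 56
    assert not t1.isna().any().any()
    for col in PREDICTOR_COLUMNS + OUTCOME_COLUMNS:
        assert col in t1.columns


def test_zero_within_donor_variance_zeroes_sd_columns():
    table = generate_feature_table(
        EffectConfig(n_donors=8, seed=1, within_donor_scale=0.0))
    sd_cols = [c for c in table.columns if c.endswith("_sd")]
    assert sd_cols and (table[sd_cols] == 0.0).all().all()


def test_null_effects_leave_traits_uncorrelated():
    """With all effect magnitudes 0, planted pairs stay near-independent."""
    hits = 0
    reps = 40
    for s in range(reps):
        table = generate_feature_table(
            EffectConfig(seed=s, effects={}))
        r = spearmanr(table.nucleus_wl_ratio_mean, table.osteo_au).statistic
        hits += abs(r) < 0.3
    assert hits / reps >= 0.85


def test_planted_spearman_recovered_in_expectation():
    """Monte-Carlo mean of the planted trait-outcome Spearman hits target."""
    targets = {("nucleus_wl_ratio_mean", "osteo_au"): -0.5,
               ("cell_area_mean", "proliferation_auc"): -0.5,
               ("nucleus_wl_ratio_mean", "cd146_pct"): -0.5}
    sums = {k: 0.0 for k in targets}
    reps = 80
    for s in range(reps):
        table = generate_feature_table(EffectConfig(seed=s))
        for (x, y) in targets:
            sums[(x, y)] += spearmanr(table[x], table[y]).statistic
    for pair, target in targets.items():
        assert abs(sums[pair] / reps - target) < 0.1, pair


def test_null_effect_on_assay_centers_correlation_at_zero():
    """b = 0 for the nucleus->osteo link: cohort correlation near 0."""
    cfg = with_effects(EffectConfig(seed=5),
                       {("mean_cell_area", "proliferation_auc"): -0.5})
    rs = []
    for s in range(30):
        truths, panels = simulate_cohort(
            with_effects(EffectConfig(seed=s), cfg.effects))
        x = [t.nucleus_wl_ratio for t in truths]
        y = [p.alizarin_au for p in panels]
        rs.append(spearmanr(x, y).statistic)
    assert abs(np.mean(rs)) < 0.1


def test_noiseless_growth_matches_doubling_closed_form():
    """Doubling every 60 h: counts at day 6 / day 1 = 2^(120/60) = 4."""
    cfg = EffectConfig(growth_noise_cv=0.0, growth_carrying_capacity=1e18,
                       seed=0)
    donor = generate_cohort(cfg)[0]
    from mscmorph.synth import _logistic_counts
    counts = _logistic_counts(60.0, cfg)
    assert counts[2] / counts[0] == pytest.approx(4.0, rel=1e-9)


def test_cd146_cohort_mean_matches_reference_marker_heterogeneity():
    """Cohort CD146+ mean lands near 62% (reference mean 62 +/- 30)."""
    means = [generate_feature_table(EffectConfig(seed=s)).cd146_pct.mean()
             for s in range(10)]
    assert abs(np.mean(means) - 62.0) < 10.0


def test_assay_panel_valid_ranges():
    truths, panels = simulate_cohort(EffectConfig(n_donors=20, seed=2))
    for p in panels:
        assert (p.growth["count"] >= 0).all()
        assert 0 <= p.lipid_pct <= 100
        for v in p.cd_markers.values():
            assert 0 <= v <= 100
        assert p.pdt_hours > 0 or np.isnan(p.pdt_hours)


def test_simulate_assays_deterministic_per_seed(default_donor):
    a = simulate_assays(default_donor, EffectConfig(), seed=99)
    b = simulate_assays(default_donor, EffectConfig(), seed=99)
    assert a.alizarin_au == b.alizarin_au
    pd.testing.assert_frame_equal(a.growth, b.growth)
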