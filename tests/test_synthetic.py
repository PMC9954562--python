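"""Generator contracts: determinism, ground truth, growth-law consistency."""

import math

import numpy as np
import pytest

from spheromorph.growth import fit_exponential
from spheromorph.morphometry import sphericity
from spheromorph.stats import circularity_variance_test
from spheromorph.synthetic import (
    MESENCHYMAL_LIKE,
    PRONEURAL_LIKE,
    SubtypeProfile,
    generate_biosphere_timecourse,
    generate_cohort,
    generate_count_series,
    generate_spheroid_mask,
    generate_volume_mask,
)


# ---------------------------------------------------------------------------
# spheroid masks


def test_zero_irregularity_truth_is_circle():
    _, truth = generate_spheroid_mask(100, 0.0, pixel_size=0.5, seed=1)
    assert truth.circularity == 1.0
    assert truth.perimeter_um == pytest.approx(math.pi * 100, rel=1e-12)
    assert truth.area_um2 == pytest.approx(math.pi * 50 ** 2, rel=1e-12)


@pytest.mark.parametrize("irr", [0.1, 0.3, 0.6])
def test_perturbed_truth_circularity_below_one(irr):
    """Isoperimetric inequality: any non-circular closed curve has
    4*pi*A/P^2 strictly below 1."""
    _, truth = generate_spheroid_mask(100, irr, seed=1)
    assert 0 < truth.circularity < 1.0


def test_mask_determinism_and_seed_sensitivity():
    m1, t1 = generate_spheroid_mask(100, 0.3, seed=1)
    m2, t2 = generate_spheroid_mask(100, 0.3, seed=1)
    m3, _ = generate_spheroid_mask(100, 0.3, seed=2)
    assert np.array_equal(m1.pixels, m2.pixels)
    assert t1.circularity == t2.circularity
    assert (m1.pixels.shape != m3.pixels.shape
            or not np.array_equal(m1.pixels, m3.pixels))


def test_spheroid_size_and_irregularity_validation():
    with pytest.raises(ValueError, match="resolvable minimum of 2"):
        generate_spheroid_mask(1.0, 0.1, pixel_size=0.5)
    with pytest.raises(ValueError, match="irregularity"):
        generate_spheroid_mask(100, 1.0)
    with pytest.raises(ValueError, match="n_modes"):
        generate_spheroid_mask(100, 0.1, n_modes=1)


def test_rasterized_area_converges_to_truth():
    """Measured pixel-count area approaches the continuous-polygon area
    as the pixel size shrinks."""
    rel_errs = []
    for px in (2.0, 0.8, 0.2):
        mask, truth = generate_spheroid_mask(100, 0.3, pixel_size=px,
                                             seed=4)
        area = mask.pixels.sum() * px ** 2
        rel_errs.append(abs(area - truth.area_um2) / truth.area_um2)
    assert rel_errs[0] > rel_errs[2]
    assert rel_errs[2] < 1e-3


# ---------------------------------------------------------------------------
# timecourse


def test_timecourse_diameter_follows_growth_law():
    """d(t) = d0 * exp((t-t0)/(3 tau)): after 9 days at tau=3 the diameter
    has grown by exactly one e^(1/3) per 3 days, i.e. factor e."""
    profile = SubtypeProfile(name="x", tau=3.0, irregularity_base=0.0,
                             irregularity_slope=0.0)
    tc = generate_biosphere_timecourse(profile, 5, [0.0, 9.0],
                                       d0_mean=50.0, d0_sd=0.0, seed=0)
    d0 = [t.diameter_um for t in tc.truths[0.0]]
    d9 = [t.diameter_um for t in tc.truths[9.0]]
    for a, b in zip(d0, d9):
        assert b == pytest.approx(a * math.e, rel=1e-9)
    assert d0[0] == pytest.approx(50.0, rel=1e-9)


def test_timecourse_truth_satisfies_area_diameter_identity():
    """A(t)/A(t0) equals (d(t)/d(t0))^2 exactly on the truth records."""
    tc = generate_biosphere_timecourse(MESENCHYMAL_LIKE, 10,
                                       [3.0, 8.0, 16.0], seed=2)
    df = tc.truth_table()
    for _, obj in df.groupby("object_id"):
        obj = obj.sort_values("time_d")
        a_ratio = obj["area_um2"].to_numpy()
        d_ratio = obj["diameter_um"].to_numpy()
        np.testing.assert_allclose(
            a_ratio / a_ratio[0], (d_ratio / d_ratio[0]) ** 2, rtol=1e-9)


def test_size_independent_profile_has_equal_stratum_variance():
    """With irregularity_slope = 0 the small/large circularity variances
    agree (no rejection even at a permissive level)."""
    tc = generate_biosphere_timecourse(MESENCHYMAL_LIKE, 150,
                                       [3.0, 8.0, 16.0], seed=3)
    res, _ = circularity_variance_test(tc.truth_table())
    assert res.p_value > 0.05


def test_size_coupled_profile_inflates_large_stratum_variance():
    tc = generate_biosphere_timecourse(PRONEURAL_LIKE, 150,
                                       [1.0, 7.0, 14.0, 18.0], seed=3)
    res, _ = circularity_variance_test(tc.truth_table())
    assert res.group_variances[1] > res.group_variances[0]
    assert res.p_value < 0.01


def test_timecourse_empty_times_errors():
    with pytest.raises(ValueError, match="non-empty"):
        generate_biosphere_timecourse(MESENCHYMAL_LIKE, 5, [])


# ---------------------------------------------------------------------------
# counts


def test_count_series_noiseless_values():
    """n(t) = n0 exp((t-t0)/tau): 4e4 cells at tau=3 give ~803,421 after
    9 days."""
    s = generate_count_series(4e4, 3.0, [0.0, 9.0], noise_cv=0.0)
    assert s.counts[0] == 4e4
    assert s.counts[1] == pytest.approx(4e4 * math.e ** 3, abs=1.0)


def test_count_series_noiseless_log_linear():
    t = np.linspace(0, 12, 7)
    s = generate_count_series(1e4, 2.5, t, noise_cv=0.0)
    slope = np.polyfit(t, np.log(s.counts), 1)[0]
    assert slope == pytest.approx(1 / 2.5, rel=1e-4)


def test_count_series_determinism_and_noise():
    s1 = generate_count_series(1e4, 2.0, [0, 2, 4], noise_cv=0.1, seed=5)
    s2 = generate_count_series(1e4, 2.0, [0, 2, 4], noise_cv=0.1, seed=5)
    s3 = generate_count_series(1e4, 2.0, [0, 2, 4], noise_cv=0.1, seed=6)
    assert np.array_equal(s1.counts, s2.counts)
    assert not np.array_equal(s1.counts, s3.counts)


def test_count_series_negative_noise_errors():
    with pytest.raises(ValueError, match="noise_cv"):
        generate_count_series(1e4, 2.0, [0, 1], noise_cv=-0.1)


def test_tau_recovery_under_lognormal_noise():
    """Log-scale OLS recovers tau with small bias and RMSE at 5% noise."""
    taus = [
        fit_exponential(
            generate_count_series(4e4, 2.0, np.linspace(0, 14, 8),
                                  noise_cv=0.05, seed=200 + i)
        ).tau
        for i in range(50)
    ]
    taus = np.asarray(taus)
    assert abs(taus.mean() / 2.0 - 1.0) < 0.02
    assert math.sqrt(np.mean((taus / 2.0 - 1.0) ** 2)) < 0.05


# ---------------------------------------------------------------------------
# volumes and cohorts


def test_ball_volume_truth_and_raster():
    vol, truth = generate_volume_mask(10.0, 0.0, voxel_size=0.5, seed=0)
    assert truth.sphericity == pytest.approx(1.0, abs=1e-6)
    measured = vol.voxels.sum() * 0.5 ** 3 / 1000.0
    assert measured == pytest.approx(10.0, rel=0.05)


def test_volume_determinism():
    v1, _ = generate_volume_mask(10.0, 0.4, seed=7)
    v2, _ = generate_volume_mask(10.0, 0.4, seed=7)
    assert np.array_equal(v1.voxels, v2.voxels)


def test_sphericity_decreases_with_irregularity():
    """Same seed, larger perturbation amplitude: lower truth sphericity."""
    for seed in range(4):
        _, lo = generate_volume_mask(10.0, 0.1, seed=seed)
        _, hi = generate_volume_mask(10.0, 0.4, seed=seed)
        assert hi.sphericity < lo.sphericity


def test_measured_surface_matches_continuous_truth():
    vol, truth = generate_volume_mask(10.0, 0.4, voxel_size=0.5, seed=3)
    rec = sphericity(vol)
    assert rec.surface_area == pytest.approx(truth.surface_cm2, rel=0.05)
    assert rec.volume == pytest.approx(truth.volume_cm3, rel=0.05)


def test_volume_too_coarse_grid_errors():
    with pytest.raises(ValueError, match="voxel_size"):
        generate_volume_mask(0.01, 0.1, voxel_size=1.0)


def test_cohort_minimal_and_coupling_zero():
    vols, table = generate_cohort(2, seed=1)
    assert len(vols) == 2 and len(table) == 2

    _, t0 = generate_cohort(30, sphericity_volume_coupling=0.0, seed=2,
                            voxel_target_across=24)
    small = t0["volume_cm3"] <= t0["volume_cm3"].median()
    med_s = t0.loc[small, "true_sphericity"].median()
    med_l = t0.loc[~small, "true_sphericity"].median()
    assert med_s == pytest.approx(med_l, abs=0.08)


def test_cohort_coupling_orders_truth_sphericity():
    _, table = generate_cohort(30, sphericity_volume_coupling=0.12,
                               seed=2, voxel_target_across=24)
    small = table["volume_cm3"] <= table["volume_cm3"].median()
    assert (table.loc[small, "true_sphericity"].median()
            > table.loc[~small, "true_sphericity"].median())
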