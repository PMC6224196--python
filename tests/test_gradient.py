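import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cytograd as cg

LN2 = np.log(2.0)


# --------------------------------------------------------------------------
# exponential trend fit and the slope statistic
# --------------------------------------------------------------------------

@pytest.mark.parametrize("Cmax, lam, expected_slope", [
    (100.0, 20.0, 100.0 / (2 * 20.0 * LN2)),   # ~3.61 AU/um
    (100.0, 100.0, 100.0 / (2 * 100.0 * LN2)),  # ~0.721 AU/um
])
def test_noiseless_exponential_fit_matches_closed_form(Cmax, lam, expected_slope):
    x = np.arange(0.0, 121.0, 1.0)
    prof = cg.profile_from_values(x, Cmax * np.exp(-x / lam))
    fit = cg.fit_exponential(prof)
    assert fit.ok
    assert fit.Cmax == pytest.approx(Cmax, rel=1e-6)
    assert fit.lam == pytest.approx(lam, rel=1e-6)
    assert fit.slope == pytest.approx(expected_slope, rel=1e-6)
    assert fit.x_half - fit.x_max == pytest.approx(lam * LN2, rel=1e-6)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(Cmax=st.floats(1.0, 500.0), lam=st.floats(5.0, 80.0))
def test_slope_closed_form_property(Cmax, lam):
    """For any background-free exponential, slope * 2 * lambda * ln2 = Cmax."""
    x = np.arange(0.0, 121.0, 1.0)
    fit = cg.fit_exponential(cg.profile_from_values(x, Cmax * np.exp(-x / lam)))
    assert fit.slope * 2.0 * fit.lam * LN2 == pytest.approx(Cmax, rel=1e-6)


def test_background_term_recovered():
    x = np.arange(0.0, 121.0, 1.0)
    fit = cg.fit_exponential(cg.profile_from_values(x, 7.0 + 50.0 * np.exp(-x / 30.0)))
    assert fit.background == pytest.approx(7.0, abs=1e-6)
    assert fit.slope == pytest.approx(50.0 / (2 * 30.0 * LN2), rel=1e-5)


def test_constant_profile_is_flagged():
    prof = cg.profile_from_values(np.arange(10.0), np.full(10, 3.0))
    fit = cg.fit_exponential(prof)
    assert not fit.ok
    assert np.isnan(fit.slope)


def test_rising_profile_is_flagged_nondecaying():
    x = np.arange(0.0, 50.0, 1.0)
    fit = cg.fit_exponential(cg.profile_from_values(x, 1.0 + x))
    assert not fit.ok


# --------------------------------------------------------------------------
# profiles / straightening
# --------------------------------------------------------------------------

def test_uniform_image_gives_constant_profile():
    img = np.full((60, 200), 7.5)
    mid = cg.axis_midline(30.0, origin=(0.0, 4.0))
    for proj in ("mean", "max"):
        prof = cg.extract_profile(img, mid, band_width_px=20, projection=proj,
                                  pixel_size=0.2, origin=(0.0, 0.0))
        assert np.allclose(prof.values, 7.5)


def test_straight_scene_axis_and_midline_profiles_agree(small_scene):
    cfg, stack, truth = small_scene
    axis = cg.axis_midline(cfg.axis_length)
    mid = cg.Midline(vertices=truth.midline,
                     s=np.linspace(0, cfg.axis_length, len(truth.midline)))
    p1 = cg.extract_profile(stack, axis, channel="ligand")
    p2 = cg.extract_profile(stack, mid, channel="ligand")
    n = min(len(p1.values), len(p2.values))
    assert np.allclose(p1.values[:n], p2.values[:n], rtol=1e-6, atol=1e-9)


def test_curved_scene_straightening_recovers_decay_length():
    """Digital straightening of a curved tube recovers the configured
    decay length within 5% (averaged replicate profiles, as measured
    profiles are)."""
    profs = []
    for seed in (1, 2, 3, 4):
        cfg = cg.SceneConfig(n_cells=12, seed=seed, curvature=0.02,
                             gradient=cg.GradientConfig(Cmax=100.0, lam=20.0))
        stack, truth = cg.render_scene(cfg)
        mid = cg.Midline(vertices=truth.midline,
                         s=np.linspace(0, cfg.axis_length, len(truth.midline)))
        profs.append(cg.extract_profile(stack, mid, channel="ligand"))
    n = min(len(p.values) for p in profs)
    vals = np.mean([p.values[:n] for p in profs], axis=0)
    fit = cg.fit_exponential(cg.profile_from_values(profs[0].positions[:n], vals))
    assert fit.lam == pytest.approx(20.0, rel=0.05)


# --------------------------------------------------------------------------
# midline fitting
# --------------------------------------------------------------------------

def test_collinear_anchors_give_straight_midline():
    pts = np.stack([np.linspace(0, 50, 12), np.zeros(12)], axis=1)
    mid = cg.fit_midline(pts, smoothing=0.0)
    assert mid.length == pytest.approx(50.0, rel=1e-3)
    assert np.allclose(mid.vertices[:, 1], 0.0, atol=1e-6)


def test_semicircle_arc_length_within_one_percent():
    R = 30.0
    th = np.linspace(0, np.pi, 20)
    pts = np.stack([R * np.cos(th), R * np.sin(th)], axis=1)
    mid = cg.fit_midline(pts, smoothing=0.0)
    assert mid.length == pytest.approx(np.pi * R, rel=0.01)


def test_midline_from_curved_scene_mask_tracks_truth():
    cfg = cg.SceneConfig(n_cells=12, seed=2, curvature=0.02)
    stack, truth = cg.render_scene(cfg)
    mid = cg.fit_midline(truth.tube_mask, max_deviation=3.0)
    pix_truth = (truth.midline - np.array(stack.origin)) / stack.pixel_size
    from scipy.spatial import cKDTree
    d, _ = cKDTree(mid.vertices).query(pix_truth[::5])
    assert float(np.sqrt(np.mean(d ** 2))) < 1.5  # px RMS


def test_self_intersecting_midline_rejected():
    # a constant-radius path over 2.5 turns revisits and crosses itself
    th = np.linspace(0, 2.5 * np.pi, 40)
    pts = np.stack([10 * np.cos(th), 10 * np.sin(th)], axis=1)
    with pytest.raises(ValueError, match="intersect"):
        cg.fit_midline(pts, smoothing=0.0)


# --------------------------------------------------------------------------
# slope-length correlation
# --------------------------------------------------------------------------

def test_perfect_negative_line_gives_r_minus_one():
    pairs = [(60.0, 3.0), (90.0, 2.0), (120.0, 1.0)]
    r, p, n = cg.correlate_slope_length(pairs)
    assert r == pytest.approx(-1.0)
    assert n == 3


def test_independent_pairs_have_small_correlation():
    rng = np.random.default_rng(0)
    pairs = np.stack([rng.uniform(50, 150, 100), rng.uniform(0.5, 3.5, 100)], axis=1)
    r, p, n = cg.correlate_slope_length(pairs)
    assert abs(r) < 0.3


def test_zero_variance_raises():
    with pytest.raises(ValueError):
        cg.correlate_slope_length([(100.0, 1.0), (100.0, 2.0), (100.0, 3.0)])


# --------------------------------------------------------------------------
# clone ratios
# --------------------------------------------------------------------------

def test_uniform_image_clone_ratio_is_one():
    img = np.full((60, 200), 5.0)
    clone = np.zeros_like(img, dtype=bool)
    clone[35:55, 40:80] = True
    control = np.zeros_like(clone)
    control[5:25, 40:80] = True
    m = cg.clone_ratio(img, clone, control_mask=control, pixel_size=0.2)
    assert m.ratio_out_in == pytest.approx(1.0)


def test_halved_clone_intensity_gives_ratio_two():
    img = np.full((60, 200), 8.0)
    clone = np.zeros_like(img, dtype=bool)
    clone[35:55, 40:80] = True
    img[clone] /= 2.0
    control = np.zeros_like(clone)
    control[5:25, 40:80] = True
    m = cg.clone_ratio(img, clone, control_mask=control, pixel_size=0.2)
    assert m.ratio_out_in == pytest.approx(2.0)


def test_mismatched_control_area_rejected():
    img = np.ones((60, 200))
    clone = np.zeros_like(img, dtype=bool)
    clone[35:55, 40:80] = True
    control = np.zeros_like(clone)
    control[5:15, 40:80] = True  # half the area
    with pytest.raises(ValueError, match="area"):
        cg.clone_ratio(img, clone, control_mask=control)


def test_overlapping_masks_rejected():
    img = np.ones((60, 200))
    clone = np.zeros_like(img, dtype=bool)
    clone[20:40, 40:80] = True
    with pytest.raises(ValueError, match="overlap"):
        cg.clone_ratio(img, clone, control_mask=clone)


def test_zero_inside_density_flags_infinite_ratio():
    img = np.zeros((60, 200))
    clone = np.zeros_like(img, dtype=bool)
    clone[35:55, 40:80] = True
    control = np.zeros_like(clone)
    control[5:25, 40:80] = True
    img[control] = 1.0
    m = cg.clone_ratio(img, clone, control_mask=control)
    assert np.isinf(m.ratio_out_in)


def test_reduced_uptake_clone_ratio_recovers_inverse_uptake():
    """Mean mirrored-control ratio over 50 scenes recovers 1/uptake within
    10% for uptake factors 0.25, 0.5 and 1 (ROIs drawn interior to the
    clone to avoid PSF-scale edge spillover)."""
    from scipy.ndimage import binary_erosion
    for uptake in (0.25, 0.5, 1.0):
        ratios = []
        for seed in range(50):
            cfg = cg.SceneConfig(
                n_cells=12, seed=seed + 1,
                clones=[cg.CloneConfig(cell_range=(4, 6), uptake_factor=uptake)])
            stack, truth = cg.render_scene(cfg)
            roi = binary_erosion(truth.clone_masks[0], iterations=4)
            m = cg.clone_ratio(stack, roi, midline=cg.axis_midline(cfg.axis_length))
            ratios.append(m.ratio_out_in)
        assert np.mean(ratios) == pytest.approx(1.0 / uptake, rel=0.10)


# --------------------------------------------------------------------------
# puncta and colocalization
# --------------------------------------------------------------------------

def test_identical_sets_fully_colocalize():
    pts = np.random.default_rng(1).uniform(0, 50, size=(40, 2))
    assert cg.colocalization_fraction(pts, pts, 0.5) == 1.0


def test_far_separated_sets_do_not_colocalize():
    a = np.zeros((10, 2))
    b = np.full((10, 2), 100.0)
    assert cg.colocalization_fraction(a, b, 0.5) == 0.0


def test_empty_reference_set_is_flagged_nan():
    with pytest.warns(UserWarning):
        frac = cg.colocalization_fraction(np.empty((0, 2)), np.zeros((3, 2)), 0.5)
    assert np.isnan(frac)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(seed=st.integers(0, 10_000))
def test_colocalization_monotone_in_distance(seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 20, size=(30, 2))
    b = rng.uniform(0, 20, size=(25, 2))
    fracs = [cg.colocalization_fraction(a, b, d) for d in (0.2, 0.5, 1.0, 3.0, 30.0)]
    assert all(0.0 <= f <= 1.0 for f in fracs)
    assert all(x <= y for x, y in zip(fracs, fracs[1:]))
    assert fracs[-1] == 1.0


def test_detected_puncta_match_planted_spots():
    img = np.zeros((80, 80))
    rng = np.random.default_rng(4)
    pts = rng.uniform(8, 72, size=(12, 2))
    for r, c in pts:
        rr, cc = np.meshgrid(np.arange(80), np.arange(80), indexing="ij")
        img += 50 * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * 1.5 ** 2))
    det = cg.detect_puncta(img, pixel_size=0.2, sigma_um=0.3, threshold=3.0)
    assert len(det) == pytest.approx(12, abs=2)
    from scipy.spatial import cKDTree
    d, _ = cKDTree(det[["y_um", "x_um"]].to_numpy() / 0.2).query(pts)
    assert np.median(d) < 1.5


def test_receptor_binding_fraction_recovered():
    """Colocalized fraction of ligand vs receptor puncta recovers the
    configured binding probability within its binomial 99% CI (20 seeds)."""
    p_bind = 0.9
    fracs, ns = [], []
    for seed in range(20):
        cfg = cg.SceneConfig(n_cells=12, seed=seed + 100,
                             puncta=cg.PunctaConfig(receptor_binding_prob=p_bind))
        _, truth = cg.render_scene(cfg)
        lig = truth.puncta
        rec = truth.puncta[truth.puncta.receptor_bound]
        fracs.append(cg.colocalization_fraction(lig, rec, 0.1))
        ns.append(len(lig))
    n_tot = int(np.sum(ns))
    ci = 2.576 * np.sqrt(p_bind * (1 - p_bind) / n_tot)
    assert abs(float(np.mean(fracs)) - p_bind) <= ci + 0.01
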