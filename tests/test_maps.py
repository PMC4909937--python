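"""Connectivity maps, composite overlays and evoked-response statistics."""

import numpy as np
import pytest

from mesocage import dff as dffmod
from mesocage import maps as mapsmod
from mesocage import synthetic as syn


def region_centroid(mask):
    ys, xs = np.nonzero(mask)
    return int(round(ys.mean())), int(round(xs.mean()))


@pytest.fixture(scope="module")
def dff900(movie900, scene64):
    _, masks = scene64
    return dffmod.preprocess(movie900.stack, masks, discard_s=0.0)


# ---------------------------------------------------------------------------
# seed maps
# ---------------------------------------------------------------------------


def test_seed_correlates_perfectly_with_itself(dff900, scene64):
    truth, _ = scene64
    seed = region_centroid(truth.region_masks["V1-R"])
    cmap = mapsmod.seed_map(dff900, seed)
    assert cmap.r_image[seed] == pytest.approx(1.0)
    assert np.nanmax(np.abs(cmap.r_image)) <= 1.0 + 1e-12


def test_homotopic_seed_correlation_recovered(dff900, movie900):
    """Seed in right V1 lights up left V1 near the injected rho=0.8."""
    truth = movie900.truth
    seed = region_centroid(truth.region_masks["V1-R"])
    cmap = mapsmod.seed_map(dff900, seed)
    partner = np.nanmedian(cmap.r_image[truth.region_masks["V1-L"]])
    assert partner == pytest.approx(0.8, abs=0.1)


def test_seed_map_requires_enough_frames(dff900):
    with pytest.raises(ValueError, match="min_frames"):
        mapsmod.seed_map(dff900, (32, 32), min_frames=10_000)


def test_seed_placement_from_bregma_mm(geom64, scene64):
    truth, _ = scene64
    seed = mapsmod.seed_from_mm(geom64, *syn.DEFAULT_REGION_COORDS_MM["V1"])
    # lands inside the right-hemisphere V1 disk of the default scene
    assert truth.region_masks["V1-R"][seed]


# ---------------------------------------------------------------------------
# region matrix
# ---------------------------------------------------------------------------


def test_region_matrix_is_symmetric_with_unit_diagonal(dff900, scene64):
    truth, _ = scene64
    m = mapsmod.region_matrix(dff900, truth.region_masks)
    np.testing.assert_allclose(m.values, m.values.T)
    np.testing.assert_allclose(np.diag(m.values), 1.0)


def test_block_structure_recovered_within_tolerance(geom64, scene64):
    """Homotopic rho=0.8 and a cross-network rho=0.2 both come back ±0.1."""
    base, masks = scene64
    truth, _ = syn.default_scene(geom64, extra_mixing={("HL-R", "M1-R"): 0.2,
                                                       ("HL-L", "M1-L"): 0.2})
    movie = syn.generate_movie(truth, geom64, duration_s=90.0, seed=31,
                               masks=masks)
    dff = dffmod.preprocess(movie.stack, masks, discard_s=0.0)
    m = mapsmod.region_matrix(dff, truth.region_masks)
    for name in ("V1", "BC", "HL"):
        assert m.loc[f"{name}-L", f"{name}-R"] == pytest.approx(0.8, abs=0.1)
    assert m.loc["HL-R", "M1-R"] == pytest.approx(0.2, abs=0.1)
    assert abs(m.loc["V1-L", "M2-R"]) < 0.15   # uncoupled pair stays low


def test_empty_roi_rejected(dff900):
    with pytest.raises(ValueError, match="empty"):
        mapsmod.region_matrix(dff900, {"a": np.zeros((64, 64), bool),
                                       "b": np.ones((64, 64), bool)})


# ---------------------------------------------------------------------------
# composite thresholded maps
# ---------------------------------------------------------------------------


def test_threshold_one_keeps_only_the_seed(dff900, scene64):
    truth, _ = scene64
    seed = region_centroid(truth.region_masks["V1-R"])
    cmap = mapsmod.seed_map(dff900, seed)
    comp = mapsmod.composite_threshold_map({"V1": cmap}, r_threshold=1.0 - 1e-9,
                                           min_area=1)
    ys, xs = np.nonzero(comp.label_images["V1"])
    assert list(zip(ys, xs)) == [seed]


def test_threshold_zero_selects_full_valid_map(dff900, scene64):
    truth, _ = scene64
    seed = region_centroid(truth.region_masks["V1-R"])
    cmap = mapsmod.seed_map(dff900, seed)
    with pytest.warns(UserWarning):
        comp = mapsmod.composite_threshold_map({"V1": cmap}, r_threshold=-1.0)
    assert comp.label_images["V1"].sum() == cmap.valid_mask.sum()


def test_remote_island_found_in_coupled_motor_region(geom64, scene64):
    """HL seed with injected HL->M1 coupling shows an island whose centroid
    falls in motor cortex."""
    _, masks = scene64
    # one sensorimotor network: every HL/M1 pair shares the homotopic-level
    # coupling (keeps the target correlation matrix positive semi-definite)
    net = {(a, b): 0.8 for i, a in enumerate(["HL-L", "HL-R", "M1-L", "M1-R"])
           for b in ["HL-L", "HL-R", "M1-L", "M1-R"][i + 1:]}
    truth, _ = syn.default_scene(geom64, extra_mixing=net)
    movie = syn.generate_movie(truth, geom64, duration_s=90.0, seed=17,
                               masks=masks)
    dff = dffmod.preprocess(movie.stack, masks, discard_s=0.0)
    seed = region_centroid(truth.region_masks["HL-R"])
    cmap = mapsmod.seed_map(dff, seed)
    comp = mapsmod.composite_threshold_map({"HL": cmap}, r_threshold=0.5,
                                           min_area=4)
    remote = comp.islands[comp.islands.remote]
    assert len(remote) >= 1
    m1 = truth.region_masks["M1-R"]
    hit = [m1[int(round(r.centroid_row)), int(round(r.centroid_col))]
           for r in remote.itertuples()]
    assert any(hit)


def test_gfp_control_seed_map_is_flat(geom64, scene64):
    """Indicator-free control through the full pipeline: off-seed |r|
    stays below 0.2 (no spurious connectivity)."""
    truth, masks = scene64
    movie = syn.generate_gfp_control(truth, geom64, duration_s=90.0, seed=23,
                                     masks=masks)
    dff = dffmod.preprocess(movie.stack, masks, discard_s=0.0)
    seed = region_centroid(truth.region_masks["BC-R"])
    cmap = mapsmod.seed_map(dff, seed)
    yy, xx = np.mgrid[:64, :64]
    off_seed = ((yy - seed[0]) ** 2 + (xx - seed[1]) ** 2 > 3 ** 2) \
        & masks.window_mask
    assert np.nanmax(np.abs(cmap.r_image[off_seed])) < 0.2


# ---------------------------------------------------------------------------
# evoked averages
# ---------------------------------------------------------------------------


def evoked_movie(geom64, scene64, n_events, peak=0.049, seed=42):
    truth, masks = scene64
    times = [5.0 + 5.0 * i for i in range(n_events)]
    ev = [syn.EvokedEvent(t, "V1-R", peak) for t in times]
    t = syn.GroundTruth(**{**truth.__dict__, "evoked": ev})
    movie = syn.generate_movie(t, geom64, duration_s=times[-1] + 5.0,
                               seed=seed, masks=masks)
    dff = dffmod.preprocess(movie.stack, masks, discard_s=0.0, band=None)
    return dff, times, truth.region_masks["V1-R"]


def test_null_fixture_shows_no_response(geom64, scene64):
    truth, masks = scene64
    movie = syn.generate_gfp_control(truth, geom64, duration_s=65.0, seed=3,
                                     masks=masks)
    dff = dffmod.preprocess(movie.stack, masks, discard_s=0.0, band=None)
    resp = mapsmod.evoked_average(dff, [5.0 + 5 * i for i in range(11)],
                                  roi=truth.region_masks["V1-R"])
    assert abs(resp.peak_amp) < 1.0
    assert resp.p_value > 0.05


def test_injected_response_recovered(geom64, scene64):
    """24 flashes with a 4.9% 0.5s-latency transient: amplitude within 20%,
    latency within 0.1 s, decisive paired test."""
    dff, times, roi = evoked_movie(geom64, scene64, n_events=24)
    resp = mapsmod.evoked_average(dff, times, roi=roi)
    assert resp.n_events == 24
    assert resp.peak_amp == pytest.approx(4.9, rel=0.2)
    assert resp.peak_latency_s == pytest.approx(0.5, abs=0.1)
    assert resp.p_value < 0.001
    assert resp.sem_trace is not None


def test_single_event_has_no_sem_or_p(geom64, scene64):
    dff, times, roi = evoked_movie(geom64, scene64, n_events=2)
    resp = mapsmod.evoked_average(dff, times[:1], roi=roi)
    assert resp.n_events == 1
    assert resp.sem_trace is None and resp.p_value is None


def test_edge_events_dropped_with_warning(geom64, scene64):
    dff, times, roi = evoked_movie(geom64, scene64, n_events=4)
    with pytest.warns(UserWarning, match="dropped"):
        resp = mapsmod.evoked_average(dff, [0.5] + times, roi=roi)
    assert resp.n_dropped == 1
    assert resp.n_events == 4


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------


def test_nine_trial_concatenation_arithmetic(geom64, scene64):
    truth, masks = scene64
    trials = []
    for s in range(9):
        movie = syn.generate_movie(truth, geom64, duration_s=28.0, seed=50 + s,
                                   masks=masks)
        dff = dffmod.preprocess(movie.stack, masks, discard_s=1.0)
        trials.append(dff)
    combo = mapsmod.concatenate_trials(trials)
    assert combo.n_frames == 9 * 810
    assert combo.session_boundaries == [810 * i for i in range(9)]


def test_single_trial_concatenation_is_identity(dff900):
    assert mapsmod.concatenate_trials([dff900]) is dff900


def test_provenance_mismatch_refused(movie900, scene64):
    _, masks = scene64
    a = dffmod.preprocess(movie900.stack, masks, discard_s=0.0)
    b = dffmod.preprocess(movie900.stack, masks, discard_s=0.0,
                          global_regression=False)
    with pytest.raises(ValueError, match="global_regressed"):
        mapsmod.concatenate_trials([a, b])


def test_concatenation_preserves_correlation_estimates(geom64, scene64):
    """r from two concatenated statistically identical trials agrees with
    the single-trial r within the Fisher-z sampling bound."""
    truth, masks = scene64
    dffs = []
    for s in (60, 61):
        movie = syn.generate_movie(truth, geom64, duration_s=30.0,
                                   seed=s, masks=masks)
        dffs.append(dffmod.preprocess(movie.stack, masks, discard_s=0.0))
    seed_px = region_centroid(truth.region_masks["V1-R"])
    partner = truth.region_masks["V1-L"]
    r1 = np.nanmedian(mapsmod.seed_map(dffs[0], seed_px).r_image[partner])
    combo = mapsmod.concatenate_trials(dffs)
    r2 = np.nanmedian(mapsmod.seed_map(combo, seed_px).r_image[partner])
    # band-limited traces carry ~2*BW independent samples per second
    n_eff = 2 * 2.7 * 30.0
    z1, z2 = np.arctanh([r1, r2])
    assert abs(z1 - z2) < 3.0 / np.sqrt(n_eff - 3)
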