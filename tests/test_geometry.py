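"""Synthetic trabeculated-heart generator: shape, motion and sampling."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from shapely.geometry import LinearRing, Point, Polygon

from trabflow.geometry import (GeometryError, GeometryParams, MotionModel,
                               MovingBoundary, TrappedCellSpec,
                               add_trapped_cells, decompose_motion,
                               default_volume_waveform, generate_groove,
                               generate_ventricle, measure_grooves,
                               measure_rotation, smooth_counterpart,
                               wall_velocities)


def shoelace(pts):
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)


# --------------------------------------------------------------------------
# parameter validation
# --------------------------------------------------------------------------

@pytest.mark.parametrize("kw", [
    {"inner_diameter": 20.0},                 # outside observed 30-50 range
    {"groove_radial": 25.0},                  # deeper than half the lumen
    {"cell_diameter": 20.0},                  # cell cannot fit a groove
    {"n_grooves": -1},
    {"node_spacing": -1.0},
])
def test_invalid_geometry_params_rejected(kw):
    with pytest.raises(GeometryError):
        GeometryParams(**kw).validate()


def test_motion_model_validation():
    with pytest.raises(GeometryError):
        MotionModel(max_rotation=0.08).validate()
    with pytest.raises(GeometryError):
        MotionModel(n_frames=4).validate()
    with pytest.raises(GeometryError):
        MotionModel(volume_waveform=lambda p: np.asarray(p)).validate()
    MotionModel().validate()


# --------------------------------------------------------------------------
# ventricle generator
# --------------------------------------------------------------------------

def test_enclosed_area_follows_volume_waveform(ventricle):
    """Shoelace polygon area per frame tracks the prescribed waveform."""
    areas = ventricle.areas()
    motion = ventricle.metadata["motion"]
    target = np.asarray(motion.volume_waveform(ventricle.phases()))
    rel = areas / areas[0] - target / target[0]
    assert np.max(np.abs(rel)) < 0.01
    # construction should actually be exact, not just within tolerance
    assert np.max(np.abs(rel)) < 1e-9


def test_every_frame_simple_and_positive(ventricle):
    for f in range(ventricle.n_frames):
        pts = ventricle.loop_coords(f, 0)
        assert shoelace(pts) > 0
        assert LinearRing(pts).is_valid


def test_seeded_determinism_bit_identical():
    a = generate_ventricle(seed=7)
    b = generate_ventricle(seed=7)
    assert np.array_equal(a.coords, b.coords)
    assert np.array_equal(a.labels, b.labels)
    c = generate_ventricle(seed=8)
    assert not np.array_equal(a.coords, c.coords)


def test_nominal_groove_dimensions_at_end_systole():
    """With zero dimension spread, the end-systolic frame realizes the
    nominal 12.5 / 8.7 / 21.7 um groove dimensions -- checked against the
    construction record and, independently, against the recession of the
    generated coordinates beyond the envelope ellipse."""
    params = GeometryParams(n_grooves=4, groove_long_sd=0.0,
                            groove_radial_sd=0.0, groove_circ_sd=0.0)
    motion = MotionModel(translation_waveform=lambda p: np.zeros(
        np.atleast_1d(np.asarray(p)).shape + (2,)), max_rotation=0.0)
    mb = generate_ventricle(params, motion, seed=3)
    dims = measure_grooves(mb)
    assert dims["depth"] == pytest.approx([8.7] * 4, rel=0.02)
    assert dims["width"] == pytest.approx([21.7] * 4, rel=0.02)
    assert dims["long"] == pytest.approx([12.5] * 4, rel=0.02)

    # independent oracle: distance of groove nodes beyond the envelope
    f_es = int(np.argmin(mb.areas()))
    scale = mb.metadata["scales"][f_es]
    a, b = mb.metadata["envelope_axes"]
    t = np.linspace(0, 2 * np.pi, 2000)
    ring = LinearRing(np.column_stack([scale * a * np.cos(t),
                                       scale * b * np.sin(t)]))
    env_poly = Polygon(ring)
    for j in range(4):
        nodes = mb.coords[f_es][(mb.groove_ids == j)
                                & (mb.labels.astype(str) == "groove")]
        depth = max(ring.distance(Point(p)) for p in nodes
                    if not env_poly.contains(Point(p)))
        assert depth == pytest.approx(8.7, rel=0.05)


def test_zero_grooves_equals_smooth_counterpart():
    mb = generate_ventricle(GeometryParams(n_grooves=0), seed=2)
    sm = smooth_counterpart(mb)
    assert sm.n_nodes == mb.n_nodes
    assert np.allclose(sm.coords, mb.coords, atol=1e-6)


def test_groove_dimension_sampling_statistics():
    """Over 100 seeds the realized dimensions reproduce the measured
    statistics: means within one sd-of-mean, sds within 30%."""
    dims = {"depth": [], "width": [], "long": []}
    for seed in range(100):
        d = measure_grooves(generate_ventricle(seed=seed))
        for k in dims:
            dims[k].extend(d[k])
    targets = {"long": (12.5, 3.1), "depth": (8.7, 0.8), "width": (21.7, 10.7)}
    for k, (mu, sd) in targets.items():
        arr = np.asarray(dims[k])
        assert abs(arr.mean() - mu) < sd / np.sqrt(arr.size)
        assert abs(arr.std() - sd) < 0.3 * sd


def test_groove_nodes_recessed_beyond_ridge_hull(ventricle):
    """Ground-truth labels: at end systole every groove node lies strictly
    outside the convex hull of the ridge crest nodes (grooves are pockets
    recessed past the crest envelope)."""
    f_es = int(np.argmin(ventricle.areas()))
    pts = ventricle.coords[f_es]
    lab = ventricle.labels.astype(str)
    hull = ConvexHull(pts[lab == "ridge"])
    poly = Polygon(pts[lab == "ridge"][hull.vertices])
    for p in pts[lab == "groove"]:
        assert not poly.contains(Point(p))


def test_rotation_measured_below_bound(ventricle):
    rot = measure_rotation(ventricle)
    assert np.max(np.abs(rot)) < 0.07
    assert ventricle.metadata["max_rotation_measured"] == pytest.approx(
        np.max(np.abs(rot)))


def test_infeasible_packing_rejected():
    with pytest.raises(GeometryError, match="packing"):
        generate_ventricle(GeometryParams(n_grooves=12, groove_circ_sd=0.0),
                           seed=0)


# --------------------------------------------------------------------------
# smooth counterpart
# --------------------------------------------------------------------------

def test_smooth_counterpart_matches_stroke_and_convexity(ventricle):
    sm = smooth_counterpart(ventricle)
    at, asm = ventricle.areas(), sm.areas()
    stroke_t = at.max() - at.min()
    stroke_s = asm.max() - asm.min()
    assert abs(stroke_t - stroke_s) / stroke_t < 0.02
    assert np.max(np.abs(at - asm) / at) < 0.02
    # no pockets: curvature sign never alternates (smooth loop is convex)
    pts = sm.loop_coords(0, 0)
    e = np.roll(pts, -1, axis=0) - pts
    cross = e[:, 0] * np.roll(e, -1, axis=0)[:, 1] \
        - e[:, 1] * np.roll(e, -1, axis=0)[:, 0]
    assert np.all(cross > -1e-9)


# --------------------------------------------------------------------------
# isolated groove
# --------------------------------------------------------------------------

def test_groove_cavity_depth_and_opening(groove):
    assert groove.metadata["groove_depth"] == pytest.approx(8.7, abs=2 * 0.8)
    assert "mouth" in groove.openings
    assert (groove.labels.astype(str) == "groove").sum() > 0


def test_zero_amplitude_motion_freezes_groove():
    flat = MotionModel(
        volume_waveform=lambda p: np.ones(np.atleast_1d(np.asarray(p)).shape),
        translation_waveform=lambda p: np.zeros(
            np.atleast_1d(np.asarray(p)).shape + (2,)),
        max_rotation=0.0)
    g = generate_groove(motion=flat, seed=0, node_spacing=0.9)
    assert np.allclose(g.coords, g.coords[:1], atol=1e-9)


# --------------------------------------------------------------------------
# motion decomposition
# --------------------------------------------------------------------------

def test_decompose_recompose_identity(groove):
    trans, deform, transl = decompose_motion(groove)
    recomposed = deform.coords + trans[:, None, :]
    scale = np.max(np.abs(groove.coords))
    assert np.max(np.abs(recomposed - groove.coords)) < 1e-9 * scale
    assert np.max(np.abs(transl.coords
                         - (groove.coords[:1] + trans[:, None, :]))) == 0.0
    # deformation-only frames share the frame-0 centroid
    for f in range(deform.n_frames):
        assert deform.centroid(f) == pytest.approx(groove.centroid(0),
                                                   abs=1e-9)


def test_decompose_pure_translation_and_pure_squeeze():
    base = generate_groove(seed=1, node_spacing=0.9)
    _, deform, transl = decompose_motion(base)
    # translation-only input: deformation splits out as all-identical frames
    _, d2, _ = decompose_motion(transl)
    assert np.allclose(d2.coords, d2.coords[:1], atol=1e-9)
    # centroid-pinned input: translation series is zero
    t3, _, _ = decompose_motion(deform)
    assert np.max(np.abs(t3)) < 1e-9


def test_decompose_requires_frames():
    g = generate_groove(seed=0, node_spacing=0.9)
    g1 = MovingBoundary(coords=g.coords[:1], labels=g.labels,
                        groove_ids=g.groove_ids, loops=g.loops,
                        openings=g.openings, cycle_duration=g.cycle_duration)
    with pytest.raises(GeometryError):
        decompose_motion(g1)


# --------------------------------------------------------------------------
# wall velocities
# --------------------------------------------------------------------------

def test_wall_velocity_static_zero():
    flat = MotionModel(
        volume_waveform=lambda p: np.ones(np.atleast_1d(np.asarray(p)).shape),
        translation_waveform=lambda p: np.zeros(
            np.atleast_1d(np.asarray(p)).shape + (2,)),
        max_rotation=0.0)
    g = generate_groove(motion=flat, seed=0, node_spacing=0.9)
    for f in (0, 3):
        assert np.max(np.abs(wall_velocities(g, f))) < 1e-9


def test_wall_velocity_sinusoid_closed_form():
    """Central differencing of x(t) = A sin(2 pi t / T) at t = 0 gives
    (A / dt) sin(2 pi dt / T), i.e. 2 pi A / T to O(dt^2)."""
    T, n, A = 0.25, 25, 3.0
    base = generate_groove(seed=0, node_spacing=0.9)
    phases = base.phases()
    coords = np.repeat(base.coords[:1], n, axis=0).copy()
    coords[:, :, 0] += A * np.sin(2 * np.pi * phases)[:, None]
    mb = MovingBoundary(coords=coords, labels=base.labels,
                        groove_ids=base.groove_ids, loops=base.loops,
                        openings=base.openings, cycle_duration=T)
    v = wall_velocities(mb, 0)[:, 0]
    dt = T / n
    expected = A / dt * np.sin(2 * np.pi * dt / T)
    assert v == pytest.approx(np.full_like(v, expected), rel=1e-9)
    assert expected == pytest.approx(2 * np.pi * A / T, rel=0.03)


def test_reynolds_transport_identity(ventricle):
    """Sum of outward normal velocity times segment length approximates
    d(enclosed area)/dt (both discretized consistently) within 2%."""
    areas = ventricle.areas()
    n = ventricle.n_frames
    dt = ventricle.dt
    peak = np.max(np.abs((np.roll(areas, -1) - np.roll(areas, 1)) / (2 * dt)))
    for f in (3, 6, 12, 18):
        v = wall_velocities(ventricle, f)
        pts = ventricle.loop_coords(f, 0)
        e = np.roll(pts, -1, axis=0) - pts
        nrm = np.column_stack([e[:, 1], -e[:, 0]])  # length-weighted outward
        vmid = 0.5 * (v + np.roll(v, -1, axis=0))
        flux = np.sum(vmid * nrm)
        dadt = (areas[(f + 1) % n] - areas[(f - 1) % n]) / (2 * dt)
        assert abs(flux - dadt) < 0.02 * peak


# --------------------------------------------------------------------------
# trapped cells
# --------------------------------------------------------------------------

def test_trapped_cell_accepted_and_periodic(groove):
    gc = add_trapped_cells(groove, [TrappedCellSpec(diameter=7.0)], seed=0)
    assert len(gc.loops) == 2
    cell = gc.loops[1]
    # period-1 closure is inherited: frame n == frame 0 by construction,
    # and the wobble is built to return to its start
    w0 = gc.coords[0, cell]
    assert np.all(gc.labels[cell] == "cell")
    # cell never touches the wall
    for f in range(gc.n_frames):
        poly = Polygon(gc.loop_coords(f, 0))
        for p in gc.coords[f, cell][::5]:
            assert poly.contains(Point(p))
    assert w0.shape[0] >= 12


def test_oversized_cell_rejected(groove):
    with pytest.raises(GeometryError):
        add_trapped_cells(groove, [TrappedCellSpec(diameter=20.0)], seed=0)


def test_zero_wobble_cell_moves_with_host(groove):
    gc = add_trapped_cells(groove, [TrappedCellSpec(diameter=7.0,
                                                    wobble_amplitude=0.0)],
                           seed=0)
    cell = gc.loops[1]
    host = np.flatnonzero((gc.labels.astype(str) == "groove")
                          & (gc.groove_ids == 0))
    host_disp = gc.coords[:, host, :].mean(axis=1)
    cell_disp = gc.coords[:, cell, :].mean(axis=1)
    rel = (cell_disp - cell_disp[0]) - (host_disp - host_disp[0])
    assert np.max(np.abs(rel)) < 1e-9


def test_volume_waveform_periodic_two_phase():
    p = np.linspace(0, 1, 101)
    a = default_volume_waveform(p)
    assert a[0] == pytest.approx(a[-1])
    assert a.min() == pytest.approx(0.65, abs=1e-9)
    # ejection reaches the minimum at the systole split, then refills
    assert np.argmin(a) == pytest.approx(36, abs=1)
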