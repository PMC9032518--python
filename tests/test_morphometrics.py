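"""Morphometry: volume fractions, GI, thickness, sulcal widening, report."""
import math

import numpy as np
import pytest

from atrophysim.mechanics import SimulationResult
from atrophysim.morphometrics import (build_report, cao_reference_gi,
                                      cortical_thickness,
                                      cortical_thickness_of_mesh,
                                      gyrification_index,
                                      gyrification_index_2d, sulcal_widening,
                                      volume_fractions)
from atrophysim.phantom import (CSF, GM, HIPPO, VENT, WM, LabeledMesh,
                                PhantomParams, build_brain_phantom)


# ------------------------------------------------------- volume fractions

def test_brain_fractions_sum_to_one(ad_result):
    for k in range(ad_result.n_steps):
        vf = volume_fractions(ad_result.mesh, ad_result.deformed_coords(k))
        total = sum(v for r, v in vf.items() if r != "CSF")
        assert abs(total - 1.0) <= 1e-10


def test_fractions_invariant_under_uniform_scaling(small_phantom):
    m = small_phantom
    vf0 = volume_fractions(m)
    vf1 = volume_fractions(m, 0.9 * m.nodes)
    for region in vf0:
        assert vf1[region] == pytest.approx(vf0[region], rel=1e-12)


def test_annulus_fractions_match_construction(annulus_phantom):
    vf = volume_fractions(annulus_phantom)
    vols = {r: annulus_phantom.region_volume(r)
            for r in ("WM", "GM", "HIPPO", "VENT")}
    brain = sum(vols.values())
    for region, v in vols.items():
        assert vf[region] == pytest.approx(v / brain, rel=1e-12)


def test_gm_fraction_scales_with_theta_under_fixed_denominator(
        small_phantom):
    """40 healthy years in the free-shrink limit (ultrasoft fluid, so the
    tissue is barely constrained) with a fixed intracranial denominator:
    the GM fraction scales by theta_GM(40) = 0.96."""
    from atrophysim.constitutive import ultrasoft_csf_table
    from atrophysim.mechanics import SimulationConfig, run_simulation
    res = run_simulation(small_phantom, ultrasoft_csf_table(),
                         SimulationConfig(mode="healthy", t_end=40.0,
                                          dt=0.5, output_every=80))
    last = res.n_steps - 1
    vf0 = volume_fractions(res.mesh, res.deformed_coords(0),
                           denominator="intracranial")
    vf1 = volume_fractions(res.mesh, res.deformed_coords(last),
                           denominator="intracranial",
                           reference_coords=res.deformed_coords(0))
    assert vf1["GM"] / vf0["GM"] == pytest.approx(0.96, abs=0.02)


def test_zero_denominator_rejected():
    nodes = np.array([[0., 0.], [1., 0.], [0., 1.]])
    mesh = LabeledMesh(nodes=nodes, simplices=np.array([[0, 1, 2]]),
                       element_region=np.array([WM], dtype=np.int32))
    with pytest.raises(ValueError):
        volume_fractions(mesh, 0.0 * nodes)


# ------------------------------------------------------------ gyrification

def fan_mesh(boundary_pts, region=WM):
    """Fan triangulation of a star-shaped polygon about its centroid."""
    c = boundary_pts.mean(axis=0)
    nodes = np.vstack([boundary_pts, c])
    n = len(boundary_pts)
    simp = np.array([[i, (i + 1) % n, n] for i in range(n)])
    return LabeledMesh(nodes=nodes, simplices=simp,
                       element_region=np.full(n, region, dtype=np.int32))


def test_gi_of_convex_domain_is_one(annulus_phantom):
    assert gyrification_index_2d(annulus_phantom) == pytest.approx(1.0,
                                                                   abs=0.01)
    prof = gyrification_index(annulus_phantom)
    assert prof.positions.shape == (1,)
    assert prof.mean == pytest.approx(1.0, abs=0.01)


def test_gi_of_star_polygon_is_exact_perimeter_ratio():
    n_points, r_out, r_in = 12, 10.0, 6.0
    ang = np.arange(2 * n_points) * np.pi / n_points
    radii = np.where(np.arange(2 * n_points) % 2 == 0, r_out, r_in)
    pts = np.column_stack([radii * np.cos(ang), radii * np.sin(ang)])
    mesh = fan_mesh(pts)
    # closed-form: perimeter of the star and of its convex hull (12-gon)
    edge = np.linalg.norm(pts[1] - pts[0])
    star_perimeter = 2 * n_points * edge
    hull_edge = 2 * r_out * math.sin(math.pi / n_points)
    hull_perimeter = n_points * hull_edge
    gi = gyrification_index_2d(mesh)
    assert gi == pytest.approx(star_perimeter / hull_perimeter, rel=1e-12)
    assert gi > 1.0


def test_gi_3d_slicing_and_absent_slices():
    m3 = build_brain_phantom(PhantomParams(
        outer_radius=40.0, n_folds=0, fold_amplitude=0.0,
        ventricle_semiaxes=(7.0, 7.0), hippocampus_radius=4.0,
        hippocampus_center=(11.0, 0.0), target_edge_length=2.5,
        dimension=3, extrusion_thickness=5.0))
    prof = gyrification_index(m3, axis=1, n_slices=24, pixel=0.5)
    # slices beyond the tissue disk (|y| > ~35) cut only CSF -> absent
    assert np.isnan(prof.gi).any()
    inner = prof.gi[np.abs(prof.positions) < 20.0]
    assert np.all(np.isfinite(inner))
    # cross sections of the annulus stack are convex (rectangular slabs)
    assert np.nanmax(inner) < 1.12


@pytest.mark.parametrize("age, expected, places", [
    (40.0, 2.8, 1),
    (80.0, 2.6, 1),
    (85.0, 2.63, 2),
])
def test_reference_gi_curve(age, expected, places):
    assert round(cao_reference_gi(age), places) == expected


def test_reference_gi_domain_violation():
    with pytest.raises(ValueError):
        cao_reference_gi(2.0)


# -------------------------------------------------------------- thickness

def brute_force_thickness(pial, wm):
    """O(n^2) oracle for the bidirectional nearest-node thickness."""
    d2 = np.linalg.norm(pial[:, None, :] - wm[None, :, :], axis=2)
    j = np.argmin(d2, axis=1)
    d_ij = d2[np.arange(len(pial)), j]
    back = np.linalg.norm(wm[j][:, None, :] - pial[None, :, :], axis=2)
    d_jk = back.min(axis=1)
    return 0.5 * (d_ij + d_jk)


def test_thickness_of_concentric_circles():
    t, R, n = 2.0, 10.0, 500
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pial = R * np.column_stack([np.cos(ang), np.sin(ang)])
    wm = (R - t) * np.column_stack([np.cos(ang), np.sin(ang)])
    tm = cortical_thickness(pial, wm)
    spacing = 2 * np.pi * R / n
    assert np.abs(tm.values - t).max() < spacing


def test_thickness_of_parallel_polylines():
    x = np.linspace(0, 10, 200)
    pial = np.column_stack([x, np.full_like(x, 1.5)])
    wm = np.column_stack([x, np.zeros_like(x)])
    tm = cortical_thickness(pial, wm)
    np.testing.assert_allclose(tm.values, 1.5, atol=1e-12)


@pytest.mark.parametrize("n", [100, 1000])
def test_thickness_matches_brute_force_oracle(n):
    rng = np.random.default_rng(n)
    pial = rng.uniform(0, 50, size=(n, 2))
    wm = rng.uniform(0, 50, size=(n, 2))
    tm = cortical_thickness(pial, wm)
    np.testing.assert_allclose(tm.values, brute_force_thickness(pial, wm),
                               atol=1e-12)


def test_degenerate_surface_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        cortical_thickness(np.zeros((2, 2)), np.zeros((5, 2)))


def test_phantom_thickness_matches_generation_parameter(study_phantom):
    tm = cortical_thickness_of_mesh(study_phantom)
    assert tm.mean == pytest.approx(3.0, abs=0.25)
    assert tm.min > 0


# --------------------------------------------------------- sulcal widening

def pocket_fixture(delta):
    """Unit-square fluid pocket whose right wall is displaced by +delta."""
    nodes = np.array([[0., 0.], [1., 0.], [1., 1.], [0., 1.]])
    simp = np.array([[0, 1, 2], [0, 2, 3]])
    mesh = LabeledMesh(nodes=nodes, simplices=simp,
                       element_region=np.array([CSF, CSF], dtype=np.int32),
                       element_sets={"pocket": np.array([0, 1])})
    u1 = np.zeros_like(nodes)
    u1[[1, 2], 0] = delta
    return SimulationResult(mesh=mesh, mode="healthy",
                            times=np.array([0.0, 1.0]),
                            displacements=[np.zeros_like(nodes), u1],
                            thetas=[np.ones(2)] * 2,
                            concentrations=[None, None])


def test_pocket_volume_change_equals_displaced_wedge():
    res = pocket_fixture(delta=0.1)
    sw = sulcal_widening(res)
    final = sw[sw.time == 1.0].iloc[0]
    assert final.volume == pytest.approx(1.1, rel=1e-12)
    assert final.change == pytest.approx(0.1, rel=1e-12)


def test_unknown_sulcus_name_lists_available(ad_result):
    with pytest.raises(ValueError, match="sylvian"):
        sulcal_widening(ad_result, ["bogus"])


def test_ad_pocket_volumes_non_decreasing(ad_result):
    sw = sulcal_widening(ad_result)
    for _, grp in sw.groupby("sulcus"):
        v = grp.sort_values("time").volume.values
        assert np.all(np.diff(v) >= -1e-9 * v[0])


# ------------------------------------------------------------------ report

def test_report_healthy_run_properties(healthy_result):
    rep = build_report(healthy_result)
    assert rep.ventricular_expansion_factor > 1.0
    assert all(0.0 <= v <= 1.0
               for pair in rep.volume_fractions_brain.values() for v in pair)
    assert rep.thickness_young["min"] > 0


def test_report_zero_duration_changes_are_zero(small_phantom):
    from atrophysim.mechanics import SimulationConfig, run_simulation
    res = run_simulation(small_phantom, config=SimulationConfig(
        mode="healthy", t_end=0.0, dt=0.1))
    rep = build_report(res)
    assert rep.ventricular_expansion_factor == pytest.approx(1.0, abs=1e-14)
    assert rep.hippocampal_fraction_change == pytest.approx(0.0, abs=1e-14)
    assert all(v == pytest.approx(0.0, abs=1e-14)
               for v in rep.sulcal_volume_change.values())
    assert rep.gi_young == rep.gi_aged


def test_metrics_invariant_under_rigid_motion(small_phantom):
    """GI, thickness and fractions must not change under rotation+shift."""
    m = small_phantom
    a = 0.7
    Q = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    moved = m.nodes @ Q.T + np.array([12.0, -5.0])
    assert gyrification_index_2d(m, moved) == pytest.approx(
        gyrification_index_2d(m), rel=1e-12)
    t0 = cortical_thickness_of_mesh(m).values
    t1 = cortical_thickness_of_mesh(m, moved).values
    np.testing.assert_allclose(t1, t0, atol=1e-9)
    vf0, vf1 = volume_fractions(m), volume_fractions(m, moved)
    for region in vf0:
        assert vf1[region] == pytest.approx(vf0[region], rel=1e-12)
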