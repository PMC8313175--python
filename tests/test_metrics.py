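"""Validation metrics: NMSE identities, opening gap, height/bulge,
anatomic transforms, preload formula."""

import numpy as np
import pytest

import resdisc as rd
from resdisc.metrics import Curve, opening_gap


def _curve(y_model, y_mean, y_ci):
    x = np.arange(len(y_model), dtype=float)
    return Curve(x=x, y_model=y_model, y_expmean=y_mean, y_ci=y_ci)


def test_nmse_identities():
    mean = np.array([1.0, 2.0, 3.0, 2.5, 2.0])
    ci = mean + np.array([0.2, 0.3, 0.25, 0.2, 0.3])
    assert rd.nmse(_curve(mean.copy(), mean, ci)) == 0.0
    assert rd.nmse(_curve(ci.copy(), mean, ci)) == pytest.approx(1.0)


def test_nmse_hand_sum():
    model = np.array([1.1, 1.9, 3.2, 2.4, 2.2])
    mean = np.array([1.0, 2.0, 3.0, 2.5, 2.0])
    ci = mean + 0.25
    expected = np.sum((model - mean) ** 2) / np.sum(0.25**2 * np.ones(5))
    assert rd.nmse(_curve(model, mean, ci)) == pytest.approx(expected, rel=1e-12)


def test_nmse_scale_invariance():
    model = np.array([1.1, 1.9, 3.2, 2.4, 2.2])
    mean = np.array([1.0, 2.0, 3.0, 2.5, 2.0])
    ci = mean + 0.3
    v1 = rd.nmse(_curve(model, mean, ci))
    v2 = rd.nmse(_curve(7.5 * model, 7.5 * mean, 7.5 * ci))
    assert v1 == pytest.approx(v2, rel=1e-12)


def test_nmse_interpolates_model_abscissa():
    x_exp = np.array([0.0, 1.0, 2.0])
    mean = np.array([0.0, 1.0, 2.0])
    ci = mean + 1.0
    # model sampled twice as finely, exactly linear -> interpolation exact
    c = Curve(x=x_exp, y_model=np.array([0.0, 0.5, 1.0, 1.5, 2.0]).copy()[::2],
              y_expmean=mean, y_ci=ci)
    model_x = np.linspace(0, 2, 5)
    c2 = Curve(x=x_exp, y_model=np.linspace(0, 2, 5)[:3], y_expmean=mean, y_ci=ci)
    val = rd.nmse(
        Curve(x=x_exp, y_model=mean, y_expmean=mean, y_ci=ci)
    )
    assert val == 0.0
    # explicit resampling path
    cm = Curve(x=x_exp, y_model=mean, y_expmean=mean, y_ci=ci)
    assert rd.nmse(cm, model_x=None) == 0.0


def test_nmse_degenerate_ci():
    mean = np.array([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        rd.nmse(_curve(mean, mean, mean.copy()))


def test_curve_invariants():
    with pytest.raises(ValueError):
        Curve(x=np.array([0.0, 0.0, 1.0]), y_model=np.zeros(3))
    with pytest.raises(ValueError):
        Curve(x=np.array([0.0, 1.0]), y_model=np.zeros(3))


@pytest.fixture(scope="module")
def small_bovine():
    spec = rd.GeometrySpec(
        shape="bovine_cylinder", n_theta=16, n_axial=2, n_np=1, n_iaf=1, n_oaf=1
    )
    return rd.build_bovine_cylinder(spec)


def test_opening_gap_requires_release(small_bovine):
    with pytest.raises(ValueError):
        opening_gap(small_bovine, np.zeros_like(small_bovine.nodes))


def test_opening_gap_tied_zero_and_rigid_rotation(small_bovine):
    mesh = rd.release_cut(small_bovine)
    u = np.zeros_like(mesh.nodes)
    assert opening_gap(mesh, u) == pytest.approx(0.0, abs=1e-12)
    # rotate one half rigidly about z: gap equals the rotation chord length
    phi = np.deg2rad(20.0)
    Rz = np.array(
        [[np.cos(phi), -np.sin(phi), 0], [np.sin(phi), np.cos(phi), 0], [0, 0, 1]]
    )
    side_b = mesh.nodes[:, 1] < -1e-12
    rot = mesh.nodes @ Rz.T - mesh.nodes
    u = np.where(side_b[:, None], rot, 0.0)
    # the B-side cut copies are geometrically on y = 0 but belong to the
    # rotated half
    u[mesh.node_sets["cut_b"]] = rot[mesh.node_sets["cut_b"]]
    gap = opening_gap(mesh, u)
    r_out = np.linalg.norm(mesh.nodes[:, :2], axis=1).max()
    chord = 2.0 * r_out * np.sin(phi / 2.0)
    assert gap == pytest.approx(chord, rel=1e-9)
    # invariance to a rigid motion of the whole opened mesh
    u2 = u + np.array([3.0, -1.0, 2.0])
    assert opening_gap(mesh, u2) == pytest.approx(gap, rel=1e-12)


def test_height_and_bulge_synthetic_fields():
    mesh = rd.build_human_parametric(
        rd.GeometrySpec(
            shape="human_parametric", height=11.0, n_theta=16, n_axial=2,
            n_np=1, n_iaf=1, n_oaf=1, bulge=0.0,
        )
    )
    u = np.zeros_like(mesh.nodes)
    geo = rd.disc_height_and_bulge(mesh, u)
    assert geo.median_height == pytest.approx(11.0)
    assert geo.bulge_left == pytest.approx(0.0, abs=1e-9)
    # rigid translation leaves the height unchanged
    geo2 = rd.disc_height_and_bulge(mesh, u + np.array([0.5, -0.2, 3.0]))
    assert geo2.median_height == pytest.approx(11.0)
    # prescribed barrel displacement: bulge equals the mid-height offset
    H = 11.0
    w = 0.7 * np.sin(np.pi * mesh.nodes[:, 2] / H)
    r = np.linalg.norm(mesh.nodes[:, :2], axis=1)
    rmax = r.max()
    amp = (r / rmax) ** 6
    dirs = np.where(r[:, None] > 1e-9, mesh.nodes[:, :2] / np.clip(r[:, None], 1e-9, None), 0.0)
    u3 = np.zeros_like(u)
    u3[:, :2] = (w * amp)[:, None] * dirs
    geo3 = rd.disc_height_and_bulge(mesh, u3)
    assert geo3.bulge_right == pytest.approx(0.7, rel=0.05)
    assert geo3.bulge_left == pytest.approx(0.7, rel=0.05)


def test_anatomic_transform(small_bovine):
    m = small_bovine.n_elems
    cents = small_bovine.centroids()
    # hydrostatic tensors are unchanged
    T = np.tile(-2.5 * np.eye(3), (m, 1, 1))
    out = rd.anatomic_transform(T, small_bovine)
    assert np.allclose(out, T, atol=1e-12)
    # a tensor aligned with global axes permutes correctly for an element
    # on the +x axis (radial = x, circumferential = y, axial = z)
    T = np.zeros((m, 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = 1.0, 2.0, 3.0
    out = rd.anatomic_transform(T, small_bovine)
    e = int(np.argmin(np.abs(cents[:, 1]) + np.abs(cents[:, 0] - cents[:, 0].max())))
    # centroid sits half a sector off the +x axis; tolerance reflects that
    assert np.allclose(np.diag(out[e]), [1.0, 2.0, 3.0], atol=0.05)
    # trace and determinant preserved everywhere
    T = np.tile(np.array([[1.0, 0.3, 0.0], [0.3, -0.5, 0.2], [0.0, 0.2, 2.0]]), (m, 1, 1))
    out = rd.anatomic_transform(T, small_bovine)
    assert np.allclose(np.trace(out, axis1=1, axis2=2), np.trace(T, axis1=1, axis2=2), atol=1e-10)
    assert np.allclose(np.linalg.det(out), np.linalg.det(T), atol=1e-10)


def test_preload_from_lengths():
    A, P = rd.preload_from_lengths(0.0, 10.0)
    assert P == 0.0
    # A = 900 mm^2 reproduces the 270 N physiological preload
    L_ap = 900.0 / (0.84 * 40.0)
    A, P = rd.preload_from_lengths(40.0, L_ap)
    assert A == pytest.approx(900.0)
    assert P == pytest.approx(270.0)
    A, P = rd.preload_from_lengths(55.0, 37.0)
    assert A == pytest.approx(1709.4)
    assert P == pytest.approx(512.82, rel=1e-4)
    with pytest.raises(ValueError):
        rd.preload_from_lengths(-1.0, 10.0)
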