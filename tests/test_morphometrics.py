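"""OCTA-style metrics: analytic indices, rasterization, FD, IVD, Strahler."""

import numpy as np
import pytest
from scipy import ndimage

from retinapop.morphometrics import (analytic_indices, diameter_by_order,
                                     fractal_dimension, intervessel_distance,
                                     rasterize_plexus, strahler_orders)
from retinapop.network import VascularNetwork


def _single_vessel(length_mm=1.0, d_um=10.0):
    net = VascularNetwork()
    net.add_nodes([[-length_mm / 2, 0, 0], [length_mm / 2, 0, 0]],
                  "arterial", "SVP")
    net.add_segments([[0, 1]], d_um / 2, "artery", "SVP")
    return net


def test_analytic_indices_single_vessel():
    net = _single_vessel(1.0, 10.0)
    m = analytic_indices(net, "SVP")
    X = np.pi * 1.5 ** 2
    assert m["VAD"] == pytest.approx(0.01 / X)
    assert m["VSD"] == pytest.approx(1.0 / X)
    assert m["VDI"] == pytest.approx(0.01)  # 10 um in mm
    assert m["VCI"] == pytest.approx(4.0 / (4 * np.pi * 0.01))


def test_analytic_indices_clip_partial_segments():
    net = _single_vessel(10.0, 10.0)  # extends far beyond the disk
    m = analytic_indices(net, "SVP")
    assert m["L_mm"] == pytest.approx(3.0, rel=1e-9)  # disk chord


def test_analytic_indices_empty_plexus():
    net = _single_vessel()
    m = analytic_indices(net, "DCP")
    assert m["VAD"] == 0.0 and m["VSD"] == 0.0
    assert np.isnan(m["VDI"]) and np.isnan(m["VCI"])


def test_rasterize_thickness_and_skeleton():
    net = _single_vessel(2.0, 20.0)  # d = 20 um = 2 px
    mask, skel = rasterize_plexus(net, "SVP")
    cols = mask.sum(axis=0)
    mid = cols[cols > 0]
    assert np.median(mid) == pytest.approx(2.0, abs=1.0)
    # skeleton pixel count tracks segment length / px (2 mm = 200 px) within 10%
    assert abs(skel.sum() - 200) / 200 < 0.1


def test_rasterize_empty():
    net = VascularNetwork()
    mask, skel = rasterize_plexus(net, "SVP")
    assert not mask.any() and not skel.any()


def test_fractal_dimension_known_shapes():
    line = np.zeros((243, 243), bool)
    line[121, :] = True
    assert fractal_dimension(line) == pytest.approx(1.0, abs=0.05)
    assert fractal_dimension(np.ones((243, 243), bool)) == pytest.approx(
        2.0, abs=0.05)

    def carpet(k):
        if k == 0:
            return np.ones((1, 1), bool)
        c = carpet(k - 1)
        z = np.zeros_like(c)
        return np.block([[c, c, c], [c, z, c], [c, c, c]])

    expected = np.log(8) / np.log(3)
    assert fractal_dimension(carpet(3)) == pytest.approx(expected, abs=0.05)
    assert fractal_dimension(carpet(4)) == pytest.approx(expected, abs=0.05)


def test_fractal_dimension_empty_error():
    with pytest.raises(ValueError):
        fractal_dimension(np.zeros((32, 32), bool))


def test_ivd_matches_brute_force_edt():
    rng = np.random.default_rng(1)
    img = rng.random((64, 64)) < 0.05
    img[0, 0] = True
    edt = ndimage.distance_transform_edt(~img)
    ys, xs = np.nonzero(img)
    pts = np.column_stack([ys, xs])
    yy, xx = np.mgrid[0:64, 0:64]
    brute = np.sqrt(((yy[..., None] - pts[:, 0]) ** 2
                     + (xx[..., None] - pts[:, 1]) ** 2).min(axis=-1))
    assert np.allclose(edt, brute)
    got = intervessel_distance(img, px_um=10.0, fov_disk=False)
    want = 2.0 * brute[~img].mean() * 10.0
    assert got == pytest.approx(want, rel=1e-12)


def test_ivd_stripes_and_monotonicity():
    def stripes(spacing):
        sk = np.zeros((240, 240), bool)
        sk[:, ::spacing] = True
        return sk

    # spacing s: IVD ~ s/2 in pixel units (x 10 um), up to discretization
    got = intervessel_distance(stripes(20), px_um=10.0, fov_disk=False)
    assert got == pytest.approx(100.0, rel=0.2)
    assert (intervessel_distance(stripes(10), px_um=10.0, fov_disk=False)
            < intervessel_distance(stripes(20), px_um=10.0, fov_disk=False)
            < intervessel_distance(stripes(40), px_um=10.0, fov_disk=False))


# ----------------------------------------------------------------------
# Strahler ordering
# ----------------------------------------------------------------------

def _y_tree(extra_levels=0):
    """Root artery splitting into two branches, each feeding 2 capillaries."""
    net = VascularNetwork()
    pts = [[0, 0], [1, 0], [2, 1], [2, -1], [3, 1.5], [3, 0.5], [3, -0.5],
           [3, -1.5]]
    xyz = np.column_stack([np.array(pts, float), np.zeros(len(pts))])
    net.add_nodes(xyz, "arterial", "SVP")
    net.node_kind[0] = 4  # root
    net.add_segments([[0, 1]], 40.0, "artery", "SVP")
    net.add_segments([[1, 2], [1, 3]], 30.0, "artery", "SVP")
    caps = net.add_nodes(np.column_stack([np.full(4, 4.0),
                                          [1.7, 0.7, -0.7, -1.7],
                                          np.zeros(4)]), "capillary", "SVP")
    net.add_segments([[2, caps[0]], [2, caps[1]]], 2.5, "capillary", "SVP")
    net.add_segments([[3, caps[2]], [3, caps[3]]], 2.5, "capillary", "SVP")
    return net


def test_strahler_printed_rules():
    net = _y_tree()
    orders = strahler_orders(net)
    cap = net.seg_kind_mask("capillary")
    assert np.all(orders[cap] == 0)          # capillaries are order 0
    assert orders[1] == 1 and orders[2] == 1  # two order-0 branches -> 1
    assert orders[0] == 2                     # two order-1 branches -> 2


def test_strahler_mixed_orders_keep_max():
    # a vessel with branches of orders {1, 0} stays order 1
    net = VascularNetwork()
    net.add_nodes(np.column_stack([np.arange(3.0), np.zeros(3), np.zeros(3)]),
                  "arterial", "SVP")
    net.add_segments([[0, 1], [1, 2]], 30.0, "artery", "SVP")
    caps = net.add_nodes([[3, 1, 0], [3, -1, 0], [1, -1, 0]],
                         "capillary", "SVP")
    net.add_segments([[2, caps[0]], [2, caps[1]]], 2.5, "capillary", "SVP")
    net.add_segments([[1, caps[2]]], 2.5, "capillary", "SVP")
    orders = strahler_orders(net)
    assert orders[1] == 1   # two order-0 capillary branches -> 1
    assert orders[0] == 1   # branches {1, 0}: single max -> stays 1


def test_strahler_invariant_under_subdivision():
    net = _y_tree()
    base = strahler_orders(net)
    # split the trunk [0,1] into two collinear halves
    mid = net.add_nodes([[0.5, 0, 0]], "arterial", "SVP")[0]
    end = net.conn[0, 1]
    net.conn[0, 1] = mid
    net.add_segments([[mid, end]], 40.0, "artery", "SVP")
    orders = strahler_orders(net)
    assert orders[0] == base[0] and orders[-1] == base[0]
    assert np.array_equal(orders[1:3], base[1:3])


def test_diameter_by_order_symmetric_ratio(tiny_individual):
    table = tiny_individual.morphometrics.strahler
    # counts accounting: totals match the macular artery/vein segment count
    net = tiny_individual.network
    orders = strahler_orders(net)
    mid = net.midpoints()
    mac = (mid[:, :2] ** 2).sum(1) <= 9.0
    n_art = int((net.seg_kind_mask("artery") & mac).sum())
    n_ven = int((net.seg_kind_mask("vein") & mac).sum())
    assert table["n_arteriole"].sum() == n_art
    assert table["n_venule"].sum() == n_ven


def test_identical_trees_give_unit_ratio():
    net = _y_tree()
    # mirror the whole arterial tree (capillaries included) as a venous tree
    # of identical diameters
    n0 = net.n_segments
    nv = net.add_nodes(net.xyz + np.array([0, 10, 0]), "venous", "SVP")
    net.node_kind[nv[0]] = 4
    for j in range(n0):
        a, b = net.conn[j]
        kind = "vein" if net.seg_kind[j] == 0 else "capillary"
        net.add_segments([[nv[a], nv[b]]], net.radius_um[j], kind, "SVP")
    t = diameter_by_order(net, region_radius_mm=100.0)
    assert t.attrs["combined_ratio"] == pytest.approx(1.0)
    sub = t.dropna(subset=["ratio"])
    assert np.allclose(sub["ratio"], 1.0)
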