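"""Capillary beds, pruning, wiring, diameters, and flow orientation."""

import numpy as np
import pytest

from retinapop.network import VascularNetwork
from retinapop.plexus import (_seg_seg_distance,
                              assign_and_smooth_diameters, build_voronoi_bed,
                              capillary_potentials, orient_capillary_flow,
                              prune_capillaries_near_macro)


@pytest.fixture(scope="module")
def bed():
    return build_voronoi_bed(1000, 3.0, 0.25, np.random.default_rng(1))


def test_bed_inside_disk_and_faz_clear(bed):
    r = np.hypot(*bed.vertices.T)
    assert np.all(r <= 3.0 + 1e-9)
    a = bed.vertices[bed.edges[:, 0]]
    b = bed.vertices[bed.edges[:, 1]]
    ab = b - a
    t = np.clip(-(a * ab).sum(1) / np.maximum((ab * ab).sum(1), 1e-18), 0, 1)
    proj = a + t[:, None] * ab
    assert np.all(np.hypot(*proj.T) > 0.25)


def test_interior_voronoi_vertices_degree_three(bed):
    deg = np.bincount(bed.edges.ravel(), minlength=len(bed.vertices))
    r = np.hypot(*bed.vertices.T)
    interior = r < 2.0  # away from the clipped rim
    assert np.median(deg[interior]) == 3
    assert (deg[interior] == 3).mean() > 0.9


def test_edge_count_scales_linearly_with_seeds():
    rng = np.random.default_rng(2)
    b1 = build_voronoi_bed(1000, 3.0, 0.25, rng)
    b4 = build_voronoi_bed(4000, 3.0, 0.25, rng)
    ratio1 = b1.n_edges / 1000
    ratio4 = b4.n_edges / 4000
    assert abs(ratio1 - ratio4) / ratio4 < 0.2


def test_prune_empty_macro_is_identity(bed):
    out = prune_capillaries_near_macro(bed, np.empty((0, 2)), np.empty((0, 2)),
                                       np.empty(0))
    assert out.n_edges == bed.n_edges


def test_prune_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    bed = build_voronoi_bed(100, 3.0, 0.25, rng)
    macro_a = np.array([[-2.5, -0.4], [0.4, -2.5]])
    macro_b = np.array([[2.5, 0.6], [0.2, 2.5]])
    radii = np.array([0.08, 0.05])
    pruned = prune_capillaries_near_macro(bed, macro_a, macro_b, radii)
    # brute force: all-pairs segment distance
    keep_oracle = []
    for e in bed.edges:
        p, q = bed.vertices[e[0]], bed.vertices[e[1]]
        hit = False
        for a, b, r in zip(macro_a, macro_b, radii):
            if _seg_seg_distance(a, b, p[None], q[None])[0] < r:
                hit = True
        keep_oracle.append(not hit)
    expected = bed.edges[np.array(keep_oracle)]
    assert np.array_equal(np.sort(pruned.edges, axis=0),
                          np.sort(expected, axis=0))


def test_macro_crossing_removes_crossing_edges():
    rng = np.random.default_rng(4)
    bed = build_voronoi_bed(500, 3.0, 0.25, rng)
    a = np.array([[-3.0, 1.0]])
    b = np.array([[3.0, 1.0]])
    pruned = prune_capillaries_near_macro(bed, a, b, np.array([0.05]))
    p = pruned.vertices[pruned.edges[:, 0]][:, 1]
    q = pruned.vertices[pruned.edges[:, 1]][:, 1]
    # no surviving edge crosses the line y = 1 within the lumen
    crossing = ((p - 1.0) * (q - 1.0) < 0)
    e0 = pruned.vertices[pruned.edges[:, 0]]
    e1 = pruned.vertices[pruned.edges[:, 1]]
    d = _seg_seg_distance(a[0], b[0], e0, e1)
    assert np.all(d[crossing] >= 0.05)


# ----------------------------------------------------------------------
# Diameters
# ----------------------------------------------------------------------

def _chain(radii_um, kinds):
    net = VascularNetwork()
    k = len(radii_um)
    xyz = np.column_stack([np.arange(k + 1, dtype=float),
                           np.zeros(k + 1), np.zeros(k + 1)])
    net.add_nodes(xyz, "capillary", "SVP")
    for i, (r, kind) in enumerate(zip(radii_um, kinds)):
        net.add_segments([[i, i + 1]], r, kind, "SVP")
    return net


def test_smoothing_fixed_point_on_uniform_chain():
    net = _chain([2.5] * 5, ["capillary"] * 5)
    out = assign_and_smooth_diameters(net, 2.5)
    assert np.allclose(out.radius_um, 2.5)


def test_smoothing_example_mean_of_parent_and_daughters():
    # capillary (d=10, it touches the arteriole) with arteriole parent d=10
    # and two capillary daughters d=5: new d = mean(10, 10, 5, 5) = 7.5;
    # with a d=10 parent and daughters 5,5 on a d=5 segment: mean = 6.25
    net = VascularNetwork()
    net.add_nodes(np.column_stack([np.arange(7.0), np.zeros(7), np.zeros(7)]),
                  "capillary", "SVP")
    net.add_segments([[0, 1]], 5.0, "artery", "SVP")      # parent d=10
    net.add_segments([[1, 2]], 2.5, "capillary", "SVP")   # junction, d -> 10
    net.add_segments([[2, 3], [2, 4]], 2.5, "capillary", "SVP")  # daughters d=5
    net.add_segments([[3, 5], [3, 6]], 2.5, "capillary", "SVP")  # grand-daughters
    out = assign_and_smooth_diameters(net, 2.5)
    # junction capillary: pre-pass d = 2*(2*2.5) = 10; neighbors are the
    # 10 um arteriole parent and the two 5 um daughters
    assert out.radius_um[1] * 2 == pytest.approx(np.mean([10, 10, 5, 5]))
    # interior capillary d=5 with parent d=10 and daughters d=5,5
    assert out.radius_um[2] * 2 == pytest.approx(6.25)


def test_smoothing_is_contractive(tiny_config, shape_model):
    from retinapop.population import generate_network, sample_population
    rng = np.random.default_rng(6)
    params = sample_population(1, rng, tiny_config)[0]
    net = generate_network(params, tiny_config, rng, shape_model)
    cap = net.seg_kind_mask("capillary")
    d = net.radius_um[cap]
    assert d.min() >= 2.5 - 1e-9
    macro_max = net.radius_um[~cap & ~net.seg_kind_mask("artificial")].max()
    assert d.max() <= macro_max + 1e-9


# ----------------------------------------------------------------------
# Orientation
# ----------------------------------------------------------------------

def _laplace_toy(edges, art_nodes, ven_nodes, n):
    net = VascularNetwork()
    xyz = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
    net.add_nodes(xyz, "capillary", "SVP")
    for a in art_nodes:
        net.node_kind[a] = 0
    net.add_segments(edges, 2.5, "capillary", "SVP")
    # tag attachments with tiny macro stubs
    extra = net.add_nodes(np.column_stack([np.arange(len(art_nodes) + len(ven_nodes))
                                           + 100.0,
                                           np.zeros(len(art_nodes) + len(ven_nodes)),
                                           np.zeros(len(art_nodes) + len(ven_nodes))]),
                          "arterial", "SVP")
    for i, a in enumerate(art_nodes):
        net.add_segments([[extra[i], a]], 20.0, "artery", "SVP")
    for i, v in enumerate(ven_nodes):
        net.add_segments([[v, extra[len(art_nodes) + i]]], 20.0, "vein", "SVP")
    return net


def test_orientation_simple_path():
    # A - c1 - c2 - V: potentials 1 > u1 > u2 > 0, directed A -> V
    net = _laplace_toy([[0, 1], [1, 2], [2, 3]], art_nodes=[0], ven_nodes=[3],
                       n=4)
    u = capillary_potentials(net)
    assert 1.0 > u[1] > u[2] > 0.0
    out = orient_capillary_flow(net)
    cap = out.seg_kind_mask("capillary")
    conn = out.conn[cap]
    assert np.array_equal(conn, [[0, 1], [1, 2], [2, 3]])


def test_orientation_symmetric_diamond():
    # A - {c1, c2} - V: both branches directed arterial -> venous
    net = _laplace_toy([[0, 1], [1, 3], [0, 2], [2, 3]], art_nodes=[0],
                       ven_nodes=[3], n=4)
    out = orient_capillary_flow(net)
    cap = out.seg_kind_mask("capillary")
    for a, b in out.conn[cap]:
        u = {0: 1.0, 3: 0.0, 1: 0.5, 2: 0.5}
        assert u[a] >= u[b]


def test_potentials_match_direct_sparse_oracle():
    bed = build_voronoi_bed(250, 3.0, 0.25, np.random.default_rng(7))
    n = len(bed.vertices)
    net = VascularNetwork()
    xyz = np.column_stack([bed.vertices, np.zeros(n)])
    net.add_nodes(xyz, "capillary", "SVP")
    net.add_segments(bed.edges, 2.5, "capillary", "SVP")
    art, ven = 0, n - 1
    stubs = net.add_nodes([[10, 0, 0], [11, 0, 0]], "arterial", "SVP")
    net.add_segments([[stubs[0], art]], 20.0, "artery", "SVP")
    net.add_segments([[ven, stubs[1]]], 20.0, "vein", "SVP")
    u = capillary_potentials(net)
    # independent dense solve of the clamped Laplace system
    L = np.zeros((n, n))
    for a, b in bed.edges:
        L[a, a] += 1
        L[b, b] += 1
        L[a, b] -= 1
        L[b, a] -= 1
    val = np.zeros(n)
    val[art], val[ven] = 1.0, 0.0
    free = np.ones(n, bool)
    free[[art, ven]] = False
    val[free] = np.linalg.solve(L[np.ix_(free, free)],
                                -L[np.ix_(free, ~free)] @ val[~free])
    assert np.allclose(u[:n], val, atol=1e-8)


def test_oriented_capillary_graph_is_dag(tiny_individual):
    """Topological sort of the directed capillary subgraph succeeds."""
    net = tiny_individual.network
    cap = net.seg_kind_mask("capillary")
    e = net.conn[cap]
    n = net.n_nodes
    indeg = np.zeros(n, np.int64)
    np.add.at(indeg, e[:, 1], 1)
    out_adj = {}
    for a, b in e:
        out_adj.setdefault(int(a), []).append(int(b))
    from collections import deque
    q = deque(np.flatnonzero(indeg == 0).tolist())
    seen_edges = 0
    while q:
        v = q.popleft()
        for w in out_adj.get(v, []):
            seen_edges += 1
            indeg[w] -= 1
            if indeg[w] == 0:
                q.append(w)
    assert seen_edges == len(e)


def test_capillaries_lie_on_artery_vein_paths(tiny_individual):
    """Every capillary component touches both an arterial and a venous
    attachment after cleanup."""
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components
    net = tiny_individual.network
    cap = net.seg_kind_mask("capillary")
    e = net.conn[cap]
    n = net.n_nodes
    adj = sp.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    art = np.zeros(n, bool)
    ven = np.zeros(n, bool)
    art[net.conn[net.seg_kind_mask("artery")].ravel()] = True
    ven[net.conn[net.seg_kind_mask("vein")].ravel()] = True
    for lab in np.unique(labels[e[:, 0]]):
        members = labels == lab
        assert art[members].any() and ven[members].any()


def test_alpha_limits(tiny_config, shape_model):
    """alpha=0 wires only terminals and descenders; alpha=1 splits every
    eligible macular segment."""
    from retinapop.population import generate_network, sample_population
    import copy
    rng = np.random.default_rng(8)
    params = sample_population(1, rng, tiny_config)[0]
    counts = {}
    for alpha in (0.0, 1.0):
        cfg = copy.deepcopy(tiny_config)
        cfg.alpha = alpha
        cfg.frac_deep = 0.0
        net = generate_network(params, cfg, np.random.default_rng(9),
                               shape_model)
        cap = net.seg_kind_mask("capillary")
        macro_touch = np.zeros(net.n_nodes, bool)
        macro = net.seg_kind_mask("artery") | net.seg_kind_mask("vein")
        macro_touch[net.conn[macro].ravel()] = True
        counts[alpha] = int((cap & macro_touch[net.conn].any(1)).sum())
    # alpha=0 keeps only the terminal attachments; alpha=1 adds one junction
    # per eligible macular arteriole/venule segment
    assert counts[1.0] >= counts[0.0] + 15
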