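"""Voronoi capillary beds and macro-to-micro wiring of the three plexuses.

Capillaries form looping nets rather than bifurcating trees, so each plexus
(SVP at depth 0, ICP at 135 µm, DCP at 180 µm) is synthesized as the edge set
of a Voronoi diagram: N_seeds points are sampled uniformly in the macular
disk, Delaunay-triangulated, and the triangle centroids seed the Voronoi
diagram whose edges become capillary segments. Edges are clipped to the disk,
the foveal avascular zone is kept vessel-free, and (in the SVP) capillaries
intersecting the dilated lumen of arterioles/venules are removed, which also
produces the capillary-free sleeves seen around SVP arterioles.

Wiring: all macular terminal vessels and a fraction α of macular
arterioles/venules connect to their nearest SVP capillary vertex; a fraction
``frac_deep`` of macular arterioles/venules bifurcate at their midpoint down
to the ICP, and those branches immediately continue to the DCP. Extramacular
terminals close through a single compartment node via fixed-resistance
artificial segments.

Flow direction in the capillary mesh comes from a discrete Laplace problem:
arterial attachment nodes are clamped at 1, venous at 0, capillary nodes
relax under the graph Laplacian, and each capillary edge is directed from
high to low potential, which guarantees an acyclic capillary graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, Voronoi, cKDTree

from .config import RunConfig
from .network import VascularNetwork

__all__ = [
    "CapillaryBed", "build_voronoi_bed", "prune_capillaries_near_macro",
    "connect_network", "assign_and_smooth_diameters", "orient_capillary_flow",
]

log = logging.getLogger(__name__)


@dataclass
class CapillaryBed:
    """Planar capillary mesh of one plexus."""

    vertices: np.ndarray   # (V, 2) mm
    edges: np.ndarray      # (E, 2) vertex indices
    z_um: float
    plexus: str

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _sample_disk(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(0.0, 1.0, n))
    th = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _segment_origin_distance(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    PQ = Q - P
    denom = np.maximum((PQ * PQ).sum(-1), 1e-18)
    t = np.clip((-P * PQ).sum(-1) / denom, 0.0, 1.0)
    proj = P + t[..., None] * PQ
    return np.linalg.norm(proj, axis=-1)


def build_voronoi_bed(N_seeds: int, disk_radius: float, r_FAZ: float,
                      rng: np.random.Generator, z_um: float = 0.0,
                      plexus: str = "SVP") -> CapillaryBed:
    """Voronoi capillary bed inside the macular disk, FAZ kept clear.

    Seeds are uniform in the disk; their Delaunay triangulation's centroids
    generate the Voronoi diagram whose finite edges become capillaries. Edges
    leaving the disk or entering the FAZ are discarded and the largest
    connected component is retained.
    """
    if N_seeds < 4:
        raise ValueError("N_seeds must be >= 4")
    for attempt in range(3):
        seeds = _sample_disk(N_seeds, disk_radius, rng)
        try:
            tri = Delaunay(seeds)
            centroids = seeds[tri.simplices].mean(axis=1)
            vor = Voronoi(centroids)
        except Exception:  # degenerate (collinear) seeds: jitter and retry
            log.warning("degenerate seed set (attempt %d); re-seeding with jitter",
                        attempt + 1)
            continue
        break
    else:
        raise RuntimeError("could not build a non-degenerate Voronoi bed")

    verts = vor.vertices
    ridges = np.asarray([rv for rv in vor.ridge_vertices if min(rv) >= 0],
                        dtype=np.int64)
    if len(ridges) == 0:
        raise RuntimeError("Voronoi diagram has no finite edges")
    inside = (verts ** 2).sum(axis=1) <= disk_radius ** 2
    keep = inside[ridges[:, 0]] & inside[ridges[:, 1]]
    ridges = ridges[keep]
    # FAZ clearance
    d0 = _segment_origin_distance(verts[ridges[:, 0]], verts[ridges[:, 1]])
    ridges = ridges[d0 > r_FAZ]

    # compact vertex indices, then keep the largest connected component
    used = np.unique(ridges)
    remap = -np.ones(len(verts), np.int64)
    remap[used] = np.arange(len(used))
    verts = verts[used]
    edges = remap[ridges]
    n = len(verts)
    adj = sp.coo_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
                        shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        main = np.bincount(labels).argmax()
        keep_v = labels == main
        remap2 = -np.ones(n, np.int64)
        remap2[keep_v] = np.arange(keep_v.sum())
        edges = remap2[edges[keep_v[edges[:, 0]] & keep_v[edges[:, 1]]]]
        verts = verts[keep_v]
    return CapillaryBed(vertices=verts, edges=edges, z_um=z_um, plexus=plexus)


# ----------------------------------------------------------------------
# SVP pruning against the macrovasculature
# ----------------------------------------------------------------------

def _seg_seg_distance(p0: np.ndarray, p1: np.ndarray,
                      q0: np.ndarray, q1: np.ndarray) -> np.ndarray:
    """2-D distance between segment p0-p1 and each segment q0[i]-q1[i]
    (0 where they properly intersect)."""
    def cross(o, a, b):
        return ((a[..., 0] - o[..., 0]) * (b[..., 1] - o[..., 1])
                - (a[..., 1] - o[..., 1]) * (b[..., 0] - o[..., 0]))

    p0b = np.broadcast_to(p0, q0.shape)
    p1b = np.broadcast_to(p1, q0.shape)
    d1 = cross(p0b, p1b, q0)
    d2 = cross(p0b, p1b, q1)
    d3 = cross(q0, q1, p0b)
    d4 = cross(q0, q1, p1b)
    intersects = ((d1 * d2) < 0) & ((d3 * d4) < 0)

    def pt_seg(x, a, b):
        ab = b - a
        denom = np.maximum((ab * ab).sum(-1), 1e-18)
        t = np.clip(((x - a) * ab).sum(-1) / denom, 0.0, 1.0)
        proj = a + t[..., None] * ab
        return np.linalg.norm(x - proj, axis=-1)

    d = np.minimum.reduce([
        pt_seg(q0, p0b, p1b), pt_seg(q1, p0b, p1b),
        pt_seg(p0b, q0, q1), pt_seg(p1b, q0, q1)])
    return np.where(intersects, 0.0, d)


def prune_capillaries_near_macro(bed: CapillaryBed, macro_a: np.ndarray,
                                 macro_b: np.ndarray,
                                 macro_radius_mm: np.ndarray) -> CapillaryBed:
    """Remove SVP capillary edges intersecting the dilated lumen (stadium of
    the segment's radius) of any arteriole/venule."""
    if len(macro_a) == 0 or bed.n_edges == 0:
        return bed
    e0 = bed.vertices[bed.edges[:, 0]]
    e1 = bed.vertices[bed.edges[:, 1]]
    mid = 0.5 * (e0 + e1)
    half_len = 0.5 * np.linalg.norm(e1 - e0, axis=1)
    tree = cKDTree(mid)
    max_half = float(half_len.max(initial=0.0))
    remove = np.zeros(bed.n_edges, bool)
    for a, b, r in zip(macro_a, macro_b, macro_radius_mm):
        m = 0.5 * (a + b)
        reach = 0.5 * np.linalg.norm(b - a) + r + max_half + 1e-6
        cand = tree.query_ball_point(m, reach)
        if not cand:
            continue
        cand = np.asarray(cand)
        d = _seg_seg_distance(a, b, e0[cand], e1[cand])
        remove[cand[d < r]] = True
    edges = bed.edges[~remove]
    return CapillaryBed(vertices=bed.vertices, edges=edges, z_um=bed.z_um,
                        plexus=bed.plexus)


# ----------------------------------------------------------------------
# Network assembly
# ----------------------------------------------------------------------

def _copy_network(net: VascularNetwork) -> VascularNetwork:
    return VascularNetwork(
        xyz=net.xyz.copy(), node_kind=net.node_kind.copy(),
        node_plexus=net.node_plexus.copy(), conn=net.conn.copy(),
        radius_um=net.radius_um.copy(), seg_kind=net.seg_kind.copy(),
        seg_plexus=net.seg_plexus.copy(), is_terminal=net.is_terminal.copy(),
        fixed_resistance=net.fixed_resistance.copy(),
        metadata=dict(net.metadata))


def connect_network(svp_macro: VascularNetwork, beds: dict[str, CapillaryBed],
                    alpha: float, frac_deep: float, rng: np.random.Generator,
                    config: RunConfig) -> VascularNetwork:
    """Wire the macrovasculature to the three capillary beds and close the
    extramacular terminals through the compartment.

    Returns one connected network CRA -> arteries -> capillaries -> veins -> CRV.
    """
    domain = config.domain
    net = _copy_network(svp_macro)
    n_macro_segs = net.n_segments

    # append beds; attachments go to each bed's largest connected component
    # (pruning can shed fragments that would strand their attachments)
    bed_nodes: dict[str, np.ndarray] = {}
    bed_trees: dict[str, cKDTree] = {}
    bed_main: dict[str, np.ndarray] = {}
    for name in ("SVP", "ICP", "DCP"):
        bed = beds[name]
        xyz = np.column_stack([bed.vertices,
                               np.full(len(bed.vertices), bed.z_um * 1e-3)])
        ids = net.add_nodes(xyz, "capillary", name)
        if bed.n_edges:
            net.add_segments(ids[bed.edges], config.plexi[name].r_capillary,
                             "capillary", name)
        bed_nodes[name] = ids
        nv = len(bed.vertices)
        if bed.n_edges:
            adj = sp.coo_matrix((np.ones(bed.n_edges),
                                 (bed.edges[:, 0], bed.edges[:, 1])),
                                shape=(nv, nv))
            _, labels = connected_components(adj, directed=False)
            counts = np.bincount(labels, minlength=labels.max() + 1)
            main = np.flatnonzero(labels == counts.argmax())
        else:
            main = np.arange(nv)
        bed_main[name] = main
        bed_trees[name] = cKDTree(bed.vertices[main])

    r_peri2 = domain.r_perifovea ** 2

    # --- terminal vessels -------------------------------------------------
    term = np.flatnonzero(net.is_terminal[:n_macro_segs]
                          & (net.seg_kind_mask("artery")[:n_macro_segs]
                             | net.seg_kind_mask("vein")[:n_macro_segs]))
    distal = net.conn[term, 1]
    macular_term = (net.xyz[distal, :2] ** 2).sum(axis=1) <= r_peri2

    new_conn, new_plexus = [], []
    for j, dn in zip(term[macular_term], distal[macular_term]):
        _, vi = bed_trees["SVP"].query(net.xyz[dn, :2])
        new_conn.append([dn, bed_nodes["SVP"][bed_main["SVP"][vi]]])
        new_plexus.append("SVP")

    # --- alpha-connections and interplexus descenders --------------------
    mids = net.midpoints()[:n_macro_segs]
    eligible_base = (~net.is_terminal[:n_macro_segs]
                     & ((mids[:, :2] ** 2).sum(axis=1) <= r_peri2))
    root_nodes = np.flatnonzero(net.node_kind_mask("root"))
    touches_root = np.isin(net.conn[:n_macro_segs], root_nodes).any(axis=1)
    eligible_base &= ~touches_root

    selections: dict[int, set[str]] = {}
    for kind in ("artery", "vein"):
        elig = np.flatnonzero(eligible_base & net.seg_kind_mask(kind)[:n_macro_segs])
        for frac, tag in ((alpha, "svp"), (frac_deep, "deep")):
            k = int(round(frac * len(elig)))
            if k:
                chosen = rng.choice(elig, size=k, replace=False)
                for j in chosen:
                    selections.setdefault(int(j), set()).add(tag)

    icp_to_dcp_done: set[int] = set()
    for j, tags in sorted(selections.items()):
        a, b = net.conn[j]
        m = 0.5 * (net.xyz[a] + net.xyz[b])
        node_kind = "arterial" if net.seg_kind_mask("artery")[j] else "venous"
        m_id = net.add_nodes(m, node_kind, "SVP")[0]
        # split the host segment at its midpoint
        net.conn[j, 1] = m_id
        net.add_segments([[m_id, b]], net.radius_um[j],
                         "artery" if node_kind == "arterial" else "vein", "SVP")
        if "svp" in tags:
            _, vi = bed_trees["SVP"].query(m[:2])
            new_conn.append([m_id, bed_nodes["SVP"][bed_main["SVP"][vi]]])
            new_plexus.append("SVP")
        if "deep" in tags:
            _, vi = bed_trees["ICP"].query(m[:2])
            icp_node = bed_nodes["ICP"][bed_main["ICP"][vi]]
            new_conn.append([m_id, icp_node])
            new_plexus.append("ICP")
            if vi not in icp_to_dcp_done:
                icp_to_dcp_done.add(int(vi))
                _, wi = bed_trees["DCP"].query(net.xyz[icp_node, :2])
                new_conn.append([icp_node, bed_nodes["DCP"][bed_main["DCP"][wi]]])
                new_plexus.append("DCP")

    for conn, plexus in zip(new_conn, new_plexus):
        net.add_segments([conn], config.plexi["SVP"].r_capillary, "capillary",
                         plexus)

    # --- compartment closure ---------------------------------------------
    comp = net.add_nodes([domain.disc_center_x, domain.disc_center_y, -1.0],
                         "compartment")[0]
    art_term = term[~macular_term & net.seg_kind_mask("artery")[term]]
    ven_term = term[~macular_term & net.seg_kind_mask("vein")[term]]
    for j in art_term:
        net.add_segments([[net.conn[j, 1], comp]], 10.0, "artificial",
                         fixed_resistance=True)
    for j in ven_term:
        net.add_segments([[comp, net.conn[j, 1]]], 10.0, "artificial",
                         fixed_resistance=True)
    if len(art_term) == 0 or len(ven_term) == 0:
        log.warning("compartment closure one-sided: %d arterial / %d venous "
                    "extramacular terminals", len(art_term), len(ven_term))

    net.metadata["alpha"] = alpha
    net.metadata["frac_deep"] = frac_deep
    return net


def assign_and_smooth_diameters(net: VascularNetwork,
                                r_capillary: float) -> VascularNetwork:
    """Set capillary radii (doubled where a capillary touches an
    arteriole/venule) and apply one diameter-smoothing pass: each capillary's
    new diameter becomes the mean of its own, its parent's and its daughters'
    diameters, all taken from pre-pass values.

    Parent/daughter adjacency is directional (segments are stored
    proximal->distal): the parent of segment j is the segment ending at j's
    proximal node, the daughters start at j's distal node. A sibling branch
    at the same bifurcation is not averaged in. Macro-tree radii are left as
    grown (their Murray structure is the growth model's contract); artificial
    compartment segments are ignored.
    """
    cap = net.seg_kind_mask("capillary")
    if not cap.any():
        return net
    macro = net.seg_kind_mask("artery") | net.seg_kind_mask("vein")
    touches_macro_node = np.zeros(net.n_nodes, bool)
    touches_macro_node[net.conn[macro].ravel()] = True
    r = net.radius_um.copy()
    r[cap] = r_capillary
    junction = cap & touches_macro_node[net.conn].any(axis=1)
    r[junction] = 2.0 * r_capillary
    net.radius_um = r

    d = 2.0 * net.radius_um
    anatomical = ~net.seg_kind_mask("artificial")
    d_eff = np.where(anatomical, d, 0.0)
    cnt_eff = anatomical.astype(float)
    a, b = net.conn[:, 0], net.conn[:, 1]
    head_sum = np.zeros(net.n_nodes)   # segments ending at the node (parents)
    head_cnt = np.zeros(net.n_nodes)
    tail_sum = np.zeros(net.n_nodes)   # segments starting at the node (daughters)
    tail_cnt = np.zeros(net.n_nodes)
    np.add.at(head_sum, b, d_eff)
    np.add.at(head_cnt, b, cnt_eff)
    np.add.at(tail_sum, a, d_eff)
    np.add.at(tail_cnt, a, cnt_eff)
    neigh_sum = head_sum[a] + tail_sum[b]
    neigh_cnt = head_cnt[a] + tail_cnt[b]
    new_d = np.where(neigh_cnt > 0, (d + neigh_sum) / (1.0 + neigh_cnt), d)
    r2 = net.radius_um.copy()
    r2[cap] = 0.5 * new_d[cap]
    net.radius_um = r2
    return net


# ----------------------------------------------------------------------
# Capillary cleanup and flow orientation
# ----------------------------------------------------------------------

def _remove_segments(net: VascularNetwork, keep: np.ndarray) -> None:
    net.conn = net.conn[keep]
    net.radius_um = net.radius_um[keep]
    net.seg_kind = net.seg_kind[keep]
    net.seg_plexus = net.seg_plexus[keep]
    net.is_terminal = net.is_terminal[keep]
    net.fixed_resistance = net.fixed_resistance[keep]


def _drop_isolated_nodes(net: VascularNetwork) -> None:
    deg = net.degrees()
    keep = deg > 0
    if keep.all():
        return
    remap = -np.ones(net.n_nodes, np.int64)
    remap[keep] = np.arange(keep.sum())
    net.xyz = net.xyz[keep]
    net.node_kind = net.node_kind[keep]
    net.node_plexus = net.node_plexus[keep]
    net.conn = remap[net.conn]


def prune_dead_end_capillaries(net: VascularNetwork) -> VascularNetwork:
    """Iteratively remove degree-1 capillary-only dead ends and capillary
    components lacking either an arterial or a venous attachment (they would
    carry no flow and make the pressure system singular)."""
    cap = net.seg_kind_mask("capillary")
    macro = ~cap
    macro_touch = np.zeros(net.n_nodes, bool)
    macro_touch[net.conn[macro].ravel()] = True

    keep = np.ones(net.n_segments, bool)
    while True:
        deg = np.zeros(net.n_nodes, np.int64)
        np.add.at(deg, net.conn[keep].ravel(), 1)
        endpoint_dead = (deg[net.conn] == 1) & ~macro_touch[net.conn]
        drop = keep & cap & endpoint_dead.any(axis=1)
        if not drop.any():
            break
        keep &= ~drop
    _remove_segments(net, keep)

    # component audit on the capillary subgraph
    cap = net.seg_kind_mask("capillary")
    if cap.any():
        art_touch = np.zeros(net.n_nodes, bool)
        ven_touch = np.zeros(net.n_nodes, bool)
        art_touch[net.conn[net.seg_kind_mask("artery")].ravel()] = True
        ven_touch[net.conn[net.seg_kind_mask("vein")].ravel()] = True
        e = net.conn[cap]
        n = net.n_nodes
        adj = sp.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
        cap_labels = labels[e[:, 0]]
        ok_lab = np.zeros(labels.max() + 1, bool)
        for lab in np.unique(cap_labels):
            members = labels == lab
            ok_lab[lab] = (art_touch[members].any() and ven_touch[members].any())
        keep2 = np.ones(net.n_segments, bool)
        keep2[np.flatnonzero(cap)[~ok_lab[cap_labels]]] = False
        _remove_segments(net, keep2)
    _drop_isolated_nodes(net)
    return net


def orient_capillary_flow(net: VascularNetwork) -> VascularNetwork:
    """Direct every capillary segment from high to low Laplace potential.

    Arterial attachment nodes are clamped at 1, venous at 0; capillary node
    potentials solve the discrete Laplace equation on the capillary subgraph
    (the fixed point of relaxing nodal values under the graph Laplacian). The
    resulting directed capillary graph is acyclic.
    """
    cap = net.seg_kind_mask("capillary")
    if not cap.any():
        return net
    e = net.conn[cap]
    art_touch = np.zeros(net.n_nodes, bool)
    ven_touch = np.zeros(net.n_nodes, bool)
    art_touch[net.conn[net.seg_kind_mask("artery")].ravel()] = True
    ven_touch[net.conn[net.seg_kind_mask("vein")].ravel()] = True

    nodes = np.unique(e)
    local = -np.ones(net.n_nodes, np.int64)
    local[nodes] = np.arange(len(nodes))
    el = local[e]
    n = len(nodes)
    w = np.ones(len(el))
    L = sp.coo_matrix(
        (np.concatenate([w, w, -w, -w]),
         (np.concatenate([el[:, 0], el[:, 1], el[:, 0], el[:, 1]]),
          np.concatenate([el[:, 0], el[:, 1], el[:, 1], el[:, 0]]))),
        shape=(n, n)).tocsr()
    u = np.full(n, 0.5)
    clamped = art_touch[nodes] | ven_touch[nodes]
    u[art_touch[nodes]] = 1.0
    u[ven_touch[nodes]] = 0.0
    free = ~clamped
    if free.any():
        A = L[free][:, free].tocsc()
        rhs = -L[free][:, clamped] @ u[clamped]
        u[free] = spla.spsolve(A, rhs)
    if not np.all(np.isfinite(u)):
        raise ValueError("Laplace potentials undefined: capillary component "
                         "without attachments survived cleanup")

    # tie-break equal potentials deterministically, then direct high -> low
    u_eff = u + 1e-12 * np.arange(n)
    ua, ub = u_eff[el[:, 0]], u_eff[el[:, 1]]
    n_flipped = int((ub > ua).sum())
    if n_flipped:
        flip_idx = np.flatnonzero(cap)[ub > ua]
        net.conn[flip_idx] = net.conn[flip_idx][:, ::-1]
    # acyclicity: potentials strictly decrease along every directed edge
    e2 = local[net.conn[cap]]
    if not np.all(u_eff[e2[:, 0]] > u_eff[e2[:, 1]]):
        raise RuntimeError("residual cycle: non-decreasing potential on a "
                           "directed capillary edge")
    pot = np.full(net.n_nodes, np.nan)
    pot[nodes] = u
    net.metadata["capillary_potential_range"] = [float(u.min()), float(u.max())]
    return net


def capillary_potentials(net: VascularNetwork) -> np.ndarray:
    """Solve and return the clamped-Laplace potentials (NaN off the capillary
    subgraph) without re-orienting; reference implementation for audits."""
    net2 = _copy_network(net)
    cap = net2.seg_kind_mask("capillary")
    e = net2.conn[cap]
    art_touch = np.zeros(net2.n_nodes, bool)
    ven_touch = np.zeros(net2.n_nodes, bool)
    art_touch[net2.conn[net2.seg_kind_mask("artery")].ravel()] = True
    ven_touch[net2.conn[net2.seg_kind_mask("vein")].ravel()] = True
    nodes = np.unique(e)
    local = -np.ones(net2.n_nodes, np.int64)
    local[nodes] = np.arange(len(nodes))
    el = local[e]
    n = len(nodes)
    w = np.ones(len(el))
    L = sp.coo_matrix(
        (np.concatenate([w, w, -w, -w]),
         (np.concatenate([el[:, 0], el[:, 1], el[:, 0], el[:, 1]]),
          np.concatenate([el[:, 0], el[:, 1], el[:, 1], el[:, 0]]))),
        shape=(n, n)).tocsr()
    u = np.full(n, 0.5)
    clamped = art_touch[nodes] | ven_touch[nodes]
    u[art_touch[nodes]] = 1.0
    u[ven_touch[nodes]] = 0.0
    free = ~clamped
    if free.any():
        u[free] = spla.spsolve(L[free][:, free].tocsc(),
                               -L[free][:, clamped] @ u[clamped])
    out = np.full(net2.n_nodes, np.nan)
    out[nodes] = u
    return out
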