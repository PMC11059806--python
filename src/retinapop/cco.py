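"""Staged constrained constructive optimization (CCO) growth of the
arterial and venous trees of the superficial vascular plexus.

Trees grow from the temporal arcades by repeatedly adding terminal segments:
a candidate terminal site is drawn from a fovea-biased radial law, screened by
a minimum-separation rule, and connected to the existing tree at the
bifurcation point that minimizes a total-volume cost while satisfying the
geometric constraints (Murray's law with exponent γ, a radius-symmetry floor
δ, and a minimum bifurcation angle θ_min). Growth never crosses the raphe
(the line through the optic-disc center and the fovea) and keeps the foveal
avascular zone vessel-free.

Radii follow Murray's law exactly: every leaf carries one unit of relative
radius, parents accumulate bottom-up with the γ in force when the bifurcation
was created, and a single global scale factor is chosen by fixed-point
iteration (effective viscosity recomputed from absolute diameters each pass)
so that the mean root-to-terminal pressure drop equals the stage target at
equal terminal flows Q_root / N. Uniform scaling preserves all Murray ratios,
so stage-to-stage retargeting is a pure rescale.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .config import RetinalDomain, StageConfig
from .hemodynamics import _RES_COEF, effective_viscosity
from .network import VascularNetwork

__all__ = [
    "min_separation", "sample_terminal_site", "parent_radius",
    "bifurcation_admissible", "CCOTree", "grow_tree", "grow_macrovasculature",
    "stage_region_area", "in_stage_region",
]

_MAX_SITE_REJECTIONS = 10_000
_LMIN_FAILURE_WINDOW = 20     # consecutive failures before l_min is reduced
_N_HOST_CANDIDATES = 20       # nearest admissible host segments examined per site
_MIN_SEG_LEN = 0.01           # mm, degeneracy floor for new segments


# ----------------------------------------------------------------------
# Elementary rules
# ----------------------------------------------------------------------

def min_separation(nu: float, domain_area: float, n_terms: int) -> float:
    """Minimum distance of a new terminal site from the existing tree:
    l_min = sqrt(nu * A / (pi * (N + 1)))."""
    if nu < 0 or domain_area <= 0 or n_terms < 0:
        raise ValueError("nu must be >= 0, domain_area > 0, n_terms >= 0")
    return math.sqrt(nu * domain_area / (math.pi * (n_terms + 1)))


def parent_radius(r1: float, r2: float, gamma: float) -> float:
    """Murray's law: r_p = (r1^g + r2^g)^(1/g)."""
    return (r1 ** gamma + r2 ** gamma) ** (1.0 / gamma)


def bifurcation_admissible(r1: float, r2: float, theta_deg: float,
                           stage: StageConfig) -> bool:
    """True iff min(r1,r2)/max(r1,r2) > delta and theta > theta_min."""
    lo, hi = min(r1, r2), max(r1, r2)
    return (lo / hi > stage.delta) and (theta_deg > stage.theta_min)


def stage_region_area(stage: StageConfig, domain: RetinalDomain) -> float:
    """Area (mm^2) of the stage's growth region, FAZ excluded."""
    if stage.region == "full":
        return math.pi * (domain.r_retina ** 2 - domain.r_FAZ ** 2)
    if stage.region == "annulus":
        return math.pi * (domain.r_perifovea ** 2 - domain.r_parafovea ** 2)
    if stage.region == "parafovea":
        return math.pi * (domain.r_parafovea ** 2 - domain.r_FAZ ** 2)
    raise ValueError(f"unknown stage region {stage.region!r}")


def in_stage_region(r: float, stage: StageConfig, domain: RetinalDomain) -> bool:
    if r <= domain.r_FAZ:
        return False
    if stage.region == "full":
        return r <= domain.r_retina
    if stage.region == "annulus":
        return domain.r_parafovea <= r <= domain.r_perifovea
    if stage.region == "parafovea":
        return r <= domain.r_parafovea
    raise ValueError(f"unknown stage region {stage.region!r}")


def sample_terminal_site(stage: StageConfig, domain: RetinalDomain,
                         rng: np.random.Generator, side: int = 0) -> np.ndarray:
    """Draw a terminal site from the fovea-biased law r = r0 + exp(mu + s*Z),
    theta ~ U[0, 2*pi), rejection-resampled into the stage region, outside the
    FAZ and on the requested side of the raphe (side=+1 superior, -1 inferior,
    0 unconstrained)."""
    for _ in range(_MAX_SITE_REJECTIONS):
        r = stage.lognormal_r0 + math.exp(
            stage.lognormal_mu + stage.lognormal_sigma * rng.standard_normal())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        if not in_stage_region(r, stage, domain):
            continue
        y = r * math.sin(theta)
        if side and side * y <= 0:
            continue
        return np.array([r * math.cos(theta), y])
    raise RuntimeError(
        f"terminal-site sampling failed {_MAX_SITE_REJECTIONS} times; "
        f"stage region {stage.region!r} likely incompatible with the radial law")


# ----------------------------------------------------------------------
# Tree container
# ----------------------------------------------------------------------

@dataclass
class BifurcationRecord:
    """Creation-time audit record of one bifurcation."""

    seg_parent: int
    r1: float            # relative radii of the daughters at creation
    r2: float
    theta_deg: float
    gamma: float
    delta: float
    theta_min: float


class CCOTree:
    """One growing arterial or venous tree (planar, SVP).

    Storage is preallocated NumPy (doubling on demand); ``children`` stays a
    list of lists. ``pos``/``seg_a``/... expose live views for inspection.
    """

    def __init__(self, side: int = 0) -> None:
        self._node_cap = 64
        self._seg_cap = 64
        self._pos = np.empty((self._node_cap, 2))
        self._a = np.empty(self._seg_cap, np.int64)
        self._b = np.empty(self._seg_cap, np.int64)
        self._parent = np.empty(self._seg_cap, np.int64)
        self._gamma = np.empty(self._seg_cap)
        self._nterm = np.empty(self._seg_cap, np.int64)
        self._rel = np.empty(self._seg_cap)
        self._len = np.empty(self._seg_cap)
        self._term = np.empty(self._seg_cap, bool)
        self._n_nodes = 0
        self._m = 0
        self.children: list[list[int]] = []
        self.scale_um: float = 20.0      # absolute tip radius, µm
        self.q_root_mL_s: float = 0.0
        self.side = side
        self.audit: list[BifurcationRecord] = []
        self.rejection_streak = 0
        self.lmin_reductions = 0
        self.n_terminals = 0

    # live views --------------------------------------------------------
    @property
    def pos(self) -> np.ndarray:
        return self._pos[:self._n_nodes]

    @property
    def seg_a(self) -> np.ndarray:
        return self._a[:self._m]

    @property
    def seg_b(self) -> np.ndarray:
        return self._b[:self._m]

    @property
    def parent(self) -> np.ndarray:
        return self._parent[:self._m]

    @property
    def gamma_at(self) -> np.ndarray:
        return self._gamma[:self._m]

    @property
    def nterm(self) -> np.ndarray:
        return self._nterm[:self._m]

    @property
    def rel_r(self) -> np.ndarray:
        return self._rel[:self._m]

    @property
    def length(self) -> np.ndarray:
        return self._len[:self._m]

    @property
    def is_grown_terminal(self) -> np.ndarray:
        return self._term[:self._m]

    # -- construction ---------------------------------------------------
    @classmethod
    def from_polyline(cls, points: np.ndarray, side: int = 0) -> "CCOTree":
        """Root a tree on an arcade polyline (node 0 = root end)."""
        t = cls(side=side)
        pts = np.asarray(points, float)
        for p in pts:
            t._add_node(p)
        for i in range(len(pts) - 1):
            t._append_segment(i, i + 1, parent=i - 1)
        t._recompute_all()
        return t

    @classmethod
    def from_root_point(cls, point: np.ndarray, side: int = 0) -> "CCOTree":
        t = cls(side=side)
        t._add_node(np.asarray(point, float))
        return t

    def _add_node(self, p: np.ndarray) -> int:
        if self._n_nodes == self._node_cap:
            self._node_cap *= 2
            new = np.empty((self._node_cap, 2))
            new[:self._n_nodes] = self._pos[:self._n_nodes]
            self._pos = new
        self._pos[self._n_nodes] = p
        self._n_nodes += 1
        return self._n_nodes - 1

    def _append_segment(self, a: int, b: int, parent: int) -> int:
        if self._m == self._seg_cap:
            self._seg_cap *= 2
            for name in ("_a", "_b", "_parent", "_gamma", "_nterm", "_rel",
                         "_len", "_term"):
                old = getattr(self, name)
                new = np.empty(self._seg_cap, old.dtype)
                new[:self._m] = old[:self._m]
                setattr(self, name, new)
        j = self._m
        self._m += 1
        self._a[j] = a
        self._b[j] = b
        self._parent[j] = parent
        self._gamma[j] = 3.0
        self._nterm[j] = 1
        self._rel[j] = 1.0
        self._len[j] = float(np.linalg.norm(self._pos[a] - self._pos[b]))
        self._term[j] = False
        self.children.append([])
        if parent >= 0:
            self.children[parent].append(j)
        return j

    @property
    def n_segments(self) -> int:
        return self._m

    def leaves(self) -> list[int]:
        return [j for j in range(self.n_segments) if not self.children[j]]

    # -- bookkeeping ----------------------------------------------------
    def _recompute_all(self) -> None:
        """Full bottom-up recomputation of nterm and rel_r (DFS order)."""
        order: list[int] = []
        stack = [j for j in range(self.n_segments) if self._parent[j] == -1]
        while stack:
            j = stack.pop()
            order.append(j)
            stack.extend(self.children[j])
        for j in reversed(order):
            if self.children[j]:
                self._nterm[j] = sum(self._nterm[c] for c in self.children[j])
                g = self._gamma[j]
                self._rel[j] = sum(self._rel[c] ** g
                                   for c in self.children[j]) ** (1.0 / g)
            else:
                self._nterm[j] = 1
                self._rel[j] = 1.0

    def _update_upward(self, j: int) -> None:
        """Propagate nterm/rel_r changes from segment j to the root."""
        while j >= 0:
            if self.children[j]:
                self._nterm[j] = sum(self._nterm[c] for c in self.children[j])
                g = self._gamma[j]
                self._rel[j] = sum(self._rel[c] ** g
                                   for c in self.children[j]) ** (1.0 / g)
            j = self._parent[j]

    # -- hemodynamic sizing --------------------------------------------
    def mean_terminal_pressure_drop(self, scale_um: float, eta_start: float,
                                    use_eta: bool = False) -> float:
        """Mean root-to-leaf pressure drop (mmHg) at equal leaf flows, for tip
        radius ``scale_um``. Each segment i lies on the path of nterm_i leaves,
        so the leaf-mean path sum is sum_i Q_i R_i nterm_i / N."""
        rel = self.rel_r
        ln = self.length
        nt = self.nterm.astype(float)
        n_leaves = sum(1 for j in range(self.n_segments) if not self.children[j])
        r_um = scale_um * rel
        mu = np.full_like(r_um, eta_start) if use_eta else \
            effective_viscosity(2.0 * r_um)
        R = _RES_COEF * mu * np.maximum(ln, 1e-9) / (np.pi * r_um ** 4)
        Q = self.q_root_mL_s * nt / n_leaves
        return float(np.sum(Q * R * nt / n_leaves))

    def rescale_to_pressure_drop(self, dp_target: float, eta_start: float = 0.36,
                                 tol: float = 1e-6, max_iter: int = 60) -> None:
        """Fixed-point iteration on the global radius scale so the mean
        root-to-terminal pressure drop equals ``dp_target`` (mmHg). Viscosity
        starts at ``eta_start`` cP and is then recomputed from diameters."""
        if self.n_segments == 0 or self.q_root_mL_s <= 0:
            return
        s = self.scale_um
        dp = self.mean_terminal_pressure_drop(s, eta_start, use_eta=True)
        for _ in range(max_iter):
            s_new = s * (dp / dp_target) ** 0.25
            s_new = min(max(s_new, 0.6), 500.0)  # µm; keeps tip diameters > 1.12 µm
            dp = self.mean_terminal_pressure_drop(s_new, eta_start)
            if abs(s_new - s) <= tol * s:
                s = s_new
                break
            s = s_new
        self.scale_um = s

    def radii_um(self) -> np.ndarray:
        return self.scale_um * self.rel_r

    # -- geometry helpers ----------------------------------------------
    def _segment_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        P = self.pos
        return P[self.seg_a], P[self.seg_b]

    def point_segment_distances(self, x: np.ndarray) -> np.ndarray:
        A, B = self._segment_arrays()
        return _point_to_segments(np.asarray(x, float), A, B)

    # -- growth ---------------------------------------------------------
    def try_add_terminal(self, x_new: np.ndarray, stage: StageConfig,
                         domain: RetinalDomain) -> bool:
        """Attempt to connect a terminal at ``x_new``; returns success."""
        if self.n_segments == 0:
            # first terminal: the root segment itself
            b = self._add_node(np.asarray(x_new, float))
            j = self._append_segment(0, b, parent=-1)
            self._term[j] = True
            self.n_terminals += 1
            return True

        A, B = self._segment_arrays()
        d = _point_to_segments(x_new, A, B)
        search_radius = stage.f_n * math.sqrt(stage_region_area(stage, domain))
        in_reach = np.flatnonzero(d <= search_radius)
        if len(in_reach) == 0:
            return False
        hosts = in_reach[np.argsort(d[in_reach])][:_N_HOST_CANDIDATES]
        # radius-symmetry screen: the new daughter has relative radius 1
        rel = self.rel_r[hosts]
        ratio = np.minimum(rel, 1.0) / np.maximum(rel, 1.0)
        hosts = hosts[ratio > stage.delta]
        if len(hosts) == 0:
            return False

        x = np.asarray(x_new, float)
        a, b = A[hosts], B[hosts]
        rel = self.rel_r[hosts]
        ts = np.linspace(0.1, 0.9, 7)
        ws = np.array([0.0, 0.15, 0.3, 0.45])
        M, theta, cost = _evaluate_bifurcations(a, b, x, rel, ts, ws, stage,
                                                domain)
        k = np.unravel_index(np.argmin(cost), cost.shape)
        if not np.isfinite(cost[k]):
            return False
        # one local refinement around the winning host's best grid point
        h = k[0]
        t0, w0 = ts[k[1]], ws[k[2]]
        ts2 = np.clip(np.linspace(t0 - 0.08, t0 + 0.08, 5), 0.02, 0.98)
        ws2 = np.clip(np.linspace(w0 - 0.08, w0 + 0.08, 5), 0.0, 0.9)
        M2, theta2, cost2 = _evaluate_bifurcations(
            a[h:h + 1], b[h:h + 1], x, rel[h:h + 1], ts2, ws2, stage, domain)
        k2 = np.unravel_index(np.argmin(cost2), cost2.shape)
        if np.isfinite(cost2[k2]) and cost2[k2] < cost[k]:
            m, th = M2[k2].copy(), float(theta2[k2])
        else:
            m, th = M[k].copy(), float(theta[k])
        host = int(hosts[h])
        r_host = float(rel[h])
        self._commit_terminal(host, m, x, th,
                              min(r_host, 1.0) / max(r_host, 1.0), stage)
        return True

    def _commit_terminal(self, host: int, m: np.ndarray, x: np.ndarray,
                         theta: float, ratio: float, stage: StageConfig) -> None:
        m_id = self._add_node(np.asarray(m, float))
        x_id = self._add_node(np.asarray(x, float))
        b_old = int(self._b[host])
        old_children = list(self.children[host])
        self.children[host] = []
        # distal half of the host inherits its children
        self._b[host] = m_id
        self._len[host] = float(np.linalg.norm(self._pos[self._a[host]] - m))
        distal = self._append_segment(m_id, b_old, parent=host)
        self.children[distal] = old_children
        self._gamma[distal] = self._gamma[host]
        for c in old_children:
            self._parent[c] = distal
        self._term[distal] = self._term[host]
        self._term[host] = False
        term = self._append_segment(m_id, x_id, parent=host)
        self._term[term] = True
        self.n_terminals += 1
        self._gamma[host] = stage.gamma
        # distal keeps the host's old subtree values
        self._nterm[distal] = self._nterm[host]
        self._rel[distal] = self._rel[host]
        self._update_upward(host)
        self.audit.append(BifurcationRecord(
            seg_parent=host, r1=float(self._rel[distal]), r2=1.0, theta_deg=theta,
            gamma=stage.gamma, delta=stage.delta, theta_min=stage.theta_min))

    def grow_stage(self, stage: StageConfig, domain: RetinalDomain,
                   dp_target: float, rng: np.random.Generator) -> None:
        """Add ``stage.N_terms`` terminals, then retarget the pressure drop."""
        area = stage_region_area(stage, domain)
        self.lmin_reductions = 0
        self.rejection_streak = 0
        added = 0
        attempts = 0
        max_attempts = 500 * stage.N_terms
        while added < stage.N_terms:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"growth stalled after {attempts} attempts "
                    f"({added}/{stage.N_terms} terminals, region={stage.region!r})")
            l_min = (min_separation(stage.nu, area, self.n_terminals)
                     * stage.l_fr ** self.lmin_reductions)
            if l_min < 1e-3:  # 1 µm: the separation rule has collapsed
                raise RuntimeError(
                    f"l_min exhausted after {added}/{stage.N_terms} terminals "
                    f"(reductions={self.lmin_reductions}, region={stage.region!r})")
            x = sample_terminal_site(stage, domain, rng, side=self.side)
            ok = True
            if self.n_segments and float(np.min(self.point_segment_distances(x))) < l_min:
                ok = False
            if ok:
                ok = self.try_add_terminal(x, stage, domain)
            if ok:
                added += 1
                self.rejection_streak = 0
            else:
                self.rejection_streak += 1
                if self.rejection_streak >= _LMIN_FAILURE_WINDOW:
                    self.lmin_reductions += 1
                    self.rejection_streak = 0
        # uniform scaling is memoryless, so retargeting once at stage end
        # yields exactly the radii of continuous retargeting
        self.rescale_to_pressure_drop(dp_target, stage.eta)

    # -- audits ----------------------------------------------------------
    def murray_residuals(self) -> np.ndarray:
        """|r_p^g - sum r_c^g| / r_p^g at each bifurcation, with that
        bifurcation's creation-stage gamma."""
        res = []
        for j in range(self.n_segments):
            if len(self.children[j]) >= 2:
                g = self.gamma_at[j]
                rp = self.rel_r[j] ** g
                rc = sum(self.rel_r[c] ** g for c in self.children[j])
                res.append(abs(rp - rc) / rp)
        return np.asarray(res)


def _norm(v: np.ndarray) -> np.ndarray:
    return np.sqrt((v * v).sum(-1))


def _evaluate_bifurcations(a: np.ndarray, b: np.ndarray, x: np.ndarray,
                           rel: np.ndarray, ts: np.ndarray, ws: np.ndarray,
                           stage: StageConfig, domain: RetinalDomain):
    """Cost surface of candidate bifurcation points for H hosts at once.

    For host h, the bifurcation point M(t, w) sweeps the triangle spanned by
    the host endpoints (a_h, b_h) and the terminal site x; the cost is the
    volume proxy rel_h^2 (|aM| + |Mb|) + |Mx|, infinite where the branching
    angle, degeneracy or FAZ constraints fail. Shapes: (H, len(ts), len(ws)).
    """
    ab = (b - a)[:, None, None, :]
    base = a[:, None, None, :] + ts[None, :, None, None] * ab
    M = base + ws[None, None, :, None] * (x[None, None, None, :] - base)
    am = M - a[:, None, None, :]
    mb = b[:, None, None, :] - M
    mx = x[None, None, None, :] - M
    l_am, l_mb, l_mx = _norm(am), _norm(mb), _norm(mx)
    cosang = (mb * mx).sum(-1) / np.maximum(l_mb * l_mx, 1e-12)
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ok = ((l_am >= _MIN_SEG_LEN) & (l_mb >= _MIN_SEG_LEN)
          & (l_mx >= _MIN_SEG_LEN) & (theta > stage.theta_min))
    # FAZ clearance: the new segments stay inside the hull of (a, b, x), so
    # hosts whose whole triangle clears the FAZ need no per-point test
    near = _triangle_near_origin(a, b, x, domain.r_FAZ)
    if near.any():
        sub = np.flatnonzero(near)
        okf = ok[sub]
        okf &= _segments_origin_distance(a[sub, None, None, :], M[sub]) > domain.r_FAZ
        okf &= _segments_origin_distance(M[sub], b[sub, None, None, :]) > domain.r_FAZ
        okf &= _segments_origin_distance(M[sub], x[None, None, None, :]) > domain.r_FAZ
        ok[sub] = okf
    cost = rel[:, None, None] ** 2 * (l_am + l_mb) + l_mx
    return M, theta, np.where(ok, cost, np.inf)


def _triangle_near_origin(a: np.ndarray, b: np.ndarray, x: np.ndarray,
                          r: float) -> np.ndarray:
    """True per host when the triangle (a, b, x) comes within r of the origin
    (edge distance below r, or origin inside the triangle)."""
    xs = np.broadcast_to(x, a.shape)
    d = np.minimum.reduce([
        _segments_origin_distance(a, b),
        _segments_origin_distance(b, xs),
        _segments_origin_distance(xs, a)])
    near = d <= r

    def cross(p, q, o):
        return (q[:, 0] - p[:, 0]) * (o[..., 1] - p[:, 1]) \
            - (q[:, 1] - p[:, 1]) * (o[..., 0] - p[:, 0])

    o = np.zeros(2)
    c1, c2, c3 = cross(a, b, o), cross(b, xs, o), cross(xs, a, o)
    inside = ((c1 >= 0) & (c2 >= 0) & (c3 >= 0)) | ((c1 <= 0) & (c2 <= 0) & (c3 <= 0))
    return near | inside


def _point_to_segments(x: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Distances from point x to segments A->B (vectorized)."""
    AB = B - A
    denom = np.maximum((AB * AB).sum(-1), 1e-18)
    t = np.clip(((x - A) * AB).sum(-1) / denom, 0.0, 1.0)
    proj = A + t[..., None] * AB
    return np.linalg.norm(x - proj, axis=-1)


def _segments_origin_distance(P, Q) -> np.ndarray:
    """Distance from the origin to segments P->Q (broadcasting endpoints)."""
    P, Q = np.broadcast_arrays(np.asarray(P, float), np.asarray(Q, float))
    PQ = Q - P
    denom = np.maximum((PQ * PQ).sum(-1), 1e-18)
    t = np.clip((-P * PQ).sum(-1) / denom, 0.0, 1.0)
    proj = P + t[..., None] * PQ
    return np.linalg.norm(proj, axis=-1)


# ----------------------------------------------------------------------
# Public growth entry points
# ----------------------------------------------------------------------

def grow_tree(root_points: np.ndarray, domain: RetinalDomain, stage: StageConfig,
              target_flow_mL_s: float, dp_target: float,
              rng: np.random.Generator, side: int = 0) -> CCOTree:
    """Grow one tree for one stage.

    ``root_points`` is either a single root point (the first terminal then
    forms the root segment) or an arcade polyline.
    """
    if dp_target <= 0:
        raise ValueError("dp_target must be > 0")
    pts = np.atleast_2d(np.asarray(root_points, float))
    tree = (CCOTree.from_root_point(pts[0], side=side) if len(pts) == 1
            else CCOTree.from_polyline(pts, side=side))
    tree.q_root_mL_s = target_flow_mL_s
    tree.grow_stage(stage, domain, dp_target, rng)
    return tree


def cra_flow_uL_min(r_CRA_um: float, v_CRA_cm_s: float) -> float:
    """Q = v * pi * r^2, converted to µL/min."""
    return v_CRA_cm_s * 1e-2 * math.pi * (r_CRA_um * 1e-6) ** 2 * 6e10


def grow_macrovasculature(arcades, pop_params, config,
                          rng: np.random.Generator) -> VascularNetwork:
    """Grow the four SVP trees (superior/inferior x arterial/venous) over the
    three CCO stages and assemble them into one network with CRA/CRV roots.

    Arterial stages target a drop p_CRA - p_precapillary, venous stages
    p_precapillary - p_CRV. The CRA flow v*pi*r^2 splits equally between the
    two arterial arcades (and, by mass conservation, the two venous ones).
    """
    from .hemodynamics import ocular_pressures

    p_cra, p_crv, _ = ocular_pressures(pop_params.MAP, pop_params.IOP)
    q_total_mL_s = cra_flow_uL_min(pop_params.r_CRA, pop_params.v_CRA) / 6e4
    domain = config.domain

    labels = ("sup-artery", "inf-artery", "sup-vein", "inf-vein")
    by_label = {c.label: c for c in arcades}
    trees: dict[str, CCOTree] = {}
    for t_idx, label in enumerate(labels):
        curve = by_label[label]
        side = 1 if label.startswith("sup") else -1
        arterial = label.endswith("artery")
        tree = CCOTree.from_polyline(curve.points, side=side)
        tree.q_root_mL_s = q_total_mL_s / 2.0
        for stage in config.stages:
            if getattr(config, "stage_terms_shared", True):
                # stage count covers the whole retina: split across the 4 trees
                n_tree = stage.N_terms // 4 + (1 if t_idx < stage.N_terms % 4 else 0)
                stage = dataclasses.replace(stage, N_terms=n_tree)
            dp = (p_cra - stage.p_precapillary) if arterial \
                else (stage.p_precapillary - p_crv)
            if dp <= 0:
                raise ValueError(
                    f"non-positive stage pressure drop for {label}: {dp:.2f} mmHg")
            tree.grow_stage(stage, domain, dp, rng)
        if getattr(config, "radius_anchor", "root") == "root":
            # arcades inherit the central-vessel caliber: each of the two
            # trees per side is a Murray daughter of the CRA (or CRV) at the
            # optic disc, so the tree root is r_central * 2^(-1/gamma)
            r_central = pop_params.r_CRA if arterial \
                else config.crv_cra_radius_ratio * pop_params.r_CRA
            gamma0 = config.stages[0].gamma
            r_branch = r_central * 2.0 ** (-1.0 / gamma0)
            tree.scale_um = r_branch / float(tree.rel_r[0])
        trees[label] = tree

    return _assemble_network(trees, pop_params, config)


def _assemble_network(trees: dict[str, CCOTree], pop_params, config) -> VascularNetwork:
    domain = config.domain
    net = VascularNetwork()
    disc = np.array([domain.disc_center_x, domain.disc_center_y, 0.0])
    nasal = disc + np.array([-config.cra_length_mm, 0.0, 0.0])

    r_crv = config.crv_cra_radius_ratio * pop_params.r_CRA
    cra_root = net.add_nodes(nasal, "root")[0]
    cra_disc = net.add_nodes(disc, "arterial", "SVP")[0]
    net.add_segments([[cra_root, cra_disc]], pop_params.r_CRA, "artery", "SVP")
    crv_root = net.add_nodes(nasal, "root")[0]
    crv_disc = net.add_nodes(disc, "venous", "SVP")[0]
    net.add_segments([[crv_root, crv_disc]], r_crv, "vein", "SVP")

    audit = {"min_sym_ratio": np.inf, "min_angle_deg": np.inf,
             "max_murray_residual": 0.0, "n_bifurcations": 0}
    for label, tree in trees.items():
        arterial = label.endswith("artery")
        kind = "artery" if arterial else "vein"
        node_kind = "arterial" if arterial else "venous"
        junction = cra_disc if arterial else crv_disc
        pos = np.asarray(tree.pos)
        xyz = np.column_stack([pos, np.zeros(len(pos))])
        ids = net.add_nodes(xyz, node_kind, "SVP")
        # the tree root node coincides with the disc junction
        remap = ids.copy()
        remap[0] = junction
        conn = np.column_stack([remap[np.asarray(tree.seg_a, int)],
                                remap[np.asarray(tree.seg_b, int)]])
        radii = np.maximum(tree.radii_um(), 1.2)
        leaves = np.array([len(tree.children[j]) == 0
                           for j in range(tree.n_segments)])
        net.add_segments(conn, radii, kind, "SVP", is_terminal=leaves)
        res = tree.murray_residuals()
        if len(res):
            audit["max_murray_residual"] = max(audit["max_murray_residual"],
                                               float(res.max()))
        for rec in tree.audit:
            audit["min_sym_ratio"] = min(audit["min_sym_ratio"],
                                         min(rec.r1, rec.r2) / max(rec.r1, rec.r2))
            audit["min_angle_deg"] = min(audit["min_angle_deg"], rec.theta_deg)
            audit["n_bifurcations"] += 1

    net.metadata["pop_params"] = {"r_CRA": pop_params.r_CRA, "v_CRA": pop_params.v_CRA,
                                  "MAP": pop_params.MAP, "IOP": pop_params.IOP}
    net.metadata["cco_audit"] = audit
    return net
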