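"""OCTA-style morphometrics of the generated plexuses.

Metrics mirror what is computed on en-face OCT angiograms of the macula,
inside an analysis disk of diameter 3 mm centered on the fovea:

* analytic indices from cumulated vessel length L = Σ l_i and projected
  lumen area A = Σ 2 r_i l_i within the field of view of area X:
  VAD = A/X (vessel area density), VSD = L/X (skeleton density, mm⁻¹),
  VDI = A/L (diameter index, mm), VCI = (2L)²/(4πA) (complexity index,
  reading the vessel perimeter as ≈ 2L);
* fractal dimension FD by box counting on the binarized full-width vessel
  map (the OCTA convention);
* intervessel distance IVD from the Euclidean distance transform of the
  skeleton background (reported as twice the mean background distance);
* Horton–Strahler stream orders (capillaries are order 0; moving rootward, a
  vessel keeps the largest branch order i unless two or more branches share
  it, in which case it becomes i + 1), and per-order diameter tables with
  arteriole:venule ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as _skline

from .network import VascularNetwork

__all__ = [
    "analytic_indices", "rasterize_plexus", "fractal_dimension",
    "intervessel_distance", "strahler_orders", "diameter_by_order",
    "MorphometricsReport", "compute_morphometrics", "save_binary_image",
]


def save_binary_image(img: np.ndarray, path: str) -> None:
    """Write a binary mask/skeleton as an 8-bit PNG (vessels white)."""
    import imageio.v3 as iio
    iio.imwrite(path, (np.asarray(img, bool) * np.uint8(255)))

ANALYSIS_DISK_RADIUS_MM = 1.5   # 3 mm-diameter analysis disk
DEFAULT_PX_MM = 0.01            # 10 µm pixels


# ----------------------------------------------------------------------
# Analytic indices
# ----------------------------------------------------------------------

def _clip_fraction_to_disk(p: np.ndarray, q: np.ndarray, R: float) -> np.ndarray:
    """Fraction of each 2-D segment p->q lying inside the disk of radius R."""
    d = q - p
    a = (d * d).sum(-1)
    b = 2.0 * (p * d).sum(-1)
    c = (p * p).sum(-1) - R * R
    frac = np.zeros(len(p))
    disc = b * b - 4 * a * c
    ok = (disc > 0) & (a > 1e-18)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    t0 = np.clip((-b - sq) / (2 * np.maximum(a, 1e-18)), 0.0, 1.0)
    t1 = np.clip((-b + sq) / (2 * np.maximum(a, 1e-18)), 0.0, 1.0)
    frac[ok] = (t1 - t0)[ok]
    # degenerate (point-like in 2-D, e.g. vertical descenders): inside test
    pointlike = a <= 1e-18
    frac[pointlike] = (c[pointlike] <= 0).astype(float)
    return frac


def _plexus_segments(net: VascularNetwork, plexus: str) -> np.ndarray:
    mask = net.seg_plexus_mask(plexus) & ~net.seg_kind_mask("artificial")
    return np.flatnonzero(mask)


def analytic_indices(net: VascularNetwork, plexus: str,
                     fov_radius_mm: float = ANALYSIS_DISK_RADIUS_MM) -> dict:
    """VAD, VSD (mm^-1), VDI (mm), VCI for one plexus inside the analysis disk.

    Segments partially inside the disk contribute their clipped length. With
    no vessel length in view, VDI and VCI are undefined (NaN).
    """
    idx = _plexus_segments(net, plexus)
    X = np.pi * fov_radius_mm ** 2
    if len(idx) == 0:
        return {"VAD": 0.0, "VSD": 0.0, "VDI": np.nan, "VCI": np.nan, "X_mm2": X,
                "L_mm": 0.0, "A_mm2": 0.0}
    p = net.xyz[net.conn[idx, 0], :2]
    q = net.xyz[net.conn[idx, 1], :2]
    frac = _clip_fraction_to_disk(p, q, fov_radius_mm)
    l = net.length_mm[idx] * frac
    r_mm = net.radius_um[idx] * 1e-3
    L = float(l.sum())
    A = float((2.0 * r_mm * l).sum())
    if L == 0:
        return {"VAD": 0.0, "VSD": 0.0, "VDI": np.nan, "VCI": np.nan, "X_mm2": X,
                "L_mm": 0.0, "A_mm2": 0.0}
    return {"VAD": A / X, "VSD": L / X, "VDI": A / L,
            "VCI": (2.0 * L) ** 2 / (4.0 * np.pi * A), "X_mm2": X,
            "L_mm": L, "A_mm2": A}


# ----------------------------------------------------------------------
# Rasterization
# ----------------------------------------------------------------------

def rasterize_plexus(net: VascularNetwork, plexus: str | list[str],
                     fov_radius_mm: float = ANALYSIS_DISK_RADIUS_MM,
                     px_mm: float = DEFAULT_PX_MM) -> tuple[np.ndarray, np.ndarray]:
    """Binary full-width vessel mask and 1-px skeleton of a plexus (or a list
    of plexuses rendered together), on a square canvas covering the analysis
    disk."""
    plexi = [plexus] if isinstance(plexus, str) else list(plexus)
    n = int(round(2 * fov_radius_mm / px_mm))
    mask = np.zeros((n, n), bool)
    skel = np.zeros((n, n), bool)
    idx = np.concatenate([_plexus_segments(net, p) for p in plexi]) \
        if plexi else np.empty(0, int)
    if len(idx) == 0:
        return mask, skel

    def to_px(xy):
        return (xy + fov_radius_mm) / px_mm - 0.5

    P = to_px(net.xyz[net.conn[idx, 0], :2])
    Q = to_px(net.xyz[net.conn[idx, 1], :2])
    r_px = net.radius_um[idx] * 1e-3 / px_mm
    # skip segments entirely outside the canvas (inflated by their width)
    pad = np.maximum(r_px, 0.5)[:, None] + 2
    on_canvas = ~(np.any((np.maximum(P, Q) < -pad) | (np.minimum(P, Q) > n + pad),
                         axis=1))
    for p, q, r in zip(P[on_canvas], Q[on_canvas], r_px[on_canvas]):
        # skeleton: 1-px centerline
        r0, c0 = int(round(p[1])), int(round(p[0]))
        r1, c1 = int(round(q[1])), int(round(q[0]))
        rr, cc = _skline(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
        skel[rr[ok], cc[ok]] = True
        if r <= 0.5:  # thinner than a pixel: the mask is the centerline
            mask[rr[ok], cc[ok]] = True
            continue
        # mask: stadium of half-width r (at least half a pixel)
        w = max(r, 0.5)
        lo = np.floor(np.minimum(p, q) - w - 1).astype(int)
        hi = np.ceil(np.maximum(p, q) + w + 1).astype(int)
        lo = np.clip(lo, 0, n - 1)
        hi = np.clip(hi, 0, n - 1)
        if np.any(hi < lo):
            continue
        xs = np.arange(lo[0], hi[0] + 1)
        ys = np.arange(lo[1], hi[1] + 1)
        XX, YY = np.meshgrid(xs, ys)
        pts = np.stack([XX, YY], axis=-1).astype(float)
        d = q - p
        denom = max(float((d * d).sum()), 1e-18)
        t = np.clip(((pts - p) * d).sum(-1) / denom, 0.0, 1.0)
        proj = p + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
        sub = mask[lo[1]:hi[1] + 1, lo[0]:hi[0] + 1]
        sub |= dist <= w
    return mask, skel


# ----------------------------------------------------------------------
# Fractal dimension and intervessel distance
# ----------------------------------------------------------------------

def _box_count(img: np.ndarray, s: int) -> int:
    h, w = img.shape
    H, W = -(-h // s) * s, -(-w // s) * s
    padded = np.zeros((H, W), bool)
    padded[:h, :w] = img
    blocks = padded.reshape(H // s, s, W // s, s)
    return int(blocks.any(axis=(1, 3)).sum())


def fractal_dimension(img: np.ndarray, box_sizes: np.ndarray | None = None) -> float:
    """Box-counting fractal dimension: FD = -slope of log N(s) vs log s.

    Default box sizes are the divisors of the shorter image side up to a
    quarter of it (boxes tile the image exactly, avoiding padding bias at the
    large-box end); powers of 2 are used as a fallback when a side has too
    few divisors."""
    img = np.asarray(img, bool)
    if not img.any():
        raise ValueError("empty image has no fractal dimension")
    if box_sizes is None:
        n = min(img.shape)
        m = max(n // 4, 2)
        sizes = [s for s in range(1, m + 1) if n % s == 0]
        if len(sizes) < 2:
            sizes = sorted({1} | {2 ** k for k in range(1, int(np.log2(m)) + 1)})
        box_sizes = np.array(sizes)
    counts = np.array([_box_count(img, int(s)) for s in box_sizes], float)
    slope = np.polyfit(np.log(box_sizes), np.log(counts), 1)[0]
    return float(-slope)


def intervessel_distance(skeleton: np.ndarray, px_um: float = 10.0,
                         fov_disk: bool = True) -> float:
    """Intervessel distance (µm): twice the mean Euclidean distance from
    background pixels (inside the analysis disk) to the nearest skeleton
    pixel."""
    skeleton = np.asarray(skeleton, bool)
    if not skeleton.any():
        raise ValueError("empty skeleton")
    edt = ndimage.distance_transform_edt(~skeleton)
    if fov_disk:
        n = skeleton.shape[0]
        yy, xx = np.mgrid[0:n, 0:skeleton.shape[1]]
        c = (np.array(skeleton.shape) - 1) / 2.0
        inside = (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= (min(c)) ** 2
    else:
        inside = np.ones_like(skeleton)
    bg = inside & ~skeleton
    return float(2.0 * edt[bg].mean() * px_um)


# ----------------------------------------------------------------------
# Horton-Strahler ordering
# ----------------------------------------------------------------------

def strahler_orders(net: VascularNetwork) -> np.ndarray:
    """Stream order per segment.

    Capillaries are order 0. Arterial segments are processed from their
    capillary-facing tips toward the CRA, venous segments toward the CRV
    (both trees are stored proximal->distal, so processing is
    reverse-topological in both). Branches of a segment are the macro
    segments and capillary attachments at its distal node. Artificial
    compartment segments get order -1 (not part of the anatomy).
    """
    m = net.n_segments
    orders = np.full(m, -1, np.int64)
    cap = net.seg_kind_mask("capillary")
    orders[cap] = 0

    cap_count_at_node = np.zeros(net.n_nodes, np.int64)
    np.add.at(cap_count_at_node, net.conn[cap].ravel(), 1)

    for kind in ("artery", "vein"):
        segs = np.flatnonzero(net.seg_kind_mask(kind))
        if len(segs) == 0:
            continue
        # children: same-kind segments emanating from this segment's distal node
        start_at = {}
        for j in segs:
            start_at.setdefault(int(net.conn[j, 0]), []).append(int(j))
        children = {int(j): start_at.get(int(net.conn[j, 1]), []) for j in segs}
        # roots: segments whose proximal node starts no other same-kind segment's distal end
        distal_nodes = {int(net.conn[j, 1]) for j in segs}
        roots = [int(j) for j in segs if int(net.conn[j, 0]) not in distal_nodes]
        order_list: list[int] = []
        seen = set()
        stack = list(roots)
        while stack:
            j = stack.pop()
            if j in seen:
                raise ValueError(f"cycle encountered in {kind} tree at segment {j}")
            seen.add(j)
            order_list.append(j)
            stack.extend(children[j])
        if len(seen) != len(segs):
            raise ValueError(f"cycle or disconnected {kind} segments detected")
        for j in reversed(order_list):
            branch_orders = [int(orders[c]) for c in children[j]]
            n_cap = int(cap_count_at_node[net.conn[j, 1]])
            if not branch_orders:
                # a vessel feeding only capillaries is a first-order
                # arteriole/venule (order 0 is the capillary class);
                # a bare tip (compartment-closed) stays at 0
                orders[j] = 1 if n_cap else 0
                continue
            branch_orders += [0] * n_cap
            i_max = max(branch_orders)
            n_max = sum(1 for o in branch_orders if o == i_max)
            orders[j] = i_max + 1 if n_max >= 2 else i_max
    return orders


def diameter_by_order(net: VascularNetwork, orders: np.ndarray | None = None,
                      region_radius_mm: float = 3.0) -> pd.DataFrame:
    """Per-order diameter table for macular vessels (segment midpoint inside
    the given disk): arteriole and venule mean diameters, counts, and their
    ratio per order. The combined arteriole:venule ratio over all orders is in
    the attrs of the returned frame."""
    if orders is None:
        orders = strahler_orders(net)
    mid = net.midpoints()
    macular = (mid[:, :2] ** 2).sum(axis=1) <= region_radius_mm ** 2
    d_um = 2.0 * net.radius_um
    rows = []
    art = net.seg_kind_mask("artery") & macular
    ven = net.seg_kind_mask("vein") & macular
    all_orders = sorted(set(orders[art | ven].tolist()))
    for o in all_orders:
        da = d_um[art & (orders == o)]
        dv = d_um[ven & (orders == o)]
        rows.append({
            "order": o,
            "n_arteriole": len(da), "n_venule": len(dv),
            "arteriole_diam_um": da.mean() if len(da) else np.nan,
            "venule_diam_um": dv.mean() if len(dv) else np.nan,
            "ratio": (da.mean() / dv.mean()) if len(da) and len(dv) else np.nan,
        })
    table = pd.DataFrame(rows)
    combined = (d_um[art].mean() / d_um[ven].mean()
                if art.any() and ven.any() else np.nan)
    table.attrs["combined_ratio"] = float(combined)
    return table


# ----------------------------------------------------------------------
# Report
# ----------------------------------------------------------------------

@dataclass
class MorphometricsReport:
    """Per-plexus OCTA-style metrics of one virtual eye."""

    per_plexus: dict            # plexus -> dict of metric values
    strahler: pd.DataFrame      # diameter-by-order table (macular vessels)
    combined_av_ratio: float    # arteriole:venule diameter ratio, all orders

    def flat(self) -> dict[str, float]:
        out = {}
        for plexus, metrics in self.per_plexus.items():
            for k, v in metrics.items():
                if k in ("VAD", "VSD", "VDI", "VCI", "FD", "IVD"):
                    out[f"{k}_{plexus}"] = v
        out["av_ratio_all_orders"] = self.combined_av_ratio
        return out


def compute_morphometrics(net: VascularNetwork,
                          px_mm: float = DEFAULT_PX_MM) -> MorphometricsReport:
    """Full metric panel: VAD/VSD/VDI/VCI/FD/IVD for the SVP; VAD and FD for
    the ICP, DCP and the ICP–DCP complex; Strahler diameter table."""
    per = {}
    for plexus in ("SVP", "ICP", "DCP"):
        metrics = analytic_indices(net, plexus)
        mask, skel = rasterize_plexus(net, plexus, px_mm=px_mm)
        # FD on the full-width vessel mask (the OCTA convention); IVD needs
        # the 1-px skeleton
        metrics["FD"] = fractal_dimension(mask) if mask.any() else np.nan
        metrics["IVD"] = (intervessel_distance(skel, px_um=px_mm * 1e3)
                          if skel.any() else np.nan)
        per[plexus] = metrics
    # ICP-DCP complex: union projection
    both = ["ICP", "DCP"]
    m = analytic_indices(net, "ICP")
    m2 = analytic_indices(net, "DCP")
    L = m["L_mm"] + m2["L_mm"]
    A = m["A_mm2"] + m2["A_mm2"]
    X = m["X_mm2"]
    mask, skel = rasterize_plexus(net, both, px_mm=px_mm)
    per["ICP_DCP"] = {
        "VAD": A / X, "VSD": L / X,
        "VDI": A / L if L else np.nan,
        "VCI": (2 * L) ** 2 / (4 * np.pi * A) if A else np.nan,
        "FD": fractal_dimension(mask) if mask.any() else np.nan,
        "IVD": intervessel_distance(skel, px_um=px_mm * 1e3) if skel.any() else np.nan,
        "X_mm2": X, "L_mm": L, "A_mm2": A,
    }
    orders = strahler_orders(net)
    table = diameter_by_order(net, orders)
    return MorphometricsReport(per_plexus=per, strahler=table,
                               combined_av_ratio=table.attrs["combined_ratio"])
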