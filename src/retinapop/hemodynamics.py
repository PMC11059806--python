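"""Poiseuille network hemodynamics with diameter-dependent blood viscosity.

Blood is treated as incompressible and Newtonian per segment, flowing through
straight tubes: Q = Δp / R with R = 8 µ l / (π r⁴). The Fåhræus–Lindqvist
effect is captured by the empirical in-vivo effective-viscosity law of
Pries & Secomb, evaluated at a fixed discharge hematocrit (0.45 by default).
Because hematocrit is constant, viscosity depends only on diameter and the
whole network is a linear resistor system: one sparse solve of the nodal
conductance (weighted-Laplacian) equations with Dirichlet pressures at the
central retinal artery (CRA) and vein (CRV) yields all nodal pressures and
segment flows.

Extramacular terminal vessels close through a single compartment node reached
by "artificial" segments of fixed resistance ``R_compartment``; these bypass
the viscosity model entirely.

Unit boundaries: pressures mmHg, flows µL/min (mL/s internally), radii µm,
lengths mm, viscosity cP. All conversions happen inside this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import HemoConfig
from .network import VascularNetwork

__all__ = [
    "MMHG_TO_PA",
    "ocular_pressures",
    "effective_viscosity",
    "segment_resistance",
    "solve_flow",
    "perfusion_summary",
    "HemodynamicsSolution",
]

MMHG_TO_PA = 133.322387415
# R[mmHg*s/mL] = _RES_COEF * mu[cP] * l[mm] / (pi * r[um]^4)
_RES_COEF = 8.0 * 1e-3 * 1e-3 / 1e-24 / (MMHG_TO_PA / 1e-6)


@dataclass
class HemodynamicsSolution:
    """Nodal pressures and per-segment flow of one solved network."""

    pressure_mmHg: np.ndarray        # per node
    flow_uL_min: np.ndarray          # per segment, signed along conn[:,0]->conn[:,1]
    velocity_cm_s: np.ndarray        # per segment, |Q|/(pi r^2)
    pressure_drop_mmHg: np.ndarray   # per segment, p(a)-p(b)
    p_CRA: float
    p_CRV: float
    OPP: float
    retinal_blood_flow: float        # µL/min through the CRA
    macular_flow_fraction: float     # % of retinal blood flow entering the perifoveal disk
    v_CRA: float                     # cm/s in the CRA


def ocular_pressures(MAP: float, IOP: float) -> tuple[float, float, float]:
    """Root boundary pressures: p_CRA = (2/3) MAP, p_CRV = IOP, OPP = p_CRA - p_CRV."""
    if MAP < 0 or IOP < 0:
        raise ValueError("MAP and IOP must be non-negative")
    p_cra = 2.0 / 3.0 * MAP
    p_crv = float(IOP)
    opp = p_cra - p_crv
    if opp <= 0:
        raise ValueError(f"non-perfusing eye: OPP = {opp:.2f} mmHg <= 0")
    return p_cra, p_crv, opp


def effective_viscosity(D_um, H_D: float = 0.45, mu_plasma: float = 1.0):
    """In-vivo effective viscosity (cP) for vessel diameter ``D_um`` (µm).

    Relative apparent viscosity law

        µ(D, H) = [1 + (µ₀.₄₅ − 1) · ((1−H)^C − 1)/((1−0.45)^C − 1) · W] · W,
        W = (D/(D − 1.12))²,

    with µ₀.₄₅ = 6 e^(−0.085 D) + 3.2 − 2.44 e^(−0.06 D^0.645) and the shape
    exponent C = (0.8 + e^(−0.075 D)) (−1 + S) + S, S = 1/(1 + 10⁻¹¹ D¹²),
    multiplied by the plasma viscosity (cP).
    """
    D = np.asarray(D_um, float)
    if not (0.0 < H_D < 1.0):
        raise ValueError("H_D must be in (0, 1)")
    if np.any(D <= 1.12):
        raise ValueError("diameter must exceed 1.12 um (law singularity)")
    mu45 = 6.0 * np.exp(-0.085 * D) + 3.2 - 2.44 * np.exp(-0.06 * D ** 0.645)
    S = 1.0 / (1.0 + 1e-11 * D ** 12)
    C = (0.8 + np.exp(-0.075 * D)) * (-1.0 + S) + S
    W = (D / (D - 1.12)) ** 2
    ratio = ((1.0 - H_D) ** C - 1.0) / ((1.0 - 0.45) ** C - 1.0)
    mu = (1.0 + (mu45 - 1.0) * ratio * W) * W
    return mu_plasma * mu


def segment_resistance(r_um, l_mm, mu_cP):
    """Poiseuille resistance R = 8 µ l / (π r⁴) in mmHg·s/mL."""
    r = np.asarray(r_um, float)
    l = np.asarray(l_mm, float)
    mu = np.asarray(mu_cP, float)
    if np.any(r <= 0) or np.any(l <= 0) or np.any(mu <= 0):
        raise ValueError("radius, length and viscosity must be positive")
    return _RES_COEF * mu * l / (np.pi * r ** 4)


def network_resistances(network: VascularNetwork, hemo: HemoConfig) -> np.ndarray:
    """Per-segment resistance (mmHg·s/mL); artificial segments use the fixed
    compartment resistance."""
    R = np.empty(network.n_segments)
    fixed = network.fixed_resistance
    free = ~fixed
    if free.any():
        D = 2.0 * network.radius_um[free]
        mu = effective_viscosity(D, hemo.H_D, hemo.mu_plasma)
        R[free] = segment_resistance(network.radius_um[free],
                                     network.length_mm[free], mu)
    R[fixed] = hemo.R_compartment
    return R


def _find_root_nodes(network: VascularNetwork) -> tuple[int, int]:
    roots = np.flatnonzero(network.node_kind_mask("root"))
    if len(roots) != 2:
        raise ValueError("network must carry exactly two root nodes (CRA inlet, CRV outlet)")
    a, b = roots
    # the inlet is the root touching artery segments
    art = network.seg_kind_mask("artery")
    touches_a = np.any(np.isin(network.conn[art], a))
    return (int(a), int(b)) if touches_a else (int(b), int(a))


def solve_flow(network: VascularNetwork, p_CRA: float, p_CRV: float,
               hemo: HemoConfig | None = None,
               r_perifovea: float = 3.0) -> HemodynamicsSolution:
    """Solve nodal pressures and segment flows with Dirichlet pressures at the
    CRA inlet and CRV outlet root nodes."""
    hemo = hemo or HemoConfig()
    n = network.n_nodes
    inlet, outlet = _find_root_nodes(network)
    R = network_resistances(network, hemo)
    g = 1.0 / R
    a, b = network.conn[:, 0], network.conn[:, 1]

    # weighted graph Laplacian
    L = sp.coo_matrix(
        (np.concatenate([g, g, -g, -g]),
         (np.concatenate([a, b, a, b]), np.concatenate([a, b, b, a]))),
        shape=(n, n)).tocsr()

    fixed = np.zeros(n, bool)
    fixed[[inlet, outlet]] = True
    p = np.zeros(n)
    p[inlet], p[outlet] = p_CRA, p_CRV
    free = ~fixed
    if free.any():
        A = L[free][:, free].tocsc()
        # a free node with no connections makes the system singular
        deg = network.degrees()
        orphan = np.flatnonzero(free & (deg == 0))
        if len(orphan):
            raise ValueError(f"disconnected nodes with no segments: {orphan[:10].tolist()}")
        rhs = -L[free][:, fixed] @ p[fixed]
        try:
            p[free] = spla.spsolve(A, rhs)
        except RuntimeError as exc:  # pragma: no cover - singular systems
            raise ValueError(f"singular conductance system: {exc}") from None
        if not np.all(np.isfinite(p)):
            bad = np.flatnonzero(~np.isfinite(p))
            raise ValueError(f"singular system; orphaned nodes include {bad[:10].tolist()}")

    dp = p[a] - p[b]
    q_mL_s = dp * g
    q = q_mL_s * 6e4  # µL/min
    area_m2 = np.pi * (network.radius_um * 1e-6) ** 2
    v = np.abs(q_mL_s) * 1e-6 / area_m2 * 100.0  # cm/s

    # retinal blood flow: flow through the CRA root segment
    cra_seg = _root_segment(network, inlet)
    rbf = float(abs(q[cra_seg]))
    v_cra = float(v[cra_seg])

    mff = _macular_flow_fraction(network, q, rbf, r_perifovea)
    return HemodynamicsSolution(
        pressure_mmHg=p, flow_uL_min=q, velocity_cm_s=v, pressure_drop_mmHg=dp,
        p_CRA=float(p_CRA), p_CRV=float(p_CRV), OPP=float(p_CRA - p_CRV),
        retinal_blood_flow=rbf, macular_flow_fraction=mff, v_CRA=v_cra)


def _root_segment(network: VascularNetwork, root_node: int) -> int:
    js = np.flatnonzero(np.any(network.conn == root_node, axis=1))
    if len(js) != 1:
        raise ValueError("root node must carry exactly one segment")
    return int(js[0])


def _macular_flow_fraction(network: VascularNetwork, q: np.ndarray,
                           rbf: float, r_perifovea: float) -> float:
    """Percentage of retinal blood flow entering the perifoveal disk: the net
    arterial inflow across the disk boundary (inward minus outward arterial
    crossings, so arterioles merely passing through the disk do not count)."""
    if rbf == 0:
        return float("nan")
    r2 = r_perifovea ** 2
    ra2 = (network.xyz[network.conn[:, 0], :2] ** 2).sum(axis=1)
    rb2 = (network.xyz[network.conn[:, 1], :2] ** 2).sum(axis=1)
    art = network.seg_kind_mask("artery")
    a_out = art & (ra2 > r2) & (rb2 <= r2)
    b_out = art & (rb2 > r2) & (ra2 <= r2)
    inflow = q[a_out].sum() - q[b_out].sum()
    return float(100.0 * inflow / rbf)


def perfusion_summary(solution: HemodynamicsSolution,
                      network: VascularNetwork) -> dict[str, float]:
    """Scalar summary of macular perfusion."""
    return {
        "retinal_blood_flow_uL_min": solution.retinal_blood_flow,
        "macular_flow_fraction_pct": solution.macular_flow_fraction,
        "v_CRA_cm_s": solution.v_CRA,
        "OPP_mmHg": solution.OPP,
    }


def kirchhoff_residual(network: VascularNetwork,
                       solution: HemodynamicsSolution) -> float:
    """Maximum absolute net flow at interior (non-root) nodes, in µL/min."""
    net_flow = np.zeros(network.n_nodes)
    np.add.at(net_flow, network.conn[:, 0], -solution.flow_uL_min)
    np.add.at(net_flow, network.conn[:, 1], solution.flow_uL_min)
    interior = ~network.node_kind_mask("root")
    return float(np.abs(net_flow[interior]).max(initial=0.0))
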