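"""Viscosity law, resistances, and the network flow solver."""

import numpy as np
import pytest

from retinapop.config import HemoConfig
from retinapop.hemodynamics import (effective_viscosity, kirchhoff_residual,
                                    ocular_pressures, perfusion_summary,
                                    segment_resistance, solve_flow)
from retinapop.network import VascularNetwork


@pytest.mark.parametrize("MAP,IOP,expected", [
    (84.0, 11.1, (56.0, 11.1, 44.9)),
    (90.0, 15.0, (60.0, 15.0, 45.0)),
])
def test_ocular_pressures(MAP, IOP, expected):
    assert ocular_pressures(MAP, IOP) == pytest.approx(expected)


def test_non_perfusing_eye_rejected():
    with pytest.raises(ValueError, match="OPP"):
        ocular_pressures(0.0, 0.0)


def test_viscosity_hematocrit_045_cancels():
    # at the reference hematocrit the hematocrit ratio term is identically 1,
    # so the law reduces to [1 + (mu45 - 1) W] W with no dependence on the
    # shape exponent C
    for D in (3.0, 10.0, 50.0, 200.0):
        mu45 = 6 * np.exp(-0.085 * D) + 3.2 - 2.44 * np.exp(-0.06 * D ** 0.645)
        W = (D / (D - 1.12)) ** 2
        want = (1 + (mu45 - 1) * W) * W
        assert effective_viscosity(D, 0.45) == pytest.approx(want, rel=1e-12)


def test_viscosity_large_diameter_limit():
    assert effective_viscosity(1e7) == pytest.approx(3.2, rel=1e-4)


def test_viscosity_reference_value():
    assert effective_viscosity(10.0, 0.45) == pytest.approx(5.92, abs=0.01)


def test_viscosity_singularity_guard():
    with pytest.raises(ValueError):
        effective_viscosity(1.0)


def test_resistance_scaling_laws():
    base = segment_resistance(40.0, 1.0, 3.0)
    assert segment_resistance(80.0, 1.0, 3.0) == pytest.approx(base / 16)
    assert segment_resistance(40.0, 2.0, 3.0) == pytest.approx(2 * base)


def test_resistance_si_hand_value():
    # R = 8 mu l / (pi r^4) in SI, converted to mmHg*s/mL by hand
    r, l, mu = 40e-6, 1e-3, 3e-3
    R_si = 8 * mu * l / (np.pi * r ** 4)            # Pa*s/m^3
    R_mmHg_s_mL = R_si / (133.322387415 / 1e-6)
    assert segment_resistance(40.0, 1.0, 3.0) == pytest.approx(R_mmHg_s_mL,
                                                               rel=1e-9)


def _chain_network(radii, lengths):
    net = VascularNetwork()
    k = len(radii)
    xs = np.concatenate([[0.0], np.cumsum(lengths)])
    nodes = np.column_stack([xs, np.zeros(k + 1), np.zeros(k + 1)])
    ids = net.add_nodes(nodes, "arterial", "SVP")
    net.node_kind[ids[0]] = 4  # root
    net.node_kind[ids[-1]] = 4
    net.add_segments(np.column_stack([ids[:-1], ids[1:]]), radii, "artery", "SVP")
    return net


def test_series_resistors_exact():
    net = _chain_network([20.0, 10.0], [1.0, 2.0])
    hemo = HemoConfig()
    from retinapop.hemodynamics import network_resistances
    R = network_resistances(net, hemo)
    sol = solve_flow(net, 50.0, 10.0, hemo)
    q_expected = (50.0 - 10.0) / R.sum() * 6e4
    assert sol.retinal_blood_flow == pytest.approx(q_expected, rel=1e-12)


def test_parallel_resistors_exact():
    net = VascularNetwork()
    ids = net.add_nodes([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                        "arterial", "SVP")
    net.node_kind[[0, 3]] = 4
    net.add_segments([[0, 1]], 40.0, "artery", "SVP")
    net.add_segments([[1, 2], [1, 2]], [10.0, 15.0], "artery", "SVP")
    net.add_segments([[2, 3]], 40.0, "artery", "SVP")
    from retinapop.hemodynamics import network_resistances
    R = network_resistances(net, HemoConfig())
    R_total = R[0] + 1.0 / (1 / R[1] + 1 / R[2]) + R[3]
    sol = solve_flow(net, 60.0, 20.0, HemoConfig())
    assert sol.retinal_blood_flow == pytest.approx(40.0 / R_total * 6e4,
                                                   rel=1e-12)
    # flow splits inversely to resistance
    assert sol.flow_uL_min[1] / sol.flow_uL_min[2] == pytest.approx(R[2] / R[1])


def test_random_network_matches_dense_solve():
    rng = np.random.default_rng(8)
    n = 60
    net = VascularNetwork()
    ids = net.add_nodes(rng.normal(size=(n, 3)), "arterial", "SVP")
    net.node_kind[[0, n - 1]] = 4
    # spanning tree over interior nodes 1..n-2, roots attached by one segment
    conn = [[rng.integers(1, i), i] for i in range(2, n - 1)]
    extra = rng.integers(1, n - 1, size=(40, 2))
    conn = np.vstack([conn, extra[extra[:, 0] != extra[:, 1]]])
    conn = np.vstack([[[0, 1]], conn, [[n - 2, n - 1]]])
    net.add_segments(conn, rng.uniform(5, 50, len(conn)), "artery", "SVP")

    from retinapop.hemodynamics import network_resistances
    g = 1.0 / network_resistances(net, HemoConfig())
    L = np.zeros((n, n))
    for (a, b), gi in zip(net.conn, g):
        L[a, a] += gi
        L[b, b] += gi
        L[a, b] -= gi
        L[b, a] -= gi
    p = np.zeros(n)
    p[0], p[n - 1] = 45.0, 12.0
    free = np.ones(n, bool)
    free[[0, n - 1]] = False
    p[free] = np.linalg.solve(L[np.ix_(free, free)],
                              -L[np.ix_(free, ~free)] @ p[~free])
    sol = solve_flow(net, 45.0, 12.0, HemoConfig())
    assert np.allclose(sol.pressure_mmHg, p, rtol=1e-9, atol=1e-9)


def test_solver_invariants_on_generated_network(tiny_individual):
    net, sol = tiny_individual.network, tiny_individual.solution
    assert kirchhoff_residual(net, sol) < 1e-9 * sol.retinal_blood_flow
    assert sol.pressure_mmHg.min() >= sol.p_CRV - 1e-9
    assert sol.pressure_mmHg.max() <= sol.p_CRA + 1e-9


def test_flow_monotone_in_opp_and_mff_invariant(tiny_individual, tiny_config):
    net = tiny_individual.network
    sols = [solve_flow(net, 11.1 + opp, 11.1, tiny_config.hemo)
            for opp in (30.0, 45.0, 60.0)]
    rbf = [s.retinal_blood_flow for s in sols]
    assert rbf[0] < rbf[1] < rbf[2]
    # linear system: scaling OPP scales flows, leaving the fraction unchanged
    assert sols[0].macular_flow_fraction == pytest.approx(
        sols[2].macular_flow_fraction, rel=1e-9)
    assert rbf[2] / rbf[0] == pytest.approx(2.0, rel=1e-9)


def test_perfusion_summary_velocity(tiny_individual):
    s = tiny_individual.solution
    out = perfusion_summary(s, tiny_individual.network)
    q_m3 = out["retinal_blood_flow_uL_min"] * 1e-9 / 60.0
    r_m = tiny_individual.params.r_CRA * 1e-6
    assert out["v_CRA_cm_s"] == pytest.approx(q_m3 / (np.pi * r_m ** 2) * 100,
                                              rel=1e-9)


def test_mass_conservation_cra_equals_crv(tiny_individual):
    net, s = tiny_individual.network, tiny_individual.solution
    roots = np.flatnonzero(net.node_kind_mask("root"))
    flows = []
    for r in roots:
        j = np.flatnonzero(np.any(net.conn == r, axis=1))
        flows.append(abs(s.flow_uL_min[j]).sum())
    assert flows[0] == pytest.approx(flows[1], rel=1e-9)
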