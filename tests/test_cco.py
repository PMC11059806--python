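"""Constrained constructive optimization growth rules and tree audits."""

import numpy as np
import pytest

from retinapop.cco import (bifurcation_admissible, cra_flow_uL_min, grow_tree,
                           min_separation, parent_radius, sample_terminal_site)
from retinapop.config import RetinalDomain, StageConfig
from retinapop.hemodynamics import _RES_COEF, effective_viscosity


@pytest.mark.parametrize("nu,area,n,expected", [
    (1.0, np.pi * 15 ** 2, 0, 15.0),
    (0.0, 123.4, 7, 0.0),
    (1.0, np.pi, 3, 0.5),
])
def test_min_separation_closed_form(nu, area, n, expected):
    assert min_separation(nu, area, n) == pytest.approx(expected)


def test_min_separation_rejects_negative():
    with pytest.raises(ValueError):
        min_separation(1.0, -1.0, 0)
    with pytest.raises(ValueError):
        min_separation(1.0, 1.0, -1)


@pytest.mark.parametrize("r1,r2,g,expected", [
    (1.0, 0.0, 3.0, 1.0),
    (1.0, 1.0, 3.0, 2 ** (1 / 3)),
    (2.0, 2.0, 2.85, 2 * 2 ** (1 / 2.85)),
])
def test_parent_radius(r1, r2, g, expected):
    assert parent_radius(r1, r2, g) == pytest.approx(expected, rel=1e-12)


def test_bifurcation_admissibility_rules():
    s1 = StageConfig(delta=0.8, theta_min=60.0)
    assert bifurcation_admissible(1.0, 1.0, 61.0, s1)
    assert not bifurcation_admissible(1.0, 2.0, 179.0, s1)  # symmetry fails
    s23 = StageConfig(delta=0.0, theta_min=60.0)
    assert not bifurcation_admissible(1.0, 17.0, 59.0, s23)  # angle only
    assert bifurcation_admissible(1.0, 17.0, 61.0, s23)


def test_terminal_site_sigma_zero_deterministic_radius():
    stage = StageConfig(lognormal_sigma=0.0, lognormal_mu=-0.5,
                        lognormal_r0=0.02, region="full")
    domain = RetinalDomain()
    rng = np.random.default_rng(0)
    r_expected = 0.02 + np.exp(-0.5)
    for _ in range(50):
        p = sample_terminal_site(stage, domain, rng)
        assert np.hypot(*p) == pytest.approx(r_expected, rel=1e-12)


def test_terminal_site_respects_faz_and_side():
    stage = StageConfig(region="full")
    domain = RetinalDomain()
    rng = np.random.default_rng(1)
    for _ in range(300):
        p = sample_terminal_site(stage, domain, rng, side=1)
        assert np.hypot(*p) > domain.r_FAZ
        assert p[1] > 0


def test_terminal_site_median_matches_lognormal():
    """Monte-Carlo median of accepted radii vs r0 + exp(mu) (the log-normal
    median), inside a region wide enough not to clip the median."""
    stage = StageConfig(lognormal_sigma=4.0, lognormal_mu=-0.5,
                        lognormal_r0=0.02, region="full")
    domain = RetinalDomain(r_retina=1e9, r_FAZ=1e-9, r_parafovea=1.0,
                           r_perifovea=2.0)
    rng = np.random.default_rng(2)
    r = np.array([np.hypot(*sample_terminal_site(stage, domain, rng))
                  for _ in range(4000)])
    assert np.median(r) == pytest.approx(0.02 + np.exp(-0.5), rel=0.1)


def test_single_terminal_poiseuille_radius():
    """N_terms=1 growth is one root->terminal segment whose radius produces
    exactly the target pressure drop at the target flow."""
    domain = RetinalDomain()
    stage = StageConfig(N_terms=1, region="full", delta=0.0)
    q = 1e-4   # mL/s
    dp = 20.0  # mmHg
    tree = grow_tree(np.array([[-4.5, 0.5]]), domain, stage, q, dp,
                     np.random.default_rng(3), side=1)
    assert tree.n_segments == 1 and tree.n_terminals == 1
    r = tree.radii_um()[0]
    l = tree.length[0]
    mu = effective_viscosity(2 * r)
    dp_check = q * _RES_COEF * mu * l / (np.pi * r ** 4)
    assert dp_check == pytest.approx(dp, rel=1e-4)


@pytest.fixture(scope="module")
def grown_tree():
    domain = RetinalDomain()
    stage = StageConfig(N_terms=10, delta=0.8, theta_min=60.0, gamma=3.0,
                        region="full")
    return grow_tree(np.array([[-4.5, 0.3], [-2.0, 2.0], [2.0, 4.0]]), domain,
                     stage, 5e-4, 26.0, np.random.default_rng(4), side=1)


def test_grown_tree_terminal_count(grown_tree):
    assert grown_tree.n_terminals == 10


def test_bifurcation_constraints_audited_at_creation(grown_tree):
    assert len(grown_tree.audit) == 10
    for rec in grown_tree.audit:
        assert min(rec.r1, rec.r2) / max(rec.r1, rec.r2) > rec.delta
        assert rec.theta_deg > rec.theta_min


def test_murray_residuals_machine_precision(grown_tree):
    res = grown_tree.murray_residuals()
    assert len(res) > 0
    assert res.max() < 1e-6


def test_tree_stays_on_its_side_and_outside_faz(grown_tree):
    pos = grown_tree.pos
    assert np.all(pos[:, 1] > 0)
    a = pos[grown_tree.seg_a]
    b = pos[grown_tree.seg_b]
    ab = b - a
    t = np.clip(-(a * ab).sum(1) / np.maximum((ab * ab).sum(1), 1e-18), 0, 1)
    proj = a + t[:, None] * ab
    assert np.all(np.hypot(*proj.T) > 0.25)


def test_growth_deterministic_given_seed():
    domain = RetinalDomain()
    stage = StageConfig(N_terms=8, region="full")
    trees = [grow_tree(np.array([[-4.5, 0.3], [0.0, 3.0]]), domain, stage,
                       5e-4, 26.0, np.random.default_rng(9), side=1)
             for _ in range(2)]
    assert np.array_equal(trees[0].pos, trees[1].pos)
    assert np.array_equal(trees[0].radii_um(), trees[1].radii_um())


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(r1=st.floats(0.1, 100.0), r2=st.floats(0.1, 100.0),
           g=st.floats(0.5, 4.0))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_parent_radius_properties(r1, r2, g):
        """Murray parent dominates both daughters, is symmetric, and satisfies
        the law identically."""
        rp = parent_radius(r1, r2, g)
        assert rp >= max(r1, r2)
        assert rp == pytest.approx(parent_radius(r2, r1, g))
        assert rp ** g == pytest.approx(r1 ** g + r2 ** g, rel=1e-9)

    @given(nu=st.floats(0.0, 5.0), area=st.floats(1e-3, 1e4),
           n=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_min_separation_monotone(nu, area, n):
        """l_min shrinks with terminal count and grows with area."""
        l = min_separation(nu, area, n)
        assert l >= min_separation(nu, area, n + 1)
        assert l <= min_separation(nu, 2 * area, n)
except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass


def test_cra_flow_from_radius_and_velocity():
    assert cra_flow_uL_min(81.0, 6.3) == pytest.approx(77.9, abs=0.1)


def test_macrovasculature_structure(tiny_individual, tiny_config):
    """Assembled network: 4 trees worth of terminals, no raphe crossing,
    creation-time constraint audit clean."""
    net = tiny_individual.network
    audit = net.metadata["cco_audit"]
    total = sum(st.N_terms for st in tiny_config.stages)
    assert audit["n_bifurcations"] == total
    assert audit["max_murray_residual"] < 1e-6
    assert audit["min_angle_deg"] > 60.0
    macro = net.seg_kind_mask("artery") | net.seg_kind_mask("vein")
    y = net.xyz[:, 1]
    conn = net.conn[macro]
    crossing = (y[conn[:, 0]] * y[conn[:, 1]]) < -1e-12
    # only the two root stubs join the disc on the raphe itself
    assert crossing.sum() == 0
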