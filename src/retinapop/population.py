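"""Virtual cohorts: population sampling, the per-individual pipeline, and
structure–function correlation analysis.

Each virtual individual is defined by four clinical parameters drawn from
independent normal distributions (CRA radius and velocity, mean arterial
pressure, intraocular pressure; individuals with non-positive ocular
perfusion pressure are resampled). The pipeline then samples an arcade
quartet from the shape model, grows the macrovasculature by staged CCO,
builds and wires the three capillary plexuses, solves the network
hemodynamics at the individual's OPP, and computes the OCTA-style
morphometrics. Associations between morphology and perfusion are quantified
as Spearman rank correlations with percentile-bootstrap confidence
intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .arcades import ShapeModel, fit_shape_model, generate_arcade_fixture, sample_arcades
from .cco import grow_macrovasculature
from .config import RunConfig, default_config
from .hemodynamics import HemodynamicsSolution, ocular_pressures, solve_flow
from .morphometrics import MorphometricsReport, compute_morphometrics
from .network import VascularNetwork
from .plexus import (assign_and_smooth_diameters, build_voronoi_bed,
                     connect_network, orient_capillary_flow,
                     prune_capillaries_near_macro, prune_dead_end_capillaries)

__all__ = [
    "PopulationParams", "sample_population", "build_shape_model",
    "generate_individual", "run_cohort", "CohortResults",
    "spearman_bootstrap", "correlation_table",
]

log = logging.getLogger(__name__)

_N_FIXTURE_EYES = 8  # training-set size emulating the segmented fundus photographs


@dataclass
class PopulationParams:
    """Clinical parameters of one virtual individual."""

    r_CRA: float   # µm
    v_CRA: float   # cm/s
    MAP: float     # mmHg
    IOP: float     # mmHg

    @property
    def OPP(self) -> float:
        return 2.0 / 3.0 * self.MAP - self.IOP


def sample_population(n: int, rng: np.random.Generator,
                      config: RunConfig | None = None) -> list[PopulationParams]:
    """Independent normal draws of the population parameters; individuals with
    OPP <= 0 (or non-positive radius/velocity) are resampled."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pop = (config or default_config()).population
    out: list[PopulationParams] = []
    while len(out) < n:
        p = PopulationParams(
            r_CRA=rng.normal(pop.r_CRA_mean, pop.r_CRA_sd),
            v_CRA=rng.normal(pop.v_CRA_mean, pop.v_CRA_sd),
            MAP=rng.normal(pop.MAP_mean, pop.MAP_sd),
            IOP=rng.normal(pop.IOP_mean, pop.IOP_sd))
        if p.OPP > 0 and p.r_CRA > 0 and p.v_CRA > 0 and p.IOP > 0:
            out.append(p)
    return out


def build_shape_model(config: RunConfig, rng: np.random.Generator) -> ShapeModel:
    """Fit the arcade shape model on the synthetic landmark fixture."""
    fixture = generate_arcade_fixture(rng, _N_FIXTURE_EYES,
                                      n_landmarks=config.n_landmarks)
    return fit_shape_model(fixture, n_components=config.n_shape_modes)


@dataclass
class Individual:
    """One completed virtual-individual run."""

    params: PopulationParams
    network: VascularNetwork
    solution: HemodynamicsSolution
    morphometrics: MorphometricsReport
    seed: int


def generate_network(params: PopulationParams, config: RunConfig,
                     rng: np.random.Generator,
                     shape_model: ShapeModel | None = None) -> VascularNetwork:
    """Arcades -> staged CCO macrovasculature -> capillary plexuses -> one
    connected, flow-oriented network."""
    model = shape_model or build_shape_model(config, rng)
    arcades = sample_arcades(model, rng, clamp_sd=config.clamp_sd)
    macro = grow_macrovasculature(arcades, params, config, rng)

    domain = config.domain
    beds = {}
    for name in ("SVP", "ICP", "DCP"):
        pc = config.plexi[name]
        beds[name] = build_voronoi_bed(pc.N_seeds, domain.r_perifovea,
                                       domain.r_FAZ, rng, z_um=pc.z_um,
                                       plexus=name)
    # SVP pruning against macular arterioles/venules (dilated-lumen test)
    macro_seg = np.flatnonzero(macro.seg_kind_mask("artery")
                               | macro.seg_kind_mask("vein"))
    mids = macro.midpoints()[macro_seg]
    near = (mids[:, :2] ** 2).sum(axis=1) <= (domain.r_perifovea + 1.0) ** 2
    sel = macro_seg[near]
    beds["SVP"] = prune_capillaries_near_macro(
        beds["SVP"], macro.xyz[macro.conn[sel, 0], :2],
        macro.xyz[macro.conn[sel, 1], :2], macro.radius_um[sel] * 1e-3)

    net = connect_network(macro, beds, config.alpha, config.frac_deep, rng, config)
    net = prune_dead_end_capillaries(net)
    net = orient_capillary_flow(net)
    # smoothing last: parent/daughter adjacency follows the flow orientation
    net = assign_and_smooth_diameters(net, config.plexi["SVP"].r_capillary)
    return net


def generate_individual(params: PopulationParams, config: RunConfig, seed: int,
                        shape_model: ShapeModel | None = None) -> Individual:
    """Run the full pipeline for one individual, deterministically in
    (config, seed)."""
    rng = np.random.default_rng(seed)
    net = generate_network(params, config, rng, shape_model)
    net.metadata["seed"] = int(seed)
    p_cra, p_crv, _ = ocular_pressures(params.MAP, params.IOP)
    sol = solve_flow(net, p_cra, p_crv, config.hemo,
                     r_perifovea=config.domain.r_perifovea)
    report = compute_morphometrics(net)
    return Individual(params=params, network=net, solution=sol,
                      morphometrics=report, seed=seed)


@dataclass
class CohortResults:
    """Per-individual records and cohort summaries."""

    table: pd.DataFrame
    n_failed: int = 0
    failures: list = field(default_factory=list)
    individuals: list = field(default_factory=list)  # kept only when requested

    def summary(self) -> pd.DataFrame:
        num = self.table.select_dtypes(float)
        return pd.DataFrame({"mean": num.mean(), "sd": num.std(),
                             "min": num.min(), "max": num.max()})


def run_cohort(params_list: list[PopulationParams], config: RunConfig,
               seed: int = 0, keep_individuals: bool = False,
               shape_model: ShapeModel | None = None) -> CohortResults:
    """Simulate a cohort; individual failures are logged and skipped.

    Each individual runs on its own RNG stream derived from ``seed``; the
    arcade shape model is fitted once for the whole cohort.
    """
    master = np.random.default_rng(seed)
    model = shape_model or build_shape_model(config, master)
    child_seeds = master.integers(0, 2 ** 31 - 1, size=len(params_list))
    rows = []
    failures = []
    individuals = []
    for i, (params, s) in enumerate(zip(params_list, child_seeds)):
        try:
            ind = generate_individual(params, config, int(s), shape_model=model)
        except Exception as exc:
            log.warning("individual %d (seed %d) failed: %s", i, s, exc)
            failures.append((i, int(s), str(exc)))
            continue
        row = {
            "individual": i, "seed": int(s),
            "r_CRA": params.r_CRA, "v_CRA": params.v_CRA,
            "MAP": params.MAP, "IOP": params.IOP, "OPP": params.OPP,
            "retinal_blood_flow": ind.solution.retinal_blood_flow,
            "macular_flow_fraction": ind.solution.macular_flow_fraction,
            "v_CRA_model": ind.solution.v_CRA,
        }
        row.update(ind.morphometrics.flat())
        # order-5 arteriole:venule ratio when present
        t = ind.morphometrics.strahler
        r5 = t.loc[t["order"] == 5, "ratio"]
        row["av_ratio_order5"] = float(r5.iloc[0]) if len(r5) else np.nan
        rows.append(row)
        if keep_individuals:
            individuals.append(ind)
    table = pd.DataFrame(rows)
    return CohortResults(table=table, n_failed=len(failures), failures=failures,
                         individuals=individuals)


# ----------------------------------------------------------------------
# Correlation analysis
# ----------------------------------------------------------------------

def spearman_bootstrap(x, y, n_boot: int = 1000,
                       rng: np.random.Generator | None = None
                       ) -> tuple[float, tuple[float, float]]:
    """Spearman rank correlation with a percentile-bootstrap 95% CI
    (resampling individuals in pairs)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.warning("constant input: Spearman correlation undefined")
        return float("nan"), (float("nan"), float("nan"))
    rng = rng or np.random.default_rng()
    rho = float(stats.spearmanr(x, y).statistic)
    n = len(x)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        with np.errstate(invalid="ignore"):
            boots[i] = stats.spearmanr(x[idx], y[idx]).statistic
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return rho, (float(lo), float(hi))


#: morphology columns correlated against the hemodynamic outputs
CORRELATION_METRICS = [
    "VAD_SVP", "VSD_SVP", "VDI_SVP", "VCI_SVP", "FD_SVP", "IVD_SVP",
    "VAD_ICP", "FD_ICP", "VAD_DCP", "FD_DCP", "VAD_ICP_DCP", "FD_ICP_DCP",
]


def correlation_table(cohort: CohortResults, n_boot: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """Spearman correlations of each morphological metric against retinal
    blood flow and macular flow fraction, with bootstrap CIs and a strength
    class (weak < 0.25 <= moderate < 0.5 <= strong)."""
    t = cohort.table
    if len(t) < 10:
        raise ValueError("need a cohort of at least 10 individuals")
    rng = np.random.default_rng(seed)
    rows = []
    for metric in CORRELATION_METRICS:
        if metric not in t.columns:
            continue
        for target in ("retinal_blood_flow", "macular_flow_fraction"):
            rho, (lo, hi) = spearman_bootstrap(t[metric], t[target],
                                               n_boot=n_boot, rng=rng)
            strength = ("weak" if abs(rho) < 0.25
                        else "moderate" if abs(rho) < 0.5 else "strong")
            rows.append({"metric": metric, "target": target, "rho": rho,
                         "ci_lo": lo, "ci_hi": hi, "strength": strength})
    return pd.DataFrame(rows)
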