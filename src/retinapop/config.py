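"""Configuration objects for virtual retinal vasculature generation.

All tunable quantities of the pipeline live here, grouped the way they act:

* :class:`PopulationDistributions` -- the four clinical parameters that vary
  across virtual individuals (CRA radius and velocity, MAP, IOP).
* :class:`StageConfig` -- hyperparameters of one stage of the staged CCO
  (constrained constructive optimization) growth of arterial/venous trees.
* :class:`PlexusConfig` -- capillary-bed hyperparameters per vascular layer
  (SVP / ICP / DCP).
* :class:`HemoConfig` -- parameters of the Poiseuille network flow model.
* :class:`RetinalDomain` -- geometry of the modelled region (fovea at origin,
  left-eye orientation, optic disc on the nasal/negative-x side).

Defaults reproduce the baseline healthy-eye parameter set; every field can be
overridden programmatically or through a YAML file (see :func:`load_config`).
Units are stated per field: x/y/z coordinates and lengths in mm unless noted,
radii in µm, pressures in mmHg, viscosities in cP.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "PopulationDistributions",
    "StageConfig",
    "PlexusConfig",
    "HemoConfig",
    "RetinalDomain",
    "RunConfig",
    "default_config",
    "reduced_config",
    "load_config",
    "save_config",
]


@dataclass
class PopulationDistributions:
    """Normal distributions of the per-individual clinical parameters."""

    r_CRA_mean: float = 81.0     # central retinal artery radius, µm
    r_CRA_sd: float = 8.0
    v_CRA_mean: float = 6.3      # CRA blood velocity, cm/s
    v_CRA_sd: float = 1.2
    MAP_mean: float = 84.0       # mean arterial pressure, mmHg
    MAP_sd: float = 6.0
    IOP_mean: float = 11.1       # intraocular pressure, mmHg
    IOP_sd: float = 2.1


@dataclass
class StageConfig:
    """One stage of the staged CCO growth.

    ``region`` selects where terminal sites may fall: ``"full"`` (disk of
    radius r_retina), ``"annulus"`` ([r_parafovea, r_perifovea]) or
    ``"parafovea"`` (disk of radius r_parafovea). The foveal avascular zone is
    always excluded.
    """

    N_terms: int = 200               # terminal vessels added in this stage (per tree)
    p_precapillary: float = 30.0     # target pressure at terminal vessels, mmHg
    delta: float = 0.8               # radius-symmetry floor min(r1,r2)/max(r1,r2) > delta
    theta_min: float = 60.0          # minimum bifurcation angle, degrees
    gamma: float = 3.0               # Murray exponent r_p^g = r_1^g + r_2^g
    eta: float = 0.36                # starting viscosity of the fixed-point iteration, cP
    l_fr: float = 0.8                # l_min reduction factor after 20 consecutive rejections
    nu: float = 1.0                  # perfusion-area factor of the min-separation rule
    f_n: float = 1.0                 # neighborhood factor for candidate host search
    lognormal_sigma: float = 4.0     # terminal-site radial law r = r0 + exp(mu + sigma*Z)
    lognormal_mu: float = -0.5
    lognormal_r0: float = 0.02       # mm
    region: str = "full"

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta < 1.0):
            raise ValueError(f"delta must be in [0, 1), got {self.delta}")
        if not (0.0 <= self.theta_min < 90.0):
            raise ValueError(f"theta_min must be in [0, 90) deg, got {self.theta_min}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not (0.0 < self.l_fr < 1.0):
            raise ValueError(f"l_fr must be in (0, 1), got {self.l_fr}")


@dataclass
class PlexusConfig:
    """Capillary-bed hyperparameters for one plexus."""

    N_seeds: int = 5500          # seed points of the Delaunay/Voronoi construction
    r_capillary: float = 2.5     # capillary radius, µm
    z_um: float = 0.0            # plexus depth, µm

    def __post_init__(self) -> None:
        if self.N_seeds < 4:
            raise ValueError("N_seeds must be >= 4")


@dataclass
class HemoConfig:
    """Parameters of the network flow model."""

    R_compartment: float = 1e6   # artificial terminal resistance, mmHg*s/mL
    H_D: float = 0.45            # discharge hematocrit
    mu_plasma: float = 1.0       # plasma viscosity scaling of the relative-viscosity law, cP

    def __post_init__(self) -> None:
        if self.R_compartment <= 0:
            raise ValueError("R_compartment must be > 0")
        if not (0.0 < self.H_D < 1.0):
            raise ValueError("H_D must be in (0, 1)")


@dataclass
class RetinalDomain:
    """Geometry of the modelled retina (mm, fovea at the origin)."""

    r_retina: float = 15.0
    r_perifovea: float = 3.0
    r_parafovea: float = 1.5
    r_FAZ: float = 0.25
    disc_center_x: float = -4.5  # optic disc on the nasal side of a left eye
    disc_center_y: float = 0.0

    def __post_init__(self) -> None:
        if not (self.r_FAZ < self.r_parafovea < self.r_perifovea < self.r_retina):
            raise ValueError("require r_FAZ < r_parafovea < r_perifovea < r_retina")


@dataclass
class RunConfig:
    """Complete configuration of one virtual-individual pipeline run."""

    population: PopulationDistributions = field(default_factory=PopulationDistributions)
    domain: RetinalDomain = field(default_factory=RetinalDomain)
    stages: list[StageConfig] = field(default_factory=lambda: _default_stages())
    plexi: dict[str, PlexusConfig] = field(default_factory=lambda: _default_plexi())
    hemo: HemoConfig = field(default_factory=HemoConfig)
    alpha: float = 0.4           # fraction of macular arterioles/venules wired to the SVP bed
    frac_deep: float = 0.3       # fraction of macular arterioles/venules descending to ICP/DCP
    stage_terms_shared: bool = True  # N_terms counts terminals over the whole retina
                                     # (split across the 4 trees) rather than per tree
    radius_anchor: str = "root"  # "root": tree scale anchored to the central
                                 # retinal vessel radii (arcades inherit the CRA/CRV
                                 # caliber via Murray's law at the disc);
                                 # "pressure_drop": scale from the stage Δp target
    crv_cra_radius_ratio: float = 1.11
    cra_length_mm: float = 1.0   # root stub length of the CRA/CRV
    n_landmarks: int = 20        # landmarks per arcade curve in the shape model
    n_shape_modes: int = 5       # PCA modes retained by the shape model
    clamp_sd: float = 3.0        # shape-coefficient clamp, in SDs
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if not (0.0 <= self.frac_deep <= 1.0):
            raise ValueError("frac_deep must be in [0, 1]")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "population" in d:
            d["population"] = PopulationDistributions(**d["population"])
        if "domain" in d:
            d["domain"] = RetinalDomain(**d["domain"])
        if "stages" in d:
            d["stages"] = [StageConfig(**s) for s in d["stages"]]
        if "plexi" in d:
            d["plexi"] = {k: PlexusConfig(**v) for k, v in d["plexi"].items()}
        if "hemo" in d:
            d["hemo"] = HemoConfig(**d["hemo"])
        return cls(**d)


def _default_stages() -> list[StageConfig]:
    # Stage 1: whole temporal disk; stage 2: perifoveal annulus; stage 3: parafoveal disk.
    return [
        StageConfig(N_terms=200, p_precapillary=30.0, delta=0.8, gamma=3.0,
                    l_fr=0.8, region="full"),
        StageConfig(N_terms=150, p_precapillary=23.0, delta=0.0, gamma=2.85,
                    l_fr=0.5, region="annulus"),
        StageConfig(N_terms=75, p_precapillary=23.0, delta=0.0, gamma=2.85,
                    l_fr=0.5, region="parafovea"),
    ]


def _default_plexi() -> dict[str, PlexusConfig]:
    return {
        "SVP": PlexusConfig(N_seeds=5500, r_capillary=2.5, z_um=0.0),
        "ICP": PlexusConfig(N_seeds=16000, r_capillary=2.5, z_um=135.0),
        "DCP": PlexusConfig(N_seeds=10500, r_capillary=2.5, z_um=180.0),
    }


def default_config(seed: int = 0) -> RunConfig:
    """Baseline healthy-eye configuration."""
    return RunConfig(seed=seed)


def reduced_config(seed: int = 0, terms_scale: float = 1.0,
                   seeds_scale: float = 0.5) -> RunConfig:
    """Baseline configuration with capillary seed counts (and optionally tree
    terminal counts) scaled down for faster cohort studies.

    ``seeds_scale=0.5`` halves N_seeds in every plexus while keeping the tree
    hyperparameters at their defaults.
    """
    cfg = default_config(seed=seed)
    for st in cfg.stages:
        st.N_terms = max(1, int(round(st.N_terms * terms_scale)))
    for p in cfg.plexi.values():
        p.N_seeds = max(4, int(round(p.N_seeds * seeds_scale)))
    return cfg


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))
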