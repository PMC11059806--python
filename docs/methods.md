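# Methods

`retinapop` generates virtual populations of the human retinal vasculature —
from the central retinal artery (CRA) and vein (CRV) through the temporal
arcades and arteriolar/venular trees down to the three macular capillary
plexuses — and solves steady Poiseuille hemodynamics on the resulting
network. This note documents the models, their assumptions, the tunable
parameters, and the numerical choices.

## Coordinate frame and units

The fovea is at the origin, left-eye orientation (optic disc nasal, at
x ≈ −4.5 mm); right-eye inputs are reflected across the y-axis first. x/y/z
are stored in mm (z is the plexus depth: 0, 0.135, 0.180 mm for SVP, ICP,
DCP), radii in µm, pressures in mmHg, flows in µL/min, viscosity in cP.
Conversions to SI happen only inside the hemodynamics module.

## Arcade shape model

The four major temporal arcades (superior/inferior × arterial/venous) are
described by a PCA statistical shape model over fixed-count, arc-length
resampled landmark curves (default 20 landmarks per curve; inflexion-point
landmarks are ill-posed on synthetic curves, so equal-arc-length resampling
is used, and the landmark rule is configurable). Sampling draws component
coefficients from zero-mean normals with the fitted variances, clamped at
±3 SD.

Training curves are normally manual segmentations of fundus photographs.
The packaged stand-in, `generate_arcade_fixture`, is synthetic: noisy
parabolic arms rooted at the disc, veins arching slightly more than
arteries, superior/inferior arms clamped to their side of the raphe. It is
synthesized in field-of-view degrees and converted with the fundus rule of
thumb 10° ≈ 5 mm. The fixture reproduces the geometry class (origin,
orientation, scale, inter-eye variability) but *not* the empirical shape
statistics of any real dataset; results that depend on fine arcade shape
should be re-derived with real segmentations.

## Staged CCO growth

Arterial and venous trees grow from the arcades by constrained constructive
optimization in three stages: the full temporal disk (radius 15 mm), the
perifoveal annulus (1.5–3 mm), and the parafoveal disk (≤1.5 mm), with
per-stage terminal counts 200/150/75. The stage counts are interpreted as
totals over the whole retina and split evenly across the four trees
(`RunConfig.stage_terms_shared`; a per-tree reading is available but
produces a macrovasculature several-fold too conductive relative to the
reported physiology).

Terminal sites are drawn with a fovea-biased radial law
r = r₀ + exp(µ + σZ) (defaults σ=4, µ=−0.5, r₀=0.02 mm), uniform angle,
rejection-resampled into the stage region, outside the 0.25 mm foveal
avascular zone, and on the growing tree's side of the raphe. A site is
rejected when closer than l_min = √(ν·A/(π(N+1))) to the existing tree
(distance to segments); after 20 consecutive rejections — including sites
with no admissible connection — l_min shrinks by the factor l_fr.

Each accepted site is connected at the volume-minimizing admissible
bifurcation: the candidate hosts are the nearest segments within
f_n·√A (capped at 20 for tractability), the bifurcation point is searched on
a coarse grid over the triangle spanned by the host and the site with one
local refinement, and the cost is the volume proxy
rel_r²·(|aM|+|Mb|) + |Mx|. Admissibility enforces the branching-angle floor
θ > θ_min, the radius-symmetry floor min(r₁,r₂)/max(r₁,r₂) > δ (evaluated
with the radii in force at creation time; a post-hoc audit is recorded per
bifurcation), segment-length floors (0.01 mm) and FAZ clearance.

Radii obey Murray's law exactly: leaves carry relative radius 1; parents
accumulate r_p^γ = Σ r_c^γ with the γ of the stage in which the bifurcation
was created (3, 2.85, 2.85). Because Murray ratios are scale-invariant, the
absolute scale is a single number per tree:

* During growth and in `grow_tree`, the scale is set by fixed-point
  iteration (viscosity recomputed from diameters, starting at η = 0.36 cP,
  relative tolerance 1e-6) so the *mean* root-to-terminal pressure drop at
  equal terminal flows Q_root/N equals the stage target
  (p_CRA − p_precapillary arterial, p_precapillary − p_CRV venous, with
  p_CRA = ⅔·MAP and p_CRV = IOP). Retargeting once at stage end is exactly
  equivalent to continuous retargeting.
* In the assembled macrovasculature the default anchors each tree's scale to
  the central retinal vessels instead (`radius_anchor="root"`): the arcade
  root is a Murray daughter of the CRA (or CRV, radius 1.11 × CRA), i.e.
  r_central·2^(−1/γ). This follows the anatomical statement that arcades
  inherit the central-vessel caliber and is what reproduces the reported
  arteriole:venule diameter ratios (≈0.91 vs ≈0.78 under pure
  pressure-drop sizing). The pressure-drop anchor remains available.

CRA flow is v_CRA·π·r_CRA², split equally between the two arcades of each
side (configurable only in code; the split is unstated in the source
physiology and equal division is the symmetric default).

## Capillary plexuses

Each plexus is the edge set of a Voronoi diagram built from the centroids of
a Delaunay triangulation of N_seeds uniform points in the 3 mm-radius
macular disk (defaults 5500/16000/10500 for SVP/ICP/DCP; cohort studies at
`reduced_config` halve these). Edges leaving the disk or entering the FAZ
are removed and the largest connected component is kept. In the SVP,
capillary edges intersecting the dilated lumen (stadium of the segment
radius) of any arteriole/venule are pruned, producing the capillary-free
sleeves around SVP arterioles; the intersection test against centerlines
only is a configurable alternative.

Wiring: every macular terminal vessel, and a fraction α = 0.4 of macular
arteriole/venule segments per kind (sampled uniformly without replacement),
connect to the nearest vertex of the SVP bed's main component. A fraction
frac_deep = 0.3 per kind bifurcates at the segment midpoint to the nearest
ICP vertex, and that branch immediately continues to the nearest DCP vertex;
descenders take the 3-D distance between plexus depths. There are no lateral
ICP/DCP connections outside the macula. Extramacular terminals close through
a single compartment node via artificial segments of fixed resistance
R = 1e6 mmHg·s/mL each (one per terminal).

Cleanup removes dead-end capillary chains and capillary components lacking
either an arterial or a venous attachment (they carry no flow and would make
the pressure system singular).

Flow orientation solves the discrete Laplace problem on the capillary
subgraph (unweighted graph Laplacian, arterial attachment nodes clamped at
1, venous at 0, direct sparse solve rather than explicit relaxation — the
same fixed point), breaks exact ties by a 1e-12·node-index perturbation, and
directs each capillary from high to low potential; acyclicity follows
because potentials strictly decrease along every directed edge and is
asserted.

Diameters: capillaries get radius 2.5 µm, doubled where they touch an
arteriole/venule; one smoothing pass then sets each capillary's diameter to
the mean of its own, its parent's and its daughters' pre-pass diameters.
Parent/daughter adjacency is directional (sibling branches at the same node
are not averaged in), which is why orientation runs before smoothing.
Macro-tree radii are not smoothed — their Murray structure is the growth
model's contract.

## Hemodynamics

Blood is incompressible with a per-segment effective viscosity from the
in-vivo diameter/hematocrit law (discharge hematocrit fixed at 0.45;
µ_plasma scaling default 1.0 cP, configurable), so the network is a linear
resistor system: R = 8µl/(πr⁴) per segment (fixed R for artificial
segments), one sparse SPD solve with Dirichlet pressures p_CRA and p_CRV at
the root stubs (CRA stub length 1 mm at the sampled CRA radius; CRV radius
1.11×). Retinal blood flow is the CRA flow; CRA velocity is Q/(πr²).

The macular flow fraction is the **net** arterial inflow across the
perifoveal circle (inward minus outward arterial crossings, as a percentage
of retinal blood flow): arterioles that traverse the disk en route to
extramacular terminals do not count. Because hematocrit is constant the
system is linear, so total flow is exactly proportional to OPP at fixed
geometry and the macular flow fraction is exactly OPP-invariant.

## Morphometrics

Inside the 3 mm-diameter analysis disk (partial segments contribute their
clipped length): L = Σlᵢ, A = Σ2rᵢlᵢ, VAD = A/X, VSD = L/X, VDI = A/L,
VCI = (2L)²/(4πA) (perimeter read as ≈2L; the exponent placement is
configurable in code). Rasterization uses 10 µm pixels; the skeleton is the
1-px centerline, the mask a stadium per segment (segments thinner than a
pixel render as their centerline). FD is the box-counting slope over box
sizes that divide the image side exactly (dyadic fallback), which avoids
padding bias and recovers the known dimensions of a line (1.0), a filled
square (2.0) and a Sierpinski carpet (1.893) to machine precision on exact
grids. FD is evaluated on the full-width vessel mask, the OCTA convention —
a 1-px skeleton is radius-blind, which would decouple FD from every
caliber-driven quantity including flow. IVD is reported as twice the mean
Euclidean distance transform of the skeleton background inside the disk — a
decided normalization; comparisons should be relative.

Horton–Strahler orders: capillaries are order 0; processing from the
capillary-facing tips toward the roots, a vessel keeps the largest branch
order unless two or more branches share it (then +1). A macro segment whose
branches are exclusively capillaries is order 1 — order 0 is the capillary
class — and bare compartment-closed tips stay 0. Diameter-by-order tables
and arteriole:venule ratios are restricted to macular vessels (midpoint
within 3 mm of the fovea).

## Population, sensitivity, uncertainty

Cohorts draw r_CRA, v_CRA, MAP, IOP from independent normals
(81±8 µm, 6.3±1.2 cm/s, 84±6 mmHg, 11.1±2.1 mmHg), resampling non-positive
OPP; v_CRA enters only the growth-stage CRA flow, not the pressure-driven
solve. Each individual runs on its own RNG stream derived from the cohort
seed; failures are logged and skipped. Structure–function associations are
Spearman correlations with percentile-bootstrap CIs (N = 1000, resampling
individuals).

Sobol analysis hand-implements the Saltelli design on a scrambled Sobol'
sequence (N(k+2) runs), the Saltelli-2010 first-order and Jansen total-order
estimators, bootstrap CIs, and a nested-prefix convergence trace; the
estimators are validated against the Ishigami closed forms. The printed
hyperparameter ranges are shipped verbatim (`TABLE_RANGES_PRINTED`) but two
columns are inconsistent with their baselines (γ range [0.2, 0.5] vs
baseline 2.85; ν [2, 3] vs 1); studies default to `TABLE_RANGES_PLAUSIBLE`
(γ → [2, 3], ν → [0.2, 0.5]) because a Murray exponent of 0.3 produces
divergent parent radii. One structural realization per parameter vector,
structural seed fixed across vectors so the measured variance reflects the
hyperparameters. Sensitivity runs build the SVP only (token deeper beds, no
flow solve).

The UQ grid crosses R ∈ {5e5, 1e6, 5e6} mmHg·s/mL, OPP at 80/100/120% of
each individual's baseline, and α ∈ {0.2, …, 0.6} (45 scenarios). Geometry
is generated once per individual; α changes rewire the SVP; R/OPP changes
are linear re-solves. Per (R, α) stratum the Pearson r² between the OPP
level and the cohort-mean output is reported across the three OPP scalings
(r² = 1 for total flow and 0 for the macular fraction, exactly, by
linearity).

## Problem sizes used in the shipped studies

Cohort statistics use 50–100 individuals with capillary seed counts at 50%
of the defaults (`reduced_config`); the UQ diagnostics use 10 individuals.
These sizes give cohort-mean standard errors well inside the quoted
tolerance bands (per-individual SDs: RBF ≈ 4–9 µL/min, ratio ≈ 0.03). The
sensitivity demonstration runs at small N_base; converged indices need
thousands of runs as in the full study.

## Known limitations

No peripapillary plexus, retinal curvature, oxygen transport,
autoregulation, plasma skimming or variable hematocrit; plexuses are planar;
interplexus wiring follows a single pattern; the population parameters are
sampled independently although they are physiologically correlated; the
synthetic arcade fixture carries no real-eye shape statistics; the
compartment resistance R is a modeling closure, not a measured quantity.

One structural coupling is worth flagging: in generated cohorts the macular
flow fraction anticorrelates with the SVP area-type metrics (ρ ≈ −0.6).
A thick trunk crossing the analysis disk inflates VAD (A = Σ2rᵢlᵢ is
caliber-dominated) and at the same time marks a well-perfused temporal
periphery, which raises total flow at roughly constant macular uptake and
so lowers the macular share. The effect is insensitive to the pruning rule
and to the inflow accounting; treat MFF-vs-morphology associations from
this generator with that in mind.
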