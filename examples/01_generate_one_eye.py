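"""Generate one virtual eye and report its perfusion.

Builds a complete vascular network for a single virtual individual — arcades
sampled from the shape model, arterial/venous trees grown by staged CCO,
three Voronoi capillary plexuses wired in — solves the Poiseuille network
hemodynamics at the individual's ocular perfusion pressure, and prints the
headline perfusion numbers.

Run:  python examples/01_generate_one_eye.py
"""

import numpy as np

from retinapop import reduced_config
from retinapop.population import generate_individual, sample_population

cfg = reduced_config(seed=1)  # capillary beds at half seed count (faster)
rng = np.random.default_rng(1)
params = sample_population(1, rng, cfg)[0]
print(f"individual: r_CRA={params.r_CRA:.1f} um, v_CRA={params.v_CRA:.2f} cm/s, "
      f"MAP={params.MAP:.1f} mmHg, IOP={params.IOP:.1f} mmHg, "
      f"OPP={params.OPP:.1f} mmHg")

ind = generate_individual(params, cfg, seed=1)
net, sol = ind.network, ind.solution
print(f"network: {net.n_nodes} nodes, {net.n_segments} segments")
# Retinal blood flow is the volumetric flow through the CRA; the macular flow
# fraction is the share of it perfusing the 3 mm-radius perifoveal disk.
print(f"retinal blood flow:    {sol.retinal_blood_flow:6.2f} uL/min")
print(f"macular flow fraction: {sol.macular_flow_fraction:6.2f} %")
print(f"CRA velocity:          {sol.v_CRA:6.2f} cm/s")
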