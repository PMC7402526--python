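"""Deconvolve per-cell-type drug mechanisms from a dose-response table.

Generates a noisy synthetic dose-response for a compound that only blocks
HSC proliferation (Emax_T = 0.8, EC50 = 50 nM), then refits the 26
drug-effect parameters.  Although every downstream readout drops with dose
(propagated loss of progenitors), the L1-regularized fit attributes the
effect to HSC alone — the deconvolution the model exists for.
"""

import math

from hemodecon import (
    DOSE_GRID_NM,
    DrugEffectParameters,
    DrugFitSettings,
    NoiseModel,
    default_initial_state,
    default_system_parameters,
    fit_drug,
)
from hemodecon.synthetic import generate_dose_response_dataset

sys_params = default_system_parameters()
initial = default_initial_state()

truth = DrugEffectParameters.inert()
truth.emax_total["HSC"] = 0.8
truth.log_ec50["HSC"] = math.log(50.0)

data = generate_dose_response_dataset(
    sys_params, truth, (0.0,) + DOSE_GRID_NM,
    NoiseModel(donor_count=4, cv=0.1, seed=0), initial,
    compound="hsc-blocker",
)
print("Observed normalized HSC and Neut readouts (note both fall with dose):")
print(data.table[["HSC", "Neut"]].round(3).to_string())

settings = DrugFitSettings(lam=0.1, max_generations=10, population_size=100,
                           seed=0)
result = fit_drug(data, sys_params, settings, initial)
p = result.parameters

print(f"\nFitted mechanism (objective {result.objective:.4f}):")
for ct, emax in p.emax_total.items():
    if emax > 0.05:
        print(f"  {ct}: Emax_T = {emax:.3f}, EC50 = {p.ec50[ct]:.1f} nM")
print("All other cell types fit to Emax_T ~ 0: the downstream losses are"
      " explained by propagation, not direct toxicity.")
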