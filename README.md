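# hemodecon

Quantitative systems pharmacology (QSP) modeling of an in vitro
multi-lineage hematopoietic toxicity assay, and deconvolution of
per-cell-type drug mechanisms from dose-response data.

## The problem

Drug-induced cytopenias (neutropenia, anemia, thrombocytopenia) arise from
toxicity anywhere along the hematopoietic differentiation tree.  A day-6
CD34+ differentiation assay measures 13 live cell types plus total dead
cells across a dose panel, but the observed suppression of any readout is
*cumulative*: a drug that only kills stem cells also depletes every
downstream lineage.  Curve-level IC50s therefore describe propagated loss,
not mechanism.  `hemodecon` fits an ODE model of the differentiation tree
to the assay and attributes the observed dose response to direct
per-cell-type effects, separating "this drug kills granulocytes" from
"granulocytes disappear because their progenitors stopped dividing."

It is aimed at preclinical modelers and toxicologists triaging compounds
for hematopoietic liability.

## The model

Thirteen cell types (HSC, MPP, GMP, granulocyte/monocyte progenitors and
mature forms, neutrophils with a quiescent sub-pool, two erythroid stages,
megakaryocytes, lymphoid progenitors, B cells) form a tree rooted at HSC.
Each dividing type C divides at rate κ_C; each daughter independently
renews (probability ρ_C) or differentiates, giving the net dynamics

    d[C]/dt = (2ρ_C − 1) κ_C [C] + influx,   outflow = 2(1 − ρ_C) κ_C [C]

with branch fractions β splitting outflow at the MPP and GMP branch
points (each summing to 1) and a uniform death rate δ for the most mature
type of each lineage.  The drug-free system has 27 free parameters
(13 κ + 7 ρ + 6 β + δ).

Drug effects per cell type use a single total Emax and EC50 (26 free
parameters per compound).  The anti-proliferative component scales the
division rate,

    κ_C = κ_C⁰ (1 − min(1, Emax_T,C) · [drug]/(EC50_C + [drug])),

and the excess above one drives a first-order cell-killing flux

    max(0, Emax_T,C − 1) · [drug]/(EC50_C + [drug]) · [C]

into the dead pool, so Emax_T ≤ 1 reads as pure anti-proliferation and
Emax_T > 1 as killing on top of it.  Drug parameters are fitted to the
vehicle-normalized day-6 table by a hybrid global/local optimizer
minimizing

    Σ_C ‖w_C (M_C^model − M_C^data)‖² + λ Σ_C |Emax_T,C|

with λ = 0.1 and the dead-cell readout double-weighted, which drives
near-zero effects to exactly zero and yields a parsimonious mechanism.

## Worked example

`examples/deconvolve_drug_effects.py` generates a noisy synthetic dose
response for a compound that only blocks HSC proliferation
(Emax_T = 0.8, EC50 = 50 nM) and refits the 26 drug parameters:

```
Observed normalized HSC and Neut readouts (note both fall with dose):
           HSC   Neut
dose_nM
0.0      1.038  1.012
0.2      1.009  1.029
1.0      1.062  0.982
5.0      0.714  0.899
25.0     0.403  0.643
100.0    0.133  0.498
500.0    0.066  0.416
2500.0   0.053  0.387

Fitted mechanism (objective 0.2958):
  HSC: Emax_T = 0.775, EC50 = 47.5 nM
```

Neutrophils lose over 60 % of their counts at high dose, yet the fit
assigns them Emax_T ≈ 0: their decline is fully explained by the loss of
upstream progenitors.  The recovered HSC parameters sit within a few
percent of the generating truth (the L1 penalty shrinks Emax slightly).

Other examples cover control-kinetics simulation, curve-level IC50 /
percent-inhibition analysis versus Emax_T expression matrices
(`ic50_vs_emax_expression.py`), cross-compound PCA
(`compare_compounds_pca.py`), and profile-likelihood identifiability
(`profile_identifiability.py`).  A thin CLI (`hemodecon simulate|fit-system|
fit-drug|ic50|pca|profile|synth`) wraps the same functions.

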