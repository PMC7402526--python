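# Methods

## Model structure

The model tracks 15 population species: 13 live cell-type readouts, the
derived total of viable cells, and a cumulative dead-cell pool.
Internally the state vector has 15 compartments — the 13 live types, a
quiescent neutrophil sub-pool, and the dead pool; the reported neutrophil
readout is the sum of the active and quiescent pools.  Drug concentration
is a constant forcing input (a day-0 bolus in a closed culture; no
pharmacokinetics), so the ODE system is linear and time-invariant at any
fixed dose.

Division bookkeeping: one division consumes the parent and produces two
daughters, each of which independently renews (probability ρ) or
differentiates (1 − ρ).  This yields the self term (2ρ − 1)κ[C] and a
differentiation outflow 2(1 − ρ)κ[C], split across children by the branch
fractions β at the MPP (4 children) and GMP (2 children) branch points.
Lymphoid progenitors are an exception: they appear to differentiate
without dividing in this culture, so they carry no renewal fraction and
convert to B cells as a first-order flux κ_LymP[LymP] without the factor
of two.  (A `lymp_doubling` switch restores division-based outflow for
sensitivity analyses.)  The most mature type of each lineage — late
erythroid, megakaryocyte, monocyte, neutrophil, B — dies at a uniform
rate δ; all other natural death rates are zero.

The quiescent neutrophil pool absorbs active neutrophils at a fixed
transfer rate (default 0.5/day).  It neither divides nor differentiates,
and we chose not to apply the natural death rate δ to it — quiescence is
modeled as an inert reservoir — though drug killing removes it at the
neutrophil killing rate.  The transfer rate is deliberately excluded from
the free parameters, preserving the canonical count of 27 system
parameters: 13 κ + 7 ρ + 6 β + 1 δ.

## Drug effects

Each compound is described by 13 total-Emax values and 13 logEC50 values
(natural log, EC50 in nM; bounds [−2.3, 8.5] bracket the 0.2–2500 nM dose
panel on both sides).  The decomposition Emax_AP = min(1, Emax_T),
Emax_CK = max(0, Emax_T − 1) encodes the assumption that a drug must fully
block proliferation before killing begins, halving the parameter count
relative to separate AP/CK pairs.  The conventional range for Emax_T is
[0, 2]; fitted reference values up to 2.762 exist, which is infeasible
under that bound, so the upper bound is configurable (default 3.0) and
values above 2 are surfaced in a warning rather than silently
reconciled.

## Numerics

Because the system is linear at constant dose, the default propagator is
the matrix exponential of the 15×15 rate matrix — exact up to `expm`
accuracy, with no tolerance tuning, and fast enough for
population-based fitting (a dose-response evaluation propagates all seven
doses with one batched `expm`).  An adaptive stiff integrator
(`solve_ivp`, LSODA/BDF, rtol 1e-8) remains available as a backend and
serves as an independent numerical cross-check in the tests.  States are
clipped at zero after propagation; the dynamics preserve non-negativity
analytically, so clipping only guards floating-point undershoot.

Branch fractions are optimized on the constrained simplex: candidates are
projected so each branch point sums to one with a 0.001 floor per edge
(floor assigned first, remaining mass distributed proportionally).

## Calibration

System calibration fits the 27 parameters plus 14 initial-condition
multipliers (bounded to [0.1, 1] × the measured day-0 counts; the
quiescent pool starts at 0) to the donor-mean kinetic table.  Only days
2–6 enter the objective: day-0 counts reflect post-thaw recovery and the
final measurement day follows replating.  Residuals are scaled by each
readout's mean observed level (config: `mean` | `raw` | `log`); unscaled
squares would let the most abundant lineages dominate.  The dead-cell
readout is included alongside the 13 live readouts.

Both calibrations use the same hybrid contract: bounded differential
evolution with an explicitly seeded initial population, followed by
bounded local refinement (trust-region least squares for the system fit;
L-BFGS-B for the drug fit, whose L1 term is linear and smooth because
Emax ≥ 0).  The drug fit injects the all-zero mechanism and a crude
per-readout guess (Emax from the maximal observed drop, EC50 from the
half-drop dose) into the population, and the returned fit is never worse
than an injected candidate — so a flat response table always fits to a
(near-)zero mechanism.  Every fit records its seed, bounds, and
per-generation trace and is deterministic given the seed.

Default optimizer budgets are 50 generations × 500 population for the
system fit and 30 × 300 for drug fits.  The shipped tests, examples, and
acceptance script use reduced budgets (10 × 100 with local polish) chosen
as the smallest configuration that reproduces noiseless self-generated
data essentially exactly; because every compartment is observed, the
renewal/division pair (κ, ρ) separates generically and the reduced fits
recover all 27 parameters, not just a subset.

Profile likelihood fixes one parameter across a grid and re-optimizes the
rest by warm-started local refinement walking along the grid.  A profile
whose span is below a configurable threshold (relative, default 1e-3)
flags practical non-identifiability; this threshold is a stand-in for a
formal confidence cutoff and is labeled as such wherever it is reported.
Profiling a branch fraction renormalizes its siblings around the fixed
value.

## Curve-level analysis

The traditional analysis fits, per readout, the one-parameter model
value = 1 − c/(c + IC50) (Hill slope 1, full asymptote range) and reports
percent inhibition 100·c/(c + IC50).  A readout whose minimum observed
value never falls below 0.5 in the tested range is reported as
undetermined (rendered as 0 % suppression in the inhibition matrix), and
curves rising above baseline are rejected with a monotonicity warning.
No 4-parameter logistic variant is offered; a free-slope option exists
behind a flag but is off by default.

## Cross-compound analysis

Compound × cell-type matrices (Emax_T, logEC50, or curve-level logIC50)
feed a mean-centered, unscaled PCA via full SVD — the values already share
a scale, and a standardized variant sits behind a flag.  Signs are fixed
so each loading vector's largest-magnitude entry is positive, making the
decomposition deterministic.  Undetermined IC50s require an explicit
per-run policy (error, impute at a stated value, or drop the compound),
recorded in the matrix metadata.  Loadings are annotated with
variable-to-score correlations (labeling threshold 0.1).

## Synthetic data

The generator emulates the assay's statistical structure: six-donor
kinetic replication and dose-response wells normalized per donor to the
mean of six virtual vehicle wells, then pooled by averaging (drug studies
typically used 2–7 donors; the generator default for dose response can be
set accordingly).  Noise is multiplicative lognormal with unit mean and a
coefficient of variation of 0.2 by default — a surrogate chosen because
counts are positive and errors scale with abundance; the real assay's
donor-to-donor variance structure is not published.  The generator does
not emulate flow-cytometry event statistics, plate-position effects,
thaw-related day-0 mortality, or correlated donor effects beyond a global
scale factor (which vehicle normalization cancels exactly).  Passing
recovery tests on this generator therefore demonstrates correctness of
the estimation machinery under the stated noise model, not performance on
real donor material.

The default drug-free parameter set and seeding state shipped with the
package are synthetic: plausible rates giving ~70-fold six-day expansion
with lineage-appropriate ordering (progenitors cycle faster than stem
cells; the erythroid branch dominates output).  They are the reference
configuration for the generator and the tests, not fitted values.

## Known limitations

- No cytokine feedback (G-CSF/EPO/TPO), no in vivo compartments, no
  pharmacokinetics, and no replating simulation.
- The Emax formulation assumes anti-proliferation saturates before
  killing; compounds that kill without proliferative block are forced
  into Emax_T > 1 territory.
- Dead-cell dynamics before day 0 (thaw mortality) are absorbed into the
  fitted initial condition rather than modeled.
- Identifiability claims from noiseless self-recovery are optimistic;
  with realistic noise and partial observation, (κ, ρ) pairs can become
  practically non-identifiable, which is exactly what the profile
  machinery is for.
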