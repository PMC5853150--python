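# amcarbon

Clearance kinetics of black carbon in airway macrophages: image
quantification, Bayesian hierarchical decay modelling, model comparison and
method-agreement statistics.

## The problem

The area of black (carbonaceous) inclusions inside airway macrophages
(AM BC, in μm²) retrieved by induced sputum is an *internal* biomarker of
long-term exposure to combustion-derived particulate air pollution: unlike
monitoring-station data it reflects what an individual actually inhaled.
Using it quantitatively requires knowing its kinetics — how fast carbon
load decays after a person moves from a highly polluted to a moderately
polluted environment, and how stable it is when exposure does not change.

`amcarbon` implements that analysis as a tested, reusable pipeline for
biostatisticians and exposure scientists working with longitudinal panel
designs of the form *g* groups × *n* subjects × up to 8 visits:

1. **Quantification** (`amcarbon.quantify`): per-cell black-carbon area from
   micrographs via automatic thresholding (Otsu or IsoData) inside per-cell
   masks, pixel→μm² calibration (e.g. 146 px = 10 μm at ×100), and
   per-slide summaries (median and 90th percentile over ≥25 cells).
2. **Kinetics** (`amcarbon.kinetics`): a Bayesian hierarchical
   single-exponential decay model

       y_ij ~ LogNormal(log R0_i − k_i · t_ij, σ_obs)
       log R0_i ~ N(log R0_g, σ_R),   k_i ~ N(k_g, σ_k)

   with per-group initial load R0_g (μm²) and decay constant k_g (day⁻¹),
   newcomer time origins at the arrival day (R0 extrapolated back across the
   enrollment latency) and resident curves anchored at their first
   measurement. The clearance half-life is ln(2)/k. Sampling uses a
   subject-marginalised ensemble MCMC (emcee) with exact conditional draws
   of the subject effects.
3. **Model selection** (`amcarbon.selection`): DIC (D̄ + pD) comparison of
   competing specifications (group effect, covariates) and posterior
   predictive checks of loess-smoothed group profiles.
4. **Agreement** (`amcarbon.agreement`): Bland–Altman limits of agreement on
   natural-log areas, Spearman rank correlation with confidence interval,
   and ICC(2,1) between two quantification methods.
5. **Synthetic data** (`amcarbon.synthetic`): a cohort generator emulating
   the panel design (3 groups × 15 subjects, 8 visits ≈ 42 days apart,
   newcomer latency, 85% induction success, right-skewed per-cell areas,
   dropout) and a synthetic micrograph generator with exact pixel-level
   ground truth, so the whole pipeline is testable without external data.

## Worked example

```python
from amcarbon import (GeneratorConfig, KineticModelSpec, MCMCConfig,
                      build_design, compute_dic, fit_hierarchical_model,
                      generate_cohort, posterior_predictive_check,
                      summarize_groups)

ds = generate_cohort(GeneratorConfig(seed=7))       # 45 subjects, 3 groups
spec = KineticModelSpec()                           # group effect, median outcome
fit = fit_hierarchical_model(build_design(ds, spec), spec, MCMCConfig(seed=7))
for gk in summarize_groups(fit):
    print(gk.group, gk.r0_mean, gk.k_mean, gk.half_life_days)
```

prints (posterior mean and 95% credible interval):

```
LMIC: R0 = 1.324 (0.984-1.745) um^2, k = 0.0124 (0.0111-0.0136) /day, half-life 56 (51-62)
HIC:  R0 = 0.380 (0.288-0.497) um^2, k = 0.0022 (0.0010-0.0034) /day, half-life 318 (205-697)
BE:   R0 = 0.337 (0.265-0.423) um^2, k = -0.0004 (-0.0014-0.0006) /day, half-life no net clearance
DIC -365.00 (pD 52.6)
PPC envelope coverage: {'BE': 1.0, 'HIC': 1.0, 'LMIC': 1.0}
```

Reading this: the high-exposure newcomers (LMIC) start around 1.3 μm² of
carbon per macrophage and clear it with a half-life of ~2 months; the
moderate groups start near 0.3–0.4 μm² and stay flat (k credible intervals
at or around zero, i.e. no measurable net clearance over a year). The
generating values for this cohort were R0 = 1.122/0.387/0.275 μm² and
k = 0.013/0.002/−0.001 day⁻¹ — all inside the credible intervals. The PPC
coverage of 1.0 means the observed loess-smoothed group profiles lie inside
the 95% posterior-predictive envelope at every grid point.

The same pipeline is available from the shell:

```sh
amcarbon simulate --seed 7 --out cohort/
amcarbon fit --data cohort/ --seed 7 --out fitdir/
amcarbon ppc --fit fitdir/ --replicates 200 --seed 7 --out ppc.json --plot ppc.png
amcarbon quantify --images img/ --masks msk/ --calibration brightfield_100x --out slides.csv
amcarbon agree --pairs pairs.csv --out agreement.json
```

## Layout

```
src/amcarbon/
  synthetic.py   cohort + micrograph generators, intra-individual CV
  quantify.py    calibration, thresholding, slide summaries
  kinetics.py    hierarchical decay model, half-lives
  selection.py   DIC, model comparison, posterior predictive checks
  agreement.py   Bland-Altman, Spearman + CI, ICC(2,1)
  cli.py         click command-line interface
docs/methods.md  model, priors, generator assumptions, limitations
```
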