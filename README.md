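# predseek

Inference of predator–prey-like coupling between two health-information-
seeking behaviors — **online medical search** and **online medical
consultation** — from paired regional daily index time series.

During an epidemic wave, search-engine activity for medical topics and
online doctor-consultation volume both follow a life cycle and co-move
strongly.  `predseek` asks *how the two behaviors shape each other*: does
searching drive people to consult, and does consulting reduce the need to
search?  It is written for infodemiology / digital-epidemiology researchers
who have (or want to simulate) paired regional index series and want a
tested, reproducible implementation of the full inference pipeline.

## The model

With x₁(t), x₂(t) the cumulative search and consultation indices of one
region, the coupled model is

    dx₁/dt = r₁ x₁ (1 − x₁/K₁) + f₁(x₁, x₂)
    dx₂/dt = r₂ x₂ (1 − x₂/K₂) + f₂(x₁, x₂)

where r is the intrinsic growth rate, K the carrying capacity, and the
impact functions f₁, f₂ are signed combinations of at most six structural
factors per equation (each variable at most quadratic; every f₁ term
carries x₂, every f₂ term carries x₁).  The pipeline:

1. **Differential regression** — discretise to a daily difference equation
   with lagged-state regressors; increments become linear in (x, x²,
   factors), so estimation is no-intercept OLS.  Each fit faces a
   three-part battery: coefficient signs, R² > 0.9, all p < 0.05.
2. **Pattern detection** — enumerate all 3⁶ − 1 = 728 signed factor
   subsets per equation, fit each on growing prefix windows (half the data
   to the full cycle) across all regions, and rank structures by the
   **Conformity Rate** CR = Np/Ntotal — the fraction of attempted
   regressions passing the battery.
3. **Impact analysis** — factor the winning interaction term as
   f₁ = x₂·φ₁, f₂ = x₁·φ₂ and classify each region's late-wave sign
   regime.  φ₁ < 0 with φ₂ > 0 is the predation signature: consultation
   inhibits search, search promotes consultation.

Because no public accession exists for the regional index data this class
of method was designed around, the package ships a first-class synthetic
generator: multi-region ensembles of the coupled model with lognormal
regional parameter jitter and truncated Gaussian increment noise.

## Worked example

`examples/03_structure_search.py` generates a noiseless 8-region ensemble
from the default predation-sign preset and runs the exhaustive search:

```
search equation (generating structure: +x2^2-x1^2*x2)
rank  structure                        CR   mean R^2
   1  +x2^2-x1^2*x2                 1.000   1.000000
   2  -x1^2*x2+x1^2*x2^2            1.000   0.999984
   3  +x1*x2^2-x1^2*x2              0.996   0.999995
selected: +x2^2-x1^2*x2  (matches generating: True)

consult equation (generating structure: +x1*x2-x1^2*x2+x1*x2^2)
rank  structure                        CR   mean R^2
   1  +x1*x2-x1^2*x2+x1*x2^2        1.000   1.000000
   2  +x1^2+x1*x2^2                 0.960   1.000000
   3  +x1^2+x1^2*x2^2               0.960   0.999998
selected: +x1*x2-x1^2*x2+x1*x2^2  (matches generating: True)
```

The generating structure tops both rankings with perfect conformity
(CR = 1) and machine-precision fit; the runner-up subsets reach CR = 1 or
near it but lose the mean-R² tie-break.  `examples/04_impact_functions.py`
then fits those structures per region and classifies the late-wave
regimes:

```
late-wave sign regimes over 32 regions (days 30-61, trailing half):
phi1 (consultation -> search): {'predominantly-negative': 29, 'predominantly-positive': 3}
phi2 (search -> consultation): {'predominantly-positive': 32}
```

29 of 32 regions show φ₁ < 0 and all show φ₂ > 0 — the predation
signature.  The other examples demonstrate the dynamic-correlation band
(mean |r| ≈ 0.99 at the full window) and noisy logistic recovery
(r = 0.200, K ≈ 51000 from a true K = 50000).

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
predseek simulate -o ensemble.csv --seed 1 --n-regions 32 --n-days 61
predseek detect   -i ensemble.csv -o out/        # 728-structure sweep
predseek correlate -i ensemble.csv -o out/
predseek impact   -i ensemble.csv --fits out/fits.json -o out/
```

Every command is byte-reproducible under a fixed seed and configuration;
a YAML config file can set any option, flags override it, and each run
echoes its effective configuration to a provenance JSON.

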