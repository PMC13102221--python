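# gmolesta

Degree-day phenology modelling of adult flight in the oriental fruit moth
*Grapholita molesta* (Lepidoptera: Tortricidae), a multivoltine fruit-boring
pest of apple and stone-fruit orchards. The package is aimed at applied
entomologists and crop-protection researchers who need to forecast the
timing of the moth's four seasonal flight peaks from daily temperature
records — the timing that decides when pesticide applications against
hatching larvae actually work.

## The model

Thermal time x is accumulated from a January 1 biofix as cumulative
degree-days (CDD) with the single-sine method, using a lower developmental
threshold of 8.1 °C and an upper threshold of 32.2 °C with a horizontal
cutoff. The season's cumulative occurrence proportion of adults is a
four-component mixture, one monotone component per flight peak:

    f(x) = α₁ / (1 + (x/β₁)^γ₁)  +  Σₖ₌₂..₄ αₖ / (1 + exp(−zₖ))

with component medians μ₁ = β₁ and μₖ = β₁ + Δβ₁ + … + Δβₖ₋₁. The αₖ
(summing to 1) are each peak's share of the season's catch, β₁ the 50%
occurrence CDD of the overwintered flight, the Δβ the thermal spacings
between successive peaks, and the γₖ steepness parameters (γ₁ < 0;
zₖ = γₖ·(x − μₖ) under the default rate parameterization). The published
estimates (α = 0.2751/0.3501/0.1724/0.2024, β₁ = 172.23 DD,
Δβ = 464.08/575.33/604.38 DD) ship with the package and place the four
peak medians at 172.2, 636.3, 1211.6 and 1816.0 DD.

The package covers the full analysis loop: standardizing multi-site
pheromone-trap series onto the (CDD, cumulative proportion) scale, fitting
the 11 free parameters by constrained nonlinear least squares, segmenting
observed trap series into peaks and scoring prediction error in days
against two earlier degree-day rules, projecting peak dates under warmed
temperature scenarios, and generating synthetic climates and trap catches
with the statistical structure the analysis assumes.

## Worked example

```python
from gmolesta import (TABLE1_PARAMS, ClimateSpec, SamplingSpec,
                      gen_temperature, gen_study, accumulate_cdd,
                      predict_peak_days, filter_datasets, standardize,
                      fit_model)

# a synthetic temperate year and the dates its thermal time predicts
temps = gen_temperature(ClimateSpec(seed=0), year=2023)
cdd = accumulate_cdd(temps)
print(round(float(cdd.cumulative[-1]), 1))          # 2318.0  (annual CDD)
print(predict_peak_days(TABLE1_PARAMS, temps))      # (135, 175, 211, 249)

# close the loop: simulate a 30-site study and refit the curve
study = gen_study(TABLE1_PARAMS, n_sites=30,
                  sampling=SamplingSpec(total=500), seed=1)
kept, _ = filter_datasets([s.trap for s in study])
by = {s.trap.site_id: s for s in study}
fit = fit_model([standardize(t, by[t.site_id].cdd) for t in kept])
print(f"r2={fit.r_squared:.4f}")                    # r2=0.9992
print(f"beta1={fit.params.beta1:.2f}")              # beta1=173.21
print(tuple(round(d, 2) for d in fit.params.dbeta)) # (463.26, 569.57, 611.39)
```

The annual accumulation of ~2,318 DD means the fourth peak median
(1,816 DD) falls in late summer; the predicted Julian days 135/175/211/249
are mid-May, late June, late July and early September. Refitting the curve
to 30 simulated sites of 500 moths each returns the generating timing
parameters to within about 1%.

The same pipeline is scriptable from the shell:

```
gmolesta simulate --out-dir sim --n-sites 30 --seed 1
gmolesta fit --traps sim/traps.csv --temps sim/temperature.csv
gmolesta validate --traps sim/traps.csv --temps sim/temperature.csv
gmolesta project --baseline sim/temperature.csv --scenario warm2 warmed.csv --out shift.csv
```

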