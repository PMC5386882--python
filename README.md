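# gestwin

Time-to-event simulation of gestational age (GA) with **time-variant genetic
effects**, for researchers studying the genetic architecture of preterm
delivery (PTD) and the design of its association studies.

## The scientific problem

GA at spontaneous delivery is heritable, yet GWAS of PTD have struggled to
find loci. One candidate explanation is that maternal susceptibility
alleles do not act uniformly across pregnancy but only inside "windows of
sensitivity". A signature of such effects survives in family data: in
maternal-cousin pairs (children of full sisters), the conditional
distribution of one cousin's GA given the other's is *nonuniform* — the
lower quantiles climb far more steeply across conditioning bins than the
upper ones — whereas an ordinary polygenic trait such as height shows
parallel quantile series.

`gestwin` models this in a survival framework. Pregnancies enter the risk
set at day 150 and deliver by day 300 under the hazard

    λ(t) = λ e^{αt} · exp( Σᵢ Gᵢ Eᵢ(t) ),

where `λe^{αt}` is a Gompertz baseline (selected by AIC among exponential /
Weibull / Gompertz), `Gᵢ ∈ {0,1,2}` is the mother's additive genotype at
simulated locus `i`, and the per-allele effect is either constant,
`Eᵢ(t) = γᵢ` (proportional hazards), or a Gaussian window
`Eᵢ(t) = γᵢ/(σ√2π)·exp(−((d−μ)/σ)²/2)` peaking at gestational day μ with
spread σ. Sibling pairs share genotypes through the exact Hardy–Weinberg /
Mendelian joint distribution (additive sibling correlation 1/2), which
induces the familial GA correlation.

The package provides:

* **genotypes** — exact sibling-pair and population genotype simulation;
* **hazard** — baseline and composite hazards, parametric baseline MLE with
  AIC family selection, baseline calibration;
* **engines** — closed-form inverse-transform sampling (constant effects)
  and a general iterative daily-hazard simulator, cross-validated against
  each other;
* **quantile_cost** — conditional quantile tables (7-day bins, 5 quantiles,
  bins with >100 pairs retained) and the √N-weighted sum-of-squares cost;
* **search** — models M0–M4 and random-search fitting with `Σγpn`
  meta-modeling;
* **power** — empirical GWAS power and type-I error of linear vs Cox
  (Efron ties) regression per locus;
* **fixtures** — synthetic stand-ins for the register cousin cohort and a
  polygenic height-like control;
* a `gestwin` command line (`fixtures`, `simulate`, `fit`, `power`).

## Worked example

Generate the reference cousin-pair population (the canonical M3-like model:
one constant-effect class γ=2.6, p=0.01, n=2 plus four Gaussian windows at
days 230/237/244/258) and inspect its conditional quantile table:

```python
import gestwin as gw

cohort, table, manifest = gw.make_reference_population(n_pairs=35_541, seed=0)
print(table.to_frame())
print("slope contrast:", gw.quantile_slope_contrast(table))
```

```
   bin_left  count     q05    q25    q50     q75    q95
0     231.0    123  243.00  274.0  281.0  287.00  290.0
1     238.0    199  250.90  274.0  282.0  287.00  292.0
2     245.0    263  249.00  270.0  280.0  286.00  291.9
3     252.0    504  253.00  272.0  280.0  285.00  292.0
4     259.0   1149  255.40  273.0  281.0  286.00  292.0
5     266.0   2510  259.00  275.0  281.0  286.00  291.0
6     273.0   7036  262.00  277.0  282.0  287.00  292.0
7     280.0  13417  264.00  278.0  283.0  287.00  292.0
8     287.0   9286  264.00  278.0  283.0  287.00  292.0
9     294.0    984  266.15  279.0  283.0  287.25  292.0
```

Reading the row `bin_left = 280`: among pairs whose conditioning cousin
delivered in days [280, 287), the other cousin's median GA is 283 d and the
5th percentile is 264 d. Across the bins, the 95th percentile rises only
2 d while the 5th rises 23 d — the nonuniform pattern; the summary
statistic `quantile_slope_contrast` (slope of q05 minus slope of q95, in
days per bin) is **+2.35** here, against ≈ 0 for the polygenic control
(`gw.make_polygenic_control`).

Fit model M1 (one constant-effect class; γ, p, n free) to such a table and
check what the search recovers:

```python
import numpy as np
from gestwin.search import FitConfig, fit_model

rng = np.random.default_rng(1)
result = fit_model(gw.model_m1(), table, FitConfig(stage1_budget=1000,
                   stage2_budget=1000, n_pairs=35_541), rng)
best = result.best
print(best.classes[0], "cost:", round(best.ranking_cost, 1),
      "sum gpn:", round(best.sum_gpn, 4))
```

On a reference generated by a *known* M1 model the same call recovers the
generating `Σγpn` within a few percent (see `tests/test_acceptance.py`).

Compare the power of linear and Cox regression to detect the simulated
loci (numbers from `scripts/acceptance.py --seed 1`, 1,000 replicates at
n = 500):

| locus | Cox power | linear power |
|---|---|---|
| constant-effect (γ=2.6, p=0.01) | 0.70 | 0.42 |
| late window (μ=258, γ=−100, p=0.3) | 0.43 | 0.96 |

Cox regression wins where its proportional-hazards assumption holds (the
constant locus); the strongly nonproportional late-acting window is far
better detected by plain linear regression. Both tests hold the 5% level on
null control loci (0.048 / 0.049 at n = 1,000), and no null locus ever
reaches the genome-wide 5×10⁻⁸ threshold.

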