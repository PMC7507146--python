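# streamstoich

Dissolved vs. particulate N:P stoichiometry of streams and rivers:
censored-data Monte Carlo, bootstrap particulate nutrients, homeostasis and
discharge regressions, and land-use mixed models.

## The problem

Continental-scale stream monitoring programs report total nitrogen and
phosphorus (TN, TP, from unfiltered digested samples), the dissolved
inorganic species (NH3-N + NH4-N + NO3-N + NO2-N, summed to DIN, and
orthophosphate-P, DIP), and sometimes total dissolved N and P (TDN, TDP).
Two complications stand between those records and ecological conclusions:

1. **Censoring.** Many concentrations are reported as "estimated" or as
   "less than" a reporting limit. Discarding them would left-censor the
   data; substituting half the limit distorts distributions.
2. **No direct particulate measurements.** Suspended particulate N and P
   (PN, PP) must be derived as total minus dissolved inorganic minus
   dissolved organic, where the dissolved organic fractions (DON, DOP) are
   themselves only estimable from the subset of sites with paired
   total / total-dissolved records.

`streamstoich` implements a tested pipeline for this situation:

* **Censoring Monte Carlo** — "estimated" values are replaced by draws from
  Normal(value, cv x value) truncated at zero by resampling; "less-than"
  values by draws from Uniform(0, limit).
* **Bootstrap particulate derivation** — the dissolved-organic share
  p = (TDN - DIN)/(TN - DIN) (analogous for P) is pooled across paired
  records into an empirical distribution; for each record, 1,000 resampled
  shares give candidates (TN - DIN) x (1 - p_b), and PN is a single uniform
  draw from the candidates' interquartile range. Records with DIN > TN or
  DIP > TP are removed first and reported.
* **Stoichiometric homeostasis** — the regulation coefficient H from
  ecological stoichiometry, estimated via its reciprocal: 1/H is the OLS
  slope of log10(PN:PP) on log10(DIN:DIP) (molar ratios). 1/H -> 0 means
  static, chemostatic particle stoichiometry; 1/H -> 1 means particles
  track the dissolved supply proportionally (Redfield-like plasticity).
  Fitted globally, in low/high TP bins (< 0.025 / > 0.10 mg/L), and per
  site for streams with > 100 sequential samples.
* **Discharge power laws** — per-site N:P = a Q^b fitted as log-log OLS for
  total, dissolved and particulate ratios (b = 0 is chemostatic), then
  regressed on watershed land use.
* **Threshold exceedance** — fractions of records strictly above published
  structural thresholds (benthic algae, macroinvertebrates, fish; TN/TP)
  and functional half-saturation constants (litter breakdown, algal
  growth; DIN/DIP).
* **Land-use mixed models** — log10 concentration ~ log10 Q + pCRO + pHAY +
  pFOR + pURB with a random site intercept (REML), reporting raw and
  standardized coefficients, Wald 95% CIs, and Nakagawa-Schielzeth
  marginal/conditional R².
* **Synthetic data generator** — multi-site panels with Dirichlet land use,
  lognormal discharge, linear-model concentrations with site intercepts, a
  controllable true 1/H coupling, Beta-distributed organic shares with
  exact mass closure (TN = DIN + DON + PN), and injected censoring — with
  full ground truth, so every stage has recovery tests.

All ratios are molar unless noted; a mass N:P ratio is converted by
(cn/14.007)/(cp/30.974) = mass x 2.2113, so Redfield 16:1 molar is a mass
ratio of 7.2.

## Worked example

`examples/01_synthetic_pipeline.py` runs the whole pipeline on a 63-site
synthetic world and prints:

```
Medians (all records):
              TN: 1.1 mg/L (IQR 0.397-2.28)
             din: 0.902 mg/L (IQR 0.286-1.97)
              TP: 0.072 mg/L (IQR 0.0365-0.118)
             DIP: 0.0327 mg/L (IQR 0.0168-0.0564)
    np_dissolved: 56.5 molar (IQR 28.9-104)
  np_particulate: 4.03 molar (IQR 2.24-8.36)
...
Homeostasis slope 1/H = 0.081 (p = 0.0068, n = 1251)
```

Dissolved N:P (median ~57) sits far above Redfield while particulate N:P
(median ~4) is low and narrow, and the small 1/H says particle
stoichiometry barely responds to the dissolved supply — the generator's
true coupling here is 0.096, and the fitted slope recovers it within
sampling error. The other examples isolate the homeostasis / power-law
estimators and the censoring + bootstrap derivation on a four-row table.

A thin CLI wraps the same library calls:

```sh
streamstoich simulate --seed 3 --out sim/            # synthetic CSVs + truth
streamstoich run --config config.yaml --seed 7 --out out/
streamstoich report out/
```

`run` writes `summary.csv`, `exceedance.csv`, `landuse_models.csv`,
`homeostasis.csv`, `site_homeostasis.csv`, `power_law.csv`, `derived.csv`,
a JSON manifest with the seed and stage record counts, and a log.
Re-running with the same config and seed reproduces every output
byte-for-byte.

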