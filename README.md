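# vaxineq

Survey-weighted analysis of essential childhood immunization coverage and
its socioeconomic and spatial inequalities, for epidemiologists and health
economists working with DHS-style household survey microdata.

Given one row per surveyed child (region, primary sampling unit, sampling
weight, age, household wealth score, per-dose vaccine indicators), the
package estimates:

- **Full immunization coverage (FIC)** — the weighted share of children who
  completed the basic EPI schedule (1 BCG + 3 DTP + 3 OPV + 1 MCV), at
  national and subnational level, for children aged 15–35 months (24–35 as
  a sensitivity window);
- **Wealth-related inequality** via the concentration index
  `C = (2/μ) cov_w(h, r)`, where `h` is the full-immunization indicator,
  `r` the weighted fractional wealth rank and `μ` the weighted mean of `h`,
  with the bounds corrections for binary outcomes
  `W = C/(1−μ)` (Wagstaff) and `E = 4μC` (Erreygers), linked by
  `E = 4μ(1−μ)W`, plus PSU-cluster-robust 95% confidence bounds from the
  convenient-regression formulation;
- **Within/between-country dispersion** of subnational estimates via the
  Theil-T index (GE(1)) with its exact additive decomposition;
- **Spatial clusters** of high/low coverage or inequality via the
  Getis-Ord Gi* local statistic on queen-contiguity weights, with
  Benjamini–Hochberg FDR control before hot/cold labeling, and 3×3
  bivariate coverage-by-inequality classes (the low-coverage /
  high-inequality corner marking "double disadvantage" regions);
- **Missed-vaccine set intersections** — the weighted share of children
  missing each of the 16 combinations of the four vaccines (a vaccine
  counts once however many of its doses are missing), optionally scaled to
  population counts.

A fully tested synthetic-survey generator (`vaxineq.synth`) emulates the
two-stage DHS design — PSUs within regions, relative sampling weights, a
wealth gradient on the logit scale, spatially autocorrelated region
effects, planted hot/cold clusters — with exact ground truth for
parameter-recovery checks.

## Worked example

```python
import vaxineq as vq

cfg = vq.SynthConfig(n_countries=2, regions_per_country=25,
                     psus_per_region=6, children_per_psu=20, seed=11)
children, geojson, truth = vq.generate_survey(cfg)
status = vq.complete_course(vq.filter_age(children, 15, 35))
print(vq.weighted_coverage(status, level="national").round(3).to_string(index=False))
```

```
country  n_children   bcg   dtp   opv   mcv   fic
    C00        2131 0.883 0.715 0.702 0.720 0.373
    C01        2106 0.875 0.688 0.676 0.685 0.340
```

Coverage falls from single-dose BCG (~88%) to the full course (~35–37%):
each additional required dose loses children, so FIC is far below any
individual vaccine's coverage. Wealth-related inequality for one country:

```python
grp = status[status["country"] == "C00"]
h = grp["fully_immunized"].to_numpy(float)
w = grp["weight"].to_numpy(float)
r = vq.weighted_fractional_rank(grp["wealth_score"].to_numpy(float), w)
res = vq.index_inference(h, r, w, grp["psu_id"].to_numpy())
```

which prints `W = 0.310 [0.254, 0.366], E = 0.290 [0.238, 0.342]`: both
indices positive and bounded away from zero, i.e., full immunization is
concentrated among wealthier households (the generator's default wealth
slope of 1.5 logits per rank unit is deliberately pro-rich). Dispersion of
the 50 subnational estimates decomposes as

```
Theil(FIC): total=0.1419 within=0.1409 between=0.0010
```

— the two simulated countries share the same uptake model, so nearly all
inequality is within-country. Finally

```python
miss = vq.tabulate_missed_sets(status, group_by="country")
print(vq.modal_missed_combination(miss).to_string(index=False))
```

```
group combination    share
  C00         OPV 0.114039
  C01         MCV 0.111267
```

identifies the single most common missed-vaccine combination per country
(here the late-schedule OPV course and the measles vaccine).

The same analysis runs from the shell:

```sh
vaxineq simulate --out-dir sim --seed 11
vaxineq run-all --children sim/children.csv --geojson sim/regions.geojson --out-dir results
```

writing national/subnational coverage and inequality tables, the Theil
decomposition, Gi* cluster tables for FIC/W/E, bivariate class tables,
missed-set tables and a manifest with the config hash and seed.

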