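# adaudit

Analysis pipeline for street audits of outdoor food advertising. Given a
coded audit — photographs of advertising assets across deprivation-
stratified neighbourhoods, the adverts they display and the products those
adverts show — `adaudit` scores every product under the UK 2004/05
Nutrient Profile Model (NPM), classifies adverts against a hypothetical
Healthier Food Advertising Policy (HFAP) of the Transport-for-London
type, and quantifies advertising exposure by area deprivation with the
accompanying reliability and validity statistics. It is written for
public-health researchers auditing local food environments and for
analysts evaluating the evidence base for local advertising policies.

Because raw audit datasets are rarely shareable, the package includes a
first-class seeded generator that emulates a city-scale audit (30
neighbourhoods in five Index of Multiple Deprivation quintiles, ~295
assets of 14 types with a deprivation gradient, multi-advert digital
assets, brand-only and missing-nutrition adverts, dual-coder replicates,
boundary-straddling GPS points), so the entire pipeline is testable and
demonstrable without fieldwork data.

## The core models

**NPM score.** Per 100 g, a product accrues A points for energy,
saturated fat, total sugars and sodium (0–10 each) and C points for
fruit/vegetable/nut content (FVN%), fibre and protein. The score is

    total = A − (FVN + fibre + protein),

with protein dropped when A ≥ 11 and FVN points < 5. A food with
total ≥ 4, or a drink with total ≥ 1, fails the model ("HFSS"). Band
edges are strict and shipped as checksum-pinned data.

**HFAP verdict.** An advert showing ≥ 1 food or non-alcoholic beverage
(or food/drink brand-only imagery) is in scope. Brand-only ⇒ would-be
non-compliant; else any HFSS product ⇒ would-be non-compliant; else any
unscoreable product ⇒ not assessable; else compliant.

**Exposure statistics.** Cohen's κ = (p_o − p_e)/(1 − p_e) for dual-coder
reliability; Pearson χ² tests (no continuity correction) with Cochran's
validity rule (all expected ≥ 1, ≥ 80 % of cells ≥ 5) for the
deprivation-gradient tests; standardised residuals (O − E)/√E locate the
quintiles driving an association.

See `docs/methods.md` for assumptions, parameter defaults and numerical
conventions.

## Worked example

Simulate a study-scale audit and run the full pipeline (coding → GPS
imputation → boundary exclusion → NPM → compliance → statistics):

```sh
adaudit run-all --config examples/demo.yaml --seed 1 --out demo_out
```

prints

```
assets in=282 retained=279 excluded=3
total_advertising: chi2=54.456 df=4 p=0.0000
food_drink: chi2=0.746 df=4 p=0.9456
non_compliant: chi2=4.300 df=4 p=0.3669
report bundle in demo_out
```

Reading this: 282 assets were generated, 3 fell outside their
neighbourhood boundary (GPS jitter) and were excluded. Total advertising
is very unevenly distributed across deprivation quintiles (the
goodness-of-fit test against equal exposure rejects, p < 0.001). Under
the default flat food-enrichment settings there is no food/drink gradient
to detect, and the food/drink and compliance tests correctly fail to
reject (p = 0.95, p = 0.37). `demo_out/` then holds the dataset echo,
per-asset filter outcomes with signed boundary distances, the
NPM-augmented product table, advert verdicts, the per-quintile exposure
tables (including the asset-type × product-type heat-map matrix), χ²
results, buffer-sensitivity summaries at 0/5/10/20 m, and a manifest
with seeds, config hash and per-stage row counts.

The same stages are importable directly:

```python
from adaudit import GeneratorConfig, generate_audit, run_exposure_tests

ds = generate_audit(GeneratorConfig(food_enrichment=(3, 2.5, 1, 0.7, 0.5), seed=1))
print(run_exposure_tests(ds)["food_drink"].p_value)  # 2.2469e-06
```

Subcommands `simulate`, `score`, `classify`, `filter` and `analyse` run
individual stages on audit tables in CSV/GeoJSON form.

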