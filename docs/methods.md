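# Methods

`adaudit` analyses street-audit data on outdoor advertising: where
advertising assets stand, what they show, how healthy the advertised food
is, and how exposure varies with area deprivation. This note documents the
models and procedures, their parameters, and the design choices made where
the methodology left the design open.

## Data model

Audit records form a four-level hierarchy. A **neighbourhood** is an
LSOA-like areal unit (roughly 1 000–3 000 residents) carrying an Index of
Multiple Deprivation (IMD) rank — 1 is the most deprived area nationally —
an IMD quintile (1 = most deprived), a ward identifier and a WGS84
polygon. An **asset** is a physical advertising structure (bus shelter,
billboard, totem, …) with a size class (small/medium/large) and a point
coordinate. An **image** is a geo-tagged photograph documenting an asset.
An **advert** is one creative displayed on an asset (digital assets and
totems cycle through several), and a **product** is one item shown on an
advert, classed as food, non-alcoholic beverage, alcoholic beverage,
gambling or other.

The asset-type vocabulary is config-driven: eleven labels are pre-seeded
(the labels common across city advertising audits) and further labels must
be declared explicitly rather than silently accepted. Billboards and large
hoardings are by definition large-format; the loader rejects any coding
that says otherwise. Coordinates are stored as WGS84 lon/lat decimal
degrees, the smartphone EXIF convention. Assets are deduplicated by
identifier, never by coordinates, because several images may document one
asset and only some carry GPS.

## Area sampling

Neighbourhoods are stratified into five IMD quintiles by rank order. When
the frame size is not divisible by five, the larger groups sit at the
most-deprived end (ceiling allocation first); the methodology behind this
is silent on tie handling, so the rule is fixed and documented rather than
configurable. Six areas per quintile are selected with at most one per
ward. The most-deprived quintile is deterministic — the lowest-ranked area
inside each of six designated priority wards — while quintiles 2–5 are
uniform draws without replacement under the ward constraint, implemented
by rejection sampling (cap 10 000 attempts) with a randomised one-per-ward
fallback. Visit order is block randomised: with 30 areas in 5 weekly
blocks of 6, every block receives one area from each quintile plus one
extra, so no week is dominated by a single deprivation level; blocks
smaller than the number of quintiles relax to a seeded permutation. A 10 %
validation subsample (⌈0.1 n⌉ areas) is drawn uniformly for dual-coding.

## Nutrient Profile Model scoring

Products are scored under the UK Food Standards Agency 2004/05 Nutrient
Profile Model. Per 100 g, "A" points accrue for energy (kJ), saturated fat
(g), total sugars (g) and sodium (mg) — ten ascending bands each, 0–40
total — and "C" points for fruit/vegetable/nut content (FVN%: 1 point
above 40 %, 2 above 60 %, 5 above 80 %), fibre and protein (five bands
each). The total is A − C, except that when A ≥ 11 and the FVN component
is below 5, protein points are not counted (the protein cap). A food
scoring ≥ 4, or a drink scoring ≥ 1, fails the model and is HFSS.

Numerical conventions, each deliberately fixed:

- **Band edges are strict.** A value exactly equal to a threshold scores
  in the band below; `tests` verify this at every edge.
- **Inputs are banded unrounded.** No pre-rounding of nutrient values is
  applied before banding.
- **Fibre basis is explicit.** AOAC is the default (modern labels); NSP is
  supported and must be declared, since the two threshold ladders differ.
- **Drinks per 100 ml are treated numerically as per 100 g.**
- **FVN% derivation hierarchy:** sum of declared ingredient percentages
  (clamped to 100, because composite-ingredient percentages can
  double-count), else an exact match in a reference lookup, else zero —
  each tagged with its provenance.
- **Per-portion declarations** are scaled by 100/portion-weight using a
  measured weight first, a portion-size handbook value second; with
  neither, the product is not assessable.

The threshold tables are shipped as a data file pinned by SHA-256
checksum, so any edit to the bands is loud. The scorer is verified against
an independently written brute-force banding oracle on 10 000 random
profiles, plus monotonicity properties (raising any A-nutrient never
lowers the score; raising FVN never raises it).

## Policy compliance classification

Adverts are assessed against a hypothetical Healthier Food Advertising
Policy of the Transport-for-London type. An advert is in scope when it
shows at least one food or non-alcoholic beverage product, or is
food/drink brand-only imagery; alcohol-only and gambling adverts are out
of scope (they are harmful-commodity categories but not covered by the
policy modelled here, and a brand-only alcohol advert is likewise out of
scope). Precedence: brand-only ⇒ would-be non-compliant; else any HFSS
product ⇒ would-be non-compliant (an assessed HFSS product overrides
missing data on other products, reading the any-HFSS rule literally);
else any unassessable food/drink product ⇒ not assessable; else
compliant. The three statuses partition the food/drink adverts, a
property tested per quintile and overall. For HFSS-status tables (as
opposed to compliance tables), brand-only adverts count as N/A, since
they carry no scoreable product.

## Geographic exclusion and buffers

Neighbourhood boundaries often run down road centre lines, so fieldwork
legitimately photographs assets whose GPS point falls just outside the
surveyed polygon. Missing image coordinates are imputed in a fixed order:
EXIF, another image of the same asset, a manual lookup file; residual
gaps are flagged, not fatal. An asset is retained at buffer *b* when its
point lies in its area's polygon dilated by *b* metres; a point exactly on
the boundary is inside (the exclusion targets assets *outside* the
boundary). Retention is monotone in *b* by construction, and the signed
point-to-boundary distance (negative inside) agrees with the point-in-
polygon verdict at buffer 0. Sensitivity analyses re-run the exposure
tables at 0/5/10/20 m. An asset straddling two areas belongs to the area
containing its point and is never double-counted.

Metric distances are computed in a projected plane. The projection is an
ellipsoidal transverse Mercator implemented here (Redfearn series,
forward and inverse), with British National Grid parameters by default,
applied directly to WGS84 coordinates without a datum shift. Absolute
positions are therefore offset ~100 m from true OSGB36 grid references,
but buffering compares only relative distances between points projected
identically, for which scale distortion at city extent is far below
0.1 %; the projection's round trip is tested to 1e-9 degrees and its
local scale against a great-circle computation. A data-centred local
transverse Mercator is available for non-British extents.

## Reliability and exposure statistics

**Cohen's kappa** (unweighted — the label categories are nominal) measures
dual-coder agreement: κ = (p_o − p_e)/(1 − p_e) with p_o the observed and
p_e the chance agreement from the marginals. Degenerate tables (p_e = 1)
are flagged undefined rather than given a value. The implementation is
cross-checked against an explicit double-loop oracle and scikit-learn on
random tables to 1e-10.

**Chi-square tests** are Pearson tests with no continuity correction,
standardised residuals (O − E)/√E, and Cochran's validity rule: no
expected cell below 1 and at least 80 % of expected cells at or above 5.
An invalid test keeps its statistic but is flagged, and its p-value gets
no interpretation — mirroring fieldwork samples too sparse for a valid
test. Three planned tests run at the 95 % level, uncorrected for
multiplicity: (1) total advertising exposure across quintiles, (2)
food/drink versus other adverts by quintile, (3) would-be-non-compliant
versus other food/drink adverts by quintile. Test (1) only has a single
count per quintile, so it is a goodness-of-fit test against the
equal-exposure expectation (the design samples equal numbers of areas per
quintile); (2) and (3) are 2×5 independence tests.

Descriptive tables count product types once per advert (an advert showing
two foods contributes one food count), and product-type shares use the
advert denominator — a deliberate resolution of an ambiguity in how such
shares are conventionally reported, flagged here because a product
denominator would give different percentages. Percentages are rounded
half-away-from-zero to whole percent, uniformly.

## Synthetic data generator

No fieldwork dataset is distributed with the package, so a seeded
generator produces audit datasets with the statistical structure the
analysis assumes. Its defaults are the conditions of a city-scale audit:

| parameter | default | basis |
| --- | --- | --- |
| areas | 5 quintiles × 6 | the sampling design |
| asset intensity per quintile | 74, 73, 50, 72, 26 | the emulated per-quintile counts (middle value back-solved from the 295 total) |
| asset-type mix | bus shelter 23 %, non-electronic display 13 %, totem 11 %, … smart bench 0 % | the emulated type counts |
| adverts per multi-advert asset | 1 + Poisson(4), totems and electronic displays | back-solved: 295 assets carrying 437 adverts |
| products per advert | 1 + Poisson(0.57) | 684 products / 437 adverts |
| product mix | 15 % food, 2 % non-alcoholic, 5 % alcoholic, 0 % gambling, 78 % other | the emulated product-type shares |
| `hfss_fraction` | 0.5 | just over half of assessable food/drink products HFSS |
| `brand_only_rate` | 0.17 | 17 % of food/drink adverts brand-only |
| `missing_nutrition_rate` | 0.15 | order of magnitude of unassessable products; not a published figure |
| `coordinate_jitter_m` | 10 m | smartphone GPS error scale, produces boundary-straddling points |

Asset counts are Poisson-dispersed across the areas of a quintile — the
within-quintile dispersion is a modelling choice, not an observed fact.
Area polygons default to a synthetic rectangular grid near the surveyed
city; real boundary GeoJSON can be substituted at load time. Nutrient
vectors come from a two-component mixture ("treat-like": high energy,
saturated fat, sugars, sodium, negligible FVN; "staple-like": moderate
nutrients, substantial FVN) and are rejection-tuned so each product's NPM
verdict matches its Bernoulli(`hfss_fraction`) draw — the realised HFSS
share is exactly binomial, which the tests exploit. `food_enrichment`
scales the food/drink share per quintile to create (or flatten) a
deprivation gradient.

Dual-coding replicates take rater 1 as truth and draw rater 2 from a
row-stochastic confusion kernel, so expected agreement equals the
kernel's diagonal mass. Boundary fixtures place points strictly inside a
polygon plus points *exactly* d metres outside (on the exterior ring of
the polygon buffered by d in the projected plane), giving the filter
tests exact expected outcomes.

What the generator does **not** emulate: street-network asset placement
(points are uniform in the polygon), advertising campaign cycles,
correlated asset types within a street, demographic covariates beyond the
IMD quintile, and real LSOA boundary shapes. Passing tests therefore show
that the pipeline's statistics behave correctly under the assumed
structure, not that real cities satisfy that structure.

## Calibration properties and problem sizes

The chi-square machinery is validated by simulation under generator
conditions: with a flat deprivation gradient the food/drink test rejects
in 3–8 % of 200 seeded replicates (type-I calibration), and with a strong
gradient toward the deprived quintiles (enrichment 3.0/2.5/1.0/0.7/0.5)
it rejects in at least 80 % (power), each replicate holding ~300 assets
and ~450 adverts. The scorer-oracle equivalence uses 10 000 random
profiles; kappa and chi-square oracle comparisons use 1 000 random tables
each. These sizes are the package's test conditions and are stated here
so they can be scaled deliberately rather than rediscovered.

## Known limitations

- The projection omits the WGS84→OSGB36 datum shift (documented above);
  absolute grid references should not be read off the projected plane.
- FVN reference matching is exact-name only; fuzzy matching against a
  food-composition table is out of scope.
- The NPM implemented is the 2004/05 model; the 2018 draft revision and
  front-of-pack schemes are out of scope, as is inferring energy from
  kcal.
- Compliance classification needs a brand-only flag as input; whether a
  brand is a food/drink brand is a coding decision, not inferred.
- With realistic (small) HFSS counts the third planned test is usually
  invalid under Cochran's rule; the package reports it flagged rather
  than forcing a p-value.
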