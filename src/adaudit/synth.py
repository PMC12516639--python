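"""Seeded synthetic audit datasets with the structure the analysis assumes.

Fieldwork audit data are rarely shareable, so every downstream stage is
exercised against generated datasets that emulate a city-scale audit's
conditions: 30 neighbourhoods across 5 deprivation quintiles, roughly 295
advertising assets of 14 types with a deprivation-dependent intensity
gradient (most assets in the most-deprived quintiles, fewest in the least
deprived), multi-advert digital assets and totems, multi-product adverts,
a product mix of ~15 % food / ~2 % non-alcoholic drink / ~5 % alcohol /
remainder "other", nutrient vectors spanning HFSS and non-HFSS products,
missing-nutrition and brand-only adverts, dual-coder replicates and
boundary-straddling coordinates.

Everything is driven by a single integer seed: the same seed yields a
byte-identical dataset.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from shapely.geometry import Point, Polygon, box

from .model import (
    DEFAULT_ASSET_TYPES,
    LARGE_ONLY_ASSET_TYPES,
    PRODUCT_TYPES,
    Advert,
    Asset,
    AuditDataset,
    ImageRecord,
    Neighbourhood,
    NutrientValues,
    Product,
)
from .npm import npm_score
from .projection import BNG, TransverseMercator, to_lonlat, to_metric

__all__ = [
    "GeneratorConfig",
    "generate_audit",
    "generate_dual_coding",
    "generate_boundary_fixture",
]

#: per-quintile expected asset counts echoing the published gradient
#: (74, 73, 72 and 26 printed; the middle quintile back-solved from the 295
#: total), high in Q1/Q2/Q4 and low in Q5.
DEFAULT_ASSET_INTENSITY = (74.0, 73.0, 50.0, 72.0, 26.0)

#: asset-type mix; bus shelters most prevalent (~23 %), non-electronic
#: free-standing displays next (~13 %), totems common enough to carry the
#: multi-advert load, smart benches absent.
DEFAULT_ASSET_TYPE_MIX: dict[str, float] = {
    "bus shelter": 0.23,
    "non-electronic free-standing display": 0.13,
    "totem": 0.11,
    "billboard": 0.07,
    "large hoarding": 0.02,
    "litter/recycling bin": 0.08,
    "phone box": 0.07,
    "other transport hub": 0.05,
    "electronic free-standing display": 0.01,
    "smart bench": 0.0,
    "other": 0.23,
}

#: product-group mix over (food, non-alcoholic, alcoholic, gambling, other)
DEFAULT_PRODUCT_MIX = (0.15, 0.02, 0.05, 0.0, 0.78)

#: asset types that cycle through more than one advert
MULTI_ADVERT_TYPES = frozenset({"totem", "electronic free-standing display"})


class GeneratorConfig(BaseModel):
    """Everything the generator needs, with study-scale defaults."""

    n_quintiles: int = 5
    n_areas_per_quintile: int = 6
    #: expected asset count per quintile (Poisson-dispersed across areas)
    asset_intensity: tuple[float, ...] = DEFAULT_ASSET_INTENSITY
    asset_type_mix: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_ASSET_TYPE_MIX)
    )
    #: mean number of adverts beyond the first on multi-advert assets
    extra_adverts_mean: float = 4.0
    #: mean number of products beyond the first per product-bearing advert
    extra_products_mean: float = 0.57
    product_category_mix: tuple[float, ...] = DEFAULT_PRODUCT_MIX
    #: per-quintile multiplier on the food/drink share of the product mix
    food_enrichment: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    #: probability an assessable food/drink product fails the NPM
    hfss_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    missing_nutrition_rate: float = Field(default=0.15, ge=0.0, le=1.0)
    #: share of food/drink adverts that are brand-only imagery
    brand_only_rate: float = Field(default=0.17, ge=0.0, le=1.0)
    #: isotropic scatter (metres) applied to asset points sampled inside
    #: their area polygon, so some straddle the boundary
    coordinate_jitter_m: float = Field(default=10.0, ge=0.0)
    #: probability an image carries no EXIF coordinates
    missing_gps_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if len(self.asset_intensity) != self.n_quintiles:
            raise ValueError("asset_intensity needs one entry per quintile")
        if len(self.food_enrichment) != self.n_quintiles:
            raise ValueError("food_enrichment needs one entry per quintile")
        if any(v < 0 for v in self.asset_type_mix.values()):
            raise ValueError("asset_type_mix probabilities must be non-negative")
        if abs(sum(self.asset_type_mix.values()) - 1) > 1e-9:
            raise ValueError("asset_type_mix must sum to 1")
        if len(self.product_category_mix) != len(PRODUCT_TYPES):
            raise ValueError("product_category_mix needs one entry per product group")
        if any(p < 0 for p in self.product_category_mix):
            raise ValueError("product_category_mix probabilities must be non-negative")
        if abs(sum(self.product_category_mix) - 1) > 1e-9:
            raise ValueError("product_category_mix must sum to 1")
        return self


# ---------------------------------------------------------------------------
# neighbourhood grid


def _grid_neighbourhoods(cfg: GeneratorConfig, tm: TransverseMercator) -> dict[str, Neighbourhood]:
    """Rectangular area polygons on a grid, one row per quintile.

    Cells are ~900 m x 700 m in projected space near a northern English
    city centre; real boundary GeoJSON may be substituted at load time.
    """
    out: dict[str, Neighbourhood] = {}
    # grid origin near Leeds city centre in the projected plane
    e0, n0 = tm.forward(-1.55, 53.80)
    w, h, gap = 900.0, 700.0, 120.0
    rank = 1
    for q in range(1, cfg.n_quintiles + 1):
        for i in range(cfg.n_areas_per_quintile):
            cell = box(
                e0 + i * (w + gap),
                n0 + (q - 1) * (h + gap),
                e0 + i * (w + gap) + w,
                n0 + (q - 1) * (h + gap) + h,
            )
            area_id = f"A{q}{i + 1:02d}"
            out[area_id] = Neighbourhood(
                area_id=area_id,
                imd_rank=rank,
                imd_quintile=q,
                ward_id=f"W{q}{i + 1:02d}",
                area_km2=w * h / 1e6,
                network_km=round(2.0 + 0.5 * q + 0.3 * i, 2),
                geometry=to_lonlat(cell, tm),
            )
            rank += 1
    return out


# ---------------------------------------------------------------------------
# nutrient mixture


def _sample_nutrients(rng: np.random.Generator, treat_like: bool) -> tuple[NutrientValues, float]:
    """One draw from a two-component nutrient mixture.

    "Treat-like" products (confectionery, fast food) run high in energy,
    saturated fat, sugars and sodium with negligible fruit/veg/nut content;
    "staple-like" products are moderate with substantial FVN. Values are
    per 100 g.
    """
    if treat_like:
        profile = NutrientValues(
            energy_kj_per_100=max(0.0, rng.normal(1800, 400)),
            satfat_g_per_100=max(0.0, rng.normal(9, 4)),
            total_sugars_g_per_100=max(0.0, rng.normal(30, 12)),
            sodium_mg_per_100=max(0.0, rng.normal(500, 250)),
            fibre_g_per_100=max(0.0, rng.normal(1.0, 0.8)),
            protein_g_per_100=max(0.0, rng.normal(5, 3)),
            fibre_basis="AOAC",
        )
        fvn = float(np.clip(rng.normal(2, 5), 0, 100))
    else:
        profile = NutrientValues(
            energy_kj_per_100=max(0.0, rng.normal(350, 150)),
            satfat_g_per_100=max(0.0, rng.normal(0.5, 0.4)),
            total_sugars_g_per_100=max(0.0, rng.normal(3.5, 2.0)),
            sodium_mg_per_100=max(0.0, rng.normal(70, 40)),
            fibre_g_per_100=max(0.0, rng.normal(2.5, 1.2)),
            protein_g_per_100=max(0.0, rng.normal(3.5, 2.0)),
            fibre_basis="AOAC",
        )
        fvn = float(np.clip(rng.normal(55, 25), 0, 100))
    return profile, fvn


#: extreme profiles guaranteed on each side of the NPM verdict, used when
#: rejection sampling fails to land on the intended side
_FORCED_HFSS = NutrientValues(
    energy_kj_per_100=3400, satfat_g_per_100=20, total_sugars_g_per_100=50,
    sodium_mg_per_100=1000, fibre_g_per_100=0, protein_g_per_100=0,
)
_FORCED_PASS = NutrientValues(
    energy_kj_per_100=100, satfat_g_per_100=0, total_sugars_g_per_100=1,
    sodium_mg_per_100=10, fibre_g_per_100=5, protein_g_per_100=2,
)


def _draw_profile(
    rng: np.random.Generator, want_hfss: bool, product_class: str, max_tries: int = 60
) -> tuple[NutrientValues, float]:
    """Rejection-tuned nutrient draw whose NPM verdict matches the target,
    so the realised HFSS share among assessable products is exactly the
    configured Bernoulli fraction."""
    for _ in range(max_tries):
        profile, fvn = _sample_nutrients(rng, treat_like=want_hfss)
        if npm_score(profile, product_class, fvn).is_hfss == want_hfss:
            return profile, fvn
    return (_FORCED_HFSS, 0.0) if want_hfss else (_FORCED_PASS, 100.0)


# ---------------------------------------------------------------------------
# main generator


def generate_audit(config: GeneratorConfig) -> AuditDataset:
    """Generate a full validated audit dataset under the configuration."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tm = BNG
    neighbourhoods = _grid_neighbourhoods(cfg, tm)
    metric_polys = {a: to_metric(nb.geometry, tm) for a, nb in neighbourhoods.items()}

    type_labels = list(cfg.asset_type_mix)
    type_probs = np.array([cfg.asset_type_mix[t] for t in type_labels])
    cat_probs = np.asarray(cfg.product_category_mix, dtype=float)

    assets: dict[str, Asset] = {}
    images: dict[str, ImageRecord] = {}
    adverts: dict[str, Advert] = {}
    products: dict[str, Product] = {}
    counters = {"asset": 0, "image": 0, "advert": 0, "product": 0}

    def _next(kind: str) -> str:
        counters[kind] += 1
        return f"{kind[0].upper()}{counters[kind]:05d}"

    for area_id, nb in neighbourhoods.items():
        q = nb.imd_quintile
        mean_per_area = cfg.asset_intensity[q - 1] / cfg.n_areas_per_quintile
        n_assets = rng.poisson(mean_per_area)
        poly_m = metric_polys[area_id]
        minx, miny, maxx, maxy = poly_m.bounds

        # quintile-enriched product mix: scale food + non-alcoholic shares,
        # renormalise over the remaining groups
        enrich = cfg.food_enrichment[q - 1]
        mix = cat_probs.copy()
        mix[0] *= enrich
        mix[1] *= enrich
        mix = mix / mix.sum()

        for _ in range(n_assets):
            # uniform point in the polygon, then metric jitter (may cross
            # the boundary, as smartphone GPS error does)
            while True:
                x = rng.uniform(minx, maxx)
                y = rng.uniform(miny, maxy)
                if poly_m.covers(Point(x, y)):
                    break
            if cfg.coordinate_jitter_m > 0:
                x += rng.normal(0, cfg.coordinate_jitter_m)
                y += rng.normal(0, cfg.coordinate_jitter_m)
            lon, lat = tm.inverse(x, y)

            atype = type_labels[rng.choice(len(type_labels), p=type_probs)]
            if atype in LARGE_ONLY_ASSET_TYPES:
                size = "large"
            else:
                size = ("small", "medium", "large")[rng.choice(3, p=[0.30, 0.60, 0.10])]
            asset_id = _next("asset")
            assets[asset_id] = Asset(
                asset_id=asset_id, asset_type=atype, size_class=size,
                management_company=None, lon=lon, lat=lat, area_id=area_id,
            )

            n_images = 1 + rng.binomial(1, 0.2)
            for _ in range(n_images):
                has_gps = rng.random() >= cfg.missing_gps_rate
                image_id = _next("image")
                images[image_id] = ImageRecord(
                    image_id=image_id,
                    capture_date="2023-05-15",
                    area_id=area_id,
                    lon=lon if has_gps else None,
                    lat=lat if has_gps else None,
                    asset_id=asset_id,
                    coord_provenance="exif" if has_gps else None,
                )

            n_adverts = 1
            if atype in MULTI_ADVERT_TYPES:
                n_adverts += rng.poisson(cfg.extra_adverts_mean)
            for _ in range(n_adverts):
                advert_id = _next("advert")
                n_products = 1 + rng.poisson(cfg.extra_products_mean)
                cats = [PRODUCT_TYPES[rng.choice(len(PRODUCT_TYPES), p=mix)]
                        for _ in range(n_products)]
                is_food_drink = any(c in ("food", "non_alcoholic_beverage") for c in cats)
                brand_only = is_food_drink and rng.random() < cfg.brand_only_rate
                pids: list[str] = []
                if not brand_only:
                    for cat in cats:
                        pid = _next("product")
                        nutrients = None
                        fvn: Optional[float] = None
                        if cat in ("food", "non_alcoholic_beverage"):
                            if rng.random() >= cfg.missing_nutrition_rate:
                                want_hfss = rng.random() < cfg.hfss_fraction
                                cls = "drink" if cat == "non_alcoholic_beverage" else "food"
                                nutrients, fvn = _draw_profile(rng, want_hfss, cls)
                        products[pid] = Product(
                            product_id=pid,
                            product_type=cat,
                            name=f"{cat} item {pid}",
                            nutrients_per_100=nutrients,
                            fvn_percent=fvn,
                            price=round(float(rng.uniform(1, 20)), 2),
                        )
                        pids.append(pid)
                adverts[advert_id] = Advert(
                    advert_id=advert_id,
                    asset_id=asset_id,
                    brand=f"Brand{rng.integers(1, 60):02d}",
                    brand_only=brand_only,
                    product_ids=pids,
                )

    return AuditDataset(
        neighbourhoods=neighbourhoods,
        images=images,
        assets=assets,
        adverts=adverts,
        products=products,
        asset_types=DEFAULT_ASSET_TYPES,
    )


# ---------------------------------------------------------------------------
# dual coding


def generate_dual_coding(
    labels: Sequence[str] | AuditDataset,
    agreement: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired rater labels for reliability analysis.

    Rater 1's labels are taken as truth (asset types of the dataset's
    adverts when given a dataset, otherwise the provided label sequence);
    rater 2's label for an item with true label L is drawn from the
    confusion kernel row ``agreement[L]``. The kernel must be row
    stochastic. Expected observed agreement equals the kernel's mean
    diagonal mass over the realised label distribution.
    """
    if isinstance(labels, AuditDataset):
        ds = labels
        truth = [ds.assets[ad.asset_id].asset_type for ad in ds.adverts.values()]
    else:
        truth = list(labels)
    kernel = pd.DataFrame(agreement).T if not isinstance(agreement, pd.DataFrame) else agreement
    if not np.allclose(kernel.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("confusion kernel rows must each sum to 1")
    if (kernel.to_numpy() < 0).any():
        raise ValueError("confusion kernel entries must be non-negative")
    rng = np.random.default_rng(seed)
    cols = list(kernel.columns)
    rater2 = []
    for lab in truth:
        row = kernel.loc[lab].to_numpy(dtype=float)
        rater2.append(cols[rng.choice(len(cols), p=row)])
    return pd.DataFrame(
        {"item_id": [f"item{i:05d}" for i in range(len(truth))],
         "rater1": truth, "rater2": rater2}
    )


def identity_kernel(labels: Sequence[str]) -> pd.DataFrame:
    """Perfect-agreement confusion kernel over the given labels."""
    labels = list(dict.fromkeys(labels))
    return pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)


def uniform_kernel(labels: Sequence[str]) -> pd.DataFrame:
    """Chance-level kernel: rater 2 uniform regardless of truth."""
    labels = list(dict.fromkeys(labels))
    k = len(labels)
    return pd.DataFrame(np.full((k, k), 1.0 / k), index=labels, columns=labels)


# ---------------------------------------------------------------------------
# boundary fixtures


def generate_boundary_fixture(
    polygon: Polygon,
    n_inside: int,
    n_edge: int,
    offsets_m: Sequence[float],
    seed: int = 0,
    tm: TransverseMercator = BNG,
    interior_margin_m: float = 1.0,
) -> pd.DataFrame:
    """Asset points constructed at known distances from a boundary.

    Emits ``n_inside`` strictly interior lon/lat points (at least
    ``interior_margin_m`` metres inside), plus ``n_edge`` points exactly
    ``d`` metres outside the boundary for each positive offset ``d``
    (placed on the exterior ring of the polygon dilated by ``d`` in the
    projected plane). Columns: lon, lat, offset_m (0 for interior points).
    """
    if polygon is None or polygon.is_empty or not polygon.is_valid:
        raise ValueError("degenerate polygon")
    if any(d <= 0 for d in offsets_m):
        raise ValueError("offsets must be positive")
    rng = np.random.default_rng(seed)
    poly_m = to_metric(polygon, tm)
    core = poly_m.buffer(-interior_margin_m)
    if core.is_empty:
        raise ValueError("polygon too small for the interior margin")
    minx, miny, maxx, maxy = core.bounds
    rows = []
    n_drawn = 0
    while n_drawn < n_inside:
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if core.covers(Point(x, y)):
            lon, lat = tm.inverse(x, y)
            rows.append({"lon": lon, "lat": lat, "offset_m": 0.0})
            n_drawn += 1
    for d in offsets_m:
        ring = poly_m.buffer(d, quad_segs=64).exterior
        for _ in range(n_edge):
            pt = ring.interpolate(rng.uniform(0, ring.length))
            lon, lat = tm.inverse(pt.x, pt.y)
            rows.append({"lon": lon, "lat": lat, "offset_m": float(d)})
    return pd.DataFrame(rows, columns=["lon", "lat", "offset_m"])
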