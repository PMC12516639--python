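"""Four-level audit data hierarchy: images, assets, adverts, products.

The coding scheme mirrors a street-audit of outdoor advertising. A physical
*asset* (bus shelter, billboard, totem, ...) sits in a *neighbourhood* (an
LSOA-like areal unit carrying an Index of Multiple Deprivation rank and
quintile), is documented by one or more geo-located *images*, and hosts one
or more *adverts*; each advert shows zero or more *products* classified into
five groups (food, non-alcoholic beverage, alcoholic beverage, gambling,
other).

Tables are exchanged as plain CSV (one row per entity, a link table for the
advert–product relation) plus a GeoJSON FeatureCollection for neighbourhood
polygons, so datasets survive a write/load round trip field-for-field.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "DEFAULT_ASSET_TYPES",
    "LARGE_ONLY_ASSET_TYPES",
    "PRODUCT_TYPES",
    "FOOD_DRINK_TYPES",
    "SIZE_CLASSES",
    "Neighbourhood",
    "ImageRecord",
    "Asset",
    "Advert",
    "Product",
    "NutrientValues",
    "AuditDataset",
    "AuditValidationError",
    "load_audit",
    "write_audit",
    "count_hierarchy",
    "product_type_set",
]

#: Asset-type labels recoverable from the audit's published results. The
#: eligible list has fourteen entries but only eleven labels are public;
#: further labels are declared by passing ``extra_asset_types`` to the
#: dataset constructor / loader rather than invented here.
DEFAULT_ASSET_TYPES: tuple[str, ...] = (
    "bus shelter",
    "billboard",
    "totem",
    "electronic free-standing display",
    "non-electronic free-standing display",
    "litter/recycling bin",
    "smart bench",
    "other transport hub",
    "large hoarding",
    "phone box",
    "other",
)

#: Asset types that are by definition large-format.
LARGE_ONLY_ASSET_TYPES = frozenset({"billboard", "large hoarding"})

PRODUCT_TYPES: tuple[str, ...] = (
    "food",
    "non_alcoholic_beverage",
    "alcoholic_beverage",
    "gambling",
    "other",
)

#: Product groups that make an advert a "food and drink" advert. Alcohol and
#: gambling are harmful-commodity groups but sit outside this count.
FOOD_DRINK_TYPES = frozenset({"food", "non_alcoholic_beverage"})

SIZE_CLASSES: tuple[str, ...] = ("small", "medium", "large")


class AuditValidationError(ValueError):
    """Raised when a dataset violates the audit coding scheme."""


class Neighbourhood(BaseModel):
    """An LSOA-like areal unit with deprivation attributes and a polygon."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    area_id: str
    imd_rank: int = Field(gt=0)
    imd_quintile: int = Field(ge=1, le=5)
    ward_id: str
    area_km2: float = Field(ge=0.0, default=0.0)
    network_km: float = Field(ge=0.0, default=0.0)
    geometry: Optional[BaseGeometry] = None

    @field_validator("geometry")
    @classmethod
    def _valid_polygon(cls, geom: Optional[BaseGeometry]) -> Optional[BaseGeometry]:
        if geom is not None and not geom.is_valid:
            raise ValueError("neighbourhood geometry must be a valid polygon")
        return geom

    def __eq__(self, other: object) -> bool:  # geometry needs .equals()
        if not isinstance(other, Neighbourhood):
            return NotImplemented
        a = self.model_dump(exclude={"geometry"})
        b = other.model_dump(exclude={"geometry"})
        if a != b:
            return False
        if self.geometry is None or other.geometry is None:
            return self.geometry is other.geometry
        return self.geometry.equals(other.geometry)

    __hash__ = None  # type: ignore[assignment]


class ImageRecord(BaseModel):
    """A geo-tagged photograph documenting one asset."""

    image_id: str
    capture_date: Optional[str] = None
    area_id: str
    lon: Optional[float] = None
    lat: Optional[float] = None
    asset_id: str
    #: where the coordinate came from: exif | sibling_asset | manual | None
    coord_provenance: Optional[str] = None

    @model_validator(mode="after")
    def _paired_coords(self) -> "ImageRecord":
        if (self.lon is None) != (self.lat is None):
            raise ValueError("lon and lat must be both present or both absent")
        return self


class Asset(BaseModel):
    """A physical advertising structure hosting one or more adverts."""

    asset_id: str
    asset_type: str
    size_class: str
    management_company: Optional[str] = None
    lon: Optional[float] = None
    lat: Optional[float] = None
    area_id: str

    @field_validator("size_class")
    @classmethod
    def _known_size(cls, v: str) -> str:
        if v not in SIZE_CLASSES:
            raise ValueError(f"unknown size_class {v!r}; expected one of {SIZE_CLASSES}")
        return v

    @model_validator(mode="after")
    def _large_formats_are_large(self) -> "Asset":
        if self.asset_type in LARGE_ONLY_ASSET_TYPES and self.size_class != "large":
            raise ValueError(
                f"{self.asset_type!r} assets are large-format; got size_class={self.size_class!r}"
            )
        return self


class NutrientValues(BaseModel):
    """Per-100 g (or per-100 ml) nutrient declaration used for NPM scoring."""

    energy_kj_per_100: float = Field(ge=0.0)
    satfat_g_per_100: float = Field(ge=0.0)
    total_sugars_g_per_100: float = Field(ge=0.0)
    sodium_mg_per_100: float = Field(ge=0.0)
    fibre_g_per_100: float = Field(ge=0.0, default=0.0)
    fibre_basis: str = "AOAC"
    protein_g_per_100: float = Field(ge=0.0, default=0.0)

    @field_validator("fibre_basis")
    @classmethod
    def _basis(cls, v: str) -> str:
        v = v.upper()
        if v not in ("NSP", "AOAC"):
            raise ValueError("fibre_basis must be 'NSP' or 'AOAC'")
        return v


class Product(BaseModel):
    """One food or drink item (or other commodity) shown on an advert."""

    product_id: str
    product_type: str
    name: str = ""
    nutrients_per_100: Optional[NutrientValues] = None
    portion_weight_g: Optional[float] = Field(default=None, gt=0)
    fvn_percent: Optional[float] = Field(default=None, ge=0.0, le=100.0)
    price: Optional[float] = None

    @field_validator("product_type")
    @classmethod
    def _known_type(cls, v: str) -> str:
        if v not in PRODUCT_TYPES:
            raise ValueError(f"unknown product_type {v!r}; expected one of {PRODUCT_TYPES}")
        return v


class Advert(BaseModel):
    """One creative displayed on an asset.

    ``brand_only`` flags food/drink brand imagery with no product shown; it
    is an input coding decision, never inferred from the product list.
    """

    advert_id: str
    asset_id: str
    brand: str = ""
    brand_only: bool = False
    product_ids: list[str] = Field(default_factory=list)


class AuditDataset(BaseModel):
    """Keyed collections for the four-level hierarchy with referential links."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    neighbourhoods: dict[str, Neighbourhood] = Field(default_factory=dict)
    images: dict[str, ImageRecord] = Field(default_factory=dict)
    assets: dict[str, Asset] = Field(default_factory=dict)
    adverts: dict[str, Advert] = Field(default_factory=dict)
    products: dict[str, Product] = Field(default_factory=dict)
    asset_types: tuple[str, ...] = DEFAULT_ASSET_TYPES

    @model_validator(mode="after")
    def _referential_integrity(self) -> "AuditDataset":
        validate_dataset(self)
        return self

    def advert_products(self, advert: Advert) -> list[Product]:
        return [self.products[pid] for pid in advert.product_ids]

    def adverts_on_asset(self, asset_id: str) -> list[Advert]:
        return [a for a in self.adverts.values() if a.asset_id == asset_id]


def validate_dataset(ds: AuditDataset) -> None:
    """Check every foreign key and enum label; raise naming the offender."""
    allowed_types = set(ds.asset_types)
    for asset in ds.assets.values():
        if asset.asset_type not in allowed_types:
            raise AuditValidationError(
                f"asset {asset.asset_id!r}: undeclared asset_type {asset.asset_type!r}"
            )
        if asset.area_id not in ds.neighbourhoods:
            raise AuditValidationError(
                f"asset {asset.asset_id!r} references unknown area {asset.area_id!r}"
            )
    for img in ds.images.values():
        if img.asset_id not in ds.assets:
            raise AuditValidationError(
                f"image {img.image_id!r} references unknown asset {img.asset_id!r}"
            )
    for advert in ds.adverts.values():
        if advert.asset_id not in ds.assets:
            raise AuditValidationError(
                f"advert {advert.advert_id!r} references unknown asset {advert.asset_id!r}"
            )
        for pid in advert.product_ids:
            if pid not in ds.products:
                raise AuditValidationError(
                    f"advert {advert.advert_id!r} references unknown product {pid!r}"
                )


def count_hierarchy(ds: AuditDataset) -> dict[str, int]:
    """Cardinalities of the three analysed levels of the hierarchy."""
    return {
        "n_assets": len(ds.assets),
        "n_adverts": len(ds.adverts),
        "n_products": len(ds.products),
    }


def product_type_set(advert: Advert, products: Mapping[str, Product]) -> set[str]:
    """Distinct product types on an advert.

    An advert featuring several products of the same type contributes that
    type once; an advert mixing types contributes each type once.
    """
    return {products[pid].product_type for pid in advert.product_ids}


# ---------------------------------------------------------------------------
# serialisation


_TABLE_FILES = {
    "images": "images.csv",
    "assets": "assets.csv",
    "adverts": "adverts.csv",
    "products": "products.csv",
    "advert_products": "advert_products.csv",
    "neighbourhoods": "neighbourhoods.geojson",
}

_NUTRIENT_COLS = [
    "energy_kj_per_100",
    "satfat_g_per_100",
    "total_sugars_g_per_100",
    "sodium_mg_per_100",
    "fibre_g_per_100",
    "protein_g_per_100",
]


def table_paths(directory: str | Path) -> dict[str, Path]:
    """Canonical per-table file locations inside ``directory``."""
    d = Path(directory)
    return {name: d / fname for name, fname in _TABLE_FILES.items()}


def _cell(v) -> object:
    return "" if v is None else v


def write_audit(ds: AuditDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset as CSV tables plus a neighbourhood GeoJSON."""
    paths = table_paths(directory)
    Path(directory).mkdir(parents=True, exist_ok=True)

    img_rows = [
        {
            "image_id": i.image_id,
            "capture_date": _cell(i.capture_date),
            "area_id": i.area_id,
            "lon": _cell(i.lon),
            "lat": _cell(i.lat),
            "asset_id": i.asset_id,
            "coord_provenance": _cell(i.coord_provenance),
        }
        for i in ds.images.values()
    ]
    pd.DataFrame(
        img_rows,
        columns=["image_id", "capture_date", "area_id", "lon", "lat", "asset_id", "coord_provenance"],
    ).to_csv(paths["images"], index=False)

    asset_rows = [
        {
            "asset_id": a.asset_id,
            "asset_type": a.asset_type,
            "size_class": a.size_class,
            "management_company": _cell(a.management_company),
            "lon": _cell(a.lon),
            "lat": _cell(a.lat),
            "area_id": a.area_id,
        }
        for a in ds.assets.values()
    ]
    pd.DataFrame(
        asset_rows,
        columns=["asset_id", "asset_type", "size_class", "management_company", "lon", "lat", "area_id"],
    ).to_csv(paths["assets"], index=False)

    advert_rows = [
        {
            "advert_id": a.advert_id,
            "asset_id": a.asset_id,
            "brand": a.brand,
            "brand_only": a.brand_only,
        }
        for a in ds.adverts.values()
    ]
    pd.DataFrame(
        advert_rows, columns=["advert_id", "asset_id", "brand", "brand_only"]
    ).to_csv(paths["adverts"], index=False)

    link_rows = [
        {"advert_id": a.advert_id, "product_id": pid}
        for a in ds.adverts.values()
        for pid in a.product_ids
    ]
    pd.DataFrame(link_rows, columns=["advert_id", "product_id"]).to_csv(
        paths["advert_products"], index=False
    )

    prod_rows = []
    for p in ds.products.values():
        row: dict[str, object] = {
            "product_id": p.product_id,
            "product_type": p.product_type,
            "name": p.name,
            "portion_weight_g": _cell(p.portion_weight_g),
            "fvn_percent": _cell(p.fvn_percent),
            "price": _cell(p.price),
            "fibre_basis": "",
        }
        for col in _NUTRIENT_COLS:
            row[col] = ""
        if p.nutrients_per_100 is not None:
            n = p.nutrients_per_100
            for col in _NUTRIENT_COLS:
                row[col] = getattr(n, col)
            row["fibre_basis"] = n.fibre_basis
        prod_rows.append(row)
    pd.DataFrame(
        prod_rows,
        columns=["product_id", "product_type", "name"]
        + _NUTRIENT_COLS
        + ["fibre_basis", "portion_weight_g", "fvn_percent", "price"],
    ).to_csv(paths["products"], index=False)

    features = []
    for nb in ds.neighbourhoods.values():
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "area_id": nb.area_id,
                    "imd_rank": nb.imd_rank,
                    "imd_quintile": nb.imd_quintile,
                    "ward_id": nb.ward_id,
                    "area_km2": nb.area_km2,
                    "network_km": nb.network_km,
                },
                "geometry": None if nb.geometry is None else shapely_mapping(nb.geometry),
            }
        )
    with open(paths["neighbourhoods"], "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
    return paths


def _opt_float(v) -> Optional[float]:
    if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def _opt_str(v) -> Optional[str]:
    if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
        return None
    return str(v)


def load_audit(
    paths: Mapping[str, str | Path] | str | Path,
    extra_asset_types: Iterable[str] = (),
) -> AuditDataset:
    """Load and validate an audit dataset from its CSV/GeoJSON tables.

    ``paths`` is either a directory holding the canonical file names or a
    mapping with keys ``images, assets, adverts, products, advert_products,
    neighbourhoods``. Unknown asset-type labels are rejected unless declared
    via ``extra_asset_types``.
    """
    if isinstance(paths, (str, Path)):
        paths = table_paths(paths)
    for name, p in paths.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"audit table {name!r} missing: {p}")

    with open(paths["neighbourhoods"], encoding="utf-8") as fh:
        fc = json.load(fh)
    neighbourhoods: dict[str, Neighbourhood] = {}
    for feat in fc.get("features", []):
        props = feat["properties"]
        geom = None if feat.get("geometry") is None else shapely_shape(feat["geometry"])
        nb = Neighbourhood(
            area_id=str(props["area_id"]),
            imd_rank=int(props["imd_rank"]),
            imd_quintile=int(props["imd_quintile"]),
            ward_id=str(props["ward_id"]),
            area_km2=float(props.get("area_km2", 0.0)),
            network_km=float(props.get("network_km", 0.0)),
            geometry=geom,
        )
        neighbourhoods[nb.area_id] = nb

    str_cols = {"dtype": str, "keep_default_na": False}

    df = pd.read_csv(paths["assets"], **str_cols)
    assets: dict[str, Asset] = {}
    for _, r in df.iterrows():
        a = Asset(
            asset_id=r["asset_id"],
            asset_type=r["asset_type"],
            size_class=r["size_class"],
            management_company=_opt_str(r["management_company"]),
            lon=_opt_float(r["lon"]),
            lat=_opt_float(r["lat"]),
            area_id=r["area_id"],
        )
        assets[a.asset_id] = a

    df = pd.read_csv(paths["images"], **str_cols)
    images: dict[str, ImageRecord] = {}
    for _, r in df.iterrows():
        img = ImageRecord(
            image_id=r["image_id"],
            capture_date=_opt_str(r["capture_date"]),
            area_id=r["area_id"],
            lon=_opt_float(r["lon"]),
            lat=_opt_float(r["lat"]),
            asset_id=r["asset_id"],
            coord_provenance=_opt_str(r.get("coord_provenance", "")),
        )
        images[img.image_id] = img

    links = pd.read_csv(paths["advert_products"], **str_cols)
    by_advert: dict[str, list[str]] = {}
    for _, r in links.iterrows():
        by_advert.setdefault(r["advert_id"], []).append(r["product_id"])

    df = pd.read_csv(paths["adverts"], **str_cols)
    adverts: dict[str, Advert] = {}
    for _, r in df.iterrows():
        ad = Advert(
            advert_id=r["advert_id"],
            asset_id=r["asset_id"],
            brand=r["brand"],
            brand_only=r["brand_only"] in ("True", "true", "1"),
            product_ids=by_advert.get(r["advert_id"], []),
        )
        adverts[ad.advert_id] = ad

    df = pd.read_csv(paths["products"], **str_cols)
    products: dict[str, Product] = {}
    for _, r in df.iterrows():
        nutrients = None
        if any(r[c] != "" for c in _NUTRIENT_COLS):
            nutrients = NutrientValues(
                energy_kj_per_100=float(r["energy_kj_per_100"] or 0.0),
                satfat_g_per_100=float(r["satfat_g_per_100"] or 0.0),
                total_sugars_g_per_100=float(r["total_sugars_g_per_100"] or 0.0),
                sodium_mg_per_100=float(r["sodium_mg_per_100"] or 0.0),
                fibre_g_per_100=float(r["fibre_g_per_100"] or 0.0),
                fibre_basis=r["fibre_basis"] or "AOAC",
                protein_g_per_100=float(r["protein_g_per_100"] or 0.0),
            )
        p = Product(
            product_id=r["product_id"],
            product_type=r["product_type"],
            name=r["name"],
            nutrients_per_100=nutrients,
            portion_weight_g=_opt_float(r["portion_weight_g"]),
            fvn_percent=_opt_float(r["fvn_percent"]),
            price=_opt_float(r["price"]),
        )
        products[p.product_id] = p

    try:
        return AuditDataset(
            neighbourhoods=neighbourhoods,
            images=images,
            assets=assets,
            adverts=adverts,
            products=products,
            asset_types=tuple(DEFAULT_ASSET_TYPES) + tuple(extra_asset_types),
        )
    except Exception as exc:  # pydantic wraps the validator error
        raise AuditValidationError(str(exc)) from exc
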