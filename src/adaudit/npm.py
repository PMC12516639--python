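"""UK 2004/05 Nutrient Profile Model (NPM) scoring.

The NPM assigns "A" points for energy, saturated fat, total sugars and
sodium (0-10 each, 0-40 total) and "C" points for fruit/vegetable/nut
content (FVN%, 0/1/2/5), fibre and protein (0-5 each). The total score is
A minus counted C components, with a protein cap: when A >= 11 and the FVN
component is below 5, protein points are not counted. A food scoring >= 4,
or a drink scoring >= 1, fails the model and is classed HFSS (high in fat,
salt and sugar).

Threshold tables are shipped as data (``data/npm_thresholds.json``), pinned
by a SHA-256 checksum so any divergence from the published guidance tables
is auditable rather than silent. Band edges are strict: a nutrient value
equal to a threshold scores in the band below. Inputs are banded unrounded.
Drinks declared per 100 ml are treated numerically as per 100 g.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

from .model import NutrientValues

__all__ = [
    "THRESHOLDS",
    "NpmResult",
    "FvnDerivation",
    "IngredientEntry",
    "a_points",
    "c_points",
    "npm_score",
    "derive_fvn_percent",
    "per_portion_to_per_100",
    "score_products_frame",
]

#: checksum of the shipped threshold table; verified at import time
_THRESHOLDS_SHA256 = "f359477e145452be197e32063e17130b8967796acc9327255c136ba71d65778b"


def _load_thresholds() -> dict:
    raw = resources.files("adaudit.data").joinpath("npm_thresholds.json").read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _THRESHOLDS_SHA256:
        raise RuntimeError(
            f"npm_thresholds.json checksum mismatch ({digest}); "
            "threshold table has diverged from its pinned revision"
        )
    return json.loads(raw)


THRESHOLDS = _load_thresholds()


def _band(value: float, thresholds: Sequence[float]) -> int:
    """Points for ``value`` under strictly-exceeded ascending thresholds."""
    if value < 0:
        raise ValueError(f"nutrient value must be non-negative, got {value}")
    pts = 0
    for t in thresholds:
        if value > t:
            pts += 1
        else:
            break
    return pts


@dataclass(frozen=True)
class NpmResult:
    """Full per-product scoring breakdown with the HFSS verdict."""

    a_components: dict[str, int]
    a_points: int
    c_components: dict[str, int]
    c_points: int
    protein_capped: bool
    total_score: int
    product_class: str  # "food" | "drink"
    is_hfss: bool


def a_points(profile: NutrientValues) -> tuple[dict[str, int], int]:
    """Per-component and total A points (energy, satfat, sugars, sodium)."""
    tab = THRESHOLDS["a_points"]
    comps = {
        "energy": _band(profile.energy_kj_per_100, tab["energy_kj_per_100"]),
        "satfat": _band(profile.satfat_g_per_100, tab["satfat_g_per_100"]),
        "sugars": _band(profile.total_sugars_g_per_100, tab["total_sugars_g_per_100"]),
        "sodium": _band(profile.sodium_mg_per_100, tab["sodium_mg_per_100"]),
    }
    return comps, sum(comps.values())


def c_points(profile: NutrientValues, fvn_percent: float = 0.0) -> tuple[dict[str, int], int]:
    """Per-component and total C points (FVN, fibre on its declared basis, protein)."""
    tab = THRESHOLDS["c_points"]
    fvn_tab = tab["fvn_percent"]
    fvn_pts = 0
    for t, p in zip(fvn_tab["thresholds"], fvn_tab["points"]):
        if fvn_percent > t:
            fvn_pts = p
    fibre_key = "fibre_nsp_g_per_100" if profile.fibre_basis == "NSP" else "fibre_aoac_g_per_100"
    comps = {
        "fvn": fvn_pts,
        "fibre": _band(profile.fibre_g_per_100, tab[fibre_key]),
        "protein": _band(profile.protein_g_per_100, tab["protein_g_per_100"]),
    }
    return comps, sum(comps.values())


def npm_score(
    profile: NutrientValues,
    product_class: str = "food",
    fvn_percent: float = 0.0,
) -> NpmResult:
    """Score a product and return the verdict.

    ``product_class`` is "food" or "drink" (drink threshold is stricter:
    any positive score fails).
    """
    if product_class not in ("food", "drink"):
        raise ValueError(f"product_class must be 'food' or 'drink', got {product_class!r}")
    a_comps, a_total = a_points(profile)
    c_comps, _ = c_points(profile, fvn_percent)
    cap = THRESHOLDS["protein_cap"]
    capped = (
        a_total >= cap["a_points_at_least"]
        and c_comps["fvn"] < cap["unless_fvn_points_at_least"]
    )
    counted_c = c_comps["fvn"] + c_comps["fibre"] + (0 if capped else c_comps["protein"])
    total = a_total - counted_c
    threshold = THRESHOLDS["hfss_threshold"][product_class]
    return NpmResult(
        a_components=a_comps,
        a_points=a_total,
        c_components=c_comps,
        c_points=counted_c,
        protein_capped=capped,
        total_score=total,
        product_class=product_class,
        is_hfss=total >= threshold,
    )


# ---------------------------------------------------------------------------
# FVN% derivation and per-portion conversion


@dataclass(frozen=True)
class IngredientEntry:
    name: str
    declared_percent: Optional[float] = None
    is_fvn: bool = False


@dataclass(frozen=True)
class FvnDerivation:
    fvn_percent: float
    provenance: str  # ingredients_sum | reference_match | assumed_zero


def derive_fvn_percent(
    ingredients: Optional[Sequence[IngredientEntry]] = None,
    lookup: Optional[Mapping[str, float]] = None,
    product_name: Optional[str] = None,
) -> FvnDerivation:
    """Derive fruit/vegetable/nut percentage with a provenance tag.

    Preference order: sum of declared percentages for FVN ingredients
    (clamped to 100, since composite-ingredient percentages can
    double-count); otherwise an exact-name match in a reference table;
    otherwise assume zero FVN content.
    """
    if ingredients:
        declared = [e.declared_percent for e in ingredients if e.is_fvn]
        if any(p is not None for p in declared):
            for e in ingredients:
                if e.declared_percent is not None and not 0 <= e.declared_percent <= 100:
                    raise ValueError(
                        f"ingredient {e.name!r} declares percent {e.declared_percent} outside [0, 100]"
                    )
            total = sum(p for p in declared if p is not None)
            return FvnDerivation(min(total, 100.0), "ingredients_sum")
    if lookup is not None and product_name is not None and product_name in lookup:
        return FvnDerivation(float(lookup[product_name]), "reference_match")
    return FvnDerivation(0.0, "assumed_zero")


def per_portion_to_per_100(
    nutrients_per_portion: Mapping[str, float],
    portion_weight_g: Optional[float],
    weight_source: str = "measured",
    fibre_basis: str = "AOAC",
) -> Optional[NutrientValues]:
    """Convert a per-portion declaration to per-100 g.

    ``weight_source`` is "measured" (a weighed sample), "handbook" (portion
    size reference) or "none"; with no weight source the product is not
    assessable and ``None`` is returned.
    """
    if weight_source not in ("measured", "handbook", "none"):
        raise ValueError(f"unknown weight_source {weight_source!r}")
    if weight_source == "none":
        return None
    if portion_weight_g is None or portion_weight_g <= 0:
        raise ValueError(f"portion weight must be positive, got {portion_weight_g}")
    f = 100.0 / portion_weight_g
    return NutrientValues(
        energy_kj_per_100=f * nutrients_per_portion.get("energy_kj", 0.0),
        satfat_g_per_100=f * nutrients_per_portion.get("satfat_g", 0.0),
        total_sugars_g_per_100=f * nutrients_per_portion.get("total_sugars_g", 0.0),
        sodium_mg_per_100=f * nutrients_per_portion.get("sodium_mg", 0.0),
        fibre_g_per_100=f * nutrients_per_portion.get("fibre_g", 0.0),
        protein_g_per_100=f * nutrients_per_portion.get("protein_g", 0.0),
        fibre_basis=fibre_basis,
    )


# ---------------------------------------------------------------------------
# batch scoring


def score_products_frame(products) -> "pd.DataFrame":  # noqa: F821
    """Score a product collection into an augmented table.

    ``products`` is an iterable of :class:`~adaudit.model.Product`. Food and
    non-alcoholic-beverage products with nutrient data are scored (drinks
    under the drink threshold); products lacking nutrition are flagged not
    assessable; other product groups are out of NPM scope.
    """
    import pandas as pd

    rows = []
    for p in products:
        row: dict[str, object] = {
            "product_id": p.product_id,
            "product_type": p.product_type,
            "assessable": False,
            "a_points": None,
            "c_points": None,
            "total_score": None,
            "protein_capped": None,
            "fvn_percent": p.fvn_percent,
            "fvn_provenance": None,
            "is_hfss": None,
        }
        if p.product_type in ("food", "non_alcoholic_beverage") and p.nutrients_per_100 is not None:
            if p.fvn_percent is None:
                fvn = derive_fvn_percent()
                row["fvn_percent"], row["fvn_provenance"] = fvn.fvn_percent, fvn.provenance
            else:
                row["fvn_provenance"] = "ingredients_sum"
            cls = "drink" if p.product_type == "non_alcoholic_beverage" else "food"
            res = npm_score(p.nutrients_per_100, cls, float(row["fvn_percent"]))
            row.update(
                assessable=True,
                a_points=res.a_points,
                c_points=res.c_points,
                total_score=res.total_score,
                protein_capped=res.protein_capped,
                is_hfss=res.is_hfss,
            )
        rows.append(row)
    cols = [
        "product_id", "product_type", "assessable", "a_points", "c_points",
        "total_score", "protein_capped", "fvn_percent", "fvn_provenance", "is_hfss",
    ]
    return pd.DataFrame(rows, columns=cols)
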