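"""Advert classification against a hypothetical Healthier Food Advertising
Policy (HFAP), modelled on the Transport for London restrictions.

An advert showing at least one food or non-alcoholic beverage product (or
food/drink brand-only imagery) is in HFAP scope. It "would be
non-compliant" if any of its products is HFSS under the Nutrient Profile
Model, or if it is brand-only. If no assessed product is HFSS but some
food/drink product lacks the data to be scored, the advert is not
assessable; an assessed HFSS product always overrides missing data.
Alcohol and gambling adverts sit outside HFAP scope and receive no verdict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .model import FOOD_DRINK_TYPES, Advert, AuditDataset
from .stats import QUINTILES

__all__ = [
    "AdvertVerdict",
    "is_food_drink_advert",
    "classify_advert",
    "classify_dataset",
    "compliance_summary",
    "verdicts_to_frame",
]

STATUS_NON_COMPLIANT = "would_be_non_compliant"
STATUS_COMPLIANT = "compliant"
STATUS_NOT_ASSESSABLE = "not_assessable"


@dataclass(frozen=True)
class AdvertVerdict:
    advert_id: str
    status: str
    reason: str  # hfss_product | brand_only | all_assessable_pass | missing_data
    n_products_assessed: int
    n_products_missing: int


def is_food_drink_advert(advert: Advert, ds: AuditDataset) -> bool:
    """True iff the advert displays food or non-alcoholic drink (or is
    food/drink brand-only imagery). Alcohol alone does not qualify."""
    if advert.brand_only:
        return True
    return any(
        ds.products[pid].product_type in FOOD_DRINK_TYPES for pid in advert.product_ids
    )


def classify_advert(
    advert: Advert,
    ds: AuditDataset,
    product_hfss: Mapping[str, Optional[bool]],
) -> Optional[AdvertVerdict]:
    """HFAP verdict for one advert; None when out of scope.

    ``product_hfss`` maps product_id to True (HFSS), False (passes) or None
    (not assessable) for the advert's food/drink products. Precedence:
    brand-only, then any HFSS product, then any missing verdict, then
    compliant.
    """
    for pid in product_hfss:
        if pid not in advert.product_ids:
            raise ValueError(
                f"verdict supplied for product {pid!r} not on advert {advert.advert_id!r}"
            )
    if not is_food_drink_advert(advert, ds):
        return None
    fd_ids = [
        pid for pid in advert.product_ids if ds.products[pid].product_type in FOOD_DRINK_TYPES
    ]
    verdicts = {pid: product_hfss.get(pid) for pid in fd_ids}
    n_assessed = sum(1 for v in verdicts.values() if v is not None)
    n_missing = len(fd_ids) - n_assessed
    if advert.brand_only:
        return AdvertVerdict(advert.advert_id, STATUS_NON_COMPLIANT, "brand_only",
                             n_assessed, n_missing)
    if any(v is True for v in verdicts.values()):
        return AdvertVerdict(advert.advert_id, STATUS_NON_COMPLIANT, "hfss_product",
                             n_assessed, n_missing)
    if n_missing > 0:
        return AdvertVerdict(advert.advert_id, STATUS_NOT_ASSESSABLE, "missing_data",
                             n_assessed, n_missing)
    return AdvertVerdict(advert.advert_id, STATUS_COMPLIANT, "all_assessable_pass",
                         n_assessed, n_missing)


def classify_dataset(
    ds: AuditDataset, npm_frame: pd.DataFrame
) -> dict[str, AdvertVerdict]:
    """Classify every in-scope advert given a batch NPM scoring table.

    ``npm_frame`` is the output of
    :func:`adaudit.npm.score_products_frame` (columns product_id,
    assessable, is_hfss).
    """
    hfss_of: dict[str, Optional[bool]] = {}
    for _, r in npm_frame.iterrows():
        hfss_of[r["product_id"]] = bool(r["is_hfss"]) if r["assessable"] else None
    out: dict[str, AdvertVerdict] = {}
    for ad in ds.adverts.values():
        verdict = classify_advert(
            ad, ds, {pid: hfss_of.get(pid) for pid in ad.product_ids}
        )
        if verdict is not None:
            out[ad.advert_id] = verdict
    return out


def compliance_summary(
    ds: AuditDataset, verdicts: Mapping[str, AdvertVerdict]
) -> pd.DataFrame:
    """Per-quintile counts of compliant / non-compliant / not-assessable
    food and drink adverts; row sums equal the food/drink advert counts."""
    quintile_of_area = {a: nb.imd_quintile for a, nb in ds.neighbourhoods.items()}
    cols = [STATUS_COMPLIANT, STATUS_NON_COMPLIANT, STATUS_NOT_ASSESSABLE]
    tbl = pd.DataFrame(0, index=list(QUINTILES), columns=cols)
    for advert_id, v in verdicts.items():
        ad = ds.adverts[advert_id]
        q = quintile_of_area[ds.assets[ad.asset_id].area_id]
        tbl.loc[q, v.status] += 1
    tbl["total_food_drink"] = tbl[cols].sum(axis=1)
    return tbl


def verdicts_to_frame(verdicts: Mapping[str, AdvertVerdict]) -> pd.DataFrame:
    rows = [
        {
            "advert_id": v.advert_id,
            "status": v.status,
            "reason": v.reason,
            "n_products_assessed": v.n_products_assessed,
            "n_products_missing": v.n_products_missing,
        }
        for v in verdicts.values()
    ]
    return pd.DataFrame(
        rows,
        columns=["advert_id", "status", "reason", "n_products_assessed", "n_products_missing"],
    )
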