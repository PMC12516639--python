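"""Shared fixtures: tiny hand-built datasets and a study-scale fixture.

``study_counts_dataset`` reconstructs a dataset with exactly the marginal
counts the fieldwork reported (295 assets over quintiles 74/73/50/72/26,
68 bus shelters, 156 medium assets, 27 large assets in quintile 1, 437
adverts of which 72 food/drink, 67 advertised food products, 11
non-alcoholic and 23 alcoholic beverages) so the descriptive shares can be
recomputed arithmetically.
"""

from __future__ import annotations

import pytest

from adaudit.model import (
    Advert,
    Asset,
    AuditDataset,
    Neighbourhood,
    Product,
)


def make_neighbourhoods(n_per_quintile: int = 6) -> dict[str, Neighbourhood]:
    out = {}
    rank = 1
    for q in range(1, 6):
        for i in range(n_per_quintile):
            area_id = f"A{q}{i:02d}"
            out[area_id] = Neighbourhood(
                area_id=area_id, imd_rank=rank, imd_quintile=q, ward_id=f"W{q}{i:02d}"
            )
            rank += 1
    return out


def simple_dataset(advert_specs, neighbourhoods=None) -> AuditDataset:
    """Build a dataset from (advert_id, quintile, brand_only, [product types])."""
    neighbourhoods = neighbourhoods or make_neighbourhoods()
    area_of_q = {q: f"A{q}00" for q in range(1, 6)}
    assets, adverts, products = {}, {}, {}
    for k, (advert_id, q, brand_only, ptypes) in enumerate(advert_specs):
        asset_id = f"S{k:04d}"
        assets[asset_id] = Asset(
            asset_id=asset_id, asset_type="bus shelter", size_class="medium",
            area_id=area_of_q[q],
        )
        pids = []
        for j, pt in enumerate(ptypes):
            pid = f"P{k:04d}_{j}"
            products[pid] = Product(product_id=pid, product_type=pt, name=pt)
            pids.append(pid)
        adverts[advert_id] = Advert(
            advert_id=advert_id, asset_id=asset_id, brand="B",
            brand_only=brand_only, product_ids=pids,
        )
    return AuditDataset(
        neighbourhoods=neighbourhoods, assets=assets, adverts=adverts, products=products
    )


@pytest.fixture(scope="session")
def study_counts_dataset() -> AuditDataset:
    """Dataset reproducing the audit's printed marginal counts exactly."""
    neighbourhoods = make_neighbourhoods()
    # (quintile, asset_type, size_class, count)
    asset_plan = [
        (1, "billboard", "large", 27),
        (1, "bus shelter", "medium", 15),
        (1, "other", "small", 32),
        (2, "bus shelter", "medium", 15),
        (2, "non-electronic free-standing display", "medium", 39),
        (2, "other", "small", 19),
        (3, "bus shelter", "medium", 21),
        (3, "other", "small", 29),
        (4, "bus shelter", "medium", 15),
        (4, "electronic free-standing display", "medium", 3),
        (4, "totem", "medium", 30),
        (4, "other", "small", 24),
        (5, "bus shelter", "medium", 2),
        (5, "other", "medium", 16),
        (5, "other", "small", 8),
    ]
    assets: dict[str, Asset] = {}
    totem_ids = []
    i = 0
    for q, atype, size, count in asset_plan:
        for _ in range(count):
            asset_id = f"S{i:04d}"
            assets[asset_id] = Asset(
                asset_id=asset_id, asset_type=atype, size_class=size, area_id=f"A{q}00"
            )
            if atype == "totem":
                totem_ids.append(asset_id)
            i += 1
    assert len(assets) == 295

    # 437 adverts: one per asset plus 142 extra cycling over the totems
    adverts: dict[str, Advert] = {}
    host_assets = list(assets) + [totem_ids[k % len(totem_ids)] for k in range(142)]
    for j, asset_id in enumerate(host_assets):
        advert_id = f"D{j:04d}"
        adverts[advert_id] = Advert(advert_id=advert_id, asset_id=asset_id, brand="B")
    assert len(adverts) == 437

    # product plan over distinct adverts: 67 food (6 of which also show a
    # non-alcoholic drink), 5 drink-only, 23 alcohol, 342 "other"
    products: dict[str, Product] = {}
    advert_ids = sorted(adverts)

    def add_product(advert_id: str, ptype: str) -> None:
        pid = f"P{len(products):04d}"
        products[pid] = Product(product_id=pid, product_type=ptype, name=ptype)
        adverts[advert_id].product_ids.append(pid)

    for aid in advert_ids[:67]:
        add_product(aid, "food")
    for aid in advert_ids[:6]:
        add_product(aid, "non_alcoholic_beverage")
    for aid in advert_ids[67:72]:
        add_product(aid, "non_alcoholic_beverage")
    for aid in advert_ids[72:95]:
        add_product(aid, "alcoholic_beverage")
    for aid in advert_ids[95:]:
        add_product(aid, "other")
    assert len(advert_ids[95:]) == 342

    return AuditDataset(
        neighbourhoods=neighbourhoods, assets=assets, adverts=adverts, products=products
    )
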