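"""Coordinate imputation, boundary exclusion and buffer sensitivity.

Neighbourhood boundaries often run down the centre line of roads, so
fieldwork photographs legitimately capture assets whose GPS point falls
just outside the surveyed polygon. Assets outside the boundary are
excluded before analysis; sensitivity analyses re-run the exposure tables
with the boundary dilated by 5, 10 and 20 metre buffers.

Distances are metre-true: geometries are projected (British National Grid
parameters by default, see :mod:`adaudit.projection`) before any buffer or
distance computation. A point exactly on the boundary counts as inside
(signed distance 0, retained at every buffer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
from shapely.geometry import Point

from .model import Asset, AuditDataset, ImageRecord
from .projection import BNG, TransverseMercator, to_metric

__all__ = [
    "BufferPolicy",
    "FilterOutcome",
    "impute_coordinates",
    "filter_within_boundary",
    "apply_filter",
    "buffer_sensitivity",
    "outcomes_to_frame",
]


@dataclass(frozen=True)
class BufferPolicy:
    """Boundary dilation distances (metres) and the metric projection."""

    buffers_m: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0)
    projection: TransverseMercator = BNG

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.buffers_m):
            raise ValueError("buffers must be non-negative")
        if tuple(sorted(self.buffers_m)) != self.buffers_m:
            raise ValueError("buffers must be sorted ascending")
        if 0.0 not in self.buffers_m:
            raise ValueError("buffer list must include 0")


@dataclass(frozen=True)
class FilterOutcome:
    """Per-asset exclusion verdict across the buffer ladder."""

    asset_id: str
    area_id: str
    distance_to_boundary_m: float  # signed; negative = inside the polygon
    inside_at: Optional[float]  # smallest buffer retaining the asset; None = excluded
    retained: dict[float, bool] = field(default_factory=dict)


def impute_coordinates(
    images: Iterable[ImageRecord],
    manual_lookup: Optional[Mapping[str, tuple[float, float]]] = None,
) -> list[ImageRecord]:
    """Fill missing image coordinates: EXIF first, then another image of
    the same asset, then a manual lookup; residual gaps stay unresolved."""
    manual_lookup = manual_lookup or {}
    images = list(images)
    by_asset: dict[str, tuple[float, float]] = {}
    for img in images:
        if img.lon is not None and img.asset_id not in by_asset:
            by_asset[img.asset_id] = (img.lon, img.lat)
    out = []
    for img in images:
        if img.lon is not None:
            out.append(img.model_copy(update={"coord_provenance": img.coord_provenance or "exif"}))
        elif img.asset_id in by_asset:
            lon, lat = by_asset[img.asset_id]
            out.append(img.model_copy(update={"lon": lon, "lat": lat,
                                              "coord_provenance": "sibling_asset"}))
        elif img.image_id in manual_lookup:
            lon, lat = manual_lookup[img.image_id]
            out.append(img.model_copy(update={"lon": lon, "lat": lat,
                                              "coord_provenance": "manual"}))
        else:
            out.append(img.model_copy(update={"coord_provenance": None}))
    return out


def filter_within_boundary(
    assets: Iterable[Asset],
    area_polygons: Mapping[str, object],
    policy: BufferPolicy = BufferPolicy(),
) -> dict[str, FilterOutcome]:
    """Signed boundary distance and per-buffer retention for every asset.

    An asset is retained at buffer b when its point lies in its area's
    polygon dilated by b metres — equivalently, when its signed distance to
    the polygon is at most b. Retention is therefore monotone in b.
    """
    metric_polys = {}
    outcomes: dict[str, FilterOutcome] = {}
    for asset in assets:
        if asset.area_id not in area_polygons:
            raise ValueError(f"asset {asset.asset_id!r} references unknown area {asset.area_id!r}")
        if asset.lon is None or asset.lat is None:
            raise ValueError(f"asset {asset.asset_id!r} has no coordinates")
        if asset.area_id not in metric_polys:
            poly = area_polygons[asset.area_id]
            if poly is None or poly.is_empty or not poly.is_valid:
                raise ValueError(f"area {asset.area_id!r} has a degenerate polygon")
            metric_polys[asset.area_id] = to_metric(poly, policy.projection)
        poly_m = metric_polys[asset.area_id]
        e, n = policy.projection.forward(asset.lon, asset.lat)
        pt = Point(e, n)
        if poly_m.covers(pt):  # boundary counts as inside
            signed = -pt.distance(poly_m.boundary)
        else:
            signed = pt.distance(poly_m)
        retained = {b: signed <= b for b in policy.buffers_m}
        inside_at = next((b for b in policy.buffers_m if retained[b]), None)
        outcomes[asset.asset_id] = FilterOutcome(
            asset_id=asset.asset_id,
            area_id=asset.area_id,
            distance_to_boundary_m=float(signed),
            inside_at=inside_at,
            retained=retained,
        )
    return outcomes


def apply_filter(
    ds: AuditDataset, outcomes: Mapping[str, FilterOutcome], buffer_m: float = 0.0
) -> AuditDataset:
    """Dataset restricted to assets retained at the given buffer, with the
    dependent images, adverts and products dropped alongside."""
    keep_assets = {
        aid: a
        for aid, a in ds.assets.items()
        if outcomes[aid].retained.get(buffer_m, False)
    }
    keep_adverts = {aid: a for aid, a in ds.adverts.items() if a.asset_id in keep_assets}
    keep_pids = {pid for a in keep_adverts.values() for pid in a.product_ids}
    return AuditDataset(
        neighbourhoods=ds.neighbourhoods,
        images={i: im for i, im in ds.images.items() if im.asset_id in keep_assets},
        assets=keep_assets,
        adverts=keep_adverts,
        products={pid: p for pid, p in ds.products.items() if pid in keep_pids},
        asset_types=ds.asset_types,
    )


def buffer_sensitivity(
    ds: AuditDataset,
    policy: BufferPolicy = BufferPolicy(),
    verdicts=None,
) -> dict[float, dict[str, pd.DataFrame]]:
    """Exposure tables per buffer, for side-by-side sensitivity reading."""
    from .stats import exposure_tables

    polys = {a: nb.geometry for a, nb in ds.neighbourhoods.items()}
    outcomes = filter_within_boundary(ds.assets.values(), polys, policy)
    result = {}
    for b in policy.buffers_m:
        sub = apply_filter(ds, outcomes, b)
        sub_verdicts = (
            None
            if verdicts is None
            else {aid: v for aid, v in verdicts.items() if aid in sub.adverts}
        )
        result[b] = exposure_tables(sub, sub_verdicts)
    return result


def outcomes_to_frame(outcomes: Mapping[str, FilterOutcome]) -> pd.DataFrame:
    rows = []
    for o in outcomes.values():
        row = {
            "asset_id": o.asset_id,
            "area_id": o.area_id,
            "distance_to_boundary_m": o.distance_to_boundary_m,
            "inside_at": o.inside_at,
        }
        for b, kept in o.retained.items():
            row[f"retained_at_{b:g}m"] = kept
        rows.append(row)
    return pd.DataFrame(rows)
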