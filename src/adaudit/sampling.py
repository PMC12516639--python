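"""Two-step stratified area sampling and block-randomised visit order.

Neighbourhoods are ranked by the Index of Multiple Deprivation (rank 1 =
most deprived nationally), stratified into five quintiles, and six areas
per quintile are drawn — at most one per ward so the sample spreads across
the city. The most-deprived quintile is selected deterministically: the
lowest-ranked (most deprived) area within each designated priority ward.
Remaining quintiles are drawn uniformly at random without replacement
subject to the one-per-ward constraint. Fieldwork order is block
randomised so every weekly block mixes deprivation quintiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SamplePlan",
    "assign_quintiles",
    "select_sample",
    "block_randomise",
    "select_validation_subsample",
]


@dataclass
class SamplePlan:
    """Selected areas grouped by quintile, plus an optional visit order."""

    selected: dict[int, list[str]]  # quintile -> area_ids
    visit_order: list[tuple[int, str]] = field(default_factory=list)  # (block, area_id)

    @property
    def area_ids(self) -> list[str]:
        return [a for q in sorted(self.selected) for a in self.selected[q]]

    def to_frame(self) -> pd.DataFrame:
        """Plan as a flat table (area_id, quintile, block, order)."""
        block_of = {a: b for b, a in self.visit_order}
        order_of = {a: i for i, (_, a) in enumerate(self.visit_order)}
        rows = [
            {
                "area_id": a,
                "quintile": q,
                "block": block_of.get(a),
                "order": order_of.get(a),
            }
            for q in sorted(self.selected)
            for a in self.selected[q]
        ]
        return pd.DataFrame(rows, columns=["area_id", "quintile", "block", "order"])


def assign_quintiles(frame: pd.DataFrame, n_quantiles: int = 5) -> pd.DataFrame:
    """Stratify areas into deprivation quintiles by IMD rank order.

    Lowest ranks (most deprived) go to quintile 1. When the frame size is
    not divisible by five the larger groups sit at the most-deprived end
    (ceiling allocation first), a fixed documented rule.
    """
    if frame["imd_rank"].duplicated().any():
        raise ValueError("imd_rank values must be unique within the sampling frame")
    if (frame["imd_rank"] <= 0).any():
        raise ValueError("imd_rank values must be positive")
    n = len(frame)
    if n < n_quantiles:
        raise ValueError(f"need at least {n_quantiles} areas to form quintiles, got {n}")
    sizes = [
        (n + n_quantiles - 1 - i) // n_quantiles  # ceil for the first n % 5 groups
        for i in range(n_quantiles)
    ]
    out = frame.sort_values("imd_rank", kind="stable").reset_index(drop=True).copy()
    labels = np.repeat(np.arange(1, n_quantiles + 1), sizes)
    out["imd_quintile"] = labels
    return out


def _draw_one_per_ward(
    pool: pd.DataFrame, n: int, rng: np.random.Generator, max_attempts: int = 10_000
) -> list[str]:
    """Uniform draw of n areas, no two sharing a ward.

    Rejection sampling first (uniform over valid subsets conditional on
    acceptance), falling back to a randomised greedy/backtracking search if
    the cap is hit.
    """
    ids = pool["area_id"].to_numpy()
    wards = pool["ward_id"].to_numpy()
    if pool["ward_id"].nunique() < n:
        raise ValueError(
            f"infeasible one-per-ward constraint: {pool['ward_id'].nunique()} wards "
            f"for {n} required areas"
        )
    for _ in range(max_attempts):
        idx = rng.choice(len(ids), size=n, replace=False)
        if len({wards[i] for i in idx}) == n:
            return [ids[i] for i in idx]
    # backtracking: pick one area per randomly ordered distinct ward
    ward_order = rng.permutation(pool["ward_id"].unique())[:n]
    chosen = []
    for w in ward_order:
        cands = ids[wards == w]
        chosen.append(cands[rng.integers(len(cands))])
    return chosen


def select_sample(
    frame: pd.DataFrame,
    n_per_quintile: int = 6,
    priority_wards: set[str] | None = None,
    seed: int = 0,
) -> SamplePlan:
    """Select ``n_per_quintile`` areas per quintile, at most one per ward.

    ``frame`` must carry columns area_id, imd_rank, ward_id and
    imd_quintile (see :func:`assign_quintiles`). Quintile 1 is selected
    deterministically as the most deprived area within each priority ward;
    quintiles 2+ are uniform random draws under the ward constraint.
    """
    rng = np.random.default_rng(seed)
    selected: dict[int, list[str]] = {}
    quintiles = sorted(frame["imd_quintile"].unique())
    for q in quintiles:
        sub = frame[frame["imd_quintile"] == q]
        if q == 1 and priority_wards:
            if len(priority_wards) != n_per_quintile:
                raise ValueError(
                    f"expected {n_per_quintile} priority wards, got {len(priority_wards)}"
                )
            picks = []
            for w in sorted(priority_wards):
                in_ward = sub[sub["ward_id"] == w]
                if in_ward.empty:
                    raise ValueError(
                        f"infeasible selection in quintile 1: priority ward {w!r} "
                        "holds no quintile-1 area"
                    )
                picks.append(in_ward.loc[in_ward["imd_rank"].idxmin(), "area_id"])
            selected[q] = picks
        else:
            if len(sub) < n_per_quintile:
                raise ValueError(
                    f"infeasible selection in quintile {q}: only {len(sub)} areas available"
                )
            try:
                selected[q] = _draw_one_per_ward(sub, n_per_quintile, rng)
            except ValueError as exc:
                raise ValueError(f"infeasible selection in quintile {q}: {exc}") from exc
    return SamplePlan(selected=selected)


def block_randomise(plan: SamplePlan, n_blocks: int = 5, seed: int = 0) -> list[tuple[int, str]]:
    """Assign selected areas to visit blocks, mixing quintiles per block.

    Every block receives areas from every quintile whenever the block size
    allows it (blocks of six over five quintiles: each quintile once, one
    quintile twice). Blocks smaller than the number of quintiles cannot
    cover them all, so the coverage constraint relaxes to a seeded
    permutation. The within-block visit order is random.
    """
    rng = np.random.default_rng(seed)
    total = len(plan.area_ids)
    if total % n_blocks != 0:
        raise ValueError(f"{n_blocks} blocks do not evenly divide {total} areas")
    block_size = total // n_blocks
    quintiles = sorted(plan.selected)
    blocks: dict[int, list[str]] = {b: [] for b in range(1, n_blocks + 1)}

    if block_size >= len(quintiles):
        leftovers: list[str] = []
        for q in quintiles:
            areas = list(plan.selected[q])
            if len(areas) < n_blocks:
                raise ValueError(
                    f"quintile {q} has {len(areas)} areas; cannot cover {n_blocks} blocks"
                )
            order = rng.permutation(len(areas))
            for b, i in enumerate(order[:n_blocks], start=1):
                blocks[b].append(areas[i])
            leftovers.extend(areas[i] for i in order[n_blocks:])
        # deal remaining areas into blocks with spare capacity, randomly
        rng.shuffle(leftovers)
        open_blocks = [b for b in blocks for _ in range(block_size - len(blocks[b]))]
        rng.shuffle(open_blocks)
        for area, b in zip(leftovers, open_blocks):
            blocks[b].append(area)
    else:
        order = rng.permutation(plan.area_ids)
        for i, area in enumerate(order):
            blocks[i // block_size + 1].append(area)

    visit_order: list[tuple[int, str]] = []
    for b in sorted(blocks):
        within = list(blocks[b])
        rng.shuffle(within)
        visit_order.extend((b, a) for a in within)
    plan.visit_order = visit_order
    return visit_order


def select_validation_subsample(
    plan: SamplePlan, fraction: float = 0.10, seed: int = 0
) -> list[str]:
    """Uniform subsample of areas revisited for reliability checking."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    ids = plan.area_ids
    k = math.ceil(fraction * len(ids))
    picks = rng.choice(len(ids), size=k, replace=False)
    return [ids[i] for i in sorted(picks)]
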