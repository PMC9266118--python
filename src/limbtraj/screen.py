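"""Monotone maturation-marker screen along LSC → LPC → differentiating LPC.

Only clusters from the unwounded condition enter the screen: expression
during wound healing can be transient and stage-specific, so it cannot serve
as a homeostatic maturation marker.  A gene passes when its cell-count-
weighted stage means increase by at least ``min_ratio`` per step (low in the
putative LSCs, medium in the LPCs, high in the differentiating LPCs);
passing genes are ranked by the fold difference between the trajectory
endpoints, and the top N are selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import ClusterProfile

STAGES = ("LSC", "LPC", "differentiating_LPC")


class ScreenError(ValueError):
    pass


@dataclass
class StageGrouping:
    """Ordered stage → unwounded cluster ids."""

    stages: dict[str, set[str]]          # keys: LSC, LPC, differentiating_LPC

    def __post_init__(self) -> None:
        for s in STAGES:
            if s not in self.stages or not self.stages[s]:
                raise ScreenError(f"stage {s!r} is empty")
        all_ids = [c for s in STAGES for c in self.stages[s]]
        if len(set(all_ids)) != len(all_ids):
            raise ScreenError("stages must be disjoint")

    @classmethod
    def from_designations(cls, designations, cell_types) -> "StageGrouping":
        """Build the grouping from designation labels (unwounded members)."""
        members = {t.name: t for t in cell_types}
        stage_of = {
            "putative_quiescent_LSC": "LSC",
            "putative_active_LSC": "LSC",
            "putative_LPC": "LPC",
            "putative_differentiating_LPC": "differentiating_LPC",
        }
        stages: dict[str, set[str]] = {s: set() for s in STAGES}
        for d in designations:
            stage = stage_of.get(d.label)
            if stage is None:
                continue
            for cid in members[d.cell_type].clusters_in("unwounded"):
                stages[stage].add(cid)
        return cls(stages=stages)


@dataclass
class MaturationMarkerResult:
    gene: str
    stage_means: tuple[float, float, float]
    fold_difference: float
    rank: int
    selected: bool


def _stage_mean(
    profiles: dict[str, ClusterProfile], cluster_ids, gene_order, weighted: bool
) -> np.ndarray:
    members = [profiles[c] for c in sorted(cluster_ids)]
    mat = np.vstack([p.mean_expr.reindex(gene_order).fillna(0.0).to_numpy()
                     for p in members])
    if weighted:
        w = np.array([p.n_cells for p in members], dtype=float)
        return np.average(mat, axis=0, weights=w)
    return mat.mean(axis=0)


def screen_maturation_markers(
    profiles: list[ClusterProfile],
    grouping: StageGrouping,
    top_n: int = 10,
    min_ratio: float = 2.0,
    pseudocount: float = 0.01,
    weighted: bool = True,
) -> list[MaturationMarkerResult]:
    """Rank genes rising monotonically across the three maturation stages.

    A gene passes iff (mean_LPC + pc) >= min_ratio * (mean_LSC + pc) and
    (mean_diffLPC + pc) >= min_ratio * (mean_LPC + pc); its fold difference
    is (mean_diffLPC + pc) / (mean_LSC + pc).  Passing genes are ordered by
    fold descending (ties by gene symbol) and the top_n marked selected.
    """
    if top_n < 1:
        raise ScreenError("top_n must be >= 1")
    by_id = {p.cluster_id: p for p in profiles if p.condition == "unwounded"}
    missing = [
        c for s in STAGES for c in grouping.stages[s] if c not in by_id
    ]
    if missing:
        raise ScreenError(f"clusters missing from unwounded profiles: {missing}")
    gene_order = profiles[0].mean_expr.index
    means = {
        s: _stage_mean(by_id, grouping.stages[s], gene_order, weighted)
        for s in STAGES
    }
    lo = means["LSC"] + pseudocount
    mid = means["LPC"] + pseudocount
    hi = means["differentiating_LPC"] + pseudocount
    passing = (mid >= min_ratio * lo) & (hi >= min_ratio * mid)
    fold = hi / lo
    genes = np.asarray(gene_order)
    idx = np.flatnonzero(passing)
    order = sorted(idx, key=lambda i: (-fold[i], genes[i]))
    if top_n > len(order):
        warnings.warn(
            f"only {len(order)} genes pass the monotone screen; "
            f"selecting all of them (top_n={top_n})"
        )
    results = []
    for rank, i in enumerate(order, start=1):
        results.append(
            MaturationMarkerResult(
                gene=str(genes[i]),
                stage_means=(
                    float(means["LSC"][i]),
                    float(means["LPC"][i]),
                    float(means["differentiating_LPC"][i]),
                ),
                fold_difference=float(fold[i]),
                rank=rank,
                selected=rank <= top_n,
            )
        )
    return results


def screen_to_frame(results: list[MaturationMarkerResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "mean_LSC": [r.stage_means[0] for r in results],
            "mean_LPC": [r.stage_means[1] for r in results],
            "mean_differentiating_LPC": [r.stage_means[2] for r in results],
            "fold_difference": [r.fold_difference for r in results],
            "rank": [r.rank for r in results],
            "selected": [r.selected for r in results],
        }
    )
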