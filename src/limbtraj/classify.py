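"""Epithelial segregation, differentiation scoring and cell-type designation.

Clusters are segregated into epithelium and non-epithelium by cytokeratin
panel expression; non-epithelial clusters are typed as stromal, T-cell or
macrophage by lineage-panel z-scores.  Epithelial cell types receive a
corneal differentiation score (1–3) from their mean Krt12 expression using
the naturally segregated ranges <0.9, 5.5–20 and >180, and a conjunctival
score (1–2) from Krt13 using <0.8 and >9 — means in counts-per-10k units.
Values falling in the gaps between the printed ranges are binned to the
nearest range boundary on the multiplicative (geometric-midpoint) scale.

Designation logic: the dendrogram branch that runs from truly
undifferentiated shared cell types (corneal and conjunctival score 1) to
partially differentiated ones is the differentiation trajectory; its
undifferentiated, progenitor-marker-high shared types are the putative
LSCs, split into *active* (epithelial share drops upon wounding) and
*quiescent* (it does not), and its medium-differentiated types are putative
LPCs.  Outside the trajectory branch, differentiated corneal types are
putative differentiating LPCs, conjunctival-score-2 types are putative
conjunctival progenitors, and undifferentiated types with intermediate
progenitor-marker expression are stem/progenitor cells of unknown origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cluster import ClusterProfile
from .config import (
    EPITHELIAL_PANEL,
    HEMATOPOIETIC_PANEL,
    MACROPHAGE_PANEL,
    PROGENITOR_PANEL,
    PROLIFERATION_PANEL,
    STROMAL_PANEL,
    T_CELL_PANEL,
)
from .trajectory import BranchAssignment, CellType, leaf_label


class ClassifyError(ValueError):
    pass


@dataclass
class MarkerPanels:
    """Gene panels driving segregation, typing and flagging.

    Genes absent from a matrix contribute zero expression.
    """

    epithelial: tuple[str, ...] = EPITHELIAL_PANEL
    stromal: tuple[str, ...] = STROMAL_PANEL
    t_cell: tuple[str, ...] = T_CELL_PANEL
    macrophage: tuple[str, ...] = MACROPHAGE_PANEL
    progenitor: tuple[str, ...] = PROGENITOR_PANEL
    proliferation: tuple[str, ...] = PROLIFERATION_PANEL
    hematopoietic: tuple[str, ...] = HEMATOPOIETIC_PANEL

    def __post_init__(self) -> None:
        for name in ("epithelial", "stromal", "t_cell", "macrophage",
                     "progenitor", "proliferation"):
            if not getattr(self, name):
                raise ClassifyError(f"empty panel {name!r}")

    @classmethod
    def from_yaml(cls, path) -> "MarkerPanels":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**{k: tuple(v) for k, v in d.items()})


def _panel_means(profile: ClusterProfile, panel) -> np.ndarray:
    return profile.mean_expr.reindex(list(panel)).fillna(0.0).to_numpy()


def segregate_epithelial(
    profiles: list[ClusterProfile],
    panels: MarkerPanels | None = None,
    threshold: float = 1.0,
) -> dict[str, bool]:
    """Flag a cluster epithelial iff any cytokeratin-panel mean >= threshold.

    The max (not mean) over the panel is used: a single strongly expressed
    cytokeratin suffices to mark an epithelial identity.  Returns a map
    keyed by profile label; also sets ``profile.epithelial``.
    """
    if not profiles:
        raise ClassifyError("no profiles")
    panels = panels or MarkerPanels()
    flags = {}
    for p in profiles:
        flag = bool(_panel_means(p, panels.epithelial).max() >= threshold)
        p.epithelial = flag
        flags[p.label] = flag
    return flags


def _panel_zscores(
    profiles: list[ClusterProfile], panel
) -> np.ndarray:
    """Per-gene z-scores across profiles, averaged over the panel: one score
    per profile.  Zero-variance genes contribute z = 0."""
    mat = np.vstack([_panel_means(p, panel) for p in profiles])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)
    z = np.where(sd > 0, (mat - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return z.mean(axis=1)


def type_non_epithelial(
    profile: ClusterProfile,
    profiles: list[ClusterProfile],
    panels: MarkerPanels | None = None,
    margin: float = 0.5,
) -> str:
    """Type one non-epithelial cluster as stromal / t_cell / macrophage.

    Argmax over lineage-panel z-scores (z per gene across *all* profiles);
    ``unresolved`` when the best score does not exceed the runner-up by
    ``margin``.
    """
    panels = panels or MarkerPanels()
    if profile.epithelial:
        raise ClassifyError(f"{profile.label} is flagged epithelial")
    idx = [p.label for p in profiles].index(profile.label)
    scores = {
        "stromal": _panel_zscores(profiles, panels.stromal)[idx],
        "t_cell": _panel_zscores(profiles, panels.t_cell)[idx],
        "macrophage": _panel_zscores(profiles, panels.macrophage)[idx],
    }
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if ranked[0][1] - ranked[1][1] < margin:
        return "unresolved"
    return ranked[0][0]


# ------------------------------------------------------- differentiation

#: printed Krt12 ranges per score and the geometric midpoints of the gaps
_CORNEAL_EDGES = (math.sqrt(0.9 * 5.5), math.sqrt(20.0 * 180.0))   # ~2.22, 60.0
_CONJ_EDGE = math.sqrt(0.8 * 9.0)                                  # ~2.68


def corneal_diff_score(krt12_mean: float, gap_mode: str = "nearest") -> int:
    """Corneal differentiation score from mean Krt12 (counts-per-10k).

    1: <0.9, 2: 5.5–20, 3: >180.  In ``nearest`` mode, gap values are
    assigned by geometric midpoint (boundaries ~2.22 and 60.0); ``strict``
    mode raises on gap values.
    """
    m = _check_mean(krt12_mean)
    if m < 0.9:
        return 1
    if 5.5 <= m <= 20.0:
        return 2
    if m > 180.0:
        return 3
    if gap_mode == "strict":
        raise ClassifyError(f"Krt12 mean {m} falls outside the printed ranges")
    if m < _CORNEAL_EDGES[0]:
        return 1
    if m < _CORNEAL_EDGES[1]:
        return 2
    return 3


def conjunctival_diff_score(krt13_mean: float, gap_mode: str = "nearest") -> int:
    """Conjunctival differentiation score from mean Krt13: 1: <0.8, 2: >9."""
    m = _check_mean(krt13_mean)
    if m < 0.8:
        return 1
    if m > 9.0:
        return 2
    if gap_mode == "strict":
        raise ClassifyError(f"Krt13 mean {m} falls outside the printed ranges")
    return 1 if m < _CONJ_EDGE else 2


def _check_mean(m: float) -> float:
    m = float(m)
    if not math.isfinite(m) or m < 0:
        raise ClassifyError(f"marker mean must be finite and >= 0, got {m}")
    return m


@dataclass
class DifferentiationScore:
    corneal: int
    conjunctival: int
    krt12_mean: float
    krt13_mean: float


def score_cell_type(
    cell_type: CellType,
    profiles_by_label: dict[str, ClusterProfile],
    gap_mode: str = "nearest",
) -> DifferentiationScore:
    """Cell-count-weighted Krt12/Krt13 means over member clusters → scores."""
    members = [
        profiles_by_label[leaf_label(c, cond)] for c, cond in cell_type.member_clusters
    ]
    w = np.array([p.n_cells for p in members], dtype=float)
    k12 = float(np.average([p.mean_expr.get("Krt12", 0.0) for p in members], weights=w))
    k13 = float(np.average([p.mean_expr.get("Krt13", 0.0) for p in members], weights=w))
    return DifferentiationScore(
        corneal=corneal_diff_score(k12, gap_mode),
        conjunctival=conjunctival_diff_score(k13, gap_mode),
        krt12_mean=k12,
        krt13_mean=k13,
    )


# ------------------------------------------------------------ percentages

def epithelial_percentages(
    profiles: list[ClusterProfile],
    epithelial_flags: dict[str, bool],
    cell_types: list[CellType],
) -> dict[tuple[str, str], float]:
    """Share of epithelial cells per (cell type, condition).

    fraction = cells of the type's cluster(s) in that condition / all
    epithelial cells in that condition.  Per-condition fractions sum to 1.
    """
    by_label = {p.label: p for p in profiles}
    conditions = sorted({p.condition for p in profiles})
    totals = {
        cond: sum(
            p.n_cells
            for p in profiles
            if p.condition == cond and epithelial_flags.get(p.label, False)
        )
        for cond in conditions
    }
    out: dict[tuple[str, str], float] = {}
    for t in cell_types:
        for cond in conditions:
            n = sum(
                by_label[leaf_label(c, cc)].n_cells
                for c, cc in t.member_clusters
                if cc == cond
            )
            if n and totals[cond] == 0:
                raise ClassifyError(f"no epithelial cells in condition {cond}")
            out[(t.name, cond)] = n / totals[cond] if totals[cond] else 0.0
    return out


def flag_proliferative(
    profiles: list[ClusterProfile],
    panels: MarkerPanels | None = None,
    z_threshold: float = 1.0,
) -> dict[str, bool]:
    """Flag clusters with mean proliferation-panel z-score >= z_threshold.

    z-scores are per gene across profiles; requires >= 3 profiles.
    """
    if len(profiles) < 3:
        raise ClassifyError("need at least 3 profiles for z-scoring")
    panels = panels or MarkerPanels()
    z = _panel_zscores(profiles, panels.proliferation)
    return {p.label: bool(zi >= z_threshold) for p, zi in zip(profiles, z)}


# ------------------------------------------------------------ designation

LSC_LABELS = ("putative_quiescent_LSC", "putative_active_LSC")
EPITHELIAL_LABELS = LSC_LABELS + (
    "putative_LPC",
    "putative_differentiating_LPC",
    "putative_CjPC",
    "unknown_origin_SPC",
)


@dataclass
class Designation:
    """Biological label for one cell type plus its supporting quantities."""

    cell_type: str
    label: str
    branch: Optional[str]
    corneal_score: Optional[int] = None
    conjunctival_score: Optional[int] = None
    proliferative: bool = False
    epithelial_percentages: dict[str, float] = field(default_factory=dict)
    abundance_change: Optional[float] = None    # signed relative change
    progenitor_mean: Optional[float] = None
    trajectory_branch: bool = False


@dataclass
class DesignationConfig:
    delta: float = 0.25                 # relative decrease declaring "active"
    decrease_rule: str = "relative"     # or "ztest"
    ztest_alpha: float = 0.05
    gap_mode: str = "nearest"
    proliferation_z: float = 1.0
    epithelial_threshold: float = 1.0


def _relative_change(p_uw: float, p_wd: float) -> Optional[float]:
    if p_uw == 0:
        return None
    return (p_wd - p_uw) / p_uw


def _decreased(
    p_uw: float, p_wd: float, n_uw: int, n_wd: int, cfg: DesignationConfig
) -> bool:
    if cfg.decrease_rule == "ztest":
        from statsmodels.stats.proportion import proportions_ztest

        count = np.array([p_uw * n_uw, p_wd * n_wd])
        nobs = np.array([n_uw, n_wd])
        _, p = proportions_ztest(count, nobs, alternative="larger")
        return bool(p < cfg.ztest_alpha)
    change = _relative_change(p_uw, p_wd)
    return change is not None and change <= -cfg.delta


def designate(
    cell_types: list[CellType],
    profiles: list[ClusterProfile],
    branches: BranchAssignment,
    panels: MarkerPanels | None = None,
    config: DesignationConfig | None = None,
) -> list[Designation]:
    """Designate epithelial cell types along the differentiation trajectory.

    See the module docstring for the rule set.  Emits a warning-status
    designation list with LSC labels withheld when no trajectory branch
    exists.
    """
    panels = panels or MarkerPanels()
    config = config or DesignationConfig()
    by_label = {p.label: p for p in profiles}
    epithelial_flags = {p.label: bool(p.epithelial) for p in profiles}
    scores = {
        t.name: score_cell_type(t, by_label, config.gap_mode) for t in cell_types
    }
    percentages = epithelial_percentages(profiles, epithelial_flags, cell_types)
    prolif = flag_proliferative(profiles, panels, config.proliferation_z)

    def progenitor_mean(t: CellType) -> float:
        members = [by_label[leaf_label(c, cond)] for c, cond in t.member_clusters]
        w = np.array([p.n_cells for p in members], dtype=float)
        vals = [float(_panel_means(p, panels.progenitor).mean()) for p in members]
        return float(np.average(vals, weights=w))

    prog = {t.name: progenitor_mean(t) for t in cell_types}

    # a branch shows a differentiation trajectory iff it holds a truly
    # undifferentiated shared type (corneal AND conjunctival score 1) and a
    # partially differentiated type (corneal score >= 2)
    trajectory_branches: set[str] = set()
    for bid in branches.branches:
        members = [t for t in cell_types if t.branch == bid]
        has_anchor = any(
            t.presence == "shared"
            and scores[t.name].corneal == 1
            and scores[t.name].conjunctival == 1
            for t in members
        )
        has_diff = any(scores[t.name].corneal >= 2 for t in members)
        if has_anchor and has_diff:
            trajectory_branches.add(bid)

    # LSC eligibility: undifferentiated types above the median progenitor level
    undiff = [
        t
        for t in cell_types
        if scores[t.name].corneal == 1 and scores[t.name].conjunctival == 1
    ]
    prog_median = float(np.median([prog[t.name] for t in undiff])) if undiff else 0.0
    lsc_candidates = [
        t.name
        for t in undiff
        if t.branch in trajectory_branches
        and t.presence == "shared"
        and prog[t.name] >= prog_median
    ]
    lsc_min = min((prog[n] for n in lsc_candidates), default=np.inf)
    non_traj_diff_prog = [
        prog[t.name]
        for t in cell_types
        if t.branch not in trajectory_branches
        and (scores[t.name].corneal >= 2 or scores[t.name].conjunctival >= 2)
    ]
    diff_prog_max = max(non_traj_diff_prog, default=0.0)

    epi_totals = _epithelial_totals(profiles)
    out = []
    for t in cell_types:
        s = scores[t.name]
        p_uw = percentages.get((t.name, "unwounded"), 0.0)
        p_wd = percentages.get((t.name, "wounded"), 0.0)
        is_prolif = any(
            prolif.get(leaf_label(c, cond), False) for c, cond in t.member_clusters
        )
        label = "unclassified"
        if t.branch in trajectory_branches:
            if t.name in lsc_candidates:
                if _decreased(
                    p_uw, p_wd, epi_totals.get("unwounded", 0),
                    epi_totals.get("wounded", 0), config,
                ):
                    label = "putative_active_LSC"
                else:
                    label = "putative_quiescent_LSC"
            elif s.corneal >= 2:
                label = "putative_LPC"
            elif s.conjunctival == 2:
                label = "putative_CjPC"
        else:
            if s.conjunctival == 2:
                label = "putative_CjPC"
            elif s.corneal >= 2:
                label = "putative_differentiating_LPC"
            elif diff_prog_max < prog[t.name] < lsc_min:
                label = "unknown_origin_SPC"
        out.append(
            Designation(
                cell_type=t.name,
                label=label,
                branch=t.branch,
                corneal_score=s.corneal,
                conjunctival_score=s.conjunctival,
                proliferative=is_prolif,
                epithelial_percentages={"unwounded": p_uw, "wounded": p_wd},
                abundance_change=_relative_change(p_uw, p_wd),
                progenitor_mean=prog[t.name],
                trajectory_branch=t.branch in trajectory_branches,
            )
        )
    return out


def _epithelial_totals(profiles: list[ClusterProfile]) -> dict[str, int]:
    out: dict[str, int] = {}
    for p in profiles:
        if p.epithelial:
            out[p.condition] = out.get(p.condition, 0) + p.n_cells
    return out


def designations_to_frame(designations: list[Designation]) -> pd.DataFrame:
    rows = []
    for d in designations:
        rows.append(
            {
                "cell_type": d.cell_type,
                "label": d.label,
                "branch": d.branch,
                "corneal_score": d.corneal_score,
                "conjunctival_score": d.conjunctival_score,
                "proliferative": d.proliferative,
                "pct_unwounded": d.epithelial_percentages.get("unwounded"),
                "pct_wounded": d.epithelial_percentages.get("wounded"),
                "abundance_change": d.abundance_change,
                "progenitor_mean": d.progenitor_mean,
                "trajectory_branch": d.trajectory_branch,
            }
        )
    return pd.DataFrame(rows)
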