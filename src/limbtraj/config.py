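"""Simulation and pipeline configuration.

The default simulation emulates the composition of a two-condition
(unwounded vs wounded cornea) label-retaining-cell scRNA-seq experiment:
3136 cells in 11 clusters for the unwounded sample and 4967 cells in 12
clusters for the wounded sample, of which 8 clusters per condition are
epithelial.  Cluster identities, cross-condition pairings, dendrogram
branches and expected biological designations are planted as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

CONDITIONS = ("unwounded", "wounded")
LINEAGES = ("epithelial", "stromal", "t_cell", "macrophage")

#: lineage marker panels used both by the simulator (elevated means) and by
#: the classification stage (panel scoring).
EPITHELIAL_PANEL = ("Krt12", "Krt13", "Krt14", "Krt15", "Krt17", "Krt19")
STROMAL_PANEL = ("Col1a1", "Col1a2", "Dcn", "Cd34")
T_CELL_PANEL = ("Trdc", "Cd3g", "Trbc1")
MACROPHAGE_PANEL = ("Cxcl2", "Ccl4", "Cd14")
PROGENITOR_PANEL = ("Krt14", "Krt15")
PROLIFERATION_PANEL = ("Mki67", "Mcm2", "Mcm3", "Mcm4", "Mcm5", "Mcm6", "Mcm7")
HEMATOPOIETIC_PANEL = ("Cd34", "Cd44", "Cd14", "Cd19")


class ConfigError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass
class ClusterSpec:
    """Ground-truth description of one planted cell cluster.

    ``condition_proportions`` gives the fraction of *all* cells of each
    condition that belong to this cluster (0 = absent in that condition).
    ``marker_weights`` are per-10k relative expression weights of the
    cluster's characteristic marker genes (the units in which Seurat-style
    average expression values are printed).
    """

    name: str
    condition_proportions: dict[str, float]
    lineage: str
    corneal_stage: Optional[int] = None        # 1, 2, 3 or None
    conjunctival_stage: Optional[int] = None   # 1, 2 or None
    progenitor_level: float = 0.0              # Krt14/Krt15 weight
    proliferative: bool = False
    branch_label: str = ""
    paired_with: Optional[str] = None
    marker_weights: dict[str, float] = field(default_factory=dict)
    expected_designation: Optional[str] = None

    def present_in(self, condition: str) -> bool:
        return self.condition_proportions.get(condition, 0.0) > 0.0


@dataclass
class SimulationConfig:
    """Full description of the synthetic two-condition experiment."""

    seed: int = 42
    n_cells_per_condition: dict[str, int] = field(
        default_factory=lambda: {"unwounded": 3136, "wounded": 4967}
    )
    clusters: list[ClusterSpec] = field(default_factory=list)
    n_background_genes: int = 1800
    nb_dispersion: float = 10.0
    library_size_mean: float = 5000.0
    library_size_sigma: float = 0.25
    apoptotic_gene_count: int = 20
    maturation_gene_count: int = 9     # synthetic genes planted besides Krt12
    maturation_base_weight: float = 0.2
    maturation_fold_step: float = 20.0
    qc_fail_fraction: float = 0.05
    # per-10k weights realising the printed Krt12/Krt13 score ranges
    krt12_stage_weights: tuple[float, float, float] = (0.3, 12.0, 250.0)
    krt13_stage_weights: tuple[float, float] = (0.2, 15.0)
    baseline_epithelial_weights: dict[str, float] = field(
        default_factory=lambda: {"Krt17": 30.0, "Krt19": 20.0}
    )
    lineage_panel_weight: float = 40.0
    proliferation_weight: float = 25.0
    proliferation_baseline: float = 2.0
    apoptotic_weight: float = 1.0

    def validate(self) -> None:
        for cond in self.n_cells_per_condition:
            if cond not in CONDITIONS:
                raise ConfigError(f"unknown condition {cond!r}")
            if self.n_cells_per_condition[cond] <= 0:
                raise ConfigError(f"non-positive cell count for {cond!r}")
        if not self.clusters:
            raise ConfigError("no clusters declared")
        names = [c.name for c in self.clusters]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate cluster names")
        for cond in self.n_cells_per_condition:
            total = sum(c.condition_proportions.get(cond, 0.0) for c in self.clusters)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"cluster proportions for {cond!r} sum to {total!r}, not 1"
                )
        by_name = {c.name: c for c in self.clusters}
        for c in self.clusters:
            if c.lineage not in LINEAGES:
                raise ConfigError(f"{c.name}: unknown lineage {c.lineage!r}")
            if (c.lineage == "epithelial") != (c.corneal_stage is not None):
                raise ConfigError(
                    f"{c.name}: corneal_stage must be set iff lineage is epithelial"
                )
            if c.corneal_stage is not None and c.corneal_stage not in (1, 2, 3):
                raise ConfigError(f"{c.name}: corneal_stage must be 1, 2 or 3")
            if c.conjunctival_stage is not None and c.conjunctival_stage not in (1, 2):
                raise ConfigError(f"{c.name}: conjunctival_stage must be 1 or 2")
            if c.paired_with is not None:
                other = by_name.get(c.paired_with)
                if other is None:
                    raise ConfigError(f"{c.name}: unknown partner {c.paired_with!r}")
                if other.paired_with != c.name:
                    raise ConfigError(f"pairing {c.name}–{c.paired_with} not symmetric")
                same = [
                    cond
                    for cond in CONDITIONS
                    if c.present_in(cond) and other.present_in(cond)
                ]
                if same:
                    raise ConfigError(
                        f"pairing {c.name}–{c.paired_with} does not cross conditions"
                    )
        if self.maturation_fold_step <= 1:
            raise ConfigError("maturation_fold_step must exceed 1")
        for val, name in [
            (self.n_background_genes, "n_background_genes"),
            (self.nb_dispersion, "nb_dispersion"),
            (self.library_size_mean, "library_size_mean"),
        ]:
            if val <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.qc_fail_fraction < 1:
            raise ConfigError("qc_fail_fraction must be in [0, 1)")

    # ------------------------------------------------------------------ YAML
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["krt12_stage_weights"] = list(self.krt12_stage_weights)
        d["krt13_stage_weights"] = list(self.krt13_stage_weights)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["clusters"] = [ClusterSpec(**c) for c in d.get("clusters", [])]
        for key in ("krt12_stage_weights", "krt13_stage_weights"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _epithelial_cluster(
    name: str,
    cond: str,
    epi_fraction: float,
    stage: int,
    conj_stage: int,
    progenitor: float,
    branch: str,
    designation: str,
    markers: dict[str, float],
    paired_with: Optional[str] = None,
    proliferative: bool = False,
    epithelial_mass: float = 0.85,
) -> ClusterSpec:
    props = {c: 0.0 for c in CONDITIONS}
    props[cond] = epi_fraction * epithelial_mass
    return ClusterSpec(
        name=name,
        condition_proportions=props,
        lineage="epithelial",
        corneal_stage=stage,
        conjunctival_stage=conj_stage,
        progenitor_level=progenitor,
        proliferative=proliferative,
        branch_label=branch,
        paired_with=paired_with,
        marker_weights=markers,
        expected_designation=designation,
    )


def _non_epithelial_cluster(
    name: str, cond: str, fraction: float, lineage: str, markers: dict[str, float]
) -> ClusterSpec:
    props = {c: 0.0 for c in CONDITIONS}
    props[cond] = fraction
    return ClusterSpec(
        name=name,
        condition_proportions=props,
        lineage=lineage,
        branch_label="non_epithelial",
        marker_weights=markers,
        expected_designation=lineage,
    )


def _type_markers(tag: str, n: int = 3, weight: float = 25.0) -> dict[str, float]:
    return {f"Mkr{tag}{chr(ord('a') + i)}": weight for i in range(n)}


def default_config(seed: int = 42, n_scale: float = 1.0) -> SimulationConfig:
    """The study-condition configuration.

    ``n_scale`` scales cell counts only; composition, effect sizes and the
    planted structure are untouched (used for quick smoke runs).
    """
    # shared cell types carry identical marker sets in both conditions so
    # that paired clusters form dendrogram cherries; the two putative-LSC
    # types additionally carry their reported characteristic markers at the
    # printed average-expression values.
    spc = _type_markers("SPC")
    dlpc4 = {"Lypd2": 40.0, **_type_markers("DL4")}
    # conjunctival program beyond Krt13: mucosal keratins and mucin
    cjpc = {"Krt4": 30.0, "Krt6a": 25.0, "Muc4": 25.0, **_type_markers("CjP")}
    lsc1_uw = {"Edn2": 29.0, "Adm": 3.9, **_type_markers("Lsc1")}
    lsc1_w = {"Edn2": 13.0, "Adm": 1.0, **_type_markers("Lsc1")}
    lsc2_uw = {"Fmo2": 8.9, **_type_markers("Lsc2")}
    lsc2_w = {"Fmo2": 6.8, **_type_markers("Lsc2")}

    branch_sig = {
        b: {f"Br{b}Sig{i:02d}": 30.0 for i in range(12)} for b in ("1", "2", "3")
    }

    def epi(name, cond, frac, stage, conj, prog, branch, desig, markers,
            paired=None, prolif=False):
        m = dict(markers)
        m.update(branch_sig[branch])
        return _epithelial_cluster(
            name, cond, frac, stage, conj, prog, f"Branch{branch}", desig, m,
            paired_with=paired, proliferative=prolif,
        )

    clusters = [
        # ---- unwounded epithelium (fractions of epithelial cells)
        epi("EC1", "unwounded", 0.06, 1, 1, 20.0, "1", "unknown_origin_SPC",
            _type_markers("EC1")),
        epi("EC2", "unwounded", 0.10, 1, 1, 20.0, "1", "unknown_origin_SPC",
            spc, paired="EC9"),
        epi("EC3", "unwounded", 0.14, 3, 1, 5.0, "2",
            "putative_differentiating_LPC", dlpc4, paired="EC10"),
        epi("EC4", "unwounded", 0.10, 1, 2, 5.0, "2", "putative_CjPC",
            cjpc, paired="EC11"),
        epi("EC5", "unwounded", 0.12, 2, 1, 50.0, "3", "putative_LPC",
            _type_markers("LP1"), prolif=True),
        epi("EC6", "unwounded", 0.10, 2, 1, 50.0, "3", "putative_LPC",
            {"Ler5": 30.0, **_type_markers("LP2")}),
        epi("EC7", "unwounded", 0.18, 1, 1, 60.0, "3", "putative_quiescent_LSC",
            lsc1_uw, paired="EC15"),
        epi("EC8", "unwounded", 0.20, 1, 1, 60.0, "3", "putative_active_LSC",
            lsc2_uw, paired="EC16"),
        # ---- wounded epithelium
        epi("EC9", "wounded", 0.10, 1, 1, 20.0, "1", "unknown_origin_SPC",
            spc, paired="EC2"),
        epi("EC10", "wounded", 0.16, 3, 1, 5.0, "2",
            "putative_differentiating_LPC", dlpc4, paired="EC3"),
        epi("EC11", "wounded", 0.11, 1, 2, 5.0, "2", "putative_CjPC",
            cjpc, paired="EC4"),
        epi("EC12", "wounded", 0.10, 2, 1, 5.0, "2",
            "putative_differentiating_LPC", _type_markers("LP5")),
        epi("EC13", "wounded", 0.10, 2, 1, 5.0, "2",
            "putative_differentiating_LPC", _type_markers("LP6"), prolif=True),
        # wound-specific transient progenitor: a distinct Rdh10+ wound-response
        # program keeps it from pairing with the homeostatic LPC types
        epi("EC14", "wounded", 0.10, 2, 1, 50.0, "3", "putative_LPC",
            {"Rdh10": 30.0, **_type_markers("LP3", 7, 30.0)}),
        epi("EC15", "wounded", 0.22, 1, 1, 60.0, "3", "putative_quiescent_LSC",
            lsc1_w, paired="EC7"),
        epi("EC16", "wounded", 0.11, 1, 1, 60.0, "3", "putative_active_LSC",
            lsc2_w, paired="EC8"),
        # ---- non-epithelium (fractions of all cells; epithelium holds 0.85)
        _non_epithelial_cluster("NC1", "unwounded", 0.07, "stromal",
                                _type_markers("NC1")),
        _non_epithelial_cluster("NC2", "unwounded", 0.04, "t_cell",
                                _type_markers("NC2")),
        _non_epithelial_cluster("NC3", "unwounded", 0.04, "macrophage",
                                _type_markers("NC3")),
        _non_epithelial_cluster("NC4", "wounded", 0.05, "stromal",
                                _type_markers("NC4")),
        _non_epithelial_cluster("NC5", "wounded", 0.04, "t_cell",
                                _type_markers("NC5")),
        _non_epithelial_cluster("NC6", "wounded", 0.03, "macrophage",
                                _type_markers("NC6")),
        # Cd34-high stromal subtype (limbal niche fibroblasts), distinct from
        # the classic Col1a1/Dcn-high stromal cluster NC4
        _non_epithelial_cluster("NC7", "wounded", 0.03, "stromal",
                                {"Col1a1": 20.0, "Col1a2": 20.0, "Dcn": 5.0,
                                 "Cd34": 60.0, **_type_markers("NC7", 6, 30.0)}),
    ]
    cfg = SimulationConfig(
        seed=seed,
        n_cells_per_condition={
            "unwounded": max(2, round(3136 * n_scale)),
            "wounded": max(2, round(4967 * n_scale)),
        },
        clusters=clusters,
    )
    cfg.validate()
    return cfg
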