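"""Two-condition negative-binomial scRNA-seq simulator with planted truth.

Each cluster is a multinomial expression program: a vector of per-10k
relative weights over the gene universe (marker panels + planted maturation
genes + background).  A cell draws a log-normal library size L and, for each
gene, a Gamma-Poisson (negative binomial) count with mean L * w_g / W where
W is the cluster's total weight.  Because every cluster's W is pinned to the
same budget, a cluster's configured weight is (up to sampling noise) its
average counts-per-10k expression after library-size normalization — the
unit in which the downstream differentiation-score ranges are stated.

A configured fraction of cells per condition is emitted as QC-failing, via
one of three mechanisms matching the QC criteria: a shrunken library (low
counts), expression restricted to a small gene subset (low detected genes),
or a count mass shifted onto the apoptotic panel (high apoptotic fraction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .config import (
    CONDITIONS,
    EPITHELIAL_PANEL,
    MACROPHAGE_PANEL,
    PROLIFERATION_PANEL,
    STROMAL_PANEL,
    T_CELL_PANEL,
    ClusterSpec,
    ConfigError,
    SimulationConfig,
    default_config,
)
from .preprocess import CountMatrix, write_count_matrix

#: total per-cluster weight budget (per-10k scale)
WEIGHT_BUDGET = 1e4

QC_FAIL_MODES = ("low_counts", "low_genes", "high_apoptotic")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside the simulated matrices."""

    cell_to_cluster: dict[str, str]
    qc_fail_cells: dict[str, str]          # cell id -> failure mode
    planted_maturation_genes: list[str]
    pairing: dict[str, str]
    expected_designation: dict[str, str]
    cluster_condition: dict[str, str]
    cluster_branch: dict[str, str]
    cluster_lineage: dict[str, str]
    cluster_proliferative: dict[str, bool]
    epithelial_fractions: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def labels_for(self, cell_ids) -> list[str]:
        return [self.cell_to_cluster[c] for c in cell_ids]


def gene_universe(config: SimulationConfig) -> list[str]:
    """Ordered gene symbols: panels, characteristic markers, apoptotic panel,
    planted maturation genes, background."""
    genes: list[str] = []
    seen: set[str] = set()

    def add(gs):
        for g in gs:
            if g not in seen:
                seen.add(g)
                genes.append(g)

    add(EPITHELIAL_PANEL)
    add(STROMAL_PANEL)
    add(T_CELL_PANEL)
    add(MACROPHAGE_PANEL)
    add(PROLIFERATION_PANEL)
    add(("Cd44", "Cd19"))
    for c in config.clusters:
        add(sorted(c.marker_weights))
    add(apoptotic_panel(config))
    add(planted_maturation_genes(config))
    add(f"Bg{i:04d}" for i in range(1, config.n_background_genes + 1))
    return genes


def apoptotic_panel(config: SimulationConfig) -> list[str]:
    return [f"Apop{i:02d}" for i in range(1, config.apoptotic_gene_count + 1)]


def planted_maturation_genes(config: SimulationConfig) -> list[str]:
    """Krt12 (whose stage ladder realizes the printed score ranges) plus the
    synthetic monotone genes."""
    return ["Krt12"] + [f"Mat{i:02d}" for i in range(1, config.maturation_gene_count + 1)]


def cluster_weight_vector(
    config: SimulationConfig, spec: ClusterSpec, genes: list[str]
) -> np.ndarray:
    """Per-10k expression weights for one cluster, summing to WEIGHT_BUDGET."""
    idx = {g: i for i, g in enumerate(genes)}
    w = np.zeros(len(genes))

    def put(gene, val):
        w[idx[gene]] = val

    epithelial = spec.lineage == "epithelial"
    if epithelial:
        put("Krt12", config.krt12_stage_weights[spec.corneal_stage - 1])
        conj = spec.conjunctival_stage or 1
        put("Krt13", config.krt13_stage_weights[conj - 1])
        put("Krt14", spec.progenitor_level)
        put("Krt15", spec.progenitor_level)
        for g, v in config.baseline_epithelial_weights.items():
            put(g, v)
        base = config.maturation_base_weight
        step = config.maturation_fold_step
        stage_w = base * step ** (spec.corneal_stage - 1)
        for g in planted_maturation_genes(config)[1:]:
            put(g, stage_w)
    else:
        for g in planted_maturation_genes(config)[1:]:
            put(g, config.maturation_base_weight)
    panel = {
        "stromal": STROMAL_PANEL,
        "t_cell": T_CELL_PANEL,
        "macrophage": MACROPHAGE_PANEL,
    }.get(spec.lineage, ())
    for g in panel:
        put(g, config.lineage_panel_weight)
    # low but non-zero hematopoietic baseline everywhere it is not a lineage marker
    for g in ("Cd44", "Cd19"):
        put(g, 0.5)
    for g in ("Cd34", "Cd14"):
        if w[idx[g]] == 0:
            put(g, 0.5)
    prolif = config.proliferation_weight if spec.proliferative else config.proliferation_baseline
    for g in PROLIFERATION_PANEL:
        put(g, prolif)
    for g, v in spec.marker_weights.items():
        put(g, v)
    for g in apoptotic_panel(config):
        put(g, config.apoptotic_weight)
    # background absorbs the remaining budget so each cluster's weights are
    # directly on the per-10k normalized scale
    n_bg = config.n_background_genes
    used = w.sum()
    if used >= WEIGHT_BUDGET:
        raise ConfigError(
            f"{spec.name}: panel weights ({used:.0f}) exceed the per-10k budget"
        )
    bg_w = (WEIGHT_BUDGET - used) / n_bg
    for i in range(1, n_bg + 1):
        put(f"Bg{i:04d}", bg_w)
    return w


def _allocate_cluster_sizes(
    config: SimulationConfig, condition: str
) -> dict[str, int]:
    """Largest-remainder rounding of proportions to integer cell counts."""
    n = config.n_cells_per_condition[condition]
    present = [c for c in config.clusters if c.present_in(condition)]
    raw = np.array([c.condition_proportions[condition] for c in present])
    raw = raw / raw.sum()
    base = np.floor(raw * n).astype(int)
    rem = raw * n - base
    short = n - base.sum()
    for i in np.argsort(-rem)[:short]:
        base[i] += 1
    sizes = {c.name: int(k) for c, k in zip(present, base)}
    for name, k in sizes.items():
        if k == 0:
            raise ConfigError(
                f"cluster {name} declared present in {condition} but rounds to 0 cells"
            )
    return sizes


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson draw: Var = mu + mu^2 / theta."""
    lam = rng.gamma(theta, mu / theta)
    return rng.poisson(lam)


def _simulate_condition(
    config: SimulationConfig,
    condition: str,
    genes: list[str],
    weights: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[CountMatrix, dict[str, str], dict[str, str]]:
    sizes = _allocate_cluster_sizes(config, condition)
    gene_idx = {g: i for i, g in enumerate(genes)}
    apop_cols = np.array([gene_idx[g] for g in apoptotic_panel(config)], dtype=int)
    theta = config.nb_dispersion
    sigma = config.library_size_sigma
    log_mu = np.log(config.library_size_mean) - sigma**2 / 2

    blocks: list[np.ndarray] = []
    cluster_of: list[str] = []
    fail_mode: list[str | None] = []
    for name in sizes:  # config order; shuffled below
        k = sizes[name]
        p = weights[name] / weights[name].sum()
        n_fail = int(round(k * config.qc_fail_fraction))
        n_ok = k - n_fail
        lib = rng.lognormal(log_mu, sigma, size=k)
        mu = lib[:n_ok, None] * p[None, :]
        counts_ok = _nb_counts(rng, mu, theta)
        rows = [counts_ok]
        modes: list[str | None] = [None] * n_ok
        for j in range(n_fail):
            mode = QC_FAIL_MODES[j % len(QC_FAIL_MODES)]
            pj = p.copy()
            lj = lib[n_ok + j]
            if mode == "low_counts":
                lj *= 0.04
            elif mode == "low_genes":
                keep = rng.choice(len(p), size=80, replace=False, p=p)
                mask = np.zeros(len(p), dtype=bool)
                mask[keep] = True
                pj = np.where(mask, pj, 0.0)
                pj /= pj.sum()
            else:  # high_apoptotic
                pj *= 0.75 / pj.sum()
                pj[apop_cols] += 0.25 / len(apop_cols)
            rows.append(_nb_counts(rng, lj * pj[None, :], theta))
            modes.append(mode)
        blocks.append(np.vstack(rows))
        cluster_of.extend([name] * k)
        fail_mode.extend(modes)

    counts = np.vstack(blocks)
    order = rng.permutation(counts.shape[0])
    counts = counts[order]
    cluster_of = [cluster_of[i] for i in order]
    fail_mode = [fail_mode[i] for i in order]
    prefix = {"unwounded": "UW", "wounded": "WD"}[condition]
    cell_ids = [f"{prefix}-{i:05d}" for i in range(1, counts.shape[0] + 1)]
    m = CountMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=cell_ids,
        gene_symbols=list(genes),
        condition=condition,
    )
    cell_to_cluster = dict(zip(cell_ids, cluster_of))
    qc_fail = {c: mode for c, mode in zip(cell_ids, fail_mode) if mode}
    return m, cell_to_cluster, qc_fail


def generate_dataset(
    config: SimulationConfig | None = None,
) -> tuple[CountMatrix, CountMatrix, GroundTruth]:
    """Simulate the unwounded and wounded count matrices plus ground truth.

    The output is fully determined by ``config`` (including its seed).
    """
    if config is None:
        config = default_config()
    config.validate()
    genes = gene_universe(config)
    weights = {c.name: cluster_weight_vector(config, c, genes) for c in config.clusters}
    rng = np.random.default_rng(config.seed)
    matrices: dict[str, CountMatrix] = {}
    cell_to_cluster: dict[str, str] = {}
    qc_fail: dict[str, str] = {}
    for condition in CONDITIONS:
        if condition not in config.n_cells_per_condition:
            continue
        m, c2c, fails = _simulate_condition(config, condition, genes, weights, rng)
        matrices[condition] = m
        cell_to_cluster.update(c2c)
        qc_fail.update(fails)

    pairing = {
        c.name: c.paired_with for c in config.clusters if c.paired_with is not None
    }
    epi_fracs: dict[str, dict[str, float]] = {}
    for cond in matrices:
        epi = [c for c in config.clusters if c.lineage == "epithelial" and c.present_in(cond)]
        tot = sum(c.condition_proportions[cond] for c in epi)
        epi_fracs[cond] = {c.name: c.condition_proportions[cond] / tot for c in epi}
    truth = GroundTruth(
        cell_to_cluster=cell_to_cluster,
        qc_fail_cells=qc_fail,
        planted_maturation_genes=planted_maturation_genes(config),
        pairing=pairing,
        expected_designation={
            c.name: c.expected_designation
            for c in config.clusters
            if c.expected_designation
        },
        cluster_condition={
            c.name: next(cond for cond in CONDITIONS if c.present_in(cond))
            for c in config.clusters
        },
        cluster_branch={c.name: c.branch_label for c in config.clusters},
        cluster_lineage={c.name: c.lineage for c in config.clusters},
        cluster_proliferative={c.name: c.proliferative for c in config.clusters},
        epithelial_fractions=epi_fracs,
    )
    return matrices["unwounded"], matrices["wounded"], truth


def write_dataset(
    config: SimulationConfig, outdir, *, echo_config: bool = True
) -> GroundTruth:
    """Simulate and write MTX triplets per condition + ground truth JSON."""
    outdir = Path(outdir)
    uw, wd, truth = generate_dataset(config)
    write_count_matrix(uw, outdir / "unwounded")
    write_count_matrix(wd, outdir / "wounded")
    truth.to_json(outdir / "ground_truth.json")
    if echo_config:
        config.to_yaml(outdir / "config.yaml")
    return truth
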