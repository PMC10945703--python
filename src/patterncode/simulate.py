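"""Ground-truthed synthetic UMI count matrices for the early worm embryo.

The generator emulates the structure of a whole-embryo, multi-stage
CEL-Seq-style experiment on the invariant lineage: embryos are collected
at the canonical 1- to 102-cell stages with every cell of each embryo
profiled, early transcriptomes are dominated by a maternal deposit shared
across cells, zygotic state-specific programs switch on in defined sets
of cells, each embryo carries its own multiplicative batch signature, and
sequencing applies UMI (multinomial) sampling at a finite depth.

Expression model, per gene g and cell c of embryo e at stage s:

    E[x_gc]  ∝  base_g(s) · program_gc · batch_eg

* ``base_g(s)``: maternal genes draw a log-normal baseline that decays by
  a retention factor per stage step (the maternal deposit is degraded as
  development proceeds); zygotic genes sit at a small floor until
  switched on.
* ``program_gc``: a planted differentially expressed gene is shifted up
  by ``10**effect_size`` in the cells of its "on" states (effect sizes
  are therefore in log10 expression units).
* ``batch_eg = exp(N(0, embryo_effect_sd))``: per-embryo, per-gene
  log-normal batch factor — the confounder that per-embryo
  standardization must remove.

Counts are drawn by a single multinomial per cell at a Poisson-sampled
depth, so column sums equal the drawn depth exactly. A single seed
determines everything.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .lineage import CANONICAL_STAGES, LineageTree

#: embryos collected per stage by default: 38 embryos in total, early
#: stages sampled more deeply (cells are few), mirroring a whole-embryo
#: collection design of roughly 700-850 cells overall.
DEFAULT_EMBRYOS_PER_STAGE = {1: 6, 2: 6, 4: 6, 8: 5, 15: 5, 28: 4, 51: 3, 102: 3}

#: auto-generated TF family labels with relative repertoire weights;
#: loosely shaped like a DNA-binding-domain census (one dominant family,
#: homeodomain around a tenth of the repertoire).
DEFAULT_FAMILY_WEIGHTS = {
    "NHR": 0.28, "ZF-C2H2": 0.18, "HD": 0.11, "bHLH": 0.09, "bZIP": 0.07,
    "T-box": 0.05, "GATA": 0.04, "ETS": 0.04, "other": 0.14,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated experiment. See the module docstring
    for the expression model; all randomness flows from ``seed``."""

    stages: tuple[int, ...] = CANONICAL_STAGES
    n_embryos_per_stage: int | Mapping[int, int] | None = None
    n_genes: int = 5000
    n_tf_genes: int = 400
    family_table: Mapping[str, str] | None = None
    maternal_fraction: float = 0.4
    program_size: int = 10
    effect_size: float = 1.0          # log10 units
    embryo_effect_sd: float = 0.15    # sd of the ln-scale batch factor
    depth_mean: float = 20000.0       # mean UMIs per cell
    maternal_retention: float = 0.8   # per stage step
    baseline_sigma: float = 1.0       # ln-sd of maternal baselines
    zygotic_floor: float = 0.005      # off-state level, maternal units
    reads_per_umi: float = 3.0        # mapped_reads = depth * this
    equivalent_states: tuple[tuple[int, tuple[str, ...]], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not set(self.stages) <= set(CANONICAL_STAGES):
            raise ValueError(f"stages must be drawn from {CANONICAL_STAGES}")
        for frac in (self.maternal_fraction,):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.depth_mean <= 0 or self.n_genes <= 0:
            raise ValueError("depth_mean and n_genes must be positive")

    def embryos_at(self, stage: int) -> int:
        spec = self.n_embryos_per_stage
        if spec is None:
            return DEFAULT_EMBRYOS_PER_STAGE[stage]
        if isinstance(spec, int):
            return spec
        return spec[stage]


@dataclass
class SimTruth:
    """Ground truth of one simulation.

    ``programs`` maps each planted differentially expressed gene to its
    stage and "on" cell set — by construction the on-set lies within a
    single stage. ``family`` maps TF genes to their family label.
    """

    genes: list[str]
    maternal: dict[str, bool]
    baseline: dict[str, float]
    programs: dict[str, tuple[int, frozenset[str]]]
    family: dict[str, str]
    config: SimulationConfig = field(repr=False, default=None)

    def state_program(self, stage: int, cell: str) -> frozenset[str]:
        """Genes switched on in one (stage, cell) state."""
        return frozenset(
            g for g, (s, on) in self.programs.items() if s == stage and cell in on
        )

    def on_set_table(self, stage: int) -> dict[str, frozenset[str]]:
        """Planted gene -> on-set restricted to one stage."""
        return {g: on for g, (s, on) in self.programs.items() if s == stage}


# ----------------------------------------------------------------------
# truth construction
# ----------------------------------------------------------------------

def _auto_family_table(tf_genes: list[str], rng: np.random.Generator) -> dict[str, str]:
    fams = list(DEFAULT_FAMILY_WEIGHTS)
    w = np.array(list(DEFAULT_FAMILY_WEIGHTS.values()))
    draws = rng.choice(len(fams), size=len(tf_genes), p=w / w.sum())
    return {g: fams[i] for g, i in zip(tf_genes, draws)}


def build_truth(config: SimulationConfig, tree: LineageTree | None = None) -> SimTruth:
    """Draw gene roles, baselines, programs and TF families."""
    tree = tree or LineageTree.default()
    rng = np.random.default_rng(config.seed)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    n_maternal = int(round(config.maternal_fraction * config.n_genes))
    maternal = {g: i < n_maternal for i, g in enumerate(genes)}
    baseline = {}
    for g in genes:
        if maternal[g]:
            baseline[g] = float(rng.lognormal(0.0, config.baseline_sigma))
        else:
            baseline[g] = config.zygotic_floor

    # TF genes drawn preferentially from the zygotic pool (regulatory
    # programs are zygotic), topped up from maternal genes if needed
    zygotic = genes[n_maternal:]
    tf_pool = zygotic + genes[:n_maternal]
    n_tf = min(config.n_tf_genes, config.n_genes)
    tf_genes = sorted(rng.choice(tf_pool, size=n_tf, replace=False).tolist()) if n_tf else []
    family = (
        dict(config.family_table)
        if config.family_table is not None
        else _auto_family_table(tf_genes, rng)
    )

    programs: dict[str, tuple[int, frozenset[str]]] = {}
    if config.program_size > 0:
        equiv = {
            stage: [tuple(sorted(group)) for s2, group in config.equivalent_states if s2 == stage]
            for stage in config.stages
        }
        free = list(zygotic)
        rng.shuffle(free)
        for stage in sorted(config.stages):
            cells = sorted(tree.cells_at_stage(stage))
            grouped: dict[str, tuple[str, ...]] = {}
            for group in equiv[stage]:
                for c in group:
                    grouped[c] = group
            units: list[tuple[str, ...]] = []
            seen = set()
            for c in cells:
                unit = grouped.get(c, (c,))
                if unit not in seen:
                    units.append(unit)
                    seen.add(unit)
            need = config.program_size * len(units)
            if need > len(free):
                raise ValueError(
                    f"stage {stage}: need {need} program genes but only "
                    f"{len(free)} unassigned zygotic genes remain; increase "
                    "n_genes or lower program_size"
                )
            for unit in units:
                for _ in range(config.program_size):
                    g = free.pop()
                    programs[g] = (stage, frozenset(unit))

    return SimTruth(
        genes=genes, maternal=maternal, baseline=baseline,
        programs=programs, family=family, config=config,
    )


def plant_family_bias(
    truth: SimTruth,
    lineage: str,
    stage: int,
    family: str,
    excess: int,
    seed: int = 0,
    tree: LineageTree | None = None,
) -> SimTruth:
    """Add ``excess`` extra family-member genes to the programs of the
    (lineage, stage) states, uniformly at random — a test surface for the
    family-enrichment aggregation.

    Returns a new truth; the input is not modified. Counts must be
    re-synthesized afterwards (:func:`synthesize`).
    """
    if excess < 0:
        raise ValueError("excess must be non-negative")
    if family not in set(truth.family.values()):
        raise ValueError(f"family {family!r} not present in the family table")
    if excess == 0:
        return truth
    tree = tree or LineageTree.default()
    targets = sorted(
        c for c in tree.cells_at_stage(stage) if tree.founder_of(c) == lineage
    )
    if not targets:
        raise ValueError(f"no {lineage} cells at the {stage}-cell stage")
    candidates = sorted(
        g for g, fam in truth.family.items()
        if fam == family and not truth.maternal[g] and g not in truth.programs
    )
    if len(candidates) < excess:
        raise ValueError(
            f"only {len(candidates)} unused zygotic {family} genes available, "
            f"need {excess}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=excess, replace=False)
    out = copy.deepcopy(truth)
    for g in chosen:
        cell = targets[rng.integers(len(targets))]
        out.programs[g] = (stage, frozenset({cell}))
    return out


# ----------------------------------------------------------------------
# count synthesis
# ----------------------------------------------------------------------

def synthesize(
    truth: SimTruth,
    config: SimulationConfig | None = None,
    tree: LineageTree | None = None,
) -> ad.AnnData:
    """Draw the UMI count matrix implied by a truth object.

    Returns an AnnData with cells in ``obs`` (columns ``embryo_id``,
    ``stage``, ``true_state``, ``mapped_reads``) and genes in ``var``
    (columns ``maternal``, ``family``), ``X`` holding raw integer counts.
    """
    config = config or truth.config
    tree = tree or LineageTree.default()
    rng = np.random.default_rng(config.seed + 1)  # independent of truth draws

    genes = truth.genes
    gene_index = {g: i for i, g in enumerate(genes)}
    base = np.array([truth.baseline[g] for g in genes])
    is_maternal = np.array([truth.maternal[g] for g in genes])
    stage_rank = {s: r for r, s in enumerate(CANONICAL_STAGES)}
    effect = 10.0 ** config.effect_size

    obs_rows, columns = [], []
    for stage in sorted(config.stages):
        cells = sorted(tree.cells_at_stage(stage))
        decay = config.maternal_retention ** stage_rank[stage]
        stage_base = np.where(is_maternal, base * decay, base)
        # per-(stage,cell) program multiplier
        prog = {c: np.ones(len(genes)) for c in cells}
        for g, (s, on) in truth.programs.items():
            if s == stage:
                for c in on:
                    prog[c][gene_index[g]] = effect
        for e in range(config.embryos_at(stage)):
            embryo_id = f"E{stage}_{e}"
            if config.embryo_effect_sd > 0:
                batch = np.exp(rng.normal(0.0, config.embryo_effect_sd, len(genes)))
            else:
                batch = 1.0
            for c in cells:
                w = stage_base * prog[c] * batch
                p = w / w.sum()
                depth = max(1, int(rng.poisson(config.depth_mean)))
                counts = rng.multinomial(depth, p)
                columns.append(counts)
                obs_rows.append({
                    "cell_id": f"{embryo_id}_{c}",
                    "embryo_id": embryo_id,
                    "stage": stage,
                    "true_state": c,
                    "mapped_reads": int(round(depth * config.reads_per_umi)),
                })

    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    var = pd.DataFrame(
        {
            "maternal": [truth.maternal[g] for g in genes],
            "family": [truth.family.get(g, "") for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    X = np.vstack(columns).astype(np.int64)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["simulation"] = {"seed": config.seed, "stages": list(config.stages)}
    return adata


def simulate(
    config: SimulationConfig, tree: LineageTree | None = None
) -> tuple[ad.AnnData, SimTruth]:
    """Build a truth and draw counts from it in one call."""
    tree = tree or LineageTree.default()
    truth = build_truth(config, tree)
    return synthesize(truth, config, tree), truth


# ----------------------------------------------------------------------
# marker database derived from truth
# ----------------------------------------------------------------------

def markers_from_truth(
    truth: SimTruth,
    stage: int,
    n_on: int | None = None,
    n_off: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Derive a marker database (identity, gene, expected, note) for one
    stage from the planted programs: each state's program genes are its
    expected-on markers; expected-off markers are sampled from the other
    states' programs. States sharing a program yield identical marker
    sets and are therefore merged downstream into an equivalence group,
    as they would be for genuinely indistinguishable transcriptomes.
    """
    rng = np.random.default_rng(seed)
    on_sets = truth.on_set_table(stage)
    per_state: dict[str, set[str]] = {}
    for g, on in on_sets.items():
        for c in on:
            per_state.setdefault(c, set()).add(g)
    if not per_state:
        raise ValueError(f"no planted programs at the {stage}-cell stage")
    rows = []
    for state in sorted(per_state):
        on_genes = sorted(per_state[state])
        if n_on is not None:
            on_genes = on_genes[:n_on]
        others = sorted(set().union(*(per_state[s] for s in per_state if s != state))
                        - per_state[state])
        off_genes = (
            sorted(rng.choice(others, size=min(n_off, len(others)), replace=False))
            if others else []
        )
        for g in on_genes:
            rows.append((state, g, "on", "truth-derived"))
        for g in off_genes:
            rows.append((state, g, "off", "truth-derived"))
    return pd.DataFrame(rows, columns=["identity", "gene", "expected", "note"])


# ----------------------------------------------------------------------
# fixture IO
# ----------------------------------------------------------------------

def write_fixture(adata: ad.AnnData, truth: SimTruth, path) -> Path:
    """Write a simulation to disk as MTX + TSV sidecars.

    Layout: ``matrix.mtx`` (genes x cells, integer), ``genes.tsv``,
    ``cells.tsv`` (cell_id, embryo_id, stage, true_state, mapped_reads),
    ``truth_genes.tsv`` (gene, maternal, stage, on_states) and
    ``families.tsv`` (gene, family). Read-back is bit-exact for counts.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mat = scipy.sparse.csr_matrix(adata.X.T)  # genes x cells
    scipy.io.mmwrite(path / "matrix.mtx", mat, field="integer")
    adata.var.reset_index().to_csv(path / "genes.tsv", sep="\t", index=False)
    adata.obs.reset_index().to_csv(path / "cells.tsv", sep="\t", index=False)
    rows = []
    for g in truth.genes:
        if g in truth.programs:
            stage, on = truth.programs[g]
            rows.append((g, int(truth.maternal[g]), stage, ";".join(sorted(on))))
        else:
            rows.append((g, int(truth.maternal[g]), "", ""))
    pd.DataFrame(rows, columns=["gene", "maternal", "stage", "on_states"]).to_csv(
        path / "truth_genes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(truth.family.items()), columns=["gene", "family"]
    ).to_csv(path / "families.tsv", sep="\t", index=False)
    return path


def read_fixture(path) -> tuple[ad.AnnData, SimTruth]:
    """Inverse of :func:`write_fixture` (truth loses its config)."""
    path = Path(path)
    mat = scipy.io.mmread(path / "matrix.mtx").tocsr().T  # cells x genes
    genes = pd.read_csv(path / "genes.tsv", sep="\t").set_index("gene")
    cells = pd.read_csv(path / "cells.tsv", sep="\t").set_index("cell_id")
    adata = ad.AnnData(
        X=np.asarray(mat.todense()).astype(np.int64), obs=cells, var=genes
    )
    tg = pd.read_csv(path / "truth_genes.tsv", sep="\t", keep_default_na=False)
    fam = pd.read_csv(path / "families.tsv", sep="\t")
    programs = {}
    baseline = {}
    maternal = {}
    for row in tg.itertuples(index=False):
        maternal[row.gene] = bool(row.maternal)
        if row.on_states:
            programs[row.gene] = (int(row.stage), frozenset(str(row.on_states).split(";")))
    truth = SimTruth(
        genes=tg["gene"].tolist(), maternal=maternal, baseline=baseline,
        programs=programs, family=dict(zip(fam["gene"], fam["family"])),
        config=None,
    )
    return adata, truth


# ----------------------------------------------------------------------
# named study-condition configs
# ----------------------------------------------------------------------

def null_stage_config(seed: int = 0) -> SimulationConfig:
    """A fully null single-stage experiment: 8 states x 6 replicate cells
    (six whole embryos at the 8-cell stage), 2,000 maternal genes with no
    planted effects and no embryo batch effects. Depth is set so that a
    typical gene is detected in well under half the cells, keeping
    essentially the whole panel eligible for the differential test."""
    return SimulationConfig(
        stages=(8,), n_embryos_per_stage=6, n_genes=2000, n_tf_genes=0,
        maternal_fraction=1.0, program_size=0, effect_size=0.0,
        embryo_effect_sd=0.0, depth_mean=700.0, baseline_sigma=0.3,
        reads_per_umi=20.0, seed=seed,
    )


def recovery_config(seed: int = 0) -> SimulationConfig:
    """The parameter-recovery experiment: eight 15-cell embryos (eight
    replicate cells per state, matching a typical whole-embryo replicate
    depth), 20 planted genes per state at effect size 1.0 (a tenfold
    shift in log10 units), moderate embryo batch effects, against a
    background of 400 maternal genes and 200 unpatterned sparse zygotic
    genes — the latter keep the eligible panel realistic, since on real
    embryos most genes passing the sparseness filters are not patterned."""
    return SimulationConfig(
        stages=(15,), n_embryos_per_stage=8, n_genes=900, n_tf_genes=0,
        maternal_fraction=400 / 900, program_size=20, effect_size=1.0,
        embryo_effect_sd=0.15, depth_mean=20000.0, seed=seed,
    )
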