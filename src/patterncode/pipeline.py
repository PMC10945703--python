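"""End-to-end pipeline: configuration, input validation, per-stage
execution and output writing.

A run is described by one flat :class:`PipelineConfig` (serializable to
YAML; unknown keys are rejected). ``run_all`` executes
preprocess -> state inference -> differential expression -> family
enrichment -> stripe patterning for every requested stage, writes all
tables plus a structured log, and persists the resolved configuration
next to the outputs so a run can be reproduced bit-for-bit from its
output directory alone. A single seed governs every stochastic step.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from . import diffexp, enrichment, states, stripes
from .lineage import LineageTree, read_positions, synthetic_positions
from .preprocess import preprocess as run_preprocess
from .simulate import (
    SimulationConfig,
    markers_from_truth,
    read_fixture,
    simulate as run_simulation,
)

log = logging.getLogger("patterncode")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run, with the package defaults."""

    # inputs (None -> simulate per `simulation` below)
    counts: str | None = None
    markers: str | None = None
    tf_annotation: str | None = None
    positions: str | None = None
    lineage_table: str | None = None
    out_dir: str = "patterncode_out"
    # stage selection; None -> every stage present in the data
    stages: list[int] | None = None
    # module parameters
    min_reads: int = 10_000
    pseudocount: float = 1.0
    sd: str = "population"
    n_variable_genes: int = 1000
    dims: int = 20
    perplexity: float = 50.0
    shuffles: int = 10_000
    fdr: float = 0.01
    k_stripes: int = 8
    stripe_lineage: str = "AB"
    seed: int = 0
    # synthetic-data settings, used when `counts` is None
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    config: PipelineConfig, tree: LineageTree | None = None
) -> ValidationReport:
    """Schema and referential-integrity checks on every declared input.

    Errors are conditions the pipeline cannot run through (missing
    files, malformed tables, marker identities unknown to the lineage);
    warnings flag recoverable oddities (annotation genes absent from the
    counts).
    """
    tree = tree or LineageTree.default()
    report = ValidationReport()
    gene_names: set[str] = set()

    if config.counts is not None:
        path = Path(config.counts)
        if not path.exists():
            report.errors.append(f"counts path does not exist: {path}")
        else:
            try:
                adata = load_counts(path)
                gene_names = set(adata.var_names)
                missing = {"embryo_id", "stage", "mapped_reads"} - set(adata.obs)
                if missing:
                    report.errors.append(
                        f"cell metadata lacks columns {sorted(missing)}"
                    )
            except Exception as exc:  # malformed MTX/TSV
                report.errors.append(f"counts unreadable: {exc}")

    if config.markers is not None:
        try:
            db = states.MarkerDatabase.from_tsv(config.markers)
            for ident in db.identities():
                parts = ident.split("/")
                if not all(p in tree.nodes for p in parts):
                    report.errors.append(
                        f"marker identity {ident!r} not in the lineage"
                    )
            if gene_names:
                absent = [g for g in db.genes() if g not in gene_names]
                if absent:
                    report.warnings.append(
                        f"{len(absent)} marker genes absent from counts "
                        f"(e.g. {absent[:3]})"
                    )
        except Exception as exc:
            report.errors.append(f"marker table invalid: {exc}")

    if config.tf_annotation is not None:
        try:
            annot = enrichment.TFAnnotation.from_tsv(config.tf_annotation)
            if gene_names:
                absent = [g for g in annot.universe if g not in gene_names]
                if absent:
                    report.warnings.append(
                        f"{len(absent)} annotated TFs absent from counts"
                    )
        except Exception as exc:
            report.errors.append(f"TF annotation invalid: {exc}")

    if config.positions is not None:
        try:
            read_positions(config.positions)
        except Exception as exc:
            report.errors.append(f"position table invalid: {exc}")
    return report


# ----------------------------------------------------------------------
# input loading
# ----------------------------------------------------------------------

def load_counts(path) -> ad.AnnData:
    """Load a count matrix from a fixture directory (MTX + sidecars) or a
    single dense TSV (genes x cells, first column gene names, cell
    metadata rows embryo_id/stage/mapped_reads prefixed with '#')."""
    path = Path(path)
    if path.is_dir():
        adata, _ = read_fixture(path)
        return adata
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_rows = [r for r in df.index if str(r).startswith("#")]
    meta = df.loc[meta_rows].T
    meta.columns = [c.lstrip("#") for c in meta.columns]
    counts = df.drop(index=meta_rows).T
    obs = pd.DataFrame(index=counts.index)
    for col in ("embryo_id", "stage", "mapped_reads", "true_state"):
        if col in meta.columns:
            obs[col] = meta[col]
    if "stage" in obs:
        obs["stage"] = obs["stage"].astype(int)
    if "mapped_reads" in obs:
        obs["mapped_reads"] = obs["mapped_reads"].astype(int)
    return ad.AnnData(X=counts.to_numpy(dtype=np.int64), obs=obs,
                      var=pd.DataFrame(index=counts.columns))


# ----------------------------------------------------------------------
# run-all
# ----------------------------------------------------------------------

def _stage_seed(seed: int, stage: int, salt: int) -> int:
    return (seed * 1009 + stage * 101 + salt) % (2**31 - 1)


def run_all(config: PipelineConfig) -> Path:
    """Execute the whole pipeline; returns the output directory.

    Any stage failure aborts with the stage name and cause. Rerunning
    with the same config and inputs writes identical files.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    try:
        tree = (LineageTree.from_tsv(config.lineage_table)
                if config.lineage_table else LineageTree.default())

        truth = None
        if config.counts is None:
            sim_cfg = SimulationConfig(
                **{"seed": config.seed, **config.simulation}
            )
            log.info("simulate: stages=%s n_genes=%d seed=%d",
                     sim_cfg.stages, sim_cfg.n_genes, sim_cfg.seed)
            adata, truth = run_simulation(sim_cfg, tree)
        else:
            adata = load_counts(config.counts)
            log.info("loaded counts: %d cells x %d genes",
                     adata.n_obs, adata.n_vars)

        report = validate_inputs(config, tree)
        for w in report.warnings:
            log.warning("validate: %s", w)
        if not report.ok:
            raise RuntimeError(f"input validation failed: {report.errors}")

        adata = run_preprocess(
            adata, min_reads=config.min_reads,
            pseudocount=config.pseudocount, sd=config.sd,
        )
        log.info("preprocess: %d cells retained", adata.n_obs)

        annot = None
        if config.tf_annotation:
            annot = enrichment.TFAnnotation.from_tsv(config.tf_annotation)
        elif truth is not None and truth.family:
            annot = enrichment.TFAnnotation(family=dict(truth.family))

        stage_list = config.stages or sorted(adata.obs["stage"].unique())
        for stage in stage_list:
            _run_stage(config, adata, truth, annot, tree, int(stage), out)

        resolved = dataclasses.replace(config)
        resolved.to_yaml(out / "config.resolved.yaml")
        log.info("run_all finished in %.1fs", time.time() - t0)
        return out
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_stage(config, adata, truth, annot, tree, stage, out: Path) -> None:
    tag = f"stage {stage}"
    sub = adata[adata.obs["stage"] == stage].copy()
    if sub.n_obs == 0:
        log.info("%s: no cells, skipped", tag)
        return
    try:
        # -- state inference ------------------------------------------
        if config.markers:
            db = states.MarkerDatabase.from_tsv(config.markers)
            db = states.MarkerDatabase(
                db.table[db.table["identity"].map(
                    lambda i: all(p in tree.cells_at_stage(stage)
                                  for p in str(i).split("/"))
                )].reset_index(drop=True)
            )
        elif truth is not None:
            db = states.MarkerDatabase(
                markers_from_truth(truth, stage, seed=config.seed)
            )
        else:
            raise RuntimeError("no marker database available")
        n_states = len({
            frozenset(db.expected(i)[0]) for i in db.identities()
        })
        res = states.infer_states(
            sub, db, n_states=n_states, stage=stage,
            seed=_stage_seed(config.seed, stage, 1),
        )
        cell_states = res.state_of_cells().to_numpy()
        keep = res.retained
        log.info("%s: %d states, %d/%d cells retained",
                 tag, len(res.profiles), int(keep.sum()), sub.n_obs)
        pd.DataFrame({
            "cell_id": sub.obs_names, "cluster": res.labels,
            "state": cell_states, "retained": keep,
        }).to_csv(out / f"states_{stage}.tsv", sep="\t", index=False)
        groups = {p.name: list(p.identities) for p in res.profiles
                  if p.is_equivalence_group}
        (out / f"equivalence_{stage}.json").write_text(
            json.dumps(groups, indent=1, sort_keys=True)
        )
        prof_rows = []
        for p in res.profiles:
            for gene in p.mean.index:
                prof_rows.append((p.name, p.n_members, gene,
                                  p.mean[gene], p.sd[gene]))
        pd.DataFrame(
            prof_rows, columns=["state", "n_members", "gene", "mean", "sd"]
        ).to_csv(out / f"state_profiles_{stage}.tsv", sep="\t", index=False)

        # -- differential expression ----------------------------------
        kept = sub[keep]
        calls = diffexp.call_stage(
            counts=np.asarray(kept.X),
            log_values=np.asarray(kept.layers["log10"]),
            Z=np.asarray(kept.layers["z"]),
            states=cell_states[keep],
            genes=list(kept.var_names),
            stage=stage,
            n_shuffles=config.shuffles,
            fdr=config.fdr,
            seed=_stage_seed(config.seed, stage, 2),
            embryos=kept.obs["embryo_id"].to_numpy(),
        )
        calls.to_tsv(out / f"diffexp_{stage}.tsv")
        sig = calls.significant_genes()
        if sig:
            calls.binary_matrix(sig).to_csv(
                out / f"binary_{stage}.tsv", sep="\t"
            )
        log.info("%s: %d/%d eligible genes significant (tau=%.3g)",
                 tag, len(sig), int(calls.table["eligible"].sum()),
                 calls.threshold)

        # -- family enrichment ----------------------------------------
        if annot is not None and sig:
            scores = enrichment.score_states(calls, annot)
            scores.to_tsv(out / f"enrichment_{stage}.tsv")
            agg = enrichment.aggregate_all(scores, tree)
            agg.to_csv(out / f"enrichment_agg_{stage}.tsv", sep="\t",
                       index=False)

        # -- stripes ---------------------------------------------------
        if sig:
            pos = (read_positions(config.positions)
                   if config.positions else synthetic_positions(tree, stage))
            pos = pos[pos["stage"] == stage]
            state_of_cell = pd.Series(cell_states[keep],
                                      index=kept.obs_names)
            lin_cells = state_of_cell[[
                any(tree.founder_of(p) == config.stripe_lineage
                    for p in str(s).split("/") if p in tree.nodes)
                for s in state_of_cell
            ]]
            if len(lin_cells) >= 2:
                binary = stripes.binarize_on_lineage(calls, sig, lin_cells)
                # map cells to positions of their assigned state's cell name
                pos_rows = []
                for cid, st in lin_cells.items():
                    name = str(st).split("/")[0]
                    row = pos[pos["cell"] == name]
                    if not row.empty:
                        pos_rows.append({"cell": cid,
                                         "x": float(row["x"].iloc[0]),
                                         "y": float(row["y"].iloc[0]),
                                         "z": float(row["z"].iloc[0])})
                pos_cells = pd.DataFrame(pos_rows)
                k = min(config.k_stripes, len(pos_cells))
                if k >= 1 and not pos_cells.empty:
                    smap = stripes.stripe_cluster(
                        binary[pos_cells["cell"]], pos_cells, stage,
                        lineage=config.stripe_lineage, k=k,
                        seed=_stage_seed(config.seed, stage, 3),
                    )
                    smap.write(out / f"stripes_{stage}.tsv",
                               out / f"stripe_signatures_{stage}.tsv")
            render = stripes.render_lineage_pattern(
                calls.binary_matrix(sig).rename(
                    columns=lambda s: str(s).split("/")[0]
                ), stage, tree,
            )
            (out / f"lineage_pattern_{stage}.json").write_text(
                stripes.lineage_pattern_json(render)
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at {tag}: {exc}") from exc
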