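"""Query the invariant lineage and simulate a ground-truthed experiment.

The lineage tree answers census questions about the 1- to 102-cell
stages; the simulator draws a whole-embryo UMI experiment over it with
known per-state expression programs.
"""

import patterncode as pc

tree = pc.LineageTree.default()

print("canonical stages:", pc.CANONICAL_STAGES)
print("4-cell stage:", sorted(tree.cells_at_stage(4)))
print("founder census at 28 cells:", tree.founder_counts(28))
print("mother of MS:", tree.parent_of("MS"), "| founder of ABplppp:",
      tree.founder_of("ABplppp"))

cfg = pc.SimulationConfig(
    stages=(8, 15), n_embryos_per_stage=3, n_genes=500, n_tf_genes=100,
    maternal_fraction=0.5, program_size=5, effect_size=1.0, seed=0,
)
adata, truth = pc.simulate(cfg)
print(f"\nsimulated {adata.n_obs} cells x {adata.n_vars} genes "
      f"from {adata.obs['embryo_id'].nunique()} embryos")
print("planted differential genes:", len(truth.programs))
gene, (stage, on) = sorted(truth.programs.items())[0]
print(f"example: {gene} switches on at the {stage}-cell stage in {sorted(on)}")
# Cells are columns of a counts matrix; each embryo contributes every
# cell of its stage, and the planted on-sets are the ground truth that
# downstream modules are scored against.
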