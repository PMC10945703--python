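"""Cell-state inference: variable genes, embedding, clustering, annotation."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import patterncode as pc
from patterncode.states import (
    MarkerDatabase,
    aggregate_states,
    assign_identity,
    iterative_cluster,
    loo_robustness,
    marker_score,
)


# ------------------------------------------------------------ variable genes

def test_constant_gene_never_selected_before_varying(tiny_preprocessed):
    adata, _, _ = tiny_preprocessed
    sub = adata.copy()
    tp = np.asarray(sub.layers["tp50k"]).copy()
    tp[:, 0] = 100.0  # constant nonzero gene -> Fano 0
    sub.layers["tp50k"] = tp
    genes = pc.select_variable_genes(sub, n=sub.n_vars - 1)
    assert sub.var_names[0] not in genes


def test_poisson_genes_have_fano_near_one():
    rng = np.random.default_rng(0)
    X = rng.poisson(lam=np.geomspace(1, 50, 30), size=(500, 30))
    adata = ad.AnnData(X=X.astype(np.int64))
    adata.layers["tp50k"] = X.astype(float)  # treat counts as the layer
    mean = X.mean(axis=0)
    fano = X.var(axis=0) / mean
    assert np.all(np.abs(np.median(fano) - 1) < 0.2)
    ranked = pc.select_variable_genes(adata, n=30)
    assert len(ranked) == 30


def test_variable_genes_warns_when_n_exceeds_nonzero(tiny_preprocessed):
    adata, _, _ = tiny_preprocessed
    with pytest.warns(UserWarning, match="nonzero mean"):
        genes = pc.select_variable_genes(adata, n=10 * adata.n_vars)
    assert len(genes) <= adata.n_vars


def test_variable_gene_ranking_planted(tiny_preprocessed):
    """Planted program genes vary across states far beyond counting
    noise, so they rank above the unpatterned zygotic genes of matching
    sparseness (high-expression maternal genes can also rank high — the
    embryo batch factor inflates their Fano in proportion to the mean,
    as it does on real data)."""
    adata, truth, _ = tiny_preprocessed
    ranked = pc.select_variable_genes(adata, n=adata.n_vars)
    rank = {g: i for i, g in enumerate(ranked)}
    planted = set(truth.programs)
    null_zyg = [g for g in adata.var_names
                if not truth.maternal[g] and g not in planted]
    med_planted = np.median([rank[g] for g in planted if g in rank])
    med_null = np.median([rank[g] for g in null_zyg if g in rank])
    assert med_planted < med_null


# ---------------------------------------------------------------- embedding

def test_embed_is_deterministic_and_separates_states(tiny_preprocessed):
    adata, truth, _ = tiny_preprocessed
    genes = sorted(truth.programs)[:60]
    with pytest.warns(UserWarning, match="perplexity"):
        xy1 = pc.embed(adata, genes, dims=10, perplexity=50, seed=0)
        xy2 = pc.embed(adata, genes, dims=10, perplexity=50, seed=0)
    assert np.array_equal(xy1, xy2)
    from sklearn.metrics import silhouette_score
    assert silhouette_score(xy1, adata.obs["true_state"]) > 0


def test_embed_rejects_degenerate_input(tiny_preprocessed):
    adata, _, _ = tiny_preprocessed
    flat = adata[:, :5].copy()
    flat.layers["z"] = np.zeros((adata.n_obs, 5))
    with pytest.raises(ValueError, match="degenerate"):
        pc.embed(flat, list(flat.var_names), seed=0)


# --------------------------------------------------------------- clustering

def test_iterative_cluster_recovers_planted_states(recovery_run):
    adata, truth, _ = recovery_run
    marker_genes = sorted(truth.programs)
    Z = np.asarray(adata[:, marker_genes].layers["z"])
    labels = iterative_cluster(
        Z, adata.obs["embryo_id"].to_numpy(), n_states=15,
        cell_ids=adata.obs_names.to_numpy(), seed=0,
    )
    true = adata.obs["true_state"].to_numpy()
    # every cluster should be dominated by one true state, covering >=90%
    correct = 0
    for c in np.unique(labels):
        states_c = true[labels == c]
        correct += pd.Series(states_c).value_counts().iloc[0]
    assert correct / len(true) >= 0.9
    # clusters draw from multiple embryos
    emb = adata.obs["embryo_id"].to_numpy()
    for c in np.unique(labels):
        assert len(set(emb[labels == c])) >= 3


def test_iterative_cluster_single_state_runs_once(tiny_preprocessed):
    adata, _, _ = tiny_preprocessed
    Z = np.asarray(adata.layers["z"])[:, :20]
    labels = iterative_cluster(Z, adata.obs["embryo_id"].to_numpy(), n_states=1)
    assert set(labels) == {0}


def test_iterative_cluster_order_invariance(recovery_run):
    adata, truth, _ = recovery_run
    genes = sorted(truth.programs)[:50]
    Z = np.asarray(adata[:, genes].layers["z"])
    ids = adata.obs_names.to_numpy()
    emb = adata.obs["embryo_id"].to_numpy()
    labels = iterative_cluster(Z, emb, 15, cell_ids=ids, seed=1)
    perm = np.random.default_rng(0).permutation(len(ids))
    labels_p = iterative_cluster(Z[perm], emb[perm], 15, cell_ids=ids[perm], seed=1)
    assert np.array_equal(labels_p, labels[perm])


def test_single_embryo_falls_back_with_warning():
    rng = np.random.default_rng(2)
    Z = rng.normal(0, 1, (12, 5))
    with pytest.warns(UserWarning, match="fewer than two embryos"):
        labels = iterative_cluster(Z, np.array(["E0"] * 12), n_states=3)
    assert len(set(labels)) == 3


# --------------------------------------------------------------- annotation

def _markers(idents, genes_on, genes_off):
    rows = []
    for ident in idents:
        for g in genes_on[ident]:
            rows.append((ident, g, "on", ""))
        for g in genes_off[ident]:
            rows.append((ident, g, "off", ""))
    return MarkerDatabase(pd.DataFrame(rows, columns=["identity", "gene",
                                                      "expected", "note"]))


def test_ideal_profile_gets_its_identity():
    genes = [f"g{i}" for i in range(6)]
    db = _markers(["A", "B"],
                  {"A": genes[:3], "B": genes[3:]},
                  {"A": genes[3:], "B": genes[:3]})
    profiles = pd.DataFrame(
        [[1, 1, 1, -1, -1, -1], [-1, -1, -1, 1, 1, 1]],
        index=[0, 1], columns=genes, dtype=float,
    )
    out = assign_identity(profiles, db)
    assert out[0][0] == "A" and out[1][0] == "B"
    assert out[0][1] == pytest.approx(2.0)  # mean(on) - mean(off) = 1-(-1)


def test_identical_marker_sets_form_equivalence_group():
    genes = [f"g{i}" for i in range(4)]
    db = _markers(["A", "B", "C"],
                  {"A": genes[:2], "B": genes[:2], "C": genes[2:]},
                  {"A": genes[2:], "B": genes[2:], "C": genes[:2]})
    profiles = pd.DataFrame(
        [[1, 1, -1, -1], [-1, -1, 1, 1]], index=[0, 1], columns=genes,
        dtype=float,
    )
    out = assign_identity(profiles, db)
    names = {name for name, _ in out.values()}
    assert "A/B" in names and "C" in names


def test_marker_conflicts_rejected():
    bad = pd.DataFrame({
        "identity": ["A", "A"], "gene": ["g", "g"],
        "expected": ["on", "off"], "note": ["", ""],
    })
    with pytest.raises(ValueError, match="conflicting"):
        MarkerDatabase(bad)


def test_marker_score_ignores_absent_genes():
    profile = pd.Series({"a": 2.0, "b": -1.0})
    s = marker_score(profile, frozenset({"a", "missing"}), frozenset({"b"}))
    assert s == pytest.approx(3.0)


# ---------------------------------------------------------------- LOO + agg

def test_loo_retains_tight_clusters_and_drops_swapped_cell():
    rng = np.random.default_rng(4)
    a = rng.normal(0, 0.1, (6, 20)) + np.r_[np.ones(10), -np.ones(10)]
    b = rng.normal(0, 0.1, (6, 20)) - np.r_[np.ones(10), -np.ones(10)]
    X = np.vstack([a, b])
    labels = np.array([0] * 6 + [1] * 6)
    assert loo_robustness(labels, X).all()
    # move one b-cell into cluster a: it correlates better with b's mean
    labels_swapped = labels.copy()
    labels_swapped[11] = 0
    retained = loo_robustness(labels_swapped, X)
    assert not retained[11]
    assert retained[:11].all()


def test_loo_ties_and_singletons_retained():
    X = np.tile(np.array([1.0, -1.0, 0.5]), (4, 1))
    labels = np.array([0, 0, 1, 2])  # identical clusters 0/1, singleton 2
    assert loo_robustness(labels, X).all()


def test_aggregate_states_consistency(recovery_run):
    adata, truth, _ = recovery_run
    Z = pd.DataFrame(np.asarray(adata.layers["z"]),
                     index=adata.obs_names, columns=adata.var_names)
    labels = pd.factorize(adata.obs["true_state"])[0]
    names = {i: s for i, s in enumerate(pd.factorize(adata.obs["true_state"])[1])}
    profiles = aggregate_states(Z, labels, names)
    assert len(profiles) == 15
    p0 = profiles[0]
    block = Z.loc[list(p0.members)]
    assert np.allclose(p0.mean, block.mean(axis=0))
    assert np.allclose(p0.sd, block.std(axis=0, ddof=0))
    # a single-member state has an all-zero sd vector
    single = aggregate_states(Z.iloc[:1], np.array([0]), {0: "solo"})[0]
    assert np.allclose(single.sd, 0.0)
    # planted program genes average high in their own state
    state = p0.name
    prog = [g for g, (s, on) in truth.programs.items() if state in on]
    assert p0.mean[prog].mean() > 1.0


# ------------------------------------------------------------- full chain

def test_infer_states_end_to_end_recovery(recovery_run):
    adata, truth, cfg = recovery_run
    db = MarkerDatabase(pc.markers_from_truth(truth, 15, seed=1))
    res = pc.infer_states(adata, db, n_states=15, stage=15, seed=1)
    assigned = res.state_of_cells().to_numpy()
    true = adata.obs["true_state"].to_numpy()
    correct = np.array([t in a.split("/") for a, t in zip(assigned, true)])
    assert correct[res.retained].mean() >= 0.9
    assert all(p.n_members >= 1 for p in res.profiles)
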