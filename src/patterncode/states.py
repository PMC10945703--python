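"""Cell-state inference: variable genes, embedding, per-stage iterative
clustering, marker-based annotation, leave-one-out robustness and state
transcriptome aggregation.

The procedure works one developmental stage at a time, on per-embryo
standardized expression. Cells are clustered on a restricted panel of
marker genes; clusters are accepted one at a time by the homogeneity of
their embryo composition (a cluster drawing evenly from all embryos of
the stage looks like a genuine recurring cell state rather than one
embryo's batch artifact), the accepted cluster is removed and the
remainder re-clustered. Accepted clusters are annotated against a
marker database of expected on/off genes; identities whose markers
cannot distinguish them are merged into equivalence groups named
"A/B". Finally, cells are kept only if their expression correlates
best with their own cluster's leave-one-out mean, and each retained
cluster is summarized as a mean ± sd transcriptome.

The embryo-composition acceptance score is an explicit surrogate for
what was originally a manual curation step: we use the entropy of the
within-cluster embryo distribution, normalized by the entropy of a
uniform spread over the stage's embryos, and accept the
highest-entropy cluster first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

EQUIVALENCE_TOLERANCE = 0.1  # standardized units


# ----------------------------------------------------------------------
# marker database
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerDatabase:
    """Collated expectations: (identity, gene) -> on/off."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"identity", "gene", "expected"}
        if not required <= set(self.table.columns):
            raise ValueError(f"marker table needs columns {sorted(required)}")
        bad = ~self.table["expected"].isin(["on", "off"])
        if bad.any():
            raise ValueError("expected column must be 'on' or 'off'")
        dup = self.table.groupby(["identity", "gene"])["expected"].nunique()
        conflicts = dup[dup > 1]
        if len(conflicts):
            raise ValueError(
                f"conflicting marker expectations: {conflicts.index.tolist()}"
            )

    @classmethod
    def from_tsv(cls, path) -> "MarkerDatabase":
        return cls(pd.read_csv(path, sep="\t"))

    def identities(self) -> list[str]:
        return sorted(self.table["identity"].unique())

    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    def expected(self, identity: str) -> tuple[frozenset[str], frozenset[str]]:
        sub = self.table[self.table["identity"] == identity]
        if sub.empty:
            raise KeyError(f"no markers for identity {identity!r}")
        on = frozenset(sub.loc[sub["expected"] == "on", "gene"])
        off = frozenset(sub.loc[sub["expected"] == "off", "gene"])
        return on, off


# ----------------------------------------------------------------------
# variable genes and embedding
# ----------------------------------------------------------------------

def select_variable_genes(adata: ad.AnnData, n: int = 1000) -> list[str]:
    """Top ``n`` genes by Fano factor (variance/mean of tp50k values).

    The Fano factor is ~1 under Poisson sampling regardless of the mean,
    so ranking by it highlights genes whose variation exceeds counting
    noise. Genes with zero mean are excluded; ties break by gene name.
    """
    if "tp50k" not in adata.layers:
        raise ValueError("tp50k layer required; run normalize_tp50k first")
    X = np.asarray(adata.layers["tp50k"], dtype=float)
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    ok = mean > 0
    fano = np.where(ok, var / np.where(ok, mean, 1.0), -np.inf)
    order = sorted(
        (i for i in range(adata.n_vars) if ok[i]),
        key=lambda i: (-fano[i], adata.var_names[i]),
    )
    if n > len(order):
        warnings.warn(
            f"requested {n} variable genes but only {len(order)} have "
            "nonzero mean; returning all of them", stacklevel=2,
        )
    return [adata.var_names[i] for i in order[:n]]


def embed(
    adata: ad.AnnData,
    genes: list[str],
    dims: int = 20,
    perplexity: float = 50.0,
    seed: int = 0,
    layer: str = "z",
) -> np.ndarray:
    """2-D t-SNE of cells on the given gene panel, deterministically
    initialized from the first two principal directions scaled to unit
    variance, so repeated runs with one seed are bit-identical."""
    X = np.asarray(adata[:, genes].layers[layer], dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("embedding needs at least 4 cells")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all cells identical on this panel")
    if n - 1 < 3 * perplexity:
        new_p = max(2.0, (n - 1) / 3.0)
        warnings.warn(
            f"perplexity {perplexity} too large for {n} cells; using {new_p:.1f}",
            stacklevel=2,
        )
        perplexity = new_p
    dims = min(dims, n - 1, X.shape[1])
    pcs = PCA(n_components=dims, random_state=seed).fit_transform(X)
    init = pcs[:, :2].copy()
    init /= init.std(axis=0).clip(min=1e-12)
    coords = TSNE(
        n_components=2, perplexity=perplexity, init=init,
        random_state=seed, method="exact" if n < 1500 else "barnes_hut",
    ).fit_transform(pcs)
    return np.asarray(coords, dtype=float)


# ----------------------------------------------------------------------
# iterative cluster acceptance
# ----------------------------------------------------------------------

def _embryo_entropy(embryos: np.ndarray) -> float:
    """Entropy of the embryo composition, normalized to [0, 1] by the
    number of embryos represented in the whole stage (set by caller via
    closure variables); here: raw entropy of proportions."""
    _, counts = np.unique(embryos, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def iterative_cluster(
    Z: np.ndarray,
    embryos: np.ndarray,
    n_states: int,
    cell_ids: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Automated surrogate of iterative cluster acceptance for one stage.

    Repeatedly k-means the remaining cells (k = number of states still
    unassigned), accept the cluster with the most even multi-embryo
    composition (highest normalized entropy; ties to the larger
    cluster), remove it and re-cluster, until every cell is assigned.
    Cells are canonically ordered by ``cell_ids`` before clustering so
    the result is invariant to input column order.

    Parameters
    ----------
    Z
        Cells x marker-gene standardized values.
    embryos
        Embryo id per cell.
    n_states
        Number of clusters to accept.

    Returns an integer label per cell, 0..n_states-1 in acceptance order.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    embryos = np.asarray(embryos)
    n = Z.shape[0]
    if cell_ids is None:
        cell_ids = np.arange(n)
    order = np.argsort(np.asarray(cell_ids, dtype=str), kind="stable")
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    Zo, eo = Z[order], embryos[order]

    n_embryos = len(np.unique(eo))
    labels_o = np.full(n, -1, dtype=int)
    if n_embryos < 2:
        warnings.warn(
            "stage has fewer than two embryos; composition score undefined, "
            "falling back to one-shot clustering", stacklevel=2,
        )
        k = min(n_states, n)
        labels_o = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(Zo)
        return labels_o[inv]

    max_entropy = np.log(n_embryos)
    remaining = np.arange(n)
    next_label = 0
    k = n_states
    while len(remaining):
        if k <= 1 or len(remaining) <= k:
            # everything left is one accepted cluster per remaining slot
            if k <= 1:
                labels_o[remaining] = next_label
                next_label += 1
                break
            for i, idx in enumerate(remaining):
                labels_o[idx] = next_label + min(i, k - 1)
            next_label += k
            break
        km = KMeans(n_clusters=k, random_state=seed + next_label, n_init=10)
        sub = km.fit_predict(Zo[remaining])
        best, best_key = None, None
        for c in range(k):
            members = remaining[sub == c]
            if len(members) == 0:
                continue
            h = _embryo_entropy(eo[members]) / max_entropy
            key = (h, len(members), -c)
            if best_key is None or key > best_key:
                best, best_key = c, key
        accepted = remaining[sub == best]
        labels_o[accepted] = next_label
        next_label += 1
        remaining = remaining[sub != best]
        k -= 1
    return labels_o[inv]


# ----------------------------------------------------------------------
# annotation
# ----------------------------------------------------------------------

def marker_score(profile: pd.Series, on: frozenset[str], off: frozenset[str]) -> float:
    """Mean standardized expression over expected-on genes minus the mean
    over expected-off genes (genes absent from the profile are ignored)."""
    on_vals = [profile[g] for g in on if g in profile.index]
    off_vals = [profile[g] for g in off if g in profile.index]
    s = float(np.mean(on_vals)) if on_vals else 0.0
    if off_vals:
        s -= float(np.mean(off_vals))
    return s


def assign_identity(
    cluster_profiles: pd.DataFrame,
    markers: MarkerDatabase,
    candidates: list[str] | None = None,
    tolerance: float = EQUIVALENCE_TOLERANCE,
) -> dict[int, tuple[str, float]]:
    """Annotate clusters against the marker database.

    ``cluster_profiles`` is clusters x genes (mean standardized
    expression). Matching is one-to-one and greedy by descending score
    with lexicographic tie-breaks. After matching, any *unassigned*
    candidate identity whose score on a cluster ties the winner within
    ``tolerance`` joins that cluster's equivalence group; the returned
    identity name is then "A/B" (sorted members).

    Returns cluster -> (identity-or-group name, winning score).
    """
    candidates = candidates if candidates is not None else markers.identities()
    if not candidates:
        raise ValueError("no candidate identities with markers for this stage")
    scores = {}
    for c in cluster_profiles.index:
        profile = cluster_profiles.loc[c]
        for ident in candidates:
            on, off = markers.expected(ident)
            scores[(c, ident)] = marker_score(profile, on, off)

    triples = sorted(
        scores.items(), key=lambda kv: (-kv[1], str(kv[0][1]), str(kv[0][0]))
    )
    assigned_c: dict[int, str] = {}
    assigned_i: set[str] = set()
    for (c, ident), _ in triples:
        if c in assigned_c or ident in assigned_i:
            continue
        assigned_c[c] = ident
        assigned_i.add(ident)
        if len(assigned_c) == len(cluster_profiles.index):
            break

    out: dict[int, tuple[str, float]] = {}
    unmatched = [i for i in candidates if i not in assigned_i]
    for c, ident in assigned_c.items():
        best = scores[(c, ident)]
        group = [ident] + [
            j for j in unmatched if abs(scores[(c, j)] - best) < tolerance
        ]
        out[c] = ("/".join(sorted(group)), best)
    return out


# ----------------------------------------------------------------------
# leave-one-out robustness
# ----------------------------------------------------------------------

def loo_robustness(labels: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Boolean retain mask: a cell is kept iff its Pearson correlation to
    its own cluster's leave-one-out mean is at least its correlation to
    every other cluster's mean (ties retain; singleton clusters retain
    their cell by convention)."""
    labels = np.asarray(labels)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    uniq = np.unique(labels)
    sums = {c: X[labels == c].sum(axis=0) for c in uniq}
    counts = {c: int((labels == c).sum()) for c in uniq}
    retain = np.ones(len(labels), dtype=bool)

    def corr(a, b):
        a = a - a.mean(); b = b - b.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        return 0.0 if denom == 0 else float(a @ b / denom)

    for i in range(len(labels)):
        own = labels[i]
        if counts[own] < 2:
            continue  # singleton: retained, nothing to compare against
        own_mean = (sums[own] - X[i]) / (counts[own] - 1)
        r_own = corr(X[i], own_mean)
        for c in uniq:
            if c == own:
                continue
            r_other = corr(X[i], sums[c] / counts[c])
            if r_other > r_own:
                retain[i] = False
                break
    return retain


# ----------------------------------------------------------------------
# state aggregation
# ----------------------------------------------------------------------

@dataclass
class StateProfile:
    """Mean ± sd transcriptome of one inferred cell state."""

    name: str
    members: tuple[str, ...]
    mean: pd.Series
    sd: pd.Series
    identities: tuple[str, ...] = ()

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def is_equivalence_group(self) -> bool:
        return len(self.identities) >= 2


def aggregate_states(
    Z: pd.DataFrame, labels: np.ndarray, names: dict[int, str]
) -> list[StateProfile]:
    """Summarize each cluster as mean ± (population) sd per gene.

    ``Z`` is cells x genes with cell ids as index; ``names`` maps cluster
    label -> state name (possibly an "A/B" equivalence-group name).
    """
    labels = np.asarray(labels)
    out = []
    for c in sorted(names):
        mask = labels == c
        block = Z.loc[mask]
        out.append(StateProfile(
            name=names[c],
            members=tuple(block.index),
            mean=block.mean(axis=0),
            sd=block.std(axis=0, ddof=0),
            identities=tuple(names[c].split("/")),
        ))
    return out


# ----------------------------------------------------------------------
# per-stage driver
# ----------------------------------------------------------------------

@dataclass
class StateInferenceResult:
    stage: int
    labels: np.ndarray                 # cluster label per input cell
    retained: np.ndarray               # LOO robustness mask
    identity: dict[int, tuple[str, float]]
    profiles: list[StateProfile] = field(default_factory=list)

    def state_of_cells(self) -> pd.Series:
        names = {c: ident for c, (ident, _) in self.identity.items()}
        return pd.Series([names[int(l)] for l in self.labels])


def infer_states(
    adata: ad.AnnData,
    markers: MarkerDatabase,
    n_states: int,
    stage: int,
    seed: int = 0,
) -> StateInferenceResult:
    """Full per-stage chain: iterative clustering on marker genes,
    annotation, leave-one-out retention, aggregation over all genes.

    ``adata`` must hold one stage's cells with a ``z`` layer.
    """
    marker_genes = [g for g in markers.genes() if g in adata.var_names]
    if not marker_genes:
        raise ValueError("no marker genes present in the expression matrix")
    Zm = np.asarray(adata[:, marker_genes].layers["z"], dtype=float)
    labels = iterative_cluster(
        Zm, adata.obs["embryo_id"].to_numpy(), n_states,
        cell_ids=adata.obs_names.to_numpy(), seed=seed,
    )
    profiles_m = pd.DataFrame(
        {c: Zm[labels == c].mean(axis=0) for c in np.unique(labels)},
        index=marker_genes,
    ).T
    identity = assign_identity(profiles_m, markers)
    retained = loo_robustness(labels, Zm)

    Zall = pd.DataFrame(
        np.asarray(adata.layers["z"], dtype=float),
        index=adata.obs_names, columns=adata.var_names,
    )
    names = {c: ident for c, (ident, _) in identity.items()}
    profiles = aggregate_states(Zall.loc[retained], labels[retained], names)
    return StateInferenceResult(
        stage=stage, labels=labels, retained=retained,
        identity=identity, profiles=profiles,
    )
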