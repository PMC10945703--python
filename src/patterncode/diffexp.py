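"""Greedy "super-group" differential expression with a shuffle-derived
false-discovery threshold.

For each gene at one developmental stage, the procedure searches for the
binary partition of the stage's cell states into an expressing group and
a non-expressing group that is most significant under a two-sample t
test on per-cell standardized expression:

1. *Seed*: test every single state against all remaining cells; the
   state with the smallest p-value seeds the super-group G.
2. *Grow*: repeatedly add the state whose inclusion most improves the
   p-value of G versus the rest; stop when no addition strictly
   improves it.
3. *Orient*: the side with the higher mean is called "on", giving the
   gene a binary on/off profile with p-value p*.

Significance is calibrated by permutation: the same greedy search is run
on many cell-to-state reshuffles (state sizes preserved), and the
p-value at the FDR quantile of the sorted shuffle p-values becomes the
stage threshold τ.  Two eligibility filters restrict the test to
plausibly patterned genes: a gene must be detected in at most half of
the stage's cells, and its log10 expression range across the stage must
reach 0.75 (three quarters of a log10 unit).

The t test is the classic two-sample Student t with pooled variance by
default (Welch's unequal-variance variant is available via
``test="welch"``). Pooled variance is the right default here: the
partitions under test are tiny expressing groups against a large,
mostly silent remainder, and Welch's small-sample degrees of freedom
would cap the attainable significance of a genuine partition at the
size of its expressing group while awarding enormous degrees of
freedom to degenerate near-constant splits found by the shuffle null.
Group statistics are accumulated from per-state moments so each greedy
step costs O(1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

# -- eligibility -------------------------------------------------------

MAX_EXPRESSED_FRACTION = 0.5
MIN_LOG_RANGE = 0.75


@dataclass(frozen=True)
class Eligibility:
    pct_expressed: float   # fraction of stage cells with a nonzero count
    log_range: float       # max - min of log10(tp50k + pseudocount)
    pct_ok: bool
    range_ok: bool

    @property
    def eligible(self) -> bool:
        return self.pct_ok and self.range_ok


def eligibility(
    counts: np.ndarray,
    log_values: np.ndarray,
    max_expressed_fraction: float = MAX_EXPRESSED_FRACTION,
    min_log_range: float = MIN_LOG_RANGE,
) -> Eligibility:
    """Eligibility flags for one gene across one stage's cells."""
    counts = np.asarray(counts)
    log_values = np.asarray(log_values, dtype=float)
    frac = float((counts > 0).mean())
    rng = float(log_values.max() - log_values.min())
    return Eligibility(
        pct_expressed=frac,
        log_range=rng,
        pct_ok=frac <= max_expressed_fraction,
        range_ok=rng >= min_log_range,
    )


# -- two-sample t from group moments ----------------------------------

def _t_p(
    n1: float, s1: float, q1: float,
    n2: float, s2: float, q2: float,
    pooled: bool = True,
) -> float:
    """Two-sided two-sample t p-value from (count, sum, sum-of-squares).

    ``pooled=True`` gives the classic Student t (equal variances,
    df = n1+n2-2); ``pooled=False`` gives Welch's t. Degenerate cases:
    fewer than two samples on a side gives p = 1; a zero standard error
    gives p = 1 for equal means (nothing to test) and p = 0 for distinct
    means (perfect separation).
    """
    if n1 < 2 or n2 < 2:
        return 1.0
    m1, m2 = s1 / n1, s2 / n2
    v1 = max((q1 - s1 * s1 / n1) / (n1 - 1), 0.0)
    v2 = max((q2 - s2 * s2 / n2) / (n2 - 1), 0.0)
    if pooled:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
    else:
        se2 = v1 / n1 + v2 / n2
        if se2 > 0.0:
            df = se2 * se2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
    if se2 <= 0.0:
        return 1.0 if abs(m1 - m2) < 1e-12 else 0.0
    t = (m1 - m2) / math.sqrt(se2)
    return float(2.0 * special.stdtr(df, -abs(t)))


def student_p_from_values(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided pooled-variance t p-value between two sample vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return _t_p(len(a), a.sum(), (a * a).sum(),
                len(b), b.sum(), (b * b).sum(), pooled=True)


def welch_p_from_values(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch p-value between two sample vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return _t_p(len(a), a.sum(), (a * a).sum(),
                len(b), b.sum(), (b * b).sum(), pooled=False)


# -- greedy super-group search ----------------------------------------

@dataclass(frozen=True)
class GreedyResult:
    group: tuple[str, ...]       # the greedily grown super-group, sorted
    p_star: float                # best p along the path
    path: tuple[float, ...]      # p after the seed and after each addition
    on_states: tuple[str, ...]   # higher-mean side of the partition
    orientation: str             # 'group' if the super-group is the on side

    @property
    def off_states(self) -> tuple[str, ...]:
        return tuple(s for s in self._all_states if s not in set(self.on_states))

    _all_states: tuple[str, ...] = field(default=(), repr=False)


def greedy_supergroup(
    values: np.ndarray, states: np.ndarray, test: str = "student"
) -> GreedyResult:
    """Find the most significant state partition for one gene.

    Parameters
    ----------
    values
        Standardized expression of the gene, one entry per cell.
    states
        Cell-state label per cell (same length). At least two distinct
        states are required.
    test
        ``"student"`` (pooled variance, default) or ``"welch"``.

    Ties in seeding and growth are broken by state-name lexicographic
    order, making the search deterministic under cell reordering.
    """
    if test not in ("student", "welch"):
        raise ValueError("test must be 'student' or 'welch'")
    pooled = test == "student"
    values = np.asarray(values, dtype=float)
    states = np.asarray(states)
    names = sorted(set(states.tolist()))
    if len(names) < 2:
        raise ValueError("greedy search needs at least two cell states")

    n = {}; s = {}; q = {}
    for name in names:
        v = values[states == name]
        if len(v) == 0:
            raise ValueError(f"state {name!r} has no cells")
        n[name] = float(len(v)); s[name] = v.sum(); q[name] = (v * v).sum()
    N, S, Q = sum(n.values()), sum(s.values()), sum(q.values())

    def p_of(group: set[str]) -> float:
        n1 = sum(n[g] for g in group)
        s1 = sum(s[g] for g in group)
        q1 = sum(q[g] for g in group)
        return _t_p(n1, s1, q1, N - n1, S - s1, Q - q1, pooled)

    # seed: best singleton (lexicographic tie-break via sorted iteration)
    best_seed, best_p = None, math.inf
    for name in names:
        p = p_of({name})
        if p < best_p:
            best_seed, best_p = name, p
    group = {best_seed}
    path = [best_p]

    while len(group) < len(names) - 1:
        cand, cand_p = None, math.inf
        for name in names:
            if name in group:
                continue
            p = p_of(group | {name})
            if p < cand_p:
                cand, cand_p = name, p
        if cand_p < path[-1]:
            group.add(cand)
            path.append(cand_p)
        else:
            break

    p_star = path[-1]
    in_mask = np.isin(states, list(group))
    mean_in = values[in_mask].mean()
    mean_out = values[~in_mask].mean()
    if mean_in >= mean_out:
        on = tuple(sorted(group))
        orientation = "group"
    else:
        on = tuple(sorted(set(names) - group))
        orientation = "complement"
    return GreedyResult(
        group=tuple(sorted(group)), p_star=float(p_star),
        path=tuple(path), on_states=on, orientation=orientation,
        _all_states=tuple(names),
    )


# -- shuffle threshold -------------------------------------------------

def shuffle_threshold(
    Z: np.ndarray,
    states: np.ndarray,
    n_shuffles: int = 10_000,
    fdr: float = 0.01,
    seed: int = 0,
    test: str = "student",
    embryos: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation threshold τ for one stage.

    Each shuffle permutes the cell-to-state assignment (state sizes
    preserved) and runs the greedy search on one gene, drawn round-robin
    from the eligible panel so the null pools gene behavior across the
    panel. τ is the ⌈fdr·n⌉-th smallest shuffle p-value.

    When ``embryos`` is given, assignments are permuted *within each
    embryo*. This respects the nested design: expression is standardized
    within embryos, which ties the cells of one embryo together (their
    z-values sum to zero), so only cells of the same embryo are
    exchangeable under the null. A stage-wide shuffle breaks the
    balanced embryo-by-state structure of the true assignment and
    mis-calibrates the threshold; a within-embryo shuffle also preserves
    state sizes whenever whole embryos were collected.

    Parameters
    ----------
    Z
        Standardized expression, cells x eligible genes.
    states
        True state label per cell.
    embryos
        Embryo id per cell; None falls back to a stage-wide shuffle.

    Returns (τ, sorted shuffle p-values).
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles < 100 makes the FDR quantile unstable")
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must lie strictly between 0 and 1")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    states = np.asarray(states)
    n_genes = Z.shape[1]
    if n_genes == 0:
        raise ValueError("no eligible genes to shuffle")
    rng = np.random.default_rng(seed)
    blocks = None
    if embryos is not None:
        embryos = np.asarray(embryos)
        blocks = [np.flatnonzero(embryos == e) for e in np.unique(embryos)]
    ps = np.empty(n_shuffles)
    for i in range(n_shuffles):
        if blocks is None:
            perm = rng.permutation(states)
        else:
            perm = states.copy()
            for idx in blocks:
                perm[idx] = perm[idx][rng.permutation(len(idx))]
        ps[i] = greedy_supergroup(Z[:, i % n_genes], perm, test).p_star
    ps.sort()
    rank = math.ceil(fdr * n_shuffles)
    return float(ps[rank - 1]), ps


# -- per-stage driver --------------------------------------------------

@dataclass
class BinaryCallSet:
    """Per-gene binary on/off calls for one stage.

    ``table`` is indexed by gene with columns pct_expressed, log_range,
    eligible, group, on_states (semicolon-joined), p_value, significant.
    """

    stage: int
    states: tuple[str, ...]
    threshold: float
    table: pd.DataFrame

    def on_states(self, gene: str) -> frozenset[str]:
        row = self.table.loc[gene]
        if not row["significant"]:
            raise KeyError(
                f"gene {gene!r} is not significantly called at stage {self.stage}; "
                f"available genes: {sorted(self.significant_genes())}"
            )
        return frozenset(row["on_states"].split(";"))

    def significant_genes(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()

    def binary_matrix(self, genes=None) -> pd.DataFrame:
        """Significant genes x states matrix of 0/1 on-calls."""
        genes = list(genes) if genes is not None else self.significant_genes()
        missing = [g for g in genes if g not in self.table.index
                   or not self.table.loc[g, "significant"]]
        if missing:
            raise KeyError(
                f"genes not called at stage {self.stage}: {missing}; "
                f"available: {sorted(self.significant_genes())}"
            )
        mat = pd.DataFrame(0, index=genes, columns=list(self.states), dtype=int)
        for g in genes:
            mat.loc[g, list(self.on_states(g))] = 1
        return mat

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "stage", self.stage)
        out["threshold"] = self.threshold
        out.to_csv(path, sep="\t")


def call_stage(
    counts: np.ndarray,
    log_values: np.ndarray,
    Z: np.ndarray,
    states: np.ndarray,
    genes: list[str],
    stage: int,
    n_shuffles: int = 10_000,
    fdr: float = 0.01,
    seed: int = 0,
    shuffle_mode: str = "pooled",
    test: str = "student",
    embryos: np.ndarray | None = None,
) -> BinaryCallSet:
    """Run eligibility, greedy search and shuffle calibration for one stage.

    Parameters
    ----------
    counts, log_values, Z
        Cells x genes matrices: raw counts, log10(tp50k+1), and
        per-embryo standardized values.
    states
        Cell-state label per cell (from state inference, or true states
        on synthetic data).
    shuffle_mode
        ``"pooled"`` derives one stage-wide τ from shuffles that cycle
        round-robin through the eligible genes (default); ``"per_gene"``
        calibrates each gene against its own shuffles.
    test
        Two-sample t variant, ``"student"`` (default) or ``"welch"``.
    embryos
        Embryo id per cell; when given, the calibration shuffles permute
        assignments within embryos (see :func:`shuffle_threshold`).
    """
    if shuffle_mode not in ("pooled", "per_gene"):
        raise ValueError("shuffle_mode must be 'pooled' or 'per_gene'")
    counts = np.atleast_2d(counts)
    log_values = np.atleast_2d(log_values)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    states = np.asarray(states)
    state_names = tuple(sorted(set(states.tolist())))

    rows = []
    elig_idx = []
    for j, gene in enumerate(genes):
        e = eligibility(counts[:, j], log_values[:, j])
        rows.append({
            "gene": gene, "pct_expressed": e.pct_expressed,
            "log_range": e.log_range, "eligible": e.eligible,
        })
        if e.eligible:
            elig_idx.append(j)

    table = pd.DataFrame(rows).set_index("gene")
    table["group"] = ""
    table["on_states"] = ""
    table["p_value"] = np.nan
    table["significant"] = False

    if not elig_idx:
        return BinaryCallSet(stage=stage, states=state_names,
                             threshold=np.nan, table=table)

    results = {}
    for j in elig_idx:
        res = greedy_supergroup(Z[:, j], states, test)
        results[genes[j]] = res
        table.loc[genes[j], ["group", "on_states", "p_value"]] = (
            ";".join(res.group), ";".join(res.on_states), res.p_star,
        )

    Ze = Z[:, elig_idx]
    if shuffle_mode == "pooled":
        tau, _ = shuffle_threshold(Ze, states, n_shuffles, fdr, seed, test,
                                   embryos)
        for gene, res in results.items():
            table.loc[gene, "significant"] = bool(res.p_star < tau)
    else:
        rank = math.ceil(fdr * n_shuffles)
        taus = []
        for pos, j in enumerate(elig_idx):
            tau_g, _ = shuffle_threshold(
                Z[:, [j]], states, n_shuffles, fdr, seed + pos, test, embryos
            )
            taus.append(tau_g)
            gene = genes[j]
            table.loc[gene, "significant"] = bool(results[gene].p_star < tau_g)
        tau = float(np.median(taus))

    return BinaryCallSet(stage=stage, states=state_names,
                         threshold=float(tau), table=table)
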