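"""Signed hypergeometric enrichment/depletion of TF families per cell
state, with lineage x stage aggregation.

For one cell state expressing n TFs of which k belong to a family of
size K within a universe of N annotated TFs, both cumulative tails of
the hypergeometric distribution are computed:

    p_enr = P(X >= k)        (over-representation)
    p_dep = P(X <= k)        (under-representation)

The smaller tail picks the branch, and the score is the signed log
p-value, s = +(-log10 p_enr) for enrichments and s = -(-log10 p_dep)
for depletions.  Both tails include P(X = k), so p_enr + p_dep >= 1 and
the branch is unique except at exact ties, which resolve to the
enrichment branch.  Tail probabilities are exact (log-space factorials
via the scipy hypergeometric distribution); no normal approximation.

Lineage/stage structure in the per-state scores is summarized by a
two-sample Welch t test of the signed scores of the states inside a
(family, lineage, stage) group against all other states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import BinaryCallSet
from .lineage import LineageTree


@dataclass(frozen=True)
class TFAnnotation:
    """TF universe: gene -> DNA-binding-domain family."""

    family: dict[str, str]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "TFAnnotation":
        if not {"gene", "family"} <= set(table.columns):
            raise ValueError("annotation table needs columns gene, family")
        return cls(family=dict(zip(table["gene"], table["family"])))

    @classmethod
    def from_tsv(cls, path) -> "TFAnnotation":
        return cls.from_table(pd.read_csv(path, sep="\t"))

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.family)

    @property
    def N(self) -> int:
        return len(self.family)

    def family_size(self, family: str) -> int:
        return sum(1 for f in self.family.values() if f == family)

    def families(self) -> list[str]:
        return sorted(set(self.family.values()))


def signed_score(n: int, k: int, N: int, K: int) -> tuple[float, float]:
    """Signed enrichment score and the winning tail p-value.

    Parameters
    ----------
    n : TFs expressed by the cell state (draws).
    k : of those, members of the family (successes).
    N : TF universe size.
    K : family size within the universe.

    Returns ``(s, p)`` where ``s = +(-log10 p_enr)`` if the enrichment
    tail is the smaller (ties included) else ``-(-log10 p_dep)``.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(
            f"invalid hypergeometric parameters: n={n}, k={k}, N={N}, K={K} "
            "(need 0 <= k <= n <= N and k <= K <= N)"
        )
    p_enr = float(stats.hypergeom.sf(k - 1, N, K, n))   # P(X >= k)
    p_dep = float(stats.hypergeom.cdf(k, N, K, n))      # P(X <= k)
    if p_enr <= p_dep:
        return -math.log10(max(p_enr, 1e-300)), p_enr
    return math.log10(max(p_dep, 1e-300)), p_dep


def expressed_tfs(
    state: str, calls: BinaryCallSet, annot: TFAnnotation
) -> frozenset[str]:
    """TFs whose significant binary profile has this state on the 'on' side."""
    out = set()
    for gene in calls.significant_genes():
        if gene in annot.family and state in calls.on_states(gene):
            out.add(gene)
    return frozenset(out)


@dataclass
class EnrichmentMatrix:
    """Per-(state, family) signed scores for one or more stages.

    ``table`` columns: stage, state, family, n, k, signed_score, p_value.
    """

    table: pd.DataFrame
    N: int

    def score(self, state: str, family: str) -> float:
        sel = self.table[(self.table["state"] == state)
                         & (self.table["family"] == family)]
        if sel.empty:
            raise KeyError((state, family))
        return float(sel["signed_score"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def score_states(
    calls: BinaryCallSet,
    annot: TFAnnotation,
    families: list[str] | None = None,
) -> EnrichmentMatrix:
    """Signed score for every (state, family) pair of one stage.

    The universe is the full annotation table (global universe); states
    expressing no TFs receive a score of 0 for every family.
    """
    families = families if families is not None else annot.families()
    N = annot.N
    rows = []
    for state in calls.states:
        tfs = expressed_tfs(state, calls, annot)
        n = len(tfs)
        for fam in families:
            K = annot.family_size(fam)
            k = sum(1 for g in tfs if annot.family[g] == fam)
            if n == 0 or K == 0:
                s, p = 0.0, 1.0
            else:
                s, p = signed_score(n, k, N, K)
            rows.append({
                "stage": calls.stage, "state": state, "family": fam,
                "n": n, "k": k, "signed_score": s, "p_value": p,
            })
    return EnrichmentMatrix(table=pd.DataFrame(rows), N=N)


def aggregate(
    enrichments: EnrichmentMatrix,
    family: str,
    lineage: str,
    stage: int,
    tree: LineageTree | None = None,
) -> tuple[float, float]:
    """Welch t test of one family's signed scores: states of the given
    founder lineage at the given stage versus all other scored states.

    Returns (t, p); (nan, nan) when either side has fewer than two
    states or both sides are constant.
    """
    tree = tree or LineageTree.default()
    tab = enrichments.table[enrichments.table["family"] == family]
    if tab.empty:
        raise KeyError(f"family {family!r} not scored")

    def in_group(row) -> bool:
        # equivalence-group states are named "A/B"; membership follows
        # the first named identity
        first = str(row["state"]).split("/")[0]
        try:
            fnd = tree.founder_of(first)
        except KeyError:
            return False
        return row["stage"] == stage and fnd == lineage

    mask = tab.apply(in_group, axis=1)
    inside = tab.loc[mask, "signed_score"].to_numpy(dtype=float)
    outside = tab.loc[~mask, "signed_score"].to_numpy(dtype=float)
    if len(inside) < 2 or len(outside) < 2:
        return (float("nan"), float("nan"))
    if np.ptp(inside) == 0 and np.ptp(outside) == 0:
        return (float("nan"), float("nan"))
    t, p = stats.ttest_ind(inside, outside, equal_var=False)
    return (float(t), float(p))


def aggregate_all(
    enrichments: EnrichmentMatrix,
    tree: LineageTree | None = None,
    lineages: tuple[str, ...] = ("AB", "MS", "E", "C", "D"),
) -> pd.DataFrame:
    """Aggregation t-tests over every (family, lineage, stage) triple
    present in the score table. Returns a tidy frame sorted by p."""
    tree = tree or LineageTree.default()
    stages = sorted(enrichments.table["stage"].unique())
    fams = sorted(enrichments.table["family"].unique())
    rows = []
    for fam in fams:
        for lin in lineages:
            for st in stages:
                t, p = aggregate(enrichments, fam, lin, st, tree)
                rows.append({"family": fam, "lineage": lin, "stage": st,
                             "t": t, "p": p})
    out = pd.DataFrame(rows)
    return out.sort_values("p", na_position="last").reset_index(drop=True)
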