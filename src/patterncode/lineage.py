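"""The invariant early C. elegans embryonic lineage as a queryable tree.

The worm embryo divides through a stereotyped series of cleavages: the
zygote P0 splits into the somatic precursor AB and the germ-line cell P1,
and successive asymmetric divisions of the P line spawn the somatic
founder lineages MS, E, C and D before arresting at the primordial germ
cell P4 (which finally divides into Z2 and Z3).  Daughter cells are named
by appending a letter for their position at division (a/p =
anterior/posterior, l/r = left/right) to the mother's name, e.g.
``ABplppp``; a handful of historical names (EMS, P2, ...) break the
prefix rule and are handled by an explicit rename table.

The canonical staging used throughout this package is the eight-stage
series of 1, 2, 4, 8, 15, 28, 51 and 102 cells.  Which divisions have
completed at the 15- and 51-cell stages is transcribed from Sulston-style
lineage references into a packaged table (``data/lineage.tsv``) rather
than computed; the table is versioned with the package and can be
overridden via :func:`LineageTree.from_table` for users who prefer a
different staging convention.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CANONICAL_STAGES = (1, 2, 4, 8, 15, 28, 51, 102)

#: Founder labels: the five somatic founder lineages, the terminal germ
#: cell P4 (with daughters Z2/Z3), and the pre-founder germ-line chain.
FOUNDERS = ("AB", "MS", "E", "C", "D", "P4", "P-line")


class UnknownCellError(KeyError):
    """Raised when a cell name is not part of the packaged lineage."""


class UnknownStageError(ValueError):
    """Raised for a stage size outside the canonical eight-stage series."""


@dataclass(frozen=True)
class LineageTree:
    """Static tree of the early embryonic lineage.

    Attributes
    ----------
    parent
        Map cell -> mother cell; the root ``P0`` is absent.
    founder
        Map cell -> founder label (one of :data:`FOUNDERS`).
    stages
        Map stage size -> frozenset of member cell names.
    """

    parent: dict[str, str]
    founder: dict[str, str]
    stages: dict[int, frozenset[str]]
    root: str = "P0"
    _children: dict[str, tuple[str, ...]] = field(default=None, repr=False)

    # -- construction ---------------------------------------------------

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "LineageTree":
        """Build a tree from a table with columns cell/parent/founder/stages.

        ``stages`` holds semicolon-joined stage sizes.  Basic structural
        invariants (unique names, known parents, stage cardinalities) are
        checked eagerly so a malformed override fails loudly.
        """
        required = {"cell", "parent", "founder", "stages"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"lineage table missing columns: {sorted(missing)}")
        if table["cell"].duplicated().any():
            dupes = table.loc[table["cell"].duplicated(), "cell"].tolist()
            raise ValueError(f"duplicate cell names in lineage table: {dupes}")

        parent, founder, stages = {}, {}, {}
        for row in table.itertuples(index=False):
            if isinstance(row.parent, str) and row.parent:
                parent[row.cell] = row.parent
            founder[row.cell] = row.founder
            for s in str(row.stages).split(";"):
                stages.setdefault(int(s), set()).add(row.cell)

        cells = set(founder)
        for child, mother in parent.items():
            if mother not in cells:
                raise ValueError(f"parent {mother!r} of {child!r} not in table")
        for size, members in stages.items():
            if len(members) != size:
                raise ValueError(
                    f"stage {size} has {len(members)} members in table"
                )
        children: dict[str, list[str]] = {}
        for child, mother in parent.items():
            children.setdefault(mother, []).append(child)
        tree = cls(
            parent=parent,
            founder=founder,
            stages={s: frozenset(m) for s, m in stages.items()},
        )
        object.__setattr__(
            tree, "_children", {m: tuple(sorted(c)) for m, c in children.items()}
        )
        return tree

    @classmethod
    def from_tsv(cls, path) -> "LineageTree":
        return cls.from_table(pd.read_csv(path, sep="\t", keep_default_na=False))

    @classmethod
    def default(cls) -> "LineageTree":
        """The packaged lineage to the 102-cell stage."""
        ref = importlib.resources.files("patterncode.data") / "lineage.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)

    # -- queries --------------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.founder)

    def cells_at_stage(self, stage_size: int) -> frozenset[str]:
        """Member cells of one canonical stage.

        Parameters
        ----------
        stage_size
            One of 1, 2, 4, 8, 15, 28, 51, 102.
        """
        try:
            return self.stages[int(stage_size)]
        except (KeyError, TypeError) as exc:
            raise UnknownStageError(
                f"unknown stage size {stage_size!r}; valid stages are "
                f"{sorted(self.stages)}"
            ) from exc

    def founder_of(self, cell: str) -> str:
        try:
            return self.founder[cell]
        except KeyError as exc:
            raise UnknownCellError(f"unknown cell name {cell!r}") from exc

    def parent_of(self, cell: str) -> str:
        if cell == self.root:
            raise ValueError(f"root cell {self.root!r} has no parent")
        if cell not in self.founder:
            raise UnknownCellError(f"unknown cell name {cell!r}")
        return self.parent[cell]

    def children_of(self, cell: str) -> tuple[str, ...]:
        if cell not in self.founder:
            raise UnknownCellError(f"unknown cell name {cell!r}")
        return self._children.get(cell, ())

    def ancestors(self, cell: str) -> list[str]:
        """Chain of mothers from ``cell`` (exclusive) up to the root."""
        out = []
        while cell != self.root:
            cell = self.parent_of(cell)
            out.append(cell)
        return out

    def founder_counts(self, stage_size: int) -> dict[str, int]:
        """Number of stage members per founder label."""
        counts: dict[str, int] = {}
        for cell in self.cells_at_stage(stage_size):
            label = self.founder[cell]
            counts[label] = counts.get(label, 0) + 1
        return counts


# ----------------------------------------------------------------------
# Synthetic 3D cell positions
# ----------------------------------------------------------------------

_FOUNDER_X = {
    "AB": 0.30, "MS": 0.48, "E": 0.58, "C": 0.68, "D": 0.78,
    "P4": 0.90, "P-line": 0.55,
}


def synthetic_positions(
    tree: LineageTree, stage_size: int, jitter: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Deterministic synthetic 3D coordinates for one stage.

    This is a *synthetic geometry*, not measured embryo anatomy: each
    founder lineage is laid out along the anterior-posterior axis (+x =
    posterior by convention) at a literature-inspired base position, and
    every a/p division step moves the daughters apart along x by a
    halving displacement while l/r steps separate along y.  The layout
    preserves the one property the stripe analysis relies on — cells
    whose names differ in early a/p steps are ordered consistently along
    x — and nothing else.  Real coordinates can be supplied instead as a
    TSV with columns stage, cell, x, y, z.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for cell in sorted(tree.cells_at_stage(stage_size)):
        fnd = tree.founder_of(cell)
        x, y, z = _FOUNDER_X[fnd], 0.0, 0.0
        # suffix letters after the founder name encode the division path
        if fnd in ("P4", "P-line"):
            suffix = ""
        else:
            suffix = cell[len(fnd):]
        step = 0.12
        for ch in suffix:
            if ch == "a":
                x -= step
            elif ch == "p":
                x += step
            elif ch == "l":
                y += step
            elif ch == "r":
                y -= step
            step *= 0.5
        if jitter:
            x, y, z = np.array([x, y, z]) + rng.normal(0, jitter, 3)
        rows.append((stage_size, cell, x, y, z))
    return pd.DataFrame(rows, columns=["stage", "cell", "x", "y", "z"])


def read_positions(path) -> pd.DataFrame:
    """Read a position table (TSV: stage, cell, x, y, z)."""
    df = pd.read_csv(path, sep="\t")
    required = {"stage", "cell", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"position table missing columns: {sorted(missing)}")
    return df
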