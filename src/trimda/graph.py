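"""Core containers for the miRNA-disease-lncRNA tripartite graph.

A tripartite graph here is three aligned binary bipartite layers over shared
entity sets: miRNA-disease (MD), miRNA-lncRNA (ML) and disease-lncRNA (DL).
The graph starts in stage ``"initial"`` (G0, the known associations) and is
promoted to stage ``"updated"`` (Gu) once the collaborative-filtering step
has recommended and added new miRNA edges.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

ROLES = ("miRNA", "disease", "lncRNA")

STAGE_INITIAL = "initial"
STAGE_UPDATED = "updated"


@dataclass(frozen=True)
class EntityIndex:
    """Ordered, unique entity names for one role, with stable positions."""

    names: tuple[str, ...]
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"duplicate names in {self.role} index")
        if len(self.names) == 0:
            raise ValueError(f"empty {self.role} index")
        object.__setattr__(self, "_pos", {n: i for i, n in enumerate(self.names)})

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._pos

    def position(self, name: str) -> int:
        """Row/column position of ``name``; KeyError suggests near matches."""
        try:
            return self._pos[name]
        except KeyError:
            near = difflib.get_close_matches(name, self.names, n=3)
            hint = f"; closest matches: {', '.join(near)}" if near else ""
            raise KeyError(f"unknown {self.role} {name!r}{hint}") from None


@dataclass
class AssociationTable:
    """A deduplicated binary edge list for one bipartite layer."""

    pairs: list[tuple[str, str]]
    left_role: str
    right_role: str
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        for role in (self.left_role, self.right_role):
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r}")
        if self.left_role == self.right_role:
            raise ValueError("left and right roles must differ")

    def __len__(self) -> int:
        return len(self.pairs)

    def oriented(self, left_role: str, right_role: str) -> "AssociationTable":
        """Return this table with columns in the requested role order."""
        if (left_role, right_role) == (self.left_role, self.right_role):
            return self
        if (left_role, right_role) == (self.right_role, self.left_role):
            return AssociationTable(
                pairs=[(b, a) for a, b in self.pairs],
                left_role=left_role,
                right_role=right_role,
                n_duplicates=self.n_duplicates,
            )
        raise ValueError(
            f"table has roles ({self.left_role}, {self.right_role}), "
            f"cannot orient to ({left_role}, {right_role})"
        )

    def names(self, role: str) -> set[str]:
        if role == self.left_role:
            return {a for a, _ in self.pairs}
        if role == self.right_role:
            return {b for _, b in self.pairs}
        raise ValueError(f"role {role!r} not in table")


@dataclass
class TripartiteGraph:
    """Three aligned binary adjacency matrices plus their entity indexes.

    ``A_MD`` is n_m x n_d, ``A_ML`` is n_m x n_l, ``A_DL`` is n_d x n_l,
    all with entries in {0, 1}.
    """

    A_MD: np.ndarray
    A_ML: np.ndarray
    A_DL: np.ndarray
    mirnas: EntityIndex
    diseases: EntityIndex
    lncrnas: EntityIndex
    stage: str = STAGE_INITIAL

    def __post_init__(self) -> None:
        n_m, n_d, n_l = len(self.mirnas), len(self.diseases), len(self.lncrnas)
        expected = {"A_MD": (n_m, n_d), "A_ML": (n_m, n_l), "A_DL": (n_d, n_l)}
        for attr, shape in expected.items():
            mat = np.asarray(getattr(self, attr))
            if mat.shape != shape:
                raise ValueError(f"{attr} has shape {mat.shape}, expected {shape}")
            if not np.isin(mat, (0, 1)).all():
                raise ValueError(f"{attr} must be binary")
            setattr(self, attr, mat.astype(np.int8))
        if self.stage not in (STAGE_INITIAL, STAGE_UPDATED):
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def n_m(self) -> int:
        return len(self.mirnas)

    @property
    def n_d(self) -> int:
        return len(self.diseases)

    @property
    def n_l(self) -> int:
        return len(self.lncrnas)

    def splice_mld(self) -> np.ndarray:
        """Concatenate A_ML and A_MD column-wise into the n_m x (n_l + n_d)
        combined neighbourhood matrix; row k is the indicator vector of all
        lncRNA and disease neighbours of miRNA k."""
        return np.concatenate([self.A_ML, self.A_MD], axis=1)

    def copy(self, stage: str | None = None) -> "TripartiteGraph":
        return TripartiteGraph(
            A_MD=self.A_MD.copy(),
            A_ML=self.A_ML.copy(),
            A_DL=self.A_DL.copy(),
            mirnas=self.mirnas,
            diseases=self.diseases,
            lncrnas=self.lncrnas,
            stage=self.stage if stage is None else stage,
        )

    def to_tables(self) -> tuple[AssociationTable, AssociationTable, AssociationTable]:
        """Edge lists reconstructed from the nonzero entries of each layer."""

        def layer(mat, left: EntityIndex, right: EntityIndex, lr, rr):
            rows, cols = np.nonzero(mat)
            pairs = [(left.names[r], right.names[c]) for r, c in zip(rows, cols)]
            return AssociationTable(pairs=pairs, left_role=lr, right_role=rr)

        return (
            layer(self.A_MD, self.mirnas, self.diseases, "miRNA", "disease"),
            layer(self.A_ML, self.mirnas, self.lncrnas, "miRNA", "lncRNA"),
            layer(self.A_DL, self.diseases, self.lncrnas, "disease", "lncRNA"),
        )


def _union_index(role: str, tables: Iterable[AssociationTable], ordering: str) -> EntityIndex:
    seen: dict[str, None] = {}
    for t in tables:
        if role in (t.left_role, t.right_role):
            col = 0 if t.left_role == role else 1
            for pair in t.pairs:
                seen.setdefault(pair[col], None)
    names: Sequence[str]
    if ordering == "lexicographic":
        names = sorted(seen)
    elif ordering == "input":
        names = list(seen)
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    if not names:
        raise ValueError(f"no {role} entities found in any table")
    return EntityIndex(names=tuple(names), role=role)


def build_tripartite(
    md: AssociationTable,
    ml: AssociationTable,
    dl: AssociationTable,
    ordering: str = "lexicographic",
) -> TripartiteGraph:
    """Assemble G0 from the three edge lists.

    Entity indexes are the union of names per role across all three tables, so
    an entity appearing in only one layer keeps an all-zero row/column in the
    other layers (needed to score diseases with no known miRNA).  Tables may
    be passed in either column orientation; they are re-oriented by role.
    """
    md = md.oriented("miRNA", "disease")
    ml = ml.oriented("miRNA", "lncRNA")
    dl = dl.oriented("disease", "lncRNA")

    tables = (md, ml, dl)
    mirnas = _union_index("miRNA", tables, ordering)
    diseases = _union_index("disease", tables, ordering)
    lncrnas = _union_index("lncRNA", tables, ordering)

    def adjacency(table, left: EntityIndex, right: EntityIndex) -> np.ndarray:
        mat = np.zeros((len(left), len(right)), dtype=np.int8)
        for a, b in table.pairs:
            mat[left.position(a), right.position(b)] = 1
        return mat

    return TripartiteGraph(
        A_MD=adjacency(md, mirnas, diseases),
        A_ML=adjacency(ml, mirnas, lncrnas),
        A_DL=adjacency(dl, diseases, lncrnas),
        mirnas=mirnas,
        diseases=diseases,
        lncrnas=lncrnas,
        stage=STAGE_INITIAL,
    )
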