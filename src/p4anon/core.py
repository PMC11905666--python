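"""Domain types shared by the whole engine.

Tabular microdata is modelled as an ordered table of *text* cells.  Every
attribute plays one of four roles:

``quasi_identifier``
    indirect identifier (age, sex, zip ...) that is transformed through a
    generalization hierarchy;
``sensitive``
    value that must not be linkable to an individual (diagnosis ...);
``insensitive``
    carried through unchanged;
``identifier``
    direct identifier, always masked in the output.

Numeric attributes are handled through hierarchies whose entries are interval
strings; the engine never interprets cell values, which keeps one uniform
mechanism for categorical and numeric data alike.  The suppression symbol is
``"*"`` and is by convention also the top level of every hierarchy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

SUPPRESSED = "*"

ROLES = ("quasi_identifier", "sensitive", "insensitive", "identifier")


class HierarchyError(ValueError):
    """A generalization hierarchy violates one of its structural invariants."""


class DuplicateLeafError(HierarchyError):
    pass


class RaggedHierarchyError(HierarchyError):
    pass


class InconsistentHierarchyError(HierarchyError):
    """Equal values at level j map to different values at level j+1."""


class UnknownValueError(ValueError):
    """A dataset cell is not a leaf of its attribute's hierarchy."""


class InternalConsistencyError(RuntimeError):
    """The merged output violates a guarantee the algorithm should provide."""


@dataclass(frozen=True)
class AttributeConfig:
    """Name, role and (for quasi-identifiers) hierarchy reference of a column."""

    name: str
    role: str
    hierarchy_ref: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(
                f"attribute {self.name!r}: unknown role {self.role!r}; "
                f"expected one of {ROLES}"
            )
        if self.role != "quasi_identifier" and self.hierarchy_ref is not None:
            raise ValueError(
                f"attribute {self.name!r}: hierarchy given but role is {self.role!r}"
            )


class Hierarchy:
    """A full-domain generalization hierarchy for one attribute.

    Stored as a rectangular table with one row per distinct leaf value and one
    column per generalization level ``0..L``; level 0 is the leaf itself and by
    convention level L of a single-top hierarchy is ``"*"``.  Equal values at
    level j must map to equal values at level j+1 (functional consistency),
    which is what makes level-wise recoding well defined.
    """

    __slots__ = ("_rows", "_levels", "_maps", "_cover")

    def __init__(self, rows: Sequence[Sequence[str]]):
        rows = [tuple(str(c) for c in r) for r in rows]
        if not rows:
            raise HierarchyError("hierarchy has no rows")
        width = len(rows[0])
        if width < 1:
            raise HierarchyError("hierarchy rows are empty")
        for i, r in enumerate(rows):
            if len(r) != width:
                raise RaggedHierarchyError(
                    f"row {i} has {len(r)} columns, expected {width} "
                    f"(leaf {r[0]!r})"
                )
        leaves = [r[0] for r in rows]
        seen: set[str] = set()
        for v in leaves:
            if v in seen:
                raise DuplicateLeafError(f"duplicate leaf value {v!r}")
            seen.add(v)
        # functional consistency level j -> j+1
        for j in range(width - 1):
            mapping: dict[str, str] = {}
            for r in rows:
                prev = mapping.get(r[j])
                if prev is None:
                    mapping[r[j]] = r[j + 1]
                elif prev != r[j + 1]:
                    raise InconsistentHierarchyError(
                        f"value {r[j]!r} at level {j} maps to both "
                        f"{prev!r} and {r[j + 1]!r} at level {j + 1}"
                    )
        self._rows = rows
        self._levels = width - 1
        self._maps = [{r[0]: r[j] for r in rows} for j in range(width)]
        self._cover = [Counter(r[j] for r in rows) for j in range(width)]

    # -- structure ---------------------------------------------------------
    @property
    def levels(self) -> int:
        """Maximum generalization level L."""
        return self._levels

    @property
    def domain_size(self) -> int:
        return len(self._rows)

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self._rows)

    @property
    def rows(self) -> tuple[tuple[str, ...], ...]:
        return tuple(self._rows)

    def level_map(self, level: int) -> Mapping[str, str]:
        """leaf value -> value at ``level`` (level 0 is the identity map)."""
        self._check_level(level)
        return self._maps[level]

    def values_at(self, level: int) -> tuple[str, ...]:
        self._check_level(level)
        out, seen = [], set()
        for r in self._rows:
            if r[level] not in seen:
                seen.add(r[level])
                out.append(r[level])
        return tuple(out)

    def _check_level(self, level: int) -> None:
        if not 0 <= level <= self._levels:
            raise HierarchyError(
                f"level {level} out of range [0, {self._levels}]"
            )

    # -- operations --------------------------------------------------------
    def generalize(self, value: str, level: int) -> str:
        self._check_level(level)
        try:
            return self._maps[level][value]
        except KeyError:
            raise UnknownValueError(
                f"value {value!r} is not a leaf of this hierarchy"
            ) from None

    def leaves_covered(self, value: str, level: int) -> int:
        """Number of leaf values that generalize to ``value`` at ``level``."""
        self._check_level(level)
        n = self._cover[level].get(value, 0)
        if n == 0:
            raise UnknownValueError(
                f"value {value!r} does not occur at level {level}"
            )
        return n

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Hierarchy(leaves={self.domain_size}, levels={self._levels})"


def build_hierarchy(rows: Iterable[Sequence[str]]) -> Hierarchy:
    """Validate and build a :class:`Hierarchy` from leaf rows."""
    return Hierarchy(list(rows))


def generalize_value(h: Hierarchy, value: str, level: int) -> str:
    return h.generalize(value, level)


def leaves_covered(h: Hierarchy, value: str, level: int) -> int:
    return h.leaves_covered(value, level)


@dataclass
class Dataset:
    """An ordered table of text records with attribute roles and stable row ids.

    ``df`` holds one string column per attribute; its (unique, integer) index
    carries the row ids that survive every transformation, so callers can
    restore the original record order after partitioned processing.
    """

    df: pd.DataFrame
    attributes: list[AttributeConfig]
    hierarchies: dict[str, Hierarchy] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValueError("attribute names are not unique")
        if list(self.df.columns) != names:
            missing = set(names) - set(self.df.columns)
            if missing:
                raise ValueError(f"dataset is missing columns {sorted(missing)}")
            self.df = self.df[names]
        if not self.df.index.is_unique:
            raise ValueError("row ids are not unique")
        for a in self.attributes:
            if a.role == "quasi_identifier" and a.name not in self.hierarchies:
                raise ValueError(
                    f"quasi-identifier {a.name!r} has no hierarchy attached"
                )

    @classmethod
    def from_records(
        cls,
        records: Sequence[Sequence[str]],
        attributes: Sequence[AttributeConfig],
        hierarchies: Mapping[str, Hierarchy],
    ) -> "Dataset":
        names = [a.name for a in attributes]
        df = pd.DataFrame(
            [[str(c) for c in r] for r in records], columns=names, dtype=object
        )
        return cls(df, list(attributes), dict(hierarchies))

    # -- views -------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def qi_names(self) -> list[str]:
        return [a.name for a in self.attributes if a.role == "quasi_identifier"]

    @property
    def sensitive_names(self) -> list[str]:
        return [a.name for a in self.attributes if a.role == "sensitive"]

    @property
    def row_ids(self) -> list[int]:
        return list(self.df.index)

    def subset(self, row_ids: Iterable[int]) -> "Dataset":
        ids = set(row_ids)
        sub = self.df.loc[[i for i in self.df.index if i in ids]]
        return Dataset(sub, self.attributes, self.hierarchies)

    def with_df(self, df: pd.DataFrame) -> "Dataset":
        return Dataset(df, self.attributes, self.hierarchies)

    def validate_leaves(self) -> None:
        """Check every quasi-identifier cell is a known hierarchy leaf."""
        for name in self.qi_names:
            leaves = set(self.hierarchies[name].leaves)
            col = self.df[name]
            bad = col[~col.isin(leaves)]
            if len(bad):
                rid = bad.index[0]
                raise UnknownValueError(
                    f"attribute {name!r}, row id {rid}: value "
                    f"{bad.iloc[0]!r} is not a hierarchy leaf"
                )


Scheme = tuple[int, ...]


def validate_scheme(d: Dataset, scheme: Sequence[int]) -> Scheme:
    qi = d.qi_names
    if len(scheme) != len(qi):
        raise ValueError(
            f"scheme has {len(scheme)} components, expected {len(qi)}"
        )
    out = []
    for name, lvl in zip(qi, scheme):
        top = d.hierarchies[name].levels
        if not 0 <= int(lvl) <= top:
            raise ValueError(
                f"level {lvl} for {name!r} out of range [0, {top}]"
            )
        out.append(int(lvl))
    return tuple(out)


def generalized_frame(d: Dataset, scheme: Sequence[int]) -> pd.DataFrame:
    """Quasi-identifier columns of ``d`` recoded at the scheme's levels."""
    scheme = validate_scheme(d, scheme)
    cols = {}
    for name, lvl in zip(d.qi_names, scheme):
        col = d.df[name]
        if lvl == 0:
            # level 0 is the identity, but unknown leaves must still surface
            mapped = col.where(col.isin(set(d.hierarchies[name].leaves)))
        else:
            mapped = col.map(d.hierarchies[name].level_map(lvl))
        if mapped.isna().any():
            rid = mapped.index[mapped.isna()][0]
            raise UnknownValueError(
                f"attribute {name!r}, row id {rid}: value "
                f"{d.df.at[rid, name]!r} is not a hierarchy leaf"
            )
        cols[name] = mapped
    return pd.DataFrame(cols, index=d.df.index)


@dataclass(frozen=True)
class EquivalenceClass:
    """Records indistinguishable on the generalized quasi-identifiers."""

    key: tuple[str, ...]
    member_row_ids: frozenset[int]
    sensitive_counts: Mapping[str, Mapping[str, int]]

    @property
    def size(self) -> int:
        return len(self.member_row_ids)

    def counts(self, attr: str) -> Mapping[str, int]:
        return self.sensitive_counts[attr]


def group_into_classes(d: Dataset, scheme: Sequence[int]) -> list[EquivalenceClass]:
    """Partition ``d`` into equivalence classes under ``scheme``.

    Classes are returned sorted lexicographically by key so that all
    downstream iteration orders are canonical.
    """
    frame = generalized_frame(d, scheme)
    qi = list(frame.columns)
    if not qi:
        raise ValueError("dataset has no quasi-identifiers")
    sens = d.sensitive_names
    sens_arrays = {a: d.df[a].to_numpy() for a in sens}
    ids = d.df.index.to_numpy()
    grouped = frame.groupby(qi, sort=True).indices
    classes = []
    for key in sorted(grouped):
        key_t = key if isinstance(key, tuple) else (key,)
        pos = grouped[key]
        counts = {
            a: dict(sorted(Counter(arr[pos]).items()))
            for a, arr in sens_arrays.items()
        }
        classes.append(
            EquivalenceClass(key_t, frozenset(ids[pos].tolist()), counts)
        )
    return classes


@dataclass(frozen=True)
class ReferenceStats:
    """Record count and sensitive-value distributions of a reference scope.

    The distributions play the role of the background distribution q used by
    t-closeness, δ-disclosure and β-likeness.  ``scope`` records whether they
    were computed on the whole input ("global") or on one partition.
    """

    n: int
    sensitive_dist: Mapping[str, Mapping[str, float]]
    scope: str = "global"

    def dist(self, attr: str) -> Mapping[str, float]:
        try:
            return self.sensitive_dist[attr]
        except KeyError:
            raise ValueError(
                f"no reference distribution for sensitive attribute {attr!r}"
            ) from None


def reference_stats(d: Dataset, scope: str = "global") -> ReferenceStats:
    dists: dict[str, dict[str, float]] = {}
    for a in d.sensitive_names:
        counts = Counter(d.df[a])
        total = sum(counts.values())
        dists[a] = {v: c / total for v, c in sorted(counts.items())}
    return ReferenceStats(n=d.n, sensitive_dist=dists, scope=scope)
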