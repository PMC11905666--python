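"""Data-fidelity (domain coverage) utility metric.

A generalized cell is less useful the larger the share of its attribute's
domain it covers.  With D leaves in the hierarchy and ``covered`` the number
of leaves generalizing to the cell value, per-cell fidelity is

    1 - (covered - 1) / (D - 1)        (1 when D == 1)

so an untouched leaf scores 1 and a fully suppressed cell ("*", covering the
whole domain) scores 0.  Record fidelity is the mean over its quasi-identifier
cells, dataset fidelity the mean over records; suppressed records therefore
contribute 0.  The verbal "degree of domain coverage" definition admits
several normalizations, so the per-cell formula is a named, swappable
strategy (``CELL_FIDELITY``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import Dataset, Hierarchy


def coverage_loss(covered: int, domain_size: int) -> float:
    """Default strategy: normalized coverage loss, 1 − (covered−1)/(D−1)."""
    if domain_size <= 1:
        return 1.0
    return 1.0 - (covered - 1) / (domain_size - 1)


#: swappable per-cell strategy mapping (covered, domain size) -> [0, 1]
CELL_FIDELITY: Callable[[int, int], float] = coverage_loss


def cell_fidelity(h: Hierarchy, value: str, level: int) -> float:
    return CELL_FIDELITY(h.leaves_covered(value, level), h.domain_size)


def fidelity_map(h: Hierarchy, level: int) -> dict[str, float]:
    """leaf value -> fidelity of its level-``level`` generalization."""
    lm = h.level_map(level)
    by_value = {v: CELL_FIDELITY(h.leaves_covered(v, level), h.domain_size)
                for v in set(lm.values())}
    return {leaf: by_value[v] for leaf, v in lm.items()}


def _value_fidelity_map(h: Hierarchy) -> dict[str, float]:
    # Fidelity of any value appearing anywhere in the hierarchy table,
    # resolved at the lowest level containing it (i.e. minimal coverage).
    # Exact whenever labels are not reused across levels for different
    # groupings, which holds for all sane hierarchies.
    out: dict[str, float] = {}
    for level in range(h.levels, -1, -1):
        for v in h.values_at(level):
            out[v] = CELL_FIDELITY(h.leaves_covered(v, level), h.domain_size)
    # suppressed cells cover the whole domain even when "*" is not the
    # hierarchy's own top label
    out.setdefault("*", 0.0)
    return out


@dataclass(frozen=True)
class FidelitySummary:
    record_count: int
    mean_fidelity: float
    per_attribute_mean: Mapping[str, float]


def dataset_fidelity(output: Dataset) -> FidelitySummary:
    """Fidelity of a generalized dataset (hierarchies attached to ``output``)."""
    qi = output.qi_names
    if not qi or output.n == 0:
        return FidelitySummary(output.n, 1.0 if output.n else 0.0, {})
    per_attr = {}
    stack = np.empty((len(qi), output.n), dtype=float)
    for i, name in enumerate(qi):
        vmap = _value_fidelity_map(output.hierarchies[name])
        col = output.df[name].map(vmap)
        if col.isna().any():
            rid = col.index[col.isna()][0]
            raise ValueError(
                f"attribute {name!r}, row id {rid}: value "
                f"{output.df.at[rid, name]!r} not found in its hierarchy"
            )
        stack[i] = col.to_numpy(dtype=float)
        per_attr[name] = float(stack[i].mean())
    return FidelitySummary(output.n, float(stack.mean(axis=0).mean()), per_attr)


def pooled_fidelity(parts: Sequence[FidelitySummary]) -> float:
    """Record-count-weighted mean of per-partition fidelities.

    Identical to computing :func:`dataset_fidelity` on the concatenated
    output, which is the only self-consistent aggregation rule.
    """
    if not parts:
        raise ValueError("no partitions to pool")
    total = sum(p.record_count for p in parts)
    if total == 0:
        raise ValueError("zero records in pooled partitions")
    return sum(p.record_count * p.mean_fidelity for p in parts) / total


def relative_reduction(baseline: float, value: float) -> float:
    """Percentage reduction relative to ``baseline`` (negative = a gain)."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return 100.0 * (baseline - value) / baseline
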