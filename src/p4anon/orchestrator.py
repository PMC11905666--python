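"""The four-step partition-parallel anonymization procedure.

1. **Anonymizing partitions** — records are sorted lexicographically by their
   quasi-identifier values, split into balanced contiguous partitions, and
   each partition is anonymized independently (in parallel) with the settings
   configured for the whole dataset, using partition-local reference
   statistics.
2. **Harmonization** (global transformation only) — one common generalization
   scheme is derived from the per-partition schemes (average level rounded
   half-up, minimum, or lower median) and re-applied to every partition;
   classes failing a class-level model under the forced scheme are suppressed
   regardless of the suppression limit, because privacy outranks the limit
   once the scheme is fixed.
3. **Compliance checking** (only when a non-monotonic model is configured) —
   equivalence classes that fall together when the partitions are merged are
   re-checked against every non-monotonic class-level model using the global
   reference distribution; failing classes are suppressed.
4. **Finalization** — partitions are merged (sorted order, row ids allow
   restoring input order), all models are re-verified, dataset-level models
   are enforced on the merged result, and utility is assessed.

Everything is deterministic: iteration orders are canonical and the parallel
step yields byte-identical results for any worker count.
"""

from __future__ import annotations

import logging
import time
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Sequence

import pandas as pd
from joblib import Parallel, delayed

from .core import (
    SUPPRESSED,
    Dataset,
    EquivalenceClass,
    InternalConsistencyError,
    ReferenceStats,
    Scheme,
    group_into_classes,
    reference_stats,
)
from .models import PrivacyModel, check_class, dataset_passes, is_monotonic
from .transform import (
    AnonymizationResult,
    _classes_from_output,
    apply_scheme,
    local_recoding,
    search_optimal,
)
from .utility import FidelitySummary, dataset_fidelity, pooled_fidelity

logger = logging.getLogger("p4anon")

STAGES = ("anonymization", "harmonization", "compliance", "finalization")


@dataclass
class Partition:
    index: int
    dataset: Dataset
    result: AnonymizationResult | None = None


@dataclass
class P4Report:
    partitions: int
    transformation: str
    step_durations: dict[str, float] = field(default_factory=dict)
    per_partition_schemes: list[Any] = field(default_factory=list)
    harmonized_scheme: Scheme | None = None
    suppressed_counts: dict[str, int] = field(default_factory=dict)
    fidelity: float = 0.0

    def to_dict(self) -> dict[str, Any]:
        return {
            "partitions": self.partitions,
            "transformation": self.transformation,
            "step_durations": dict(self.step_durations),
            "per_partition_schemes": [
                list(s) if s is not None else None
                for s in self.per_partition_schemes
            ],
            "harmonized_scheme": (
                list(self.harmonized_scheme)
                if self.harmonized_scheme is not None
                else None
            ),
            "suppressed_counts": dict(self.suppressed_counts),
            "fidelity": self.fidelity,
        }


def lexicographic_partition(d: Dataset, partitions: int) -> list[Partition]:
    """Sort by quasi-identifier tuple (codepoint order) and cut into
    ``partitions`` contiguous chunks whose sizes differ by at most one."""
    if partitions < 1:
        raise ValueError("number of partitions must be >= 1")
    qi = d.qi_names
    sorted_df = d.df.sort_values(by=qi, kind="mergesort")
    n = len(sorted_df)
    base, extra = divmod(n, partitions)
    parts = []
    start = 0
    for i in range(partitions):
        size = base + (1 if i < extra else 0)
        parts.append(
            Partition(i, d.with_df(sorted_df.iloc[start : start + size]))
        )
        start += size
    return parts


def _anonymize_one(
    part: Partition,
    models: Sequence[PrivacyModel],
    transformation: str,
    suppression_limit: float,
    local_iterations: int,
    lattice_node_cap: int,
    prune: bool,
) -> tuple[AnonymizationResult, float]:
    t0 = time.perf_counter()
    ref = reference_stats(part.dataset, scope="partition")
    if transformation == "local":
        res = local_recoding(
            part.dataset,
            models,
            ref=ref,
            suppression_limit=suppression_limit,
            iterations=local_iterations,
            lattice_node_cap=lattice_node_cap,
            prune=prune,
        )
    else:
        res = search_optimal(
            part.dataset,
            models,
            ref=ref,
            suppression_limit=suppression_limit,
            lattice_node_cap=lattice_node_cap,
            prune=prune,
        )
    if res.suppressed_row_ids and len(res.suppressed_row_ids) == part.dataset.n:
        logger.warning(
            "partition %d (%d records) was fully suppressed",
            part.index,
            part.dataset.n,
        )
    return res, time.perf_counter() - t0


def anonymize_partitions(
    parts: Sequence[Partition],
    models: Sequence[PrivacyModel],
    *,
    transformation: str = "global",
    suppression_limit: float = 1.0,
    local_iterations: int = 10,
    lattice_node_cap: int = 10**6,
    prune: bool = True,
    workers: int | None = None,
) -> list[float]:
    """Anonymize each partition independently; results attach to ``parts``.

    Deterministic for any worker count: partitions are pure, independent
    tasks and results are collected in partition order.
    """
    workers = workers or len(parts)
    args = (
        models,
        transformation,
        suppression_limit,
        local_iterations,
        lattice_node_cap,
        prune,
    )
    if workers == 1 or len(parts) == 1:
        pairs = [_anonymize_one(p, *args) for p in parts]
    else:
        pairs = Parallel(n_jobs=workers, backend="threading")(
            delayed(_anonymize_one)(p, *args) for p in parts
        )
    durations = []
    for part, (res, dur) in zip(parts, pairs):
        part.result = res
        durations.append(dur)
    return durations


def harmonize_schemes(
    schemes: Sequence[Scheme], strategy: str = "average"
) -> Scheme:
    """Combine per-partition level vectors into one common scheme.

    ``average`` takes the arithmetic mean per attribute, rounded half-up to
    an integer; ``minimum`` the component-wise minimum; ``median`` the lower
    median.  The result always lies within [min, max] of the inputs.
    """
    if not schemes:
        raise ValueError("no schemes to harmonize")
    width = len(schemes[0])
    if any(len(s) != width for s in schemes):
        raise ValueError("schemes have differing lengths")
    out = []
    for i in range(width):
        levels = sorted(s[i] for s in schemes)
        if strategy == "minimum":
            out.append(levels[0])
        elif strategy == "median":
            out.append(levels[(len(levels) - 1) // 2])
        elif strategy == "average":
            mean = sum(levels) / len(levels)
            out.append(int(mean + 0.5))  # round half-up
        else:
            raise ValueError(f"unknown harmonization strategy {strategy!r}")
    return tuple(out)


def reapply_harmonized(
    parts: Sequence[Partition],
    scheme: Scheme,
    models: Sequence[PrivacyModel],
) -> None:
    """Re-anonymize every partition at exactly ``scheme`` (global mode).

    Classes failing a class-level model under the forced scheme are
    suppressed with no limit.  Partitions whose chosen scheme already equals
    ``scheme`` are reused unchanged.
    """
    class_models = [m for m in models if m.level == "class"]
    for part in parts:
        if part.result is not None and part.result.chosen_scheme == scheme:
            continue
        d = part.dataset
        ref = reference_stats(d, scope="partition")
        out = apply_scheme(d, scheme)
        classes = group_into_classes(d, scheme)
        suppressed: set[int] = set()
        surviving = []
        for c in classes:
            if all(check_class(m, c, ref) for m in class_models):
                surviving.append(c)
            else:
                suppressed |= c.member_row_ids
        if suppressed:
            out.df.loc[sorted(suppressed), d.qi_names] = SUPPRESSED
        part.result = AnonymizationResult(
            output=out,
            chosen_scheme=scheme,
            suppressed_row_ids=frozenset(suppressed),
            fidelity=dataset_fidelity(out).mean_fidelity,
            classes=surviving,
        )


def _merged_classes(
    results: Sequence[AnonymizationResult],
) -> list[tuple[tuple[str, ...], list[tuple[int, list[int]]]]]:
    """Pool non-suppressed output rows of all partitions and group by the
    generalized key.  Returns (key, [(partition index, row ids), ...])."""
    qi = results[0].output.qi_names
    by_key: dict[tuple[str, ...], list[tuple[int, list[int]]]] = {}
    for pi, res in enumerate(results):
        df = res.output.df
        supp = res.suppressed_row_ids
        keep = df.index.difference(list(supp)) if supp else df.index
        sub = df.loc[keep]
        if not len(sub):
            continue
        grouped = sub.groupby(qi, sort=True).indices
        ids = sub.index.to_numpy()
        for key, pos in grouped.items():
            key_t = key if isinstance(key, tuple) else (key,)
            by_key.setdefault(key_t, []).append((pi, ids[pos].tolist()))
    return sorted(by_key.items())


def compliance_check(
    results: Sequence[AnonymizationResult],
    models: Sequence[PrivacyModel],
    global_ref: ReferenceStats,
) -> dict[tuple[str, ...], frozenset[int]]:
    """Check merged equivalence classes against non-monotonic models.

    Classes that fall together when partitions are merged are evaluated with
    the global reference distribution; records of failing classes are
    suppressed in place.  Monotonic models cannot fail on merge, so when only
    monotonic models are configured the step is a no-op.
    """
    nm = [
        m for m in models if m.level == "class" and not is_monotonic(m)
    ]
    if not nm:
        return {}
    suppressed: dict[tuple[str, ...], frozenset[int]] = {}
    sens = results[0].output.sensitive_names
    for key, members in _merged_classes(results):
        all_ids = [rid for _, ids in members for rid in ids]
        counts_cache: dict[str, dict[str, int]] = {}

        def counts_for(attr: str) -> dict[str, int]:
            if attr not in counts_cache:
                ctr: Counter = Counter()
                for pi, ids in members:
                    ctr.update(results[pi].output.df.loc[ids, attr])
                counts_cache[attr] = dict(ctr)
            return counts_cache[attr]

        cls = EquivalenceClass(
            key,
            frozenset(all_ids),
            {a: counts_for(a) for a in sens},
        )
        if all(check_class(m, cls, global_ref) for m in nm):
            continue
        suppressed[key] = frozenset(all_ids)
        for pi, ids in members:
            res = results[pi]
            res.output.df.loc[ids, res.output.qi_names] = SUPPRESSED
            res.suppressed_row_ids = res.suppressed_row_ids | frozenset(ids)
    if suppressed:
        logger.info(
            "compliance checking suppressed %d merged classes (%d records)",
            len(suppressed),
            sum(len(v) for v in suppressed.values()),
        )
    return suppressed


def finalize(
    results: Sequence[AnonymizationResult],
    models: Sequence[PrivacyModel],
    global_ref: ReferenceStats,
    *,
    restore_order: bool = False,
) -> tuple[Dataset, FidelitySummary, int]:
    """Merge partitions, verify the guarantee, enforce dataset-level models.

    Returns the merged dataset, its fidelity summary, and the number of
    records additionally suppressed while enforcing dataset-level models
    (forcing a harmonized scheme or removing merged classes during
    compliance checking can legitimately push a class/record ratio over its
    threshold; whole smallest classes are suppressed until it holds again).
    Class-level violations at this point indicate an implementation bug and
    raise :class:`InternalConsistencyError`.
    """
    merged_df = pd.concat([r.output.df for r in results])
    template = results[0].output
    merged = Dataset(merged_df, template.attributes, template.hierarchies)
    suppressed = frozenset().union(
        *(r.suppressed_row_ids for r in results)
    )
    classes = _classes_from_output(merged, suppressed)
    class_models = [m for m in models if m.level == "class"]
    for c in classes:
        for m in class_models:
            if not check_class(m, c, global_ref):
                raise InternalConsistencyError(
                    f"merged class {c.key} violates {m.describe()}"
                )
    # dataset-level enforcement
    ds_models = [m for m in models if m.level == "dataset"]
    extra_suppressed = 0
    if ds_models:
        live = sorted(classes, key=lambda c: (c.size, c.key))
        while live and not all(
            dataset_passes(m, [c.size for c in live]) for m in ds_models
        ):
            victim = live.pop(0)  # smallest class, ties by key
            ids = sorted(victim.member_row_ids)
            merged.df.loc[ids, merged.qi_names] = SUPPRESSED
            extra_suppressed += victim.size
        if extra_suppressed:
            logger.info(
                "finalization suppressed %d records to enforce "
                "dataset-level models",
                extra_suppressed,
            )
    if restore_order:
        merged.df = merged.df.sort_index()
    fid = dataset_fidelity(merged)
    return merged, fid, extra_suppressed


def run_p4(
    d: Dataset,
    models: Sequence[PrivacyModel],
    partitions: int = 1,
    *,
    transformation: str = "global",
    suppression_limit: float = 1.0,
    harmonization: str = "average",
    local_iterations: int = 10,
    lattice_node_cap: int = 10**6,
    prune: bool = True,
    workers: int | None = None,
    restore_order: bool = False,
) -> tuple[Dataset, P4Report]:
    """Run the full four-step procedure and return (output, report)."""
    if transformation not in ("global", "local"):
        raise ValueError(f"unknown transformation mode {transformation!r}")
    global_ref = reference_stats(d, scope="global")
    report = P4Report(partitions=partitions, transformation=transformation)

    # step 1: partition + parallel anonymization
    parts = lexicographic_partition(d, partitions)
    durations = anonymize_partitions(
        parts,
        models,
        transformation=transformation,
        suppression_limit=suppression_limit,
        local_iterations=local_iterations,
        lattice_node_cap=lattice_node_cap,
        prune=prune,
        workers=workers,
    )
    # the parallel step takes as long as its slowest partition
    report.step_durations["anonymization"] = max(durations)
    report.per_partition_schemes = [
        p.result.chosen_scheme
        if p.result.chosen_scheme is not None
        else list(p.result.iteration_schemes)
        for p in parts
    ]
    report.suppressed_counts["anonymization"] = sum(
        len(p.result.suppressed_row_ids) for p in parts
    )

    # step 2: harmonization (global transformation only)
    if transformation == "global":
        t0 = time.perf_counter()
        harmonized = harmonize_schemes(
            [p.result.chosen_scheme for p in parts], harmonization
        )
        reapply_harmonized(parts, harmonized, models)
        report.step_durations["harmonization"] = time.perf_counter() - t0
        report.harmonized_scheme = harmonized
        report.suppressed_counts["harmonization"] = sum(
            len(p.result.suppressed_row_ids) for p in parts
        )
    else:
        report.step_durations["harmonization"] = 0.0

    results = [p.result for p in parts]

    # step 3: compliance checking (non-monotonic models only)
    if any(not is_monotonic(m) for m in models):
        t0 = time.perf_counter()
        removed = compliance_check(results, models, global_ref)
        report.step_durations["compliance"] = time.perf_counter() - t0
        report.suppressed_counts["compliance"] = sum(
            len(v) for v in removed.values()
        )
    else:
        report.step_durations["compliance"] = 0.0
        report.suppressed_counts["compliance"] = 0

    # step 4: finalization
    t0 = time.perf_counter()
    merged, fid, extra = finalize(
        results, models, global_ref, restore_order=restore_order
    )
    per_part = [dataset_fidelity(r.output) for r in results]
    pooled = pooled_fidelity(per_part)
    if extra == 0 and abs(pooled - fid.mean_fidelity) > 1e-9:
        raise InternalConsistencyError(
            f"pooled fidelity {pooled} disagrees with merged fidelity "
            f"{fid.mean_fidelity}"
        )
    report.step_durations["finalization"] = time.perf_counter() - t0
    report.suppressed_counts["finalization"] = extra
    report.fidelity = fid.mean_fidelity
    for stage in STAGES:
        logger.info(
            "step %-14s %.4fs", stage, report.step_durations[stage]
        )
    return merged, report
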