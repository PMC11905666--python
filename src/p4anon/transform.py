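"""Full-domain generalization with record suppression and lattice search.

The search space is the lattice of level vectors (one level per
quasi-identifier).  A node is *valid* when, after suppressing the records of
every equivalence class failing a class-level model, the suppressed fraction
stays within the configured limit and all dataset-level models hold on the
surviving classes.  Among valid nodes the search returns the one with maximal
fidelity, breaking ties by smaller level sum and then lexicographically
smaller level vector — fully deterministic.

The search enumerates the lattice exhaustively (guarded by a node cap), with
optional predictive pruning: when every configured model is monotonic and the
suppression limit is 0, a valid node's successors are valid by monotonicity
and only their fidelity needs computing.  Pruning never changes the chosen
node.  Local recoding layers an iterative scheme on top: records kept by one
global search round are fixed, the suppressed residual is re-anonymized in
the next round, and whatever remains after the last round is suppressed.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    SUPPRESSED,
    Dataset,
    EquivalenceClass,
    InternalConsistencyError,
    ReferenceStats,
    Scheme,
    generalized_frame,
    group_into_classes,
    reference_stats,
    validate_scheme,
)
from .models import PrivacyModel, class_passes, dataset_passes
from .utility import dataset_fidelity, fidelity_map

_EPS = 1e-12


class InfeasibleError(RuntimeError):
    """No lattice node satisfies the models within the suppression limit."""


@dataclass
class LatticeNode:
    scheme: Scheme
    valid: bool
    fidelity: float
    suppressed_row_ids: frozenset[int]


@dataclass
class AnonymizationResult:
    """Output of one (global or local) anonymization run."""

    output: Dataset
    chosen_scheme: Scheme | None
    suppressed_row_ids: frozenset[int]
    fidelity: float
    classes: list[EquivalenceClass]
    #: local mode only: row id -> level vector used for that record
    scheme_assignment: dict[int, Scheme] | None = None
    #: local mode only: the scheme chosen in each iteration
    iteration_schemes: list[Scheme] = field(default_factory=list)


def apply_scheme(d: Dataset, scheme: Sequence[int]) -> Dataset:
    """Recode every quasi-identifier cell at the scheme's level (global)."""
    scheme = validate_scheme(d, scheme)
    out = d.df.copy()
    gen = generalized_frame(d, scheme)
    for name in gen.columns:
        out[name] = gen[name]
    for a in d.attributes:
        if a.role == "identifier":
            out[a.name] = SUPPRESSED
    return d.with_df(out)


class _SearchContext:
    """Per-dataset caches shared across lattice nodes.

    Generalized columns and per-record fidelity columns are computed once per
    (attribute, level) pair instead of once per node, which dominates the
    cost of enumerating the lattice.
    """

    def __init__(
        self,
        d: Dataset,
        models: Sequence[PrivacyModel],
        ref: ReferenceStats,
        suppression_limit: float,
    ):
        self.d = d
        self.ref = ref
        self.limit = suppression_limit
        self.qi = d.qi_names
        self.tops = tuple(d.hierarchies[a].levels for a in self.qi)
        self.class_models = [m for m in models if m.level == "class"]
        self.ds_models = [m for m in models if m.level == "dataset"]
        self.needs_counts = any(
            m.kind != "k_anonymity" for m in self.class_models
        )
        self.sens_arrays = {a: d.df[a].to_numpy() for a in d.sensitive_names}
        self._gen: dict[tuple[str, int], pd.Series] = {}
        self._fid: dict[tuple[str, int], np.ndarray] = {}

    def gen_col(self, name: str, level: int) -> pd.Series:
        key = (name, level)
        if key not in self._gen:
            if level == 0:
                self._gen[key] = self.d.df[name]
            else:
                h = self.d.hierarchies[name]
                self._gen[key] = self.d.df[name].map(h.level_map(level))
        return self._gen[key]

    def fid_col(self, name: str, level: int) -> np.ndarray:
        key = (name, level)
        if key not in self._fid:
            fmap = fidelity_map(self.d.hierarchies[name], level)
            self._fid[key] = (
                self.d.df[name].map(fmap).to_numpy(dtype=float)
            )
        return self._fid[key]

    def frame(self, scheme: Scheme) -> pd.DataFrame:
        return pd.DataFrame(
            {a: self.gen_col(a, lvl) for a, lvl in zip(self.qi, scheme)},
            index=self.d.df.index,
        )

    def node_fidelity(self, scheme: Scheme, supp_pos: np.ndarray) -> float:
        n = self.d.n
        rec = np.zeros(n, dtype=float)
        for a, lvl in zip(self.qi, scheme):
            rec += self.fid_col(a, lvl)
        rec /= len(self.qi)
        if len(supp_pos):
            rec[supp_pos] = 0.0
        return float(rec.mean())

    def evaluate(self, scheme: Scheme) -> LatticeNode:
        d = self.d
        frame = self.frame(scheme)
        grouped = frame.groupby(self.qi, sort=True).indices
        supp_chunks = []
        surviving_sizes = []
        for key, pos in grouped.items():
            size = len(pos)
            counts_cache: dict[str, Mapping[str, int]] = {}

            def counts_for(attr: str) -> Mapping[str, int]:
                if attr not in counts_cache:
                    counts_cache[attr] = Counter(self.sens_arrays[attr][pos])
                return counts_cache[attr]

            ok = all(
                class_passes(m, size, counts_for, self.ref)
                for m in self.class_models
            )
            if ok:
                surviving_sizes.append(size)
            else:
                supp_chunks.append(pos)
        supp_pos = (
            np.concatenate(supp_chunks) if supp_chunks else np.empty(0, int)
        )
        valid = len(supp_pos) / d.n <= self.limit + _EPS and all(
            dataset_passes(m, surviving_sizes) for m in self.ds_models
        )
        ids = d.df.index.to_numpy()
        return LatticeNode(
            scheme=scheme,
            valid=valid,
            fidelity=self.node_fidelity(scheme, supp_pos),
            suppressed_row_ids=frozenset(ids[supp_pos].tolist()),
        )


def evaluate_node(
    d: Dataset,
    scheme: Sequence[int],
    models: Sequence[PrivacyModel],
    ref: ReferenceStats | None = None,
    suppression_limit: float = 1.0,
) -> LatticeNode:
    """Evaluate a single lattice node (invalid nodes are returned, not raised)."""
    scheme = validate_scheme(d, scheme)
    if ref is None:
        ref = reference_stats(d, scope="partition")
    ctx = _SearchContext(d, models, ref, suppression_limit)
    return ctx.evaluate(scheme)


def _lattice(tops: Sequence[int], cap: int) -> list[Scheme]:
    size = 1
    for t in tops:
        size *= t + 1
    if size > cap:
        raise ValueError(
            f"lattice has {size} nodes, exceeding the configured cap {cap}"
        )
    nodes = list(itertools.product(*(range(t + 1) for t in tops)))
    nodes.sort(key=lambda s: (sum(s), s))
    return nodes


def _predecessors(scheme: Scheme):
    for i, lvl in enumerate(scheme):
        if lvl > 0:
            yield scheme[:i] + (lvl - 1,) + scheme[i + 1 :]


def _build_result(
    d: Dataset, ctx: _SearchContext, node: LatticeNode
) -> AnonymizationResult:
    out = apply_scheme(d, node.scheme)
    if node.suppressed_row_ids:
        sup = list(node.suppressed_row_ids)
        out.df.loc[sup, d.qi_names] = SUPPRESSED
    kept = d.subset(set(d.df.index) - node.suppressed_row_ids)
    classes = group_into_classes(kept, node.scheme) if kept.n else []
    return AnonymizationResult(
        output=out,
        chosen_scheme=node.scheme,
        suppressed_row_ids=node.suppressed_row_ids,
        fidelity=dataset_fidelity(out).mean_fidelity,
        classes=classes,
    )


def search_optimal(
    d: Dataset,
    models: Sequence[PrivacyModel],
    *,
    ref: ReferenceStats | None = None,
    suppression_limit: float = 1.0,
    lattice_node_cap: int = 10**6,
    prune: bool = True,
) -> AnonymizationResult:
    """Exhaustive lattice search for the valid node with maximal fidelity.

    ``ref`` defaults to the dataset's own sensitive-value distribution, so a
    direct call anonymizes against global statistics while the orchestrator
    passes partition-local statistics explicitly.
    """
    if ref is None:
        ref = reference_stats(d, scope="partition")
    ctx = _SearchContext(d, models, ref, suppression_limit)
    nodes = _lattice(ctx.tops, lattice_node_cap)
    pruning = (
        prune
        and suppression_limit <= _EPS
        and all(m.monotonic for m in models)
    )
    best: LatticeNode | None = None
    valid_set: set[Scheme] = set()
    for scheme in nodes:
        if pruning and any(p in valid_set for p in _predecessors(scheme)):
            node = LatticeNode(
                scheme=scheme,
                valid=True,
                fidelity=ctx.node_fidelity(scheme, np.empty(0, int)),
                suppressed_row_ids=frozenset(),
            )
        else:
            node = ctx.evaluate(scheme)
        if node.valid:
            valid_set.add(scheme)
            if best is None or node.fidelity > best.fidelity:
                best = node
    if best is None:
        raise InfeasibleError(
            "no generalization scheme satisfies the configured models "
            f"within suppression limit {suppression_limit}"
        )
    return _build_result(d, ctx, best)


def local_recoding(
    d: Dataset,
    models: Sequence[PrivacyModel],
    *,
    ref: ReferenceStats | None = None,
    suppression_limit: float = 1.0,
    iterations: int = 10,
    lattice_node_cap: int = 10**6,
    prune: bool = True,
) -> AnonymizationResult:
    """Iterative local recoding on top of the global search.

    Each round runs :func:`search_optimal` on the not-yet-fixed records and
    fixes the records of passing classes at that round's scheme; the
    suppressed residual moves to the next round.  After the last round the
    residual is fully suppressed.  The partition-level reference distribution
    is held fixed across rounds.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if ref is None:
        ref = reference_stats(d, scope="partition")
    out = d.df.copy()
    assignment: dict[int, Scheme] = {}
    iteration_schemes: list[Scheme] = []
    remaining = d
    suppressed: set[int] = set(d.df.index)
    for _ in range(iterations):
        if remaining.n == 0:
            break
        res = search_optimal(
            remaining,
            models,
            ref=ref,
            suppression_limit=suppression_limit,
            lattice_node_cap=lattice_node_cap,
            prune=prune,
        )
        kept_ids = set(remaining.df.index) - set(res.suppressed_row_ids)
        if not kept_ids:
            break  # fixpoint: further rounds would fix nothing either
        iteration_schemes.append(res.chosen_scheme)
        kept_list = [i for i in remaining.df.index if i in kept_ids]
        out.loc[kept_list] = res.output.df.loc[kept_list]
        for i in kept_list:
            assignment[i] = res.chosen_scheme
        suppressed -= kept_ids
        remaining = remaining.subset(res.suppressed_row_ids)
    if suppressed:
        out.loc[sorted(suppressed), d.qi_names] = SUPPRESSED
    for a in d.attributes:
        if a.role == "identifier":
            out[a.name] = SUPPRESSED
    output = d.with_df(out)
    classes = _classes_from_output(output, frozenset(suppressed))
    # dataset-level models are defined on the combined local output; each
    # round enforced them on its survivors, and pooling cannot worsen either
    # size-based model, so a failure here indicates a bug
    sizes = [c.size for c in classes]
    ds_models = [m for m in models if m.level == "dataset"]
    for m in ds_models:
        if not dataset_passes(m, sizes):
            raise InternalConsistencyError(
                f"combined local output violates {m.describe()}"
            )
    return AnonymizationResult(
        output=output,
        chosen_scheme=None,
        suppressed_row_ids=frozenset(suppressed),
        fidelity=dataset_fidelity(output).mean_fidelity,
        classes=classes,
        scheme_assignment=assignment,
        iteration_schemes=iteration_schemes,
    )


def _classes_from_output(
    output: Dataset, suppressed: frozenset[int]
) -> list[EquivalenceClass]:
    """Group non-suppressed output rows by their (already generalized) QI tuple."""
    qi = output.qi_names
    sens = output.sensitive_names
    df = output.df
    keep = [i for i in df.index if i not in suppressed]
    if not keep:
        return []
    sub = df.loc[keep]
    grouped = sub.groupby(qi, sort=True).indices
    ids = sub.index.to_numpy()
    sens_arrays = {a: sub[a].to_numpy() for a in sens}
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
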