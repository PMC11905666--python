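"""Syntactic privacy-model checkers and the monotonicity registry.

Class-level models constrain single equivalence classes (k-anonymity, the
ℓ-diversity family, t-closeness, δ-disclosure, β-likeness); dataset-level
models constrain the whole collection of classes (average re-identification
risk, sample uniqueness).  Every checker is a pure function of its inputs.

Boundary conventions follow each model's canonical statement: all threshold
comparisons are inclusive (|c| ≥ k, H ≥ ln ℓ, EMD ≤ t, gain ≤ β, risk ≤ τ)
except δ-disclosure, which is strict (|ln(p/q)| < δ).  Natural logarithms are
used throughout; the entropy-ℓ threshold is base-independent and LOG, the
base used for δ-disclosure, is a module constant so the convention can be
swapped in one place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from scipy.special import digamma

from .core import EquivalenceClass, ReferenceStats

#: natural log by default; set to ``math.log2`` for the base-2 convention
LOG: Callable[[float], float] = math.log

#: slack for inclusive floating-point threshold comparisons
EPS = 1e-9

KINDS = (
    "k_anonymity",
    "distinct_l",
    "entropy_l",
    "recursive_cl",
    "t_closeness_equal",
    "t_closeness_ordered",
    "delta_disclosure",
    "beta_likeness_basic",
    "beta_likeness_enhanced",
    "average_risk",
    "sample_uniqueness",
)

DATASET_LEVEL = frozenset({"average_risk", "sample_uniqueness"})

#: kinds whose check needs a reference (background) distribution q
REFERENCE_DEPENDENT = frozenset(
    {
        "t_closeness_equal",
        "t_closeness_ordered",
        "delta_disclosure",
        "beta_likeness_basic",
        "beta_likeness_enhanced",
    }
)

SENSITIVE_DEPENDENT = REFERENCE_DEPENDENT | frozenset(
    {"distinct_l", "entropy_l", "recursive_cl"}
)

# Monotonic: merging two passing classes with equal keys always yields a
# passing class.  t-closeness is the canonical non-monotonic example; the
# reference-dependent models are non-monotonic across partitions because each
# partition checks against its own local distribution; the Grassberger
# entropy estimator is conservatively flagged non-monotonic because the
# bias-corrected estimator's behaviour under mixing is not proven here.  A
# conservative flag only adds compliance checking, never weakens guarantees.
_MONOTONIC = frozenset(
    {
        "k_anonymity",
        "distinct_l",
        ("entropy_l", "shannon"),
        "recursive_cl",
        "average_risk",
        "sample_uniqueness",
    }
)


@dataclass(frozen=True)
class PrivacyModel:
    """One configured privacy requirement (conjunction semantics across models)."""

    kind: str
    k: int | None = None
    l: int | None = None
    c: float | None = None
    t: float | None = None
    delta: float | None = None
    beta: float | None = None
    threshold: float | None = None
    sensitive: str | None = None
    estimator: str = "shannon"
    order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown privacy model kind {self.kind!r}")
        req = {
            "k_anonymity": ("k",),
            "distinct_l": ("l",),
            "entropy_l": ("l",),
            "recursive_cl": ("c", "l"),
            "t_closeness_equal": ("t",),
            "t_closeness_ordered": ("t",),
            "delta_disclosure": ("delta",),
            "beta_likeness_basic": ("beta",),
            "beta_likeness_enhanced": ("beta",),
            "average_risk": ("threshold",),
            "sample_uniqueness": ("threshold",),
        }[self.kind]
        for p in req:
            v = getattr(self, p)
            if v is None:
                raise ValueError(f"{self.kind}: missing parameter {p!r}")
            if p in ("k", "l"):
                if int(v) != v or v < 1:
                    raise ValueError(f"{self.kind}: {p} must be an integer >= 1")
            elif p == "t":
                if not 0 < v <= 1:
                    raise ValueError(f"{self.kind}: t must be in (0, 1]")
            elif p == "threshold":
                if not 0 < v <= 1:
                    raise ValueError(f"{self.kind}: threshold must be in (0, 1]")
            elif v <= 0:
                raise ValueError(f"{self.kind}: {p} must be > 0")
        if self.kind in SENSITIVE_DEPENDENT and not self.sensitive:
            raise ValueError(f"{self.kind}: requires a sensitive attribute")
        if self.estimator not in ("shannon", "grassberger"):
            raise ValueError(f"unknown entropy estimator {self.estimator!r}")

    @property
    def level(self) -> str:
        return "dataset" if self.kind in DATASET_LEVEL else "class"

    @property
    def monotonic(self) -> bool:
        return is_monotonic(self)

    @property
    def needs_reference(self) -> bool:
        return self.kind in REFERENCE_DEPENDENT

    def describe(self) -> str:
        parts = [self.kind]
        for p in ("k", "l", "c", "t", "delta", "beta", "threshold"):
            v = getattr(self, p)
            if v is not None:
                parts.append(f"{p}={v}")
        if self.kind == "entropy_l":
            parts.append(self.estimator)
        if self.sensitive:
            parts.append(f"on {self.sensitive}")
        return " ".join(parts)


def is_monotonic(m: PrivacyModel) -> bool:
    """Registry lookup: may merged passing classes be assumed passing?"""
    if m.kind == "entropy_l":
        return (m.kind, m.estimator) in _MONOTONIC
    return m.kind in _MONOTONIC


# ---------------------------------------------------------------------------
# count-based primitives (hot path: called per equivalence class)
# ---------------------------------------------------------------------------

def shannon_entropy(counts: Mapping[str, int]) -> float:
    total = sum(counts.values())
    return -sum(
        (c / total) * math.log(c / total) for c in counts.values() if c > 0
    )


def grassberger_entropy(counts: Mapping[str, int]) -> float:
    """Bias-corrected entropy estimate, Grassberger's 1988 correction.

    H = ln N - (1/N) Σ n_i G(n_i) with G(n) = ψ(n) + (-1)^n / (n (n+1)).
    Swappable: later correction variants (e.g. the 2003 G(n)) can replace
    this function without touching any caller.
    """
    total = sum(counts.values())
    s = 0.0
    for n in counts.values():
        if n > 0:
            s += n * (float(digamma(n)) + (-1.0) ** n / (n * (n + 1)))
    return math.log(total) - s / total


def _class_dist(counts: Mapping[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {v: c / total for v, c in counts.items() if c > 0}


def emd_equal(p: Mapping[str, float], q: Mapping[str, float]) -> float:
    """Earth mover's distance under the unit (equal) ground distance.

    Supports are aligned by union with zero padding; the closed form is
    half the total variation, ½ Σ |p_i − q_i| ∈ [0, 1].
    """
    support = set(p) | set(q)
    return 0.5 * sum(abs(p.get(v, 0.0) - q.get(v, 0.0)) for v in support)


def emd_ordered(
    p: Mapping[str, float],
    q: Mapping[str, float],
    order: Sequence[str],
) -> float:
    """EMD with the ordered ground distance |i−j|/(m−1) over ``order``.

    Closed form: (1/(m−1)) Σ_{i<m} |Σ_{j≤i} (p_j − q_j)|, in [0, 1].
    Fewer than two values gives distance 0 (nothing can be displaced).
    """
    support = set(p) | set(q)
    missing = support - set(order)
    if missing:
        raise ValueError(f"ordering does not cover values {sorted(missing)}")
    m = len(order)
    if m < 2:
        return 0.0
    cum = 0.0
    total = 0.0
    for v in order[:-1]:
        cum += p.get(v, 0.0) - q.get(v, 0.0)
        total += abs(cum)
    return total / (m - 1)


def passes_k(size: int, k: int) -> bool:
    return size >= k


def passes_distinct_l(counts: Mapping[str, int], l: int) -> bool:
    return sum(1 for c in counts.values() if c > 0) >= l


def passes_entropy_l(
    counts: Mapping[str, int], l: int, estimator: str = "shannon"
) -> bool:
    h = (
        grassberger_entropy(counts)
        if estimator == "grassberger"
        else shannon_entropy(counts)
    )
    return h >= math.log(l) - EPS


def passes_recursive_cl(counts: Mapping[str, int], c: float, l: int) -> bool:
    rs = sorted((v for v in counts.values() if v > 0), reverse=True)
    if len(rs) < l:
        return False
    return rs[0] < c * sum(rs[l - 1 :])


def passes_t_closeness(
    counts: Mapping[str, int],
    q: Mapping[str, float],
    t: float,
    variant: str = "equal",
    order: Sequence[str] | None = None,
) -> bool:
    p = _class_dist(counts)
    if variant == "equal":
        d = emd_equal(p, q)
    else:
        if order is None:
            order = sorted(set(p) | set(q))
        d = emd_ordered(p, q, order)
    return d <= t + EPS


def passes_delta_disclosure(
    counts: Mapping[str, int], q: Mapping[str, float], delta: float
) -> bool:
    p = _class_dist(counts)
    for v, pv in p.items():
        qv = q.get(v, 0.0)
        if qv == 0.0:
            return False  # infinite disclosure
        if abs(LOG(pv / qv)) >= delta:
            return False
    return True


def passes_beta_likeness(
    counts: Mapping[str, int],
    q: Mapping[str, float],
    beta: float,
    enhanced: bool = False,
) -> bool:
    p = _class_dist(counts)
    for v, pv in p.items():
        qv = q.get(v, 0.0)
        if qv == 0.0:
            return False  # unbounded relative gain
        if pv > qv:
            bound = min(beta, -math.log(qv)) if enhanced else beta
            if (pv - qv) / qv > bound + EPS:
                return False
    return True


def passes_average_risk(sizes: Iterable[int], threshold: float) -> bool:
    sizes = [s for s in sizes if s > 0]
    if not sizes:
        return True
    # mean over records of 1/|class| equals (#classes)/(#records)
    return len(sizes) / sum(sizes) <= threshold + EPS


def passes_sample_uniqueness(sizes: Iterable[int], threshold: float) -> bool:
    sizes = [s for s in sizes if s > 0]
    if not sizes:
        return True
    return sum(1 for s in sizes if s == 1) / sum(sizes) <= threshold + EPS


# ---------------------------------------------------------------------------
# EquivalenceClass-facing checkers
# ---------------------------------------------------------------------------

def _counts(c: EquivalenceClass, attr: str | None) -> Mapping[str, int]:
    if attr is None:
        if len(c.sensitive_counts) != 1:
            raise ValueError("sensitive attribute must be named explicitly")
        attr = next(iter(c.sensitive_counts))
    return c.counts(attr)


def check_k_anonymity(c: EquivalenceClass, k: int) -> bool:
    return passes_k(c.size, k)


def check_distinct_l(
    c: EquivalenceClass, l: int, sensitive: str | None = None
) -> bool:
    return passes_distinct_l(_counts(c, sensitive), l)


def check_entropy_l(
    c: EquivalenceClass,
    l: int,
    estimator: str = "shannon",
    sensitive: str | None = None,
) -> bool:
    return passes_entropy_l(_counts(c, sensitive), l, estimator)


def check_recursive_cl(
    c: EquivalenceClass, cparam: float, l: int, sensitive: str | None = None
) -> bool:
    return passes_recursive_cl(_counts(c, sensitive), cparam, l)


def check_t_closeness(
    c: EquivalenceClass,
    ref: ReferenceStats,
    t: float,
    variant: str = "equal",
    sensitive: str | None = None,
    order: Sequence[str] | None = None,
) -> bool:
    counts = _counts(c, sensitive)
    attr = sensitive or next(iter(c.sensitive_counts))
    return passes_t_closeness(counts, ref.dist(attr), t, variant, order)


def check_delta_disclosure(
    c: EquivalenceClass,
    ref: ReferenceStats,
    delta: float,
    sensitive: str | None = None,
) -> bool:
    attr = sensitive or next(iter(c.sensitive_counts))
    return passes_delta_disclosure(_counts(c, attr), ref.dist(attr), delta)


def check_beta_likeness(
    c: EquivalenceClass,
    ref: ReferenceStats,
    beta: float,
    enhanced: bool = False,
    sensitive: str | None = None,
) -> bool:
    attr = sensitive or next(iter(c.sensitive_counts))
    return passes_beta_likeness(_counts(c, attr), ref.dist(attr), beta, enhanced)


def check_average_risk(
    classes: Sequence[EquivalenceClass], threshold: float
) -> bool:
    return passes_average_risk((c.size for c in classes), threshold)


def check_sample_uniqueness(
    classes: Sequence[EquivalenceClass], threshold: float
) -> bool:
    return passes_sample_uniqueness((c.size for c in classes), threshold)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def class_passes(
    model: PrivacyModel,
    size: int,
    counts_for: Callable[[str], Mapping[str, int]],
    ref: ReferenceStats | None,
) -> bool:
    """Evaluate one class-level model on one class (count-based hot path)."""
    kind = model.kind
    if kind == "k_anonymity":
        return passes_k(size, model.k)
    counts = counts_for(model.sensitive)
    if kind == "distinct_l":
        return passes_distinct_l(counts, model.l)
    if kind == "entropy_l":
        return passes_entropy_l(counts, model.l, model.estimator)
    if kind == "recursive_cl":
        return passes_recursive_cl(counts, model.c, model.l)
    if ref is None:
        raise ValueError(f"{kind} requires a reference distribution")
    q = ref.dist(model.sensitive)
    if kind == "t_closeness_equal":
        return passes_t_closeness(counts, q, model.t, "equal")
    if kind == "t_closeness_ordered":
        order = model.order or tuple(sorted(q))
        return passes_t_closeness(counts, q, model.t, "ordered", order)
    if kind == "delta_disclosure":
        return passes_delta_disclosure(counts, q, model.delta)
    if kind == "beta_likeness_basic":
        return passes_beta_likeness(counts, q, model.beta, enhanced=False)
    if kind == "beta_likeness_enhanced":
        return passes_beta_likeness(counts, q, model.beta, enhanced=True)
    raise ValueError(f"{kind} is not a class-level model")


def dataset_passes(model: PrivacyModel, sizes: Sequence[int]) -> bool:
    if model.kind == "average_risk":
        return passes_average_risk(sizes, model.threshold)
    if model.kind == "sample_uniqueness":
        return passes_sample_uniqueness(sizes, model.threshold)
    raise ValueError(f"{model.kind} is not a dataset-level model")


def check_class(
    model: PrivacyModel, c: EquivalenceClass, ref: ReferenceStats | None
) -> bool:
    return class_passes(model, c.size, c.counts, ref)


@dataclass
class Verdict:
    """Joint result of evaluating a model set on a collection of classes."""

    per_class: dict[tuple[str, ...], bool] = field(default_factory=dict)
    dataset_pass: bool = True
    failing_models: list[str] = field(default_factory=list)

    @property
    def all_pass(self) -> bool:
        return self.dataset_pass and all(self.per_class.values())


def evaluate_all(
    models: Sequence[PrivacyModel],
    classes: Sequence[EquivalenceClass],
    ref: ReferenceStats | None = None,
) -> Verdict:
    """Conjunction of all models: per-class verdicts for class-level models,
    dataset-level models evaluated on the classes surviving class-level
    suppression."""
    class_models = [m for m in models if m.level == "class"]
    ds_models = [m for m in models if m.level == "dataset"]
    v = Verdict()
    failing: set[str] = set()
    surviving_sizes = []
    for c in classes:
        ok = True
        for m in class_models:
            if not check_class(m, c, ref):
                ok = False
                failing.add(m.describe())
        v.per_class[c.key] = ok
        if ok:
            surviving_sizes.append(c.size)
    for m in ds_models:
        if not dataset_passes(m, surviving_sizes):
            v.dataset_pass = False
            failing.add(m.describe())
    v.failing_models = sorted(failing)
    return v
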