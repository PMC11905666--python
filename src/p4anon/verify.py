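"""Independent global checker for anonymized outputs.

This module deliberately re-implements every privacy-model criterion from
first principles, sharing no code with the optimized evaluation path in
:mod:`p4anon.models` / :mod:`p4anon.transform`.  It is the cross-validation
route used by the test suite and by ``p4 check``: an output is accepted only
if every configured model holds on the equivalence classes of the *merged*
dataset under the global reference distribution.

Records whose quasi-identifier cells are all ``"*"`` are treated as
suppressed and excluded — a fully suppressed record carries no
re-identification information.  Since suppression never touches sensitive
cells, the global sensitive-value distribution can be recovered from the
output itself, so checking needs no access to the original input.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from scipy.special import digamma

from .models import PrivacyModel

_TOL = 1e-9


@dataclass
class VerificationReport:
    passed: bool
    n_classes: int
    n_checked_records: int
    n_suppressed_records: int
    failures: list[str] = field(default_factory=list)


def reference_from(df: pd.DataFrame, sensitive: Sequence[str]) -> dict:
    """Global sensitive-value distributions recovered from a (merged) table."""
    out = {}
    for a in sensitive:
        counts = Counter(df[a])
        n = sum(counts.values())
        out[a] = {v: c / n for v, c in counts.items()}
    return out


def _entropy(counts: Counter) -> float:
    n = sum(counts.values())
    return -sum(c / n * math.log(c / n) for c in counts.values())


def _entropy_grassberger(counts: Counter) -> float:
    n = sum(counts.values())
    corr = sum(
        c * (float(digamma(c)) + (-1.0) ** c / (c * (c + 1)))
        for c in counts.values()
    )
    return math.log(n) - corr / n


def _emd_equal(p: Mapping[str, float], q: Mapping[str, float]) -> float:
    return 0.5 * sum(
        abs(p.get(v, 0.0) - q.get(v, 0.0)) for v in set(p) | set(q)
    )


def _emd_ordered(
    p: Mapping[str, float], q: Mapping[str, float], order: Sequence[str]
) -> float:
    if len(order) < 2:
        return 0.0
    run, acc = 0.0, 0.0
    for v in list(order)[:-1]:
        run += p.get(v, 0.0) - q.get(v, 0.0)
        acc += abs(run)
    return acc / (len(order) - 1)


def _class_ok(
    model: PrivacyModel,
    counts_by_attr: Mapping[str, Counter],
    size: int,
    reference: Mapping[str, Mapping[str, float]],
) -> bool:
    kind = model.kind
    if kind == "k_anonymity":
        return size >= model.k
    counts = counts_by_attr[model.sensitive]
    if kind == "distinct_l":
        return len([c for c in counts.values() if c]) >= model.l
    if kind == "entropy_l":
        h = (
            _entropy_grassberger(counts)
            if model.estimator == "grassberger"
            else _entropy(counts)
        )
        return h >= math.log(model.l) - _TOL
    if kind == "recursive_cl":
        rs = sorted(counts.values(), reverse=True)
        if len(rs) < model.l:
            return False
        return rs[0] < model.c * sum(rs[model.l - 1 :])
    q = reference[model.sensitive]
    p = {v: c / size for v, c in counts.items()}
    if kind == "t_closeness_equal":
        return _emd_equal(p, q) <= model.t + _TOL
    if kind == "t_closeness_ordered":
        order = model.order or tuple(sorted(q))
        return _emd_ordered(p, q, order) <= model.t + _TOL
    if kind == "delta_disclosure":
        for v, pv in p.items():
            qv = q.get(v, 0.0)
            if qv == 0.0 or abs(math.log(pv / qv)) >= model.delta:
                return False
        return True
    if kind in ("beta_likeness_basic", "beta_likeness_enhanced"):
        for v, pv in p.items():
            qv = q.get(v, 0.0)
            if qv == 0.0:
                return False
            if pv > qv:
                bound = model.beta
                if kind == "beta_likeness_enhanced":
                    bound = min(bound, -math.log(qv))
                if (pv - qv) / qv > bound + _TOL:
                    return False
        return True
    raise ValueError(f"unsupported model kind {kind!r}")


def check_output(
    df: pd.DataFrame,
    qi: Sequence[str],
    models: Sequence[PrivacyModel],
    reference: Mapping[str, Mapping[str, float]] | None = None,
) -> VerificationReport:
    """Re-check a merged anonymized table against all configured models."""
    sensitive = sorted({m.sensitive for m in models if m.sensitive})
    if reference is None:
        reference = reference_from(df, sensitive)
    groups: dict[tuple, list[int]] = defaultdict(list)
    n_suppressed = 0
    qi = list(qi)
    for rid, row in zip(df.index, df[qi].itertuples(index=False, name=None)):
        if all(v == "*" for v in row):
            n_suppressed += 1
            continue
        groups[row].append(rid)
    failures: list[str] = []
    class_models = [m for m in models if m.level == "class"]
    sizes = []
    for key in sorted(groups):
        ids = groups[key]
        size = len(ids)
        sizes.append(size)
        counts_by_attr = {
            a: Counter(df.loc[ids, a]) for a in sensitive
        }
        for m in class_models:
            if not _class_ok(m, counts_by_attr, size, reference):
                failures.append(f"class {key}: fails {m.describe()}")
    for m in models:
        if m.level != "dataset" or not sizes:
            continue
        if m.kind == "average_risk":
            ok = len(sizes) / sum(sizes) <= m.threshold + _TOL
        else:  # sample uniqueness
            ok = (
                sum(1 for s in sizes if s == 1) / sum(sizes)
                <= m.threshold + _TOL
            )
        if not ok:
            failures.append(f"dataset: fails {m.describe()}")
    return VerificationReport(
        passed=not failures,
        n_classes=len(sizes),
        n_checked_records=sum(sizes),
        n_suppressed_records=n_suppressed,
        failures=failures,
    )
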