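"""Synthetic microdata and hierarchies for experiments and tests.

The generators emulate the shape of demographic survey extracts: a handful
of categorical quasi-identifiers with modest domains and balanced interval
hierarchies, one categorical sensitive attribute, and optional Zipf-like
skew in the value frequencies.  All randomness is confined to this module
and is a pure function of the seed; the anonymization engine itself is
fully deterministic.
"""

from __future__ import annotations

import numpy as np

from .core import AttributeConfig, Dataset, Hierarchy, build_hierarchy
from .models import KINDS, PrivacyModel


def _label(i: int, width: int) -> str:
    return f"v{i:0{width}d}"


def generate_hierarchy(
    domain_size: int, fanout: int = 2, seed: int | None = None
) -> Hierarchy:
    """Balanced hierarchy: leaves grouped into ``fanout``-sized ranges per
    level, up to the single top ``"*"``.  Deterministic (seed is accepted
    for interface symmetry but unused)."""
    if domain_size < 1:
        raise ValueError("domain_size must be >= 1")
    if fanout < 2:
        raise ValueError("fanout must be >= 2")
    width = max(2, len(str(domain_size - 1)))
    leaves = [_label(i, width) for i in range(domain_size)]
    columns = [leaves]
    current = leaves
    while len(set(current)) > 1:
        distinct = list(dict.fromkeys(current))
        if len(distinct) <= fanout:
            nxt_map = {v: "*" for v in distinct}
        else:
            nxt_map = {}
            for g in range(0, len(distinct), fanout):
                group = distinct[g : g + fanout]
                lo = group[0].split("-")[0]
                hi = group[-1].split("-")[-1]
                label = f"{lo}-{hi}"
                for v in group:
                    nxt_map[v] = label
        current = [nxt_map[v] for v in current]
        columns.append(current)
    rows = list(zip(*columns))
    return build_hierarchy(rows)


def _zipf_probs(domain: int, skew: float) -> np.ndarray:
    ranks = np.arange(1, domain + 1, dtype=float)
    w = ranks ** -float(skew)  # skew 0 -> uniform
    return w / w.sum()


def generate_dataset(
    n: int,
    qi_domains: tuple[int, ...] | list[int] = (4, 5, 6),
    sensitive_domain: int = 2,
    skew: float = 0.0,
    seed: int = 0,
    *,
    fanout: int = 2,
    sensitive_skew: float = 0.0,
) -> Dataset:
    """Random dataset with one sensitive attribute and attached hierarchies.

    Quasi-identifier values are drawn independently per attribute from a
    Zipf-like distribution with exponent ``skew`` (0 = uniform); the
    sensitive attribute uses ``sensitive_skew`` to control class imbalance.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    attrs = []
    hierarchies = {}
    data = {}
    for i, dom in enumerate(qi_domains):
        name = f"qi{i + 1}"
        h = generate_hierarchy(dom, fanout)
        hierarchies[name] = h
        leaves = np.array(h.leaves, dtype=object)
        idx = rng.choice(dom, size=n, p=_zipf_probs(dom, skew))
        data[name] = leaves[idx]
        attrs.append(AttributeConfig(name, "quasi_identifier", None))
    sname = "sensitive"
    svals = np.array(
        [f"s{j}" for j in range(sensitive_domain)], dtype=object
    )
    sidx = rng.choice(
        sensitive_domain, size=n, p=_zipf_probs(sensitive_domain, sensitive_skew)
    )
    data[sname] = svals[sidx]
    attrs.append(AttributeConfig(sname, "sensitive"))
    records = list(zip(*(data[a.name] for a in attrs)))
    return Dataset.from_records(records, attrs, hierarchies)


def generate_planted_dataset(
    n_classes: int,
    class_size: int,
    qi_domains: tuple[int, ...] | list[int] = (6, 6),
    sensitive_domain: int = 2,
    seed: int = 0,
    *,
    fanout: int = 2,
) -> Dataset:
    """Dataset whose level-0 equivalence classes all have exactly
    ``class_size`` members: ``n_classes`` distinct QI tuples are sampled
    without replacement and each is duplicated ``class_size`` times."""
    rng = np.random.default_rng(seed)
    space = 1
    for dom in qi_domains:
        space *= dom
    if n_classes > space:
        raise ValueError(
            f"cannot plant {n_classes} distinct tuples in a QI space of {space}"
        )
    flat = rng.choice(space, size=n_classes, replace=False)
    hierarchies = {}
    attrs = []
    leaves_per_attr = []
    for i, dom in enumerate(qi_domains):
        name = f"qi{i + 1}"
        h = generate_hierarchy(dom, fanout)
        hierarchies[name] = h
        leaves_per_attr.append(h.leaves)
        attrs.append(AttributeConfig(name, "quasi_identifier"))
    attrs.append(AttributeConfig("sensitive", "sensitive"))
    records = []
    for code in sorted(flat.tolist()):
        tup = []
        rem = code
        for dom, leaves in zip(reversed(qi_domains), reversed(leaves_per_attr)):
            tup.append(leaves[rem % dom])
            rem //= dom
        tup.reverse()
        for _ in range(class_size):
            s = f"s{rng.integers(0, max(1, int(sensitive_domain)))}"
            records.append(tuple(tup) + (s,))
    return Dataset.from_records(records, attrs, hierarchies)


def random_privacy_model(
    rng: np.random.Generator, kind: str, sensitive: str = "sensitive"
) -> PrivacyModel:
    """One randomly parameterized model of the given kind, with parameter
    ranges a practitioner would plausibly configure."""
    if kind == "k_anonymity":
        return PrivacyModel(kind, k=int(rng.integers(2, 11)))
    if kind == "distinct_l":
        return PrivacyModel(kind, l=int(rng.integers(2, 4)), sensitive=sensitive)
    if kind == "entropy_l":
        return PrivacyModel(
            kind,
            l=int(rng.integers(2, 4)),
            estimator=str(rng.choice(["shannon", "grassberger"])),
            sensitive=sensitive,
        )
    if kind == "recursive_cl":
        return PrivacyModel(
            kind,
            c=float(rng.choice([1.0, 2.0, 4.0])),
            l=int(rng.integers(2, 4)),
            sensitive=sensitive,
        )
    if kind in ("t_closeness_equal", "t_closeness_ordered"):
        return PrivacyModel(kind, t=float(rng.uniform(0.2, 0.6)), sensitive=sensitive)
    if kind == "delta_disclosure":
        return PrivacyModel(kind, delta=float(rng.uniform(1.0, 3.0)), sensitive=sensitive)
    if kind in ("beta_likeness_basic", "beta_likeness_enhanced"):
        return PrivacyModel(kind, beta=float(rng.uniform(1.0, 4.0)), sensitive=sensitive)
    if kind == "average_risk":
        return PrivacyModel(kind, threshold=float(rng.uniform(0.2, 1.0)))
    if kind == "sample_uniqueness":
        return PrivacyModel(kind, threshold=float(rng.uniform(0.1, 1.0)))
    raise ValueError(f"unknown model kind {kind!r}")


def random_scenario(
    seed: int,
    *,
    min_records: int = 100,
    max_records: int = 10_000,
    max_models: int = 3,
    partition_choices: tuple[int, ...] = (1, 2, 4, 8),
) -> tuple[Dataset, list[PrivacyModel], dict]:
    """A full randomized anonymization scenario for benchmark/stress suites.

    Returns (dataset, models, run_kwargs) where run_kwargs holds the
    partition count, transformation mode and harmonization strategy.  Every
    draw is a pure function of ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(10 ** rng.uniform(np.log10(min_records), np.log10(max_records))))
    d = generate_dataset(
        n,
        tuple(int(x) for x in rng.integers(3, 10, size=int(rng.integers(1, 4)))),
        sensitive_domain=int(rng.integers(2, 5)),
        skew=float(rng.uniform(0, 1.2)),
        seed=int(rng.integers(0, 2**31 - 1)),
        fanout=int(rng.integers(2, 4)),
    )
    kinds = rng.choice(KINDS, size=int(rng.integers(1, max_models + 1)), replace=False)
    models = [random_privacy_model(rng, str(k)) for k in kinds]
    run_kwargs = {
        "partitions": int(rng.choice(list(partition_choices))),
        "transformation": str(rng.choice(["global", "local"])),
        "harmonization": str(rng.choice(["average", "minimum", "median"])),
    }
    return d, models, run_kwargs


def extrapolate(d: Dataset, factor: float, seed: int = 0) -> Dataset:
    """Scale a dataset by seeded sampling with replacement.

    A stand-in for distribution-aware record extrapolation: it preserves the
    marginal value sets (every output record is an input record) and is
    sufficient for size-scaling experiments, not for distributional
    fidelity claims.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    n_out = int(np.ceil(factor * d.n))
    pos = rng.integers(0, d.n, size=n_out)
    df = d.df.iloc[pos].reset_index(drop=True)
    return Dataset(df, d.attributes, d.hierarchies)
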