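import logging

import numpy as np
import pytest
from scipy.optimize import linprog

from p4anon.core import AttributeConfig, Dataset, build_hierarchy

# partition-suppression warnings are expected in randomized suites
logging.getLogger("p4anon").setLevel(logging.ERROR)

AGE_ROWS = [
    ("30", "30-31", "*"),
    ("31", "30-31", "*"),
    ("32", "32-33", "*"),
    ("33", "32-33", "*"),
]


@pytest.fixture
def age_hierarchy():
    return build_hierarchy(AGE_ROWS)


@pytest.fixture
def toy_dataset(age_hierarchy):
    """4 records, one QI (age) and one sensitive attribute (sex)."""
    attrs = [
        AttributeConfig("age", "quasi_identifier"),
        AttributeConfig("sex", "sensitive"),
    ]
    records = [("30", "F"), ("30", "F"), ("32", "M"), ("33", "M")]
    return Dataset.from_records(records, attrs, {"age": age_hierarchy})


def min_cost_transport(p, q, ground):
    """Brute-force minimum-cost transport between two histograms (LP)."""
    m = len(p)
    cost = np.asarray(ground, dtype=float).reshape(-1)
    a_eq, b_eq = [], []
    for i in range(m):
        row = np.zeros((m, m))
        row[i, :] = 1
        a_eq.append(row.reshape(-1))
        b_eq.append(p[i])
    for j in range(m):
        row = np.zeros((m, m))
        row[:, j] = 1
        a_eq.append(row.reshape(-1))
        b_eq.append(q[j])
    res = linprog(
        cost,
        A_eq=np.array(a_eq),
        b_eq=np.array(b_eq),
        bounds=(0, None),
        method="highs",
    )
    assert res.success
    return res.fun
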