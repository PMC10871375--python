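"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the cube oracle walks
every subset with a plain Counter instead of pandas groupby, so agreement
between the two is evidence, not tautology.
"""

from __future__ import annotations

import itertools
from collections import Counter

import pandas as pd


def brute_force_cube(cohort: pd.DataFrame, variables: list[str]) -> dict:
    """Enumerate all 2^n subsets and count matching rows per assignment."""
    rows = {(): len(cohort)}
    records = [tuple(str(row[v]) for v in variables) for _, row in cohort.iterrows()]
    order = {v: i for i, v in enumerate(variables)}
    for r in range(1, len(variables) + 1):
        for subset in itertools.combinations(range(len(variables)), r):
            counter = Counter(tuple(rec[i] for i in subset) for rec in records)
            for levels, count in counter.items():
                assignment = tuple(sorted(
                    ((variables[i], lev) for i, lev in zip(subset, levels)),
                    key=lambda kv: order[kv[0]]))
                rows[assignment] = count
    return rows


def random_cohort(rng, n_rows: int, n_vars: int) -> pd.DataFrame:
    """A random discrete cohort with per-variable alphabet sizes 2-4."""
    data = {}
    for i in range(n_vars):
        k = int(rng.integers(2, 5))
        data[f"v{i}"] = rng.integers(0, k, size=n_rows).astype(str)
    return pd.DataFrame(data)
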