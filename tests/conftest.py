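"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from sortmet.tables import PeakTable, make_peak_table


def build_table(
    values: np.ndarray | list,
    sample_ids: list[str] | None = None,
    metabolite_ids: list[str] | None = None,
    roles: list[str] | None = None,
    event_counts: list | None = None,
    cell_types: list | None = None,
    groups: list | None = None,
    internal_standards: list[str] | None = None,
) -> PeakTable:
    """Assemble a PeakTable from a plain matrix plus optional metadata."""
    values = np.asarray(values, dtype=float)
    n_s, n_m = values.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n_s)]
    metabolite_ids = metabolite_ids or [f"m{j + 1}" for j in range(n_m)]
    roles = roles or ["cell"] * n_s
    ints = pd.DataFrame(
        values,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=pd.Index(metabolite_ids, name="metabolite"),
    )
    samples = pd.DataFrame(
        {
            "role": roles,
            "event_count": pd.array(
                event_counts if event_counts is not None else [pd.NA] * n_s, dtype="Int64"
            ),
            "cell_type": cell_types if cell_types is not None else [pd.NA] * n_s,
            "group": groups if groups is not None else [pd.NA] * n_s,
            "experiment": "exp1",
            "replicate": pd.array(range(1, n_s + 1), dtype="Int64"),
        },
        index=ints.index,
    )
    std = set(internal_standards or [])
    metabolites = pd.DataFrame(
        {
            "display_name": metabolite_ids,
            "is_internal_standard": [m in std for m in metabolite_ids],
            "standard_kind": ["c13" if m in std else "none" for m in metabolite_ids],
        },
        index=ints.columns,
    )
    return PeakTable(intensities=ints, samples=samples, metabolites=metabolites)


@pytest.fixture
def tiny_table() -> PeakTable:
    return build_table(
        [[1.0, 2.0], [3.0, np.nan]],
        roles=["cell", "debris"],
        event_counts=[100, 100],
    )


# -- independent oracles -------------------------------------------------


def brute_force_rank_sum_p(cells, debris) -> float:
    """Exact one-sided rank-sum p via the U statistic (pair counting with
    half-credit ties) enumerated over every group assignment. Independent of
    the mid-rank implementation under test."""
    pooled = list(cells) + list(debris)
    n, n1 = len(pooled), len(cells)

    def u_stat(a, b):
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
        )

    u_obs = u_stat(list(cells), list(debris))
    count = total = 0
    for idx in combinations(range(n), n1):
        chosen = set(idx)
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(n) if i not in chosen]
        total += 1
        if u_stat(a, b) >= u_obs - 1e-9:
            count += 1
    return count / total


def brute_force_bh(p_values) -> list[float]:
    """Definitional BH step-up: q_(i) = min_{j >= i} min(1, p_(j) * m / j),
    computed by a literal double loop over sorted positions."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, i in enumerate(order):
        q[i] = min(
            min(1.0, p[order[j]] * m / (j + 1)) for j in range(pos, m)
        )
    return q
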