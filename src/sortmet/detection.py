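"""Detection of metabolites above sorted-debris background.

A metabolite at a given event level is *significant* when its cell-sample
intensities exceed the matched debris samples by a one-sided rank-sum test,
Benjamini-Hochberg corrected across metabolites within the level (q < alpha).
It is *detected* under the chained rule: significant at that level and also
detected at the next higher event level (the highest level needs no chain
partner). Detected sets are therefore nested upward and detection counts are
non-decreasing in event count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sortmet.tables import PeakTable

EXACT_MAX_COMBINED_N = 12


def rank_sum_one_sided(cells: Sequence[float], debris: Sequence[float]) -> float:
    """One-sided rank-sum p-value for the alternative "cells > debris".

    For combined sample size <= 12 the p-value is exact: mid-ranks are
    assigned to the pooled values and all C(n, n1) group assignments are
    enumerated, so ties are handled without approximation. Larger samples
    use the tie-corrected normal approximation with continuity correction.
    The returned p lies in (0, 1].
    """
    a = np.asarray(cells, dtype=float)
    b = np.asarray(debris, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each group needs >= 2 values (got {a.size} and {b.size})"
        )
    n1, n = a.size, a.size + b.size
    if n <= EXACT_MAX_COMBINED_N:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        w_obs = ranks[:n1].sum()
        total = comb(n, n1)
        count = sum(
            1
            for idx in combinations(range(n), n1)
            if ranks[list(idx)].sum() >= w_obs - 1e-9
        )
        return count / total
    res = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
    return float(min(res.pvalue, 1.0))


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} min(1, p_(j) * m / j) over the sorted p-values.
    NaN entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(list(p_values), dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        bad = pv[(pv < 0) | (pv > 1)][0]
        raise ValueError(f"p-value outside [0, 1]: {bad}")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        scaled = pv[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
        q = np.empty(m)
        q[order] = q_sorted
        out[valid] = q
    return out


@dataclass
class DetectionResult:
    """Per (metabolite, event level) test outcome.

    ``frame`` columns: metabolite, event_level, p_value, q_value,
    significant, detected, is_internal_standard. Internal standards are
    excluded from the BH family (q is NaN, never significant) but reported
    alongside.
    """

    frame: pd.DataFrame
    alpha: float
    chain: str

    def at_level(self, level: int) -> pd.DataFrame:
        return self.frame[self.frame["event_level"] == level].set_index("metabolite")


@dataclass
class DetectionCurve:
    counts: pd.Series  # event_level -> number detected
    detected_sets: dict[int, set[str]]


def _test_family(
    cells_df: pd.DataFrame,
    debris_df: pd.DataFrame,
    alpha: float,
    tested: Sequence[str],
    reported_only: Sequence[str] = (),
) -> pd.DataFrame:
    """One-sided rank-sum per metabolite, BH across ``tested``; metabolites in
    ``reported_only`` get a raw p but stay out of the family. This is the
    shared code path behind level-wise detection, per-cell-type detection and
    the volcano blank gate."""
    rows = []
    for m in list(tested) + list(reported_only):
        a = cells_df[m].to_numpy(float)
        b = debris_df[m].to_numpy(float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        p = rank_sum_one_sided(a, b) if (a.size >= 2 and b.size >= 2) else np.nan
        rows.append({"metabolite": m, "p_value": p, "in_family": m in set(tested)})
    frame = pd.DataFrame(rows)
    q = np.full(len(frame), np.nan)
    fam = frame["in_family"].to_numpy()
    q[fam] = bh_adjust(frame.loc[fam, "p_value"])
    frame["q_value"] = q
    frame["significant"] = fam & (frame["q_value"] < alpha)
    return frame


def detect_above_background(
    table: PeakTable, alpha: float = 0.05, chain: str = "recursive"
) -> DetectionResult:
    """Detection above debris background across the event-count series.

    ``chain`` is one of ``recursive`` (detection at a level requires
    detection at every higher level, transitively), ``single`` (requires
    significance at the next higher level only) or ``off`` (detected ==
    significant).
    """
    if chain not in {"recursive", "single", "off"}:
        raise ValueError(f"chain must be recursive|single|off, got {chain!r}")
    smeta = table.samples
    cell_levels = set(pd.to_numeric(smeta.loc[smeta["role"] == "cell", "event_count"].dropna()))
    debris_levels = set(pd.to_numeric(smeta.loc[smeta["role"] == "debris", "event_count"].dropna()))
    if cell_levels - debris_levels:
        raise ValueError(
            f"event levels without debris counterpart: {sorted(cell_levels - debris_levels)}"
        )
    levels = sorted(cell_levels & debris_levels)
    if not levels:
        raise ValueError("no event level with both cell and debris samples")

    std_ids = set(table.internal_standard_ids())
    tested = [m for m in table.metabolite_ids if m not in std_ids]
    reported = [m for m in table.metabolite_ids if m in std_ids]

    per_level = {}
    for level in levels:
        cells = smeta.index[(smeta["role"] == "cell") & (smeta["event_count"] == level)]
        debris = smeta.index[(smeta["role"] == "debris") & (smeta["event_count"] == level)]
        fam = _test_family(
            table.intensities.loc[cells],
            table.intensities.loc[debris],
            alpha,
            tested,
            reported,
        )
        fam["event_level"] = level
        per_level[level] = fam.set_index("metabolite")

    # chained detection, top level down
    detected_next = None
    sig_next = None
    for level in reversed(levels):
        fam = per_level[level]
        sig = fam["significant"]
        if detected_next is None or chain == "off":
            det = sig.copy()
        elif chain == "recursive":
            det = sig & detected_next
        else:  # single-step: needs significance at the next higher level only
            det = sig & sig_next
        fam["detected"] = det
        detected_next, sig_next = det, sig

    frame = pd.concat([per_level[lv] for lv in levels]).reset_index()
    frame["is_internal_standard"] = frame["metabolite"].isin(std_ids)
    frame = frame[
        [
            "metabolite",
            "event_level",
            "p_value",
            "q_value",
            "significant",
            "detected",
            "is_internal_standard",
        ]
    ]
    return DetectionResult(frame=frame, alpha=alpha, chain=chain)


def detection_curve(result: DetectionResult) -> DetectionCurve:
    """Per-level detected counts and id sets; nestedness is asserted when the
    recursive chain rule was used (it is a theorem under that rule)."""
    frame = result.frame
    levels = sorted(frame["event_level"].unique())
    sets = {
        int(lv): set(frame.loc[(frame["event_level"] == lv) & frame["detected"], "metabolite"])
        for lv in levels
    }
    if result.chain == "recursive":
        for lo, hi in zip(levels, levels[1:]):
            if not sets[int(lo)] <= sets[int(hi)]:
                raise AssertionError(
                    f"detected set at {lo} events not nested in {hi} events"
                )
    counts = pd.Series({lv: len(sets[int(lv)]) for lv in levels}, name="n_detected")
    counts.index.name = "event_level"
    return DetectionCurve(counts=counts, detected_sets=sets)


@dataclass
class CellTypeDetection:
    detected: dict[str, set[str]]
    union: set[str]
    intersection: set[str]
    frames: dict[str, pd.DataFrame]


def detect_per_celltype(table: PeakTable, alpha: float = 0.05) -> CellTypeDetection:
    """Single-level detection per cell type against its own matched debris
    samples (no event-count chain). BH family = tested metabolites within a
    cell type."""
    smeta = table.samples
    cell_types = [
        t for t in smeta.loc[smeta["role"] == "cell", "cell_type"].dropna().unique()
    ]
    std_ids = set(table.internal_standard_ids())
    tested = [m for m in table.metabolite_ids if m not in std_ids]

    detected: dict[str, set[str]] = {}
    frames: dict[str, pd.DataFrame] = {}
    for t in cell_types:
        cells = smeta.index[(smeta["role"] == "cell") & (smeta["cell_type"] == t)]
        debris = smeta.index[(smeta["role"] == "debris") & (smeta["cell_type"] == t)]
        if len(debris) == 0:
            raise ValueError(f"cell type {t!r} has no matched debris samples")
        fam = _test_family(
            table.intensities.loc[cells], table.intensities.loc[debris], alpha, tested
        )
        frames[t] = fam.set_index("metabolite")
        detected[t] = set(fam.loc[fam["significant"], "metabolite"])

    union = set().union(*detected.values()) if detected else set()
    intersection = (
        set.intersection(*detected.values()) if detected else set()
    )
    return CellTypeDetection(
        detected=detected, union=union, intersection=intersection, frames=frames
    )
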