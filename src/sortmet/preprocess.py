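"""Preprocessing chain for peak tables.

Stage order mirrors the workflow it implements: low-detection filtering,
best-matched internal-standard normalization, half-minimum imputation, then
z-score outlier removal on event-number-normalized data. Each stage is a
pure function of its input table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sortmet.tables import PeakTable


@dataclass
class NormalizationReport:
    """Outcome of best-matched internal-standard normalization.

    ``matched_standard`` maps each normalized metabolite to the internal
    standard whose ratio to it has the smallest coefficient of variation;
    ``match_score`` holds that minimum CV; ``scale_factor`` holds the median
    intensity of each standard used to restore the original intensity scale.
    """

    matched_standard: dict[str, str]
    match_score: dict[str, float]
    scale_factor: dict[str, float]
    excluded_standards: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "matched_standard": pd.Series(self.matched_standard),
                "match_score": pd.Series(self.match_score),
            }
        ).rename_axis(index="metabolite")


@dataclass
class OutlierReport:
    """Per-sample statistics of the z-score filter.

    ``frame`` has, per eligible sample: the summary ``statistic`` (on
    event-count-normalized intensities), its within-group ``z_score``, the
    grouping key, and whether it was ``removed``.
    """

    frame: pd.DataFrame
    removed: list[str]
    threshold: float
    statistic: str


def filter_low_detection(
    table: PeakTable, min_samples: int = 10
) -> tuple[PeakTable, list[str]]:
    """Drop metabolites detected (non-missing) in fewer than ``min_samples``
    samples. Returns the filtered table and the dropped metabolite ids."""
    counts = table.intensities.notna().sum(axis=0)
    keep = counts[counts >= min_samples].index.tolist()
    dropped = [m for m in table.metabolite_ids if m not in set(keep)]
    return table.subset(metabolite_ids=keep), dropped


def best_matched_normalize(
    table: PeakTable, max_standard_missing: float = 0.5
) -> tuple[PeakTable, NormalizationReport]:
    """Normalize each metabolite by its best-matched internal standard.

    For every non-standard metabolite ``m`` the candidate internal standard
    ``i*`` minimizing the coefficient of variation of the ratio ``m/i``
    across samples where both are present is selected (ties broken by
    standard order in the metabolite metadata, deterministically). The
    normalized value is ``(m / i*) * median(i*)`` so intensities stay on
    their original scale; where ``i*`` is missing in a sample the value is
    left unchanged (equivalent to dividing by the median). Standards are
    passed through unchanged.
    """
    std_ids = table.internal_standard_ids()
    if not std_ids:
        raise ValueError("no internal standards present; cannot normalize")

    ints = table.intensities
    candidates = []
    excluded = []
    for sid in std_ids:
        missing_frac = ints[sid].isna().mean()
        if missing_frac > max_standard_missing:
            excluded.append(sid)
            warnings.warn(
                f"internal standard {sid!r} missing in {missing_frac:.0%} of samples; "
                "excluded from candidacy",
                stacklevel=2,
            )
        else:
            candidates.append(sid)
    if not candidates:
        raise ValueError(
            "all internal standards exceed the allowed missing fraction "
            f"({max_standard_missing:.0%})"
        )

    std_median = {sid: float(np.nanmedian(ints[sid].to_numpy(float))) for sid in candidates}

    matched: dict[str, str] = {}
    score: dict[str, float] = {}
    out = ints.copy()
    for m in table.metabolite_ids:
        if m in std_ids:
            continue
        best_sid, best_cv = None, np.inf
        for sid in candidates:
            ratio = (ints[m] / ints[sid]).to_numpy(float)
            ratio = ratio[np.isfinite(ratio)]
            if ratio.size < 2 or ratio.mean() == 0:
                continue
            cv = ratio.std(ddof=1) / ratio.mean()
            if cv < best_cv:  # strict: ties keep the earlier candidate
                best_sid, best_cv = sid, cv
        if best_sid is None:
            warnings.warn(
                f"metabolite {m!r} shares < 2 samples with every candidate "
                "standard; left unnormalized",
                stacklevel=2,
            )
            continue
        matched[m] = best_sid
        score[m] = float(best_cv)
        std_vals = ints[best_sid]
        divisor = std_vals.fillna(std_median[best_sid])
        out[m] = ints[m] / divisor * std_median[best_sid]

    report = NormalizationReport(
        matched_standard=matched,
        match_score=score,
        scale_factor=std_median,
        excluded_standards=excluded,
    )
    return table.with_intensities(out), report


def impute_half_min(table: PeakTable) -> PeakTable:
    """Replace every missing entry of a metabolite with half its minimum
    observed value. Errors on metabolites with no observed value at all
    (those should have been removed by the low-detection filter)."""
    ints = table.intensities
    all_missing = ints.isna().all(axis=0)
    if all_missing.any():
        bad = ints.columns[all_missing][0]
        raise ValueError(
            f"metabolite {bad!r} has no observed values; run filter_low_detection first"
        )
    half_min = ints.min(axis=0, skipna=True) * 0.5
    return table.with_intensities(ints.fillna(half_min))


def zscore_outlier_filter(
    table: PeakTable,
    threshold: float = 3.0,
    statistic: str = "median",
    min_group_size: int = 3,
    group_by: tuple[str, ...] = ("cell_type", "role"),
) -> tuple[PeakTable, OutlierReport]:
    """Remove outlier samples by z-score on event-number-normalized data.

    Per eligible sample (cell/debris with an event count) a summary statistic
    of intensity / event_count over metabolites is computed (``median``,
    ``mean`` or ``total``) and divided by the median statistic of the
    sample's replicate subgroup (cell_type x role x event_count), which
    removes residual level-to-level differences. The z-score of that
    normalized statistic is then taken within the sample's ``group_by``
    group and samples with ``|z| > threshold`` are removed.

    The default grouping pools event counts within (cell_type x role):
    a z-score is bounded by sqrt(n-1) within a group of n, so grouping per
    replicate set of 8 (max |z| = 2.65) could never exceed a threshold of 3.
    Pass ``group_by=("cell_type", "role", "event_count")`` for strictly
    per-level grouping (the subgroup normalization leaves z-scores within a
    single subgroup unchanged, as z is scale-invariant).

    Groups smaller than ``min_group_size`` are skipped with a warning;
    groups with zero spread remove nothing. Blank/medium samples pass
    through untouched.
    """
    reducers = {"median": np.nanmedian, "mean": np.nanmean, "total": np.nansum}
    if statistic not in reducers:
        raise ValueError(f"statistic must be one of {sorted(reducers)}, got {statistic!r}")
    reduce = reducers[statistic]

    smeta = table.samples
    eligible = smeta["role"].isin(["cell", "debris"]) & smeta["event_count"].notna()
    rows = []
    removed: list[str] = []
    if eligible.any():
        sub = smeta[eligible]
        events = pd.to_numeric(sub["event_count"]).to_numpy(float)
        mat = table.intensities.loc[sub.index].to_numpy(float) / events[:, None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            stats = np.array([reduce(row) for row in mat])
        stat_series = pd.Series(stats, index=sub.index)

        # normalize by replicate-subgroup median so levels are comparable
        subgroup = pd.Series(
            list(zip(sub["cell_type"].fillna(""), sub["role"], pd.to_numeric(sub["event_count"]))),
            index=sub.index,
        )
        sub_median = stat_series.groupby(subgroup).transform("median")
        norm_stat = stat_series.where(sub_median == 0, stat_series / sub_median)

        def key_part(col: str) -> pd.Series:
            if col == "event_count":
                return pd.to_numeric(sub[col])
            return sub[col].fillna("")

        keys = list(zip(*(key_part(col) for col in group_by)))
        group_key = pd.Series(keys, index=sub.index)
        for key in dict.fromkeys(keys):
            members = group_key.index[group_key == key]
            vals = norm_stat.loc[members]
            if len(members) < min_group_size:
                warnings.warn(
                    f"group {key} has {len(members)} samples (< {min_group_size}); "
                    "skipped by outlier filter",
                    stacklevel=2,
                )
                z = pd.Series(np.nan, index=members)
            else:
                sd = vals.std(ddof=1)
                if not np.isfinite(sd) or sd == 0:
                    z = pd.Series(0.0, index=members)
                else:
                    z = (vals - vals.mean()) / sd
            for sid in members:
                is_out = bool(np.isfinite(z[sid]) and abs(z[sid]) > threshold)
                rows.append(
                    {
                        "sample_id": sid,
                        "group_key": str(key),
                        "statistic": stat_series[sid],
                        "normalized_statistic": norm_stat[sid],
                        "z_score": z[sid],
                        "removed": is_out,
                    }
                )
                if is_out:
                    removed.append(sid)

    frame = (
        pd.DataFrame(rows).set_index("sample_id")
        if rows
        else pd.DataFrame(columns=["group_key", "statistic", "z_score", "removed"])
    )
    keep = [s for s in table.sample_ids if s not in set(removed)]
    report = OutlierReport(frame=frame, removed=removed, threshold=threshold, statistic=statistic)
    return table.subset(sample_ids=keep), report


@dataclass
class PreprocessReport:
    dropped_metabolites: list[str]
    normalization: NormalizationReport | None
    outliers: OutlierReport


def preprocess_pipeline(
    table: PeakTable,
    min_samples: int = 10,
    z_threshold: float = 3.0,
    z_statistic: str = "median",
    z_group_by: tuple[str, ...] = ("cell_type", "role"),
    normalize: bool = True,
) -> tuple[PeakTable, PreprocessReport]:
    """Run the full chain: filter -> normalize -> impute -> outlier-remove."""
    table, dropped = filter_low_detection(table, min_samples=min_samples)
    norm_report = None
    if normalize:
        table, norm_report = best_matched_normalize(table)
    table = impute_half_min(table)
    table, outlier_report = zscore_outlier_filter(
        table, threshold=z_threshold, statistic=z_statistic, group_by=z_group_by
    )
    return table, PreprocessReport(
        dropped_metabolites=dropped, normalization=norm_report, outliers=outlier_report
    )
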