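"""Downstream comparisons: blank-gated volcano analysis, buffer-effect
deltas, PCA profiles and cross-study log-ratio correlation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from sortmet.detection import _test_family, bh_adjust
from sortmet.tables import PeakTable


@dataclass
class VolcanoResult:
    """Per-metabolite fold change and Welch test between two groups.

    ``frame`` columns: log2_fold_change (group A over group B), p_value
    (two-sided, unequal variance), q_value (BH over included metabolites,
    emitted for reference), included (above blank in both groups at the
    gate FDR), hit (included and |log2FC| > 1 and p < 0.05).
    """

    frame: pd.DataFrame
    group_a: str
    group_b: str
    alpha_blank: float


def volcano(
    table: PeakTable,
    group_a: str,
    group_b: str,
    blank_role: str = "debris",
    alpha_blank: float = 0.05,
    use_median: bool = False,
) -> VolcanoResult:
    """Blank-gated volcano comparison of two sample groups.

    A metabolite enters the comparison only if it is significantly above the
    blank samples in *both* groups (one-sided rank-sum + BH within each
    group, q < ``alpha_blank`` — the same machinery as detection above
    background). Fold change is the log2 ratio of group means of processed
    intensities (medians with ``use_median``); the p-value is a two-sided
    Welch t-test.
    """
    smeta = table.samples
    std_ids = set(table.internal_standard_ids())
    tested = [m for m in table.metabolite_ids if m not in std_ids]

    def cell_ids(group: str) -> pd.Index:
        ids = smeta.index[(smeta["role"] == "cell") & (smeta["group"] == group)]
        if len(ids) < 2:
            raise ValueError(f"group {group!r} has {len(ids)} cell samples (need >= 2)")
        return ids

    ids_a, ids_b = cell_ids(group_a), cell_ids(group_b)

    def blank_ids(group: str) -> pd.Index:
        mask = smeta["role"] == blank_role
        grouped = mask & (smeta["group"] == group)
        ids = smeta.index[grouped] if grouped.any() else smeta.index[mask]
        if len(ids) == 0:
            raise ValueError(f"no samples with blank role {blank_role!r}")
        return ids

    included = None
    for group, ids in ((group_a, ids_a), (group_b, ids_b)):
        gate = _test_family(
            table.intensities.loc[ids],
            table.intensities.loc[blank_ids(group)],
            alpha_blank,
            tested,
        ).set_index("metabolite")
        above = set(gate.loc[gate["significant"]].index)
        included = above if included is None else included & above

    a = table.intensities.loc[ids_a, tested].to_numpy(float)
    b = table.intensities.loc[ids_b, tested].to_numpy(float)
    center = np.nanmedian if use_median else np.nanmean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a, mean_b = center(a, axis=0), center(b, axis=0)
        log2fc = np.log2(mean_a / mean_b)
        t_res = stats.ttest_ind(a, b, axis=0, equal_var=False, nan_policy="omit")
    p = np.asarray(t_res.pvalue, dtype=float)

    frame = pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "p_value": p,
            "included": [m in included for m in tested],
        },
        index=pd.Index(tested, name="metabolite"),
    )
    q = np.full(len(frame), np.nan)
    inc = frame["included"].to_numpy()
    q[inc] = bh_adjust(frame.loc[inc, "p_value"])
    frame["q_value"] = q
    frame["hit"] = (
        frame["included"]
        & (frame["log2_fold_change"].abs() > 1.0)
        & (frame["p_value"] < 0.05)
    )
    return VolcanoResult(frame=frame, group_a=group_a, group_b=group_b, alpha_blank=alpha_blank)


@dataclass
class BufferEffect:
    """Per-metabolite retention-time and intensity deltas of a buffer
    condition against a reference condition."""

    frame: pd.DataFrame  # columns: delta_rt, log2_intensity_ratio
    median_abs_delta_rt: float
    median_log2_ratio: float


def buffer_effect(reference: pd.DataFrame, treatment: pd.DataFrame) -> BufferEffect:
    """Compare a buffer condition to a reference condition.

    Both inputs are DataFrames indexed by metabolite with ``rt`` (minutes)
    and ``intensity`` columns. Metabolites missing in one condition are
    dropped with a warning. Returns per-metabolite delta RT (treatment minus
    reference) and log2 intensity ratio (treatment over reference).
    """
    for name, frame in (("reference", reference), ("treatment", treatment)):
        missing = {"rt", "intensity"} - set(frame.columns)
        if missing:
            raise ValueError(f"{name} table lacks columns {sorted(missing)}")
    common = reference.index.intersection(treatment.index)
    dropped = set(reference.index).symmetric_difference(treatment.index)
    if dropped:
        warnings.warn(
            f"{len(dropped)} metabolite(s) present in only one condition were dropped",
            stacklevel=2,
        )
    if len(common) == 0:
        raise ValueError("no metabolites common to both conditions")
    out = pd.DataFrame(
        {
            "delta_rt": treatment.loc[common, "rt"] - reference.loc[common, "rt"],
            "log2_intensity_ratio": np.log2(
                treatment.loc[common, "intensity"] / reference.loc[common, "intensity"]
            ),
        },
        index=common,
    )
    return BufferEffect(
        frame=out,
        median_abs_delta_rt=float(out["delta_rt"].abs().median()),
        median_log2_ratio=float(out["log2_intensity_ratio"].median()),
    )


def pca_profiles(
    table: PeakTable, metabolite_subset: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of log10, per-metabolite autoscaled intensity profiles.

    Returns (scores, loadings, variance_fractions). Zero-variance metabolites
    in the subset are dropped with a warning; intensities must be strictly
    positive (run imputation first).
    """
    subset = list(metabolite_subset)
    if not subset:
        raise ValueError("metabolite_subset is empty")
    if table.n_samples < 3:
        raise ValueError("need >= 3 samples for PCA")
    x = table.intensities[subset].to_numpy(float)
    if np.isnan(x).any():
        raise ValueError("missing values in PCA input; impute first")
    if (x <= 0).any():
        raise ValueError("non-positive intensities in PCA input; cannot log-transform")
    logx = np.log10(x)
    sd = logx.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [m for m, k in zip(subset, keep) if not k]
        warnings.warn(f"zero-variance metabolite(s) dropped from PCA: {dropped}", stacklevel=2)
        subset = [m for m, k in zip(subset, keep) if k]
        logx, sd = logx[:, keep], sd[keep]
    if not subset:
        raise ValueError("all metabolites in subset have zero variance")
    z = (logx - logx.mean(axis=0)) / sd

    pca = PCA(n_components=min(z.shape))
    scores = pca.fit_transform(z)
    comps = [f"PC{i + 1}" for i in range(scores.shape[1])]
    scores_df = pd.DataFrame(scores, index=table.intensities.index, columns=comps)
    loadings_df = pd.DataFrame(pca.components_.T, index=subset, columns=comps)
    return scores_df, loadings_df, pca.explained_variance_ratio_


@dataclass
class CrossStudyCorrelation:
    r: float
    n_common: int
    p_value: float
    common_metabolites: list[str]


def cross_study_correlation(
    ratios_a: dict[str, float], ratios_b: dict[str, float]
) -> CrossStudyCorrelation:
    """Pearson correlation of two signed log-ratio maps over their common
    metabolites (two-sided p). Requires >= 3 common metabolites."""
    common = sorted(set(ratios_a) & set(ratios_b))
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common metabolites (need >= 3)")
    a = np.array([ratios_a[m] for m in common], dtype=float)
    b = np.array([ratios_b[m] for m in common], dtype=float)
    res = stats.pearsonr(a, b)
    return CrossStudyCorrelation(
        r=float(res.statistic),
        n_common=len(common),
        p_value=float(res.pvalue),
        common_metabolites=common,
    )


def median_log_ratio(
    table: PeakTable, cell_type_a: str, cell_type_b: str, base: float = 10.0
) -> dict[str, float]:
    """Per-metabolite log ratio of median cell-sample intensity between two
    cell types — the quantity compared across studies."""
    smeta = table.samples
    out: dict[str, float] = {}
    ids_a = smeta.index[(smeta["role"] == "cell") & (smeta["cell_type"] == cell_type_a)]
    ids_b = smeta.index[(smeta["role"] == "cell") & (smeta["cell_type"] == cell_type_b)]
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError("both cell types need at least one cell sample")
    med_a = table.intensities.loc[ids_a].median(axis=0, skipna=True)
    med_b = table.intensities.loc[ids_b].median(axis=0, skipna=True)
    for m in table.metabolite_ids:
        if med_a[m] > 0 and med_b[m] > 0:
            out[m] = float(np.log(med_a[m] / med_b[m]) / np.log(base))
    return out
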