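"""Synthetic peak-table generator with matched ground truth.

Generates intensity matrices with the statistical structure the downstream
analyses assume: cell signal proportional to sorted event count for
intracellular compounds, event-count-independent background shared by cell
and debris samples for extracellular compounds, mixed compounds carrying
both terms, internal standards with a shared per-sample technical factor,
multiplicative log-normal noise, censoring below a per-metabolite limit of
detection, injected outlier samples, treatment fold changes, and
cell-type-specific content vectors.

Expected intensity of sample s, metabolite m:

    mu[s, m] = (events_s * content_m * [s is cell] + background_m) * g_s

with g_s ~ LogNormal(0, sigma_technical) shared across metabolites of a
sample and multiplicative per-cell noise eps ~ LogNormal(0, sigma_metabolite)
on top. Internal standards replace the biological term by a constant
per-sample amount, so they carry the technical factor only — which is what
makes best-matched internal-standard normalization identifiable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sortmet.tables import PeakTable

DEFAULT_EVENT_LEVELS = (100, 500, 1000, 2000, 3000, 4000, 5000)

CLASS_INTRACELLULAR = "intracellular"
CLASS_EXTRACELLULAR = "extracellular"
CLASS_MIXED = "mixed"
CLASS_INTERNAL_STANDARD = "internal_standard"


@dataclass
class SyntheticConfig:
    """Parameters of the generator.

    ``class_fractions`` partitions non-standard metabolites among
    intracellular / extracellular / mixed; ``lod_quantile`` sets the
    per-metabolite limit of detection as a quantile of that metabolite's
    realized debris-sample intensities (values below it become missing);
    ``intracellular_background_fraction`` scales the residual extracellular
    background of intracellular compounds (kept tiny but nonzero so debris
    signal is approximately, not identically, zero).
    """

    n_metabolites: int = 30
    n_internal_standards: int = 2
    event_levels: Sequence[int] = DEFAULT_EVENT_LEVELS
    replicates_per_group: int = 8
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            CLASS_INTRACELLULAR: 0.5,
            CLASS_EXTRACELLULAR: 0.2,
            CLASS_MIXED: 0.3,
        }
    )
    per_cell_content_range: tuple[float, float] = (5.0, 50.0)
    background_level_range: tuple[float, float] = (1.0e3, 1.0e4)
    intracellular_background_fraction: float = 1.0e-4
    lognormal_sigma_metabolite: float = 0.15
    lognormal_sigma_technical: float = 0.1
    lognormal_sigma_experiment: float = 0.05
    lod_quantile: float = 0.1
    outlier_rate: float = 0.005
    outlier_magnitude: float = 10.0
    treatment_log2fc: Mapping[str, float] = field(default_factory=dict)
    celltype_profiles: Mapping[str, Sequence[float]] = field(default_factory=dict)
    n_experiments: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        levels = list(self.event_levels)
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError(f"event_levels must be strictly increasing, got {levels}")
        if any(n <= 0 for n in levels):
            raise ValueError("event_levels must be positive")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class_fractions must be non-negative")
        for name in (
            "lognormal_sigma_metabolite",
            "lognormal_sigma_technical",
            "lognormal_sigma_experiment",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("lod_quantile must be in [0, 1)")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must be in [0, 1)")
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be >= 1")
        if self.n_internal_standards < 0:
            raise ValueError("n_internal_standards must be >= 0")
        for rng_name in ("per_cell_content_range", "background_level_range"):
            lo, hi = getattr(self, rng_name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{rng_name} must satisfy 0 <= lo <= hi")


def default_treatment_config(**overrides) -> SyntheticConfig:
    """Config for the treatment design with one strongly-up (+3) and one
    strongly-down (-3) compound among the intracellular metabolites."""
    cfg = SyntheticConfig(**overrides)
    if not cfg.treatment_log2fc:
        ids = metabolite_ids(cfg)
        labels = _class_labels(cfg)
        intracellular = [
            m for m in ids if labels[m] in (CLASS_INTRACELLULAR, CLASS_MIXED)
        ]
        if len(intracellular) < 2:
            raise ValueError("need >= 2 intracellular/mixed metabolites for defaults")
        cfg.treatment_log2fc = {intracellular[0]: 3.0, intracellular[1]: -3.0}
    return cfg


def default_celltype_config(cell_types: Sequence[str] = ("typeA", "typeB"), **overrides) -> SyntheticConfig:
    """Config for the cell-type panel with log-normal content multiplier
    vectors drawn per cell type (deterministic in the seed)."""
    cfg = SyntheticConfig(**overrides)
    if not cfg.celltype_profiles:
        rng = np.random.default_rng(cfg.seed + 7_777_777)
        cfg.celltype_profiles = {
            t: rng.lognormal(0.0, 0.8, size=cfg.n_metabolites).tolist() for t in cell_types
        }
    return cfg


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every generated table."""

    per_cell_content: dict[str, float]
    extracellular_background: dict[str, float]
    lod: dict[str, float]
    class_label: dict[str, str]
    injected_outlier_samples: list[str]
    seed: int
    log2_fold_change: dict[str, float] = field(default_factory=dict)
    celltype_content: dict[str, dict[str, float]] | None = None
    technical_factor: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


# -- id and truth assembly ----------------------------------------------


def metabolite_ids(config: SyntheticConfig) -> list[str]:
    mets = [f"met_{i + 1:03d}" for i in range(config.n_metabolites)]
    stds = [f"std_{i + 1:02d}" for i in range(config.n_internal_standards)]
    return mets + stds


def _class_labels(config: SyntheticConfig) -> dict[str, str]:
    """Deterministic class assignment by metabolite index (largest-remainder
    apportionment of the class fractions, in the order intracellular,
    extracellular, mixed)."""
    n = config.n_metabolites
    order = [CLASS_INTRACELLULAR, CLASS_EXTRACELLULAR, CLASS_MIXED]
    fracs = [config.class_fractions.get(c, 0.0) for c in order]
    counts = [int(np.floor(f * n)) for f in fracs]
    remainders = [f * n - c for f, c in zip(fracs, counts)]
    while sum(counts) < n:
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1.0
    labels: dict[str, str] = {}
    ids = metabolite_ids(config)
    k = 0
    for cls, cnt in zip(order, counts):
        for _ in range(cnt):
            labels[ids[k]] = cls
            k += 1
    for sid in ids[config.n_metabolites :]:
        labels[sid] = CLASS_INTERNAL_STANDARD
    return labels


def _draw_truth(config: SyntheticConfig, rng: np.random.Generator) -> SyntheticTruth:
    ids = metabolite_ids(config)
    labels = _class_labels(config)
    content: dict[str, float] = {}
    background: dict[str, float] = {}
    lo_c, hi_c = config.per_cell_content_range
    lo_b, hi_b = config.background_level_range
    for m in ids:
        cls = labels[m]
        if cls == CLASS_INTRACELLULAR:
            content[m] = float(rng.uniform(lo_c, hi_c))
            background[m] = float(
                rng.uniform(lo_b, hi_b) * config.intracellular_background_fraction
            )
        elif cls == CLASS_EXTRACELLULAR:
            content[m] = 0.0
            background[m] = float(rng.uniform(lo_b, hi_b))
        elif cls == CLASS_MIXED:
            content[m] = float(rng.uniform(lo_c, hi_c))
            background[m] = float(rng.uniform(lo_b, hi_b))
        else:  # internal standard: fixed per-sample spiked amount, no biology
            content[m] = 0.0
            background[m] = float(rng.uniform(lo_b, hi_b) * 100.0)
    return SyntheticTruth(
        per_cell_content=content,
        extracellular_background=background,
        lod={},
        class_label=labels,
        injected_outlier_samples=[],
        seed=config.seed,
    )


def _metabolite_meta(config: SyntheticConfig) -> pd.DataFrame:
    ids = metabolite_ids(config)
    is_std = [i >= config.n_metabolites for i in range(len(ids))]
    return pd.DataFrame(
        {
            "display_name": ids,
            "is_internal_standard": is_std,
            "standard_kind": ["c13" if s else "none" for s in is_std],
        },
        index=pd.Index(ids, name="metabolite"),
    )


# -- core simulation -----------------------------------------------------


def _simulate(
    config: SyntheticConfig,
    samples: pd.DataFrame,
    truth: SyntheticTruth,
    rng: np.random.Generator,
    content_of: Mapping[str, Mapping[str, float]] | None = None,
    content_scale: Mapping[str, float] | None = None,
) -> PeakTable:
    """Draw an intensity matrix for the given sample layout.

    ``content_of`` optionally maps sample_id -> per-metabolite content
    (cell-type profiles); ``content_scale`` maps sample_id -> scalar on the
    content term (treatment fold changes). Draw order is fixed (technical
    factors, experiment factors, per-cell noise, outliers) so a given seed is
    bit-reproducible.
    """
    ids = metabolite_ids(config)
    n_s, n_m = len(samples), len(ids)

    g = rng.lognormal(0.0, config.lognormal_sigma_technical, size=n_s)
    experiments = samples["experiment"].fillna("exp1").to_numpy()
    uniq_exp = list(dict.fromkeys(experiments))
    exp_factor = dict(
        zip(uniq_exp, rng.lognormal(0.0, config.lognormal_sigma_experiment, size=len(uniq_exp)))
    )
    eps = rng.lognormal(0.0, config.lognormal_sigma_metabolite, size=(n_s, n_m))

    base_content = np.array([truth.per_cell_content[m] for m in ids])
    background = np.array([truth.extracellular_background[m] for m in ids])
    is_std = np.array([truth.class_label[m] == CLASS_INTERNAL_STANDARD for m in ids])

    is_cell = (samples["role"] == "cell").to_numpy()
    events = pd.to_numeric(samples["event_count"], errors="coerce").fillna(0).to_numpy(float)

    mu = np.empty((n_s, n_m))
    for i, sid in enumerate(samples.index):
        content = base_content.copy()
        if content_of is not None and sid in content_of:
            content = np.array([content_of[sid][m] for m in ids])
        if content_scale is not None and sid in content_scale:
            content = content * content_scale[sid]
        bio = events[i] * content * is_cell[i] + background
        # internal standards: constant spiked amount, no event-count term
        bio = np.where(is_std, background, bio)
        mu[i] = bio * g[i] * exp_factor[experiments[i]]

    clean = mu * eps

    # LOD per metabolite: quantile of realized debris-sample intensities,
    # computed before outlier injection; internal standards are spiked far
    # above LOD and are never censored.
    debris_rows = (samples["role"] == "debris").to_numpy()
    lod = np.zeros(n_m)
    if debris_rows.any() and config.lod_quantile > 0:
        lod = np.quantile(clean[debris_rows], config.lod_quantile, axis=0)
    lod = np.where(is_std, 0.0, lod)
    truth.lod = dict(zip(ids, lod.astype(float)))

    # Outliers scale the biological signal but not the internal standards:
    # the 13C standards arrive with the extraction solution, so a sorting or
    # extraction anomaly changes the metabolite signal relative to them. (A
    # factor shared by the standards would be a plain technical factor, which
    # best-matched normalization removes — such a sample is not an outlier.)
    outlier_mask = rng.random(n_s) < config.outlier_rate
    values = clean.copy()
    values[np.ix_(outlier_mask, ~is_std)] *= config.outlier_magnitude
    truth.injected_outlier_samples = list(samples.index[outlier_mask])
    truth.technical_factor = dict(zip(samples.index, g.astype(float)))

    values = np.where(values < lod[None, :], np.nan, values)

    intensities = pd.DataFrame(
        values, index=samples.index, columns=pd.Index(ids, name="metabolite")
    )
    return PeakTable(
        intensities=intensities, samples=samples.copy(), metabolites=_metabolite_meta(config)
    )


def _sample_frame(records: list[dict]) -> pd.DataFrame:
    frame = pd.DataFrame.from_records(records).set_index("sample_id")
    frame["event_count"] = pd.array(frame["event_count"], dtype="Int64")
    frame["replicate"] = pd.array(frame["replicate"], dtype="Int64")
    return frame


# -- public designs ------------------------------------------------------


def generate_sorting_series(config: SyntheticConfig) -> tuple[PeakTable, SyntheticTruth]:
    """Event-count series: per level, ``replicates_per_group`` cell samples
    and the same number of matched debris samples."""
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    records = []
    for level in config.event_levels:
        for role in ("cell", "debris"):
            for r in range(1, config.replicates_per_group + 1):
                records.append(
                    {
                        "sample_id": f"{role}_{level:05d}_r{r}",
                        "role": role,
                        "event_count": level,
                        "cell_type": "B_cell",
                        "group": None,
                        "experiment": "exp1",
                        "replicate": r,
                    }
                )
    samples = _sample_frame(records)
    table = _simulate(config, samples, truth, rng)
    return table, truth


def generate_treatment_pair(config: SyntheticConfig) -> tuple[PeakTable, SyntheticTruth]:
    """Two treatment groups at a single event level (the highest configured)
    plus matched debris samples; treated content = control * 2**log2fc."""
    if not config.treatment_log2fc:
        raise ValueError("treatment_log2fc must be non-empty for the treatment design")
    unknown = set(config.treatment_log2fc) - set(metabolite_ids(config))
    if unknown:
        raise ValueError(f"treatment_log2fc names unknown metabolites: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    truth.log2_fold_change = dict(config.treatment_log2fc)

    level = max(config.event_levels)
    records = []
    for grp in ("treated", "control"):
        for r in range(1, config.replicates_per_group + 1):
            records.append(
                {
                    "sample_id": f"cell_{grp}_r{r}",
                    "role": "cell",
                    "event_count": level,
                    "cell_type": "Jurkat",
                    "group": grp,
                    "experiment": "exp1",
                    "replicate": r,
                }
            )
    for r in range(1, config.replicates_per_group + 1):
        records.append(
            {
                "sample_id": f"debris_r{r}",
                "role": "debris",
                "event_count": level,
                "cell_type": "Jurkat",
                "group": None,
                "experiment": "exp1",
                "replicate": r,
            }
        )
    samples = _sample_frame(records)

    fc = {m: 2.0 ** config.treatment_log2fc.get(m, 0.0) for m in metabolite_ids(config)}
    content_of = {
        sid: {m: truth.per_cell_content[m] * fc[m] for m in fc}
        for sid in samples.index[samples["group"] == "treated"]
    }
    table = _simulate(config, samples, truth, rng, content_of=content_of)
    return table, truth


def generate_celltype_panel(config: SyntheticConfig) -> tuple[PeakTable, SyntheticTruth]:
    """Per cell type: cell and matched debris samples at the highest
    configured event level; debris expectation is independent of cell type
    up to experiment-level technical factors."""
    if len(config.celltype_profiles) < 2:
        raise ValueError("celltype_profiles must name >= 2 cell types")
    for t, prof in config.celltype_profiles.items():
        if len(prof) != config.n_metabolites:
            raise ValueError(
                f"profile for {t!r} has length {len(prof)}, expected {config.n_metabolites}"
            )

    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    ids = metabolite_ids(config)

    level = max(config.event_levels)
    cell_types = list(config.celltype_profiles)
    experiments = [f"exp{1 + i % config.n_experiments}" for i in range(len(cell_types))]
    records = []
    for t, exp in zip(cell_types, experiments):
        for role in ("cell", "debris"):
            for r in range(1, config.replicates_per_group + 1):
                records.append(
                    {
                        "sample_id": f"{role}_{t}_r{r}",
                        "role": role,
                        "event_count": level,
                        "cell_type": t,
                        "group": None,
                        "experiment": exp,
                        "replicate": r,
                    }
                )
    samples = _sample_frame(records)

    celltype_content = {}
    for t in cell_types:
        prof = np.asarray(config.celltype_profiles[t], dtype=float)
        celltype_content[t] = {
            m: truth.per_cell_content[m] * (prof[i] if i < config.n_metabolites else 1.0)
            for i, m in enumerate(ids)
        }
    truth.celltype_content = celltype_content
    content_of = {
        sid: celltype_content[samples.loc[sid, "cell_type"]]
        for sid in samples.index[samples["role"] == "cell"]
    }
    table = _simulate(config, samples, truth, rng, content_of=content_of)
    return table, truth
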