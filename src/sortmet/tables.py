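"""Peak-table data model and CSV I/O.

The central object is :class:`PeakTable`: a samples x metabolites intensity
matrix with explicit missingness (NaN), plus per-sample and per-metabolite
metadata frames. Canonical on-disk form is a tidy CSV
(``sample_id, metabolite, intensity``) with two metadata CSVs; a wide matrix
CSV is supported read-only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALID_ROLES = frozenset({"cell", "debris", "blank", "medium"})
VALID_STANDARD_KINDS = frozenset({"c13", "spiked_extracellular", "none"})

SAMPLE_COLUMNS = ["role", "event_count", "cell_type", "group", "experiment", "replicate"]
METABOLITE_COLUMNS = ["display_name", "is_internal_standard", "standard_kind"]


class SchemaError(ValueError):
    """Raised when a peak table or its on-disk representation is invalid."""


@dataclass
class PeakTable:
    """Samples x metabolites intensity matrix with linked metadata.

    Parameters
    ----------
    intensities
        Float DataFrame indexed by sample id, columns are metabolite ids.
        Missing values are NaN; present values must be >= 0.
    samples
        DataFrame indexed by sample id with columns ``role``,
        ``event_count``, ``cell_type``, ``group``, ``experiment``,
        ``replicate``. ``role`` must be one of cell/debris/blank/medium;
        cell and debris samples must carry an event count.
    metabolites
        DataFrame indexed by metabolite id with columns ``display_name``,
        ``is_internal_standard`` and ``standard_kind``.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    metabolites: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.intensities.shape[1]

    def internal_standard_ids(self) -> list[str]:
        mask = self.metabolites["is_internal_standard"].astype(bool)
        return list(self.metabolites.index[mask])

    def samples_where(self, **criteria) -> pd.DataFrame:
        """Subset of the sample metadata matching equality criteria."""
        meta = self.samples
        mask = pd.Series(True, index=meta.index)
        for key, value in criteria.items():
            mask &= meta[key] == value
        return meta[mask]

    def subset(
        self,
        sample_ids: Iterable[str] | None = None,
        metabolite_ids: Iterable[str] | None = None,
    ) -> "PeakTable":
        """Return a new table restricted to the given samples/metabolites."""
        sids = list(sample_ids) if sample_ids is not None else self.sample_ids
        mids = list(metabolite_ids) if metabolite_ids is not None else self.metabolite_ids
        return PeakTable(
            intensities=self.intensities.loc[sids, mids].copy(),
            samples=self.samples.loc[sids].copy(),
            metabolites=self.metabolites.loc[mids].copy(),
        )

    def with_intensities(self, intensities: pd.DataFrame) -> "PeakTable":
        """Return a copy with the intensity matrix replaced."""
        return PeakTable(
            intensities=intensities,
            samples=self.samples.copy(),
            metabolites=self.metabolites.copy(),
        )

    def copy(self) -> "PeakTable":
        return PeakTable(
            intensities=self.intensities.copy(),
            samples=self.samples.copy(),
            metabolites=self.metabolites.copy(),
        )

    def equals(self, other: "PeakTable") -> bool:
        if list(self.intensities.index) != list(other.intensities.index):
            return False
        if list(self.intensities.columns) != list(other.intensities.columns):
            return False
        a, b = self.intensities.to_numpy(float), other.intensities.to_numpy(float)
        if not (
            np.array_equal(np.isnan(a), np.isnan(b))
            and np.allclose(a[~np.isnan(a)], b[~np.isnan(b)], rtol=0, atol=0)
        ):
            return False
        return _meta_equal(self.samples, other.samples) and _meta_equal(
            self.metabolites, other.metabolites
        )

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        ints, smeta, mmeta = self.intensities, self.samples, self.metabolites

        if ints.index.has_duplicates:
            dup = ints.index[ints.index.duplicated()][0]
            raise SchemaError(f"duplicate sample_id: {dup!r}")
        if ints.columns.has_duplicates:
            dup = ints.columns[ints.columns.duplicated()][0]
            raise SchemaError(f"duplicate metabolite id: {dup!r}")

        if list(ints.index) != list(smeta.index):
            raise SchemaError(
                "intensity matrix rows do not match sample metadata "
                f"({ints.shape[0]} rows vs {smeta.shape[0]} samples)"
            )
        if list(ints.columns) != list(mmeta.index):
            raise SchemaError(
                "intensity matrix columns do not match metabolite metadata "
                f"({ints.shape[1]} columns vs {mmeta.shape[0]} metabolites)"
            )

        missing_cols = [c for c in SAMPLE_COLUMNS if c not in smeta.columns]
        if missing_cols:
            raise SchemaError(f"sample metadata lacks columns: {missing_cols}")
        missing_cols = [c for c in METABOLITE_COLUMNS if c not in mmeta.columns]
        if missing_cols:
            raise SchemaError(f"metabolite metadata lacks columns: {missing_cols}")

        bad_roles = set(smeta["role"].dropna()) - VALID_ROLES
        if bad_roles:
            raise SchemaError(
                f"unknown sample role(s) {sorted(bad_roles)}; "
                f"admitted: {sorted(VALID_ROLES)}"
            )
        needs_events = smeta["role"].isin(["cell", "debris"])
        if needs_events.any():
            ec = pd.to_numeric(smeta.loc[needs_events, "event_count"], errors="coerce")
            if ec.isna().any():
                bad = ec.index[ec.isna()][0]
                raise SchemaError(
                    f"sample {bad!r} has role {smeta.loc[bad, 'role']!r} "
                    "but no event_count"
                )

        bad_kinds = set(mmeta["standard_kind"].dropna()) - VALID_STANDARD_KINDS
        if bad_kinds:
            raise SchemaError(f"unknown standard_kind(s): {sorted(bad_kinds)}")
        is_std = mmeta["is_internal_standard"].astype(bool)
        kind_none = mmeta["standard_kind"].fillna("none") == "none"
        inconsistent = is_std == kind_none
        if inconsistent.any():
            bad = mmeta.index[inconsistent][0]
            raise SchemaError(
                f"metabolite {bad!r}: is_internal_standard must be true iff "
                "standard_kind != 'none'"
            )

        values = ints.to_numpy(dtype=float)
        neg = values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise SchemaError(
                f"negative intensity at sample {ints.index[i]!r}, "
                f"metabolite {ints.columns[j]!r}"
            )


def _meta_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        return False
    for col in a.columns:
        xa, xb = a[col], b[col]
        na = xa.isna().to_numpy()
        if not np.array_equal(na, xb.isna().to_numpy()):
            return False
        if not (xa[~na] == xb[~na]).all():
            return False
    return True


def make_peak_table(
    intensities: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    metabolites: pd.DataFrame | None = None,
    roles: Mapping[str, str] | str = "cell",
) -> PeakTable:
    """Build a PeakTable, synthesizing default metadata where absent.

    Convenience for tests and interactive use: missing sample metadata gets
    the given role(s) and no event counts; missing metabolite metadata marks
    everything as a non-standard compound.
    """
    if samples is None:
        role_of = (lambda s: roles) if isinstance(roles, str) else (lambda s: roles[s])
        samples = pd.DataFrame(
            {
                "role": [role_of(s) for s in intensities.index],
                "event_count": pd.array([pd.NA] * len(intensities.index), dtype="Int64"),
                "cell_type": pd.NA,
                "group": pd.NA,
                "experiment": pd.NA,
                "replicate": pd.NA,
            },
            index=intensities.index,
        )
    if metabolites is None:
        metabolites = pd.DataFrame(
            {
                "display_name": list(intensities.columns),
                "is_internal_standard": False,
                "standard_kind": "none",
            },
            index=intensities.columns,
        )
    return PeakTable(intensities=intensities.astype(float), samples=samples, metabolites=metabolites)


# -- reading -------------------------------------------------------------


def _sniff_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_peak_table(
    intensity_path: str | Path,
    sample_meta_path: str | Path,
    metabolite_meta_path: str | Path,
    delimiter: str | None = None,
) -> PeakTable:
    """Read a peak table from tidy (or wide) intensity CSV plus metadata CSVs.

    The tidy form has columns ``sample_id, metabolite, intensity``; any other
    header is interpreted as a wide matrix whose first column holds sample ids
    and whose remaining headers are metabolite ids. Empty intensity fields
    become missing values.
    """
    for p in (intensity_path, sample_meta_path, metabolite_meta_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)

    sep = _sniff_delimiter(intensity_path, delimiter)
    raw = pd.read_csv(intensity_path, sep=sep, dtype={0: str})
    if list(raw.columns[:3]) == ["sample_id", "metabolite", "intensity"]:
        dup = raw.duplicated(subset=["sample_id", "metabolite"])
        if dup.any():
            row = raw[dup].iloc[0]
            raise SchemaError(
                f"duplicate (sample_id, metabolite) pair "
                f"({row['sample_id']!r}, {row['metabolite']!r}) in {intensity_path}"
            )
        matrix = raw.pivot(index="sample_id", columns="metabolite", values="intensity")
        # pivot sorts; restore first-appearance order
        matrix = matrix.loc[
            raw["sample_id"].drop_duplicates().tolist(),
            raw["metabolite"].drop_duplicates().tolist(),
        ]
    else:
        matrix = raw.set_index(raw.columns[0])
        matrix.index.name = "sample_id"
        if matrix.index.has_duplicates:
            dup = matrix.index[matrix.index.duplicated()][0]
            raise SchemaError(f"duplicate sample_id {dup!r} in {intensity_path}")
    matrix.columns.name = "metabolite"
    matrix = matrix.astype(float)

    smeta = pd.read_csv(
        sample_meta_path, sep=_sniff_delimiter(sample_meta_path, delimiter), dtype={"sample_id": str}
    )
    if "sample_id" not in smeta.columns:
        raise SchemaError(f"{sample_meta_path}: missing 'sample_id' column")
    if smeta["sample_id"].duplicated().any():
        dup = smeta.loc[smeta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"duplicate sample_id {dup!r} in {sample_meta_path}")
    smeta = smeta.set_index("sample_id")
    for col in SAMPLE_COLUMNS:
        if col not in smeta.columns:
            smeta[col] = pd.NA
    smeta["event_count"] = pd.array(
        pd.to_numeric(smeta["event_count"], errors="coerce"), dtype="Int64"
    )
    if "replicate" in smeta.columns:
        smeta["replicate"] = pd.array(
            pd.to_numeric(smeta["replicate"], errors="coerce"), dtype="Int64"
        )

    mmeta = pd.read_csv(
        metabolite_meta_path,
        sep=_sniff_delimiter(metabolite_meta_path, delimiter),
        dtype={"metabolite": str},
    )
    if "metabolite" not in mmeta.columns:
        raise SchemaError(f"{metabolite_meta_path}: missing 'metabolite' column")
    if mmeta["metabolite"].duplicated().any():
        dup = mmeta.loc[mmeta["metabolite"].duplicated(), "metabolite"].iloc[0]
        raise SchemaError(f"duplicate metabolite {dup!r} in {metabolite_meta_path}")
    mmeta = mmeta.set_index("metabolite")
    if "display_name" not in mmeta.columns:
        mmeta["display_name"] = mmeta.index
    if "is_internal_standard" not in mmeta.columns:
        mmeta["is_internal_standard"] = False
    mmeta["is_internal_standard"] = mmeta["is_internal_standard"].map(_parse_bool)
    if "standard_kind" not in mmeta.columns:
        mmeta["standard_kind"] = np.where(mmeta["is_internal_standard"], "c13", "none")
    mmeta["standard_kind"] = mmeta["standard_kind"].fillna("none")

    missing_samples = set(matrix.index) - set(smeta.index)
    if missing_samples:
        raise SchemaError(
            f"samples in intensity matrix but not in metadata: {sorted(missing_samples)}"
        )
    missing_mets = set(matrix.columns) - set(mmeta.index)
    if missing_mets:
        raise SchemaError(
            f"metabolites in intensity matrix but not in metadata: {sorted(missing_mets)}"
        )

    return PeakTable(
        intensities=matrix,
        samples=smeta.loc[matrix.index, SAMPLE_COLUMNS].copy(),
        metabolites=mmeta.loc[matrix.columns, METABOLITE_COLUMNS].copy(),
    )


def _parse_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"true", "1", "yes"}
    return bool(x) and not pd.isna(x)


# -- writing -------------------------------------------------------------


def write_peak_table(table: PeakTable, out_dir: str | Path, prefix: str = "peaks") -> dict[str, Path]:
    """Write a table as tidy intensity CSV plus metadata CSVs.

    Missing intensities are written as empty fields, never as zero. Returns a
    mapping of part name to path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": out / f"{prefix}_intensities.csv",
        "samples": out / f"{prefix}_samples.csv",
        "metabolites": out / f"{prefix}_metabolites.csv",
    }

    tidy = (
        table.intensities.rename_axis(index="sample_id", columns="metabolite")
        .stack(future_stack=True)
        .rename("intensity")
        .reset_index()
    )
    tidy.to_csv(paths["intensities"], index=False, na_rep="")

    smeta = table.samples.rename_axis(index="sample_id").reset_index()
    smeta.to_csv(paths["samples"], index=False, na_rep="")

    mmeta = table.metabolites.rename_axis(index="metabolite").reset_index()
    mmeta.to_csv(paths["metabolites"], index=False, na_rep="")
    return paths
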