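"""Physical sample-composition arithmetic for FACS-sorted droplets.

A sorted droplet of ~1 nL carries mostly sheath fluid (1000:1 sheath:sample);
the non-sheath fraction splits between the sorted cell (modelled as a sphere)
and the suspension buffer it came in. This module computes per-droplet and
per-sample component volumes, the resulting cell volume fraction, and the
sheath make-up volumes that keep solvent composition constant across sorted
event counts.

Units: diameters in um, volumes in nL internally; uL only at the report
boundary. 1 nL = 1e6 um^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

UM3_PER_NL = 1.0e6


@dataclass(frozen=True)
class DropletModel:
    """Physical parameters of the sorted-droplet composition model."""

    cell_diameter: float = 10.0  # um
    suspension_sphere_diameter: float = 12.0  # um
    droplet_diameter: float = 124.0  # um
    droplet_volume: float = 1.0  # nL
    sheath_to_sample_ratio: float = 1000.0
    n_events: int = 5000
    extraction_volume: float = 25_000.0  # nL
    rounding_sig_figs: int = 1

    def __post_init__(self) -> None:
        for name in (
            "cell_diameter",
            "suspension_sphere_diameter",
            "droplet_diameter",
            "droplet_volume",
            "extraction_volume",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.sheath_to_sample_ratio < 1:
            raise ValueError("sheath_to_sample_ratio must be >= 1")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if self.rounding_sig_figs < 1:
            raise ValueError("rounding_sig_figs must be >= 1")


@dataclass(frozen=True)
class CompositionTable:
    """Per-component droplet/sample volumes, raw and at printed precision.

    ``frame`` has one row per component (cells, cell_suspension_buffer,
    sheath_fluid, total_droplet, extraction_solution, total_sample) with
    columns ``diameter_um``, ``per_droplet_nl`` (unrounded),
    ``per_droplet_printed`` (printed precision), ``in_sample_nl`` (unrounded)
    and ``in_sample_printed`` (printed per-droplet value x events, the
    convention of the published table).
    """

    frame: pd.DataFrame
    cell_volume_fraction: float
    model: DropletModel

    def __getitem__(self, component: str) -> pd.Series:
        return self.frame.loc[component]


def sphere_volume(diameter: float) -> float:
    """Volume of a sphere of the given diameter (um), in nL."""
    if diameter < 0:
        raise ValueError(f"diameter must be >= 0, got {diameter}")
    return math.pi * diameter**3 / 6.0 / UM3_PER_NL


def round_printed(x: float, sig_figs: int = 1, min_decimals: int = 3) -> float:
    """Round to ``sig_figs`` significant figures, but never coarser than
    ``min_decimals`` decimal places.

    This reproduces the published table's mixed precision: tiny component
    volumes print at one significant figure (0.0005) while the sheath
    fraction prints at three decimals (0.999 rather than 1).
    """
    if x == 0:
        return 0.0
    decimals = max(min_decimals, sig_figs - 1 - math.floor(math.log10(abs(x))))
    return round(x, decimals)


def compose_sample(model: DropletModel, buffer_convention: str = "sample_split") -> CompositionTable:
    """Decompose a sorted sample into its per-component volumes.

    Per droplet, the non-sheath (sample) volume is droplet_volume/(ratio+1);
    the cell contributes its sphere volume and the suspension buffer the
    remainder (``sample_split`` convention, which matches the published
    numbers). The alternative ``shell`` convention takes the buffer as the
    spherical shell between the suspension-sphere and cell diameters, with
    the sheath absorbing the remainder so that volumes still conserve.

    Raises ``ValueError`` if the cell sphere exceeds the per-droplet sample
    volume (physically inconsistent parameters are flagged, never clipped).
    """
    dv = model.droplet_volume
    ratio = model.sheath_to_sample_ratio
    sample_per_droplet = dv / (ratio + 1.0)
    cell_per_droplet = sphere_volume(model.cell_diameter)

    if buffer_convention == "sample_split":
        if cell_per_droplet > sample_per_droplet:
            raise ValueError(
                f"cell volume {cell_per_droplet:.3g} nL exceeds per-droplet "
                f"sample volume {sample_per_droplet:.3g} nL"
            )
        buffer_per_droplet = sample_per_droplet - cell_per_droplet
        sheath_per_droplet = dv - sample_per_droplet
    elif buffer_convention == "shell":
        buffer_per_droplet = sphere_volume(model.suspension_sphere_diameter) - cell_per_droplet
        if cell_per_droplet + buffer_per_droplet > dv:
            raise ValueError("cell plus suspension shell exceeds droplet volume")
        sheath_per_droplet = dv - cell_per_droplet - buffer_per_droplet
    else:
        raise ValueError(f"unknown buffer_convention {buffer_convention!r}")

    n = model.n_events
    sig = model.rounding_sig_figs

    rows = {
        "cells": (model.cell_diameter, cell_per_droplet),
        "cell_suspension_buffer": (model.suspension_sphere_diameter, buffer_per_droplet),
        "sheath_fluid": (model.droplet_diameter, sheath_per_droplet),
        "total_droplet": (model.droplet_diameter, dv),
    }
    records = []
    for name, (diam, per_droplet) in rows.items():
        printed = round_printed(per_droplet, sig)
        records.append(
            {
                "component": name,
                "diameter_um": diam,
                "per_droplet_nl": per_droplet,
                "per_droplet_printed": printed,
                "in_sample_nl": per_droplet * n,
                "in_sample_printed": printed * n,
            }
        )
    total_sample = n * dv + model.extraction_volume
    records.append(
        {
            "component": "extraction_solution",
            "diameter_um": float("nan"),
            "per_droplet_nl": float("nan"),
            "per_droplet_printed": float("nan"),
            "in_sample_nl": model.extraction_volume,
            "in_sample_printed": model.extraction_volume,
        }
    )
    records.append(
        {
            "component": "total_sample",
            "diameter_um": float("nan"),
            "per_droplet_nl": float("nan"),
            "per_droplet_printed": float("nan"),
            "in_sample_nl": total_sample,
            "in_sample_printed": total_sample,
        }
    )
    frame = pd.DataFrame.from_records(records).set_index("component")
    fraction = cell_per_droplet * n / total_sample
    return CompositionTable(frame=frame, cell_volume_fraction=fraction, model=model)


def makeup_volume(
    n_events: int, reference_events: int = 5000, droplet_volume: float = 1.0
) -> float:
    """Sheath make-up volume (uL) added so that every well receives the same
    total droplet-plus-makeup liquid as the reference event count.

    ``droplet_volume`` is in nL; the returned volume is in uL.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if n_events > reference_events:
        raise ValueError(
            f"n_events ({n_events}) exceeds reference_events ({reference_events})"
        )
    return (reference_events - n_events) * droplet_volume / 1000.0


def makeup_table(
    event_counts: list[int],
    reference_events: int = 5000,
    droplet_volume: float = 1.0,
    extraction_volume_ul: float = 25.0,
) -> pd.DataFrame:
    """Pipetting scheme: extraction, make-up and total pipetted volume (uL)
    per event count. The total is the pipetted liquid (extraction + make-up);
    sorted droplet volume arrives via the sorter, not the pipette.
    """
    rows = []
    for n in event_counts:
        mk = makeup_volume(n, reference_events, droplet_volume)
        rows.append(
            {
                "cell_number": n,
                "extraction_solution_ul": extraction_volume_ul,
                "makeup_ul": mk,
                "total_volume_ul": extraction_volume_ul + mk,
            }
        )
    return pd.DataFrame(rows).set_index("cell_number")


def for_events(model: DropletModel, n_events: int) -> DropletModel:
    """Copy of the model at a different event count."""
    return replace(model, n_events=n_events)
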