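"""Replicate peak-area tables, compositional profiles, presence/absence.

Comparative metabolomics starts from a species x compound x replicate table
of LC-MS peak areas (three biological replicates per species in the study
design emulated here). Replicates are averaged, and the means are expressed
either as within-class percentages (each metabolite class standardised to
100% per species, monomeric and dimeric UBAS compounds separately — the
heat-map view that makes rare classes visible) or as a single closed
composition over all compounds (each species row summing to 100%, the form
used for Bray-Curtis/Mantel/NMDS analysis). Presence/absence calls
threshold the replicate mean at the quantifiability cutoff, so trace-level
detections are coded absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "NDMM_CLASSES",
    "AbundanceTable",
    "CompositionProfile",
    "PresenceMatrix",
    "aggregate_replicates",
    "within_class_percentages",
    "close_composition",
    "presence_absence",
]

NDMM_CLASSES = (
    "simple",
    "DASC",
    "NPAR",
    "PASC",
    "UBAS-monomeric",
    "UBAS-dimeric",
    "UPAS",
)


@dataclass
class AbundanceTable:
    """Long-format peak areas plus a compound -> class map.

    ``data`` columns: species, compound, replicate, area (areas >= 0).
    Missing replicates count as zero area (absence of detection).
    """

    data: pd.DataFrame
    class_map: Mapping[str, str]

    def __post_init__(self) -> None:
        required = {"species", "compound", "replicate", "area"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"abundance table missing columns {missing}")
        if (self.data["area"] < 0).any():
            raise ValueError("negative peak area")
        unmapped = set(self.data["compound"]) - set(self.class_map)
        if unmapped:
            raise ValueError(f"compounds without class mapping: {unmapped}")
        bad = set(self.class_map.values()) - set(NDMM_CLASSES)
        if bad:
            raise ValueError(f"unknown NDMM classes: {bad}")

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    @property
    def compounds(self) -> list[str]:
        return sorted(self.data["compound"].unique())

    @classmethod
    def from_csv(
        cls, areas_path: str | Path, class_map_path: str | Path
    ) -> "AbundanceTable":
        data = pd.read_csv(areas_path, comment=None)
        cmap = pd.read_csv(class_map_path)
        return cls(data, dict(zip(cmap["compound"], cmap["ndmm_class"])))


@dataclass
class CompositionProfile:
    """Species x compound percentage matrix.

    ``within_class`` profiles sum to 100 within each nonzero class per
    species; ``closed_all`` profiles sum to 100 across all compounds.
    """

    values: pd.DataFrame  # species rows, compound columns
    mode: str  # "within_class" | "closed_all"
    class_map: Mapping[str, str] = field(default_factory=dict)


@dataclass
class PresenceMatrix:
    """Boolean species x compound matrix with the threshold that made it."""

    values: pd.DataFrame
    threshold: float


def aggregate_replicates(t: AbundanceTable) -> pd.DataFrame:
    """Mean peak area per species x compound.

    The mean is taken over the maximum replicate count seen for the
    species, so a compound missing from a replicate contributes zero
    (a non-detection, not missing data).
    """
    n_reps = t.data.groupby("species")["replicate"].nunique()
    if (n_reps < 1).any():
        raise ValueError("species with zero replicates")
    sums = (
        t.data.groupby(["species", "compound"])["area"]
        .sum()
        .unstack(fill_value=0.0)
    )
    means = sums.div(n_reps, axis=0)
    # complete the matrix: compounds never seen in a species are zero
    return means.reindex(columns=sorted(means.columns), fill_value=0.0)


def within_class_percentages(
    means: pd.DataFrame, class_map: Mapping[str, str]
) -> CompositionProfile:
    """Standardise mean areas to percentages within each metabolite class.

    Per species and class, each compound's mean area is divided by the
    class total and multiplied by 100; monomeric and dimeric UBAS
    compounds form separate classes and are standardised separately. A
    class absent from a species (total zero) yields zeros, not NaN.
    """
    unmapped = set(means.columns) - set(class_map)
    if unmapped:
        raise ValueError(f"compounds without class mapping: {unmapped}")
    out = means.copy().astype(float)
    for cls in sorted(set(class_map[c] for c in means.columns)):
        cols = [c for c in means.columns if class_map[c] == cls]
        totals = means[cols].sum(axis=1)
        pct = means[cols].div(totals.where(totals > 0), axis=0) * 100.0
        out[cols] = pct.fillna(0.0)
    return CompositionProfile(out, "within_class", dict(class_map))


def close_composition(means: pd.DataFrame) -> CompositionProfile:
    """Close each species row to 100% across all compounds."""
    totals = means.sum(axis=1)
    if (totals <= 0).any():
        zero = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero species rows: {zero}")
    return CompositionProfile(
        means.div(totals, axis=0) * 100.0, "closed_all"
    )


def presence_absence(
    t: AbundanceTable, threshold: float = 1.0e3
) -> PresenceMatrix:
    """Presence calls from replicate-mean intensity at/above ``threshold``.

    Trace-level detections (mean below the quantifiability cutoff) are
    coded absent, matching the convention of excluding trace compounds
    from comparative analyses.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    means = aggregate_replicates(t)
    if threshold == 0:
        return PresenceMatrix(means > 0, threshold)
    return PresenceMatrix(means >= threshold, threshold)
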