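"""Per-slice class profiles and factor-level aggregation.

A :class:`ClassProfile` holds, for one root slice, the droplet count,
class area (mm²) and droplet density (droplets/mm²) of each of the nine
radial classes plus slice totals. Profiles aggregate over the experimental
factors — cloned elite (CE1–CE4), root classification (thin/thick), root
diameter fraction (RF1–RF4) and horizon (HZ1–HZ3) — into summary rows of
slice counts, droplet sums and per-slice means ± SD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MetadataError, UsageError
from .geometry import N_CLASSES, RadialRecord

__all__ = [
    "CLONES",
    "FRACTIONS",
    "HORIZONS",
    "SliceMeta",
    "ClassProfile",
    "FactorSummary",
    "round_half_up",
    "classification_of",
    "build_profile",
    "summarize_factor",
    "class_distribution_matrix",
]

CLONES = ("CE1", "CE2", "CE3", "CE4")
FRACTIONS = ("RF1", "RF2", "RF3", "RF4")
HORIZONS = ("HZ1", "HZ2", "HZ3")
FACTORS = ("clone", "classification", "fraction", "horizon")

#: Root morphology: CE1/CE2 are thin-rooted, CE3/CE4 thick-rooted.
_CLASSIFICATION = {"CE1": "thin", "CE2": "thin", "CE3": "thick", "CE4": "thick"}
#: Diameter fractions each clone actually forms (> 4 mm only in thick clones).
FORMED_FRACTIONS = {
    "CE1": ("RF1", "RF2", "RF3"),
    "CE2": ("RF1", "RF2", "RF3"),
    "CE3": FRACTIONS,
    "CE4": FRACTIONS,
}


def classification_of(clone: str) -> str:
    try:
        return _CLASSIFICATION[clone]
    except KeyError:
        raise MetadataError(f"unknown clone {clone!r}; expected one of {CLONES}") from None


@dataclass(frozen=True)
class SliceMeta:
    """Factor labels and spatial scale of one root slice."""

    slice_id: str
    clone: str
    fraction: str
    horizon: str
    scale: float  # µm per px

    def __post_init__(self) -> None:
        if self.clone not in CLONES:
            raise MetadataError(f"unknown clone {self.clone!r}")
        if self.fraction not in FRACTIONS:
            raise MetadataError(f"unknown fraction {self.fraction!r}")
        if self.horizon not in HORIZONS:
            raise MetadataError(f"unknown horizon {self.horizon!r}")
        if not (math.isfinite(self.scale) and self.scale > 0):
            raise MetadataError(f"scale must be finite and positive, got {self.scale}")
        if self.fraction not in FORMED_FRACTIONS[self.clone]:
            warnings.warn(
                f"slice {self.slice_id}: clone {self.clone} is not recorded as forming "
                f"fraction {self.fraction}",
                stacklevel=2,
            )

    @property
    def classification(self) -> str:
        """thin or thick, derived from the clone."""
        return classification_of(self.clone)

    def level(self, factor: str) -> str:
        if factor == "clone":
            return self.clone
        if factor == "classification":
            return self.classification
        if factor == "fraction":
            return self.fraction
        if factor == "horizon":
            return self.horizon
        raise UsageError(f"unknown factor {factor!r}; expected one of {FACTORS}")


@dataclass
class ClassProfile:
    """Counts, areas and densities over the nine classes for one slice."""

    slice_id: str
    counts: np.ndarray  # (9,) droplets
    areas: np.ndarray  # (9,) mm²
    densities: np.ndarray = field(init=False)  # (9,) droplets/mm²
    total_count: int = field(init=False)
    total_area: float = field(init=False)
    total_density: float = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.areas = np.asarray(self.areas, dtype=np.float64)
        if self.counts.shape != (N_CLASSES,) or self.areas.shape != (N_CLASSES,):
            raise UsageError(f"profile needs {N_CLASSES} classes")
        if np.any(self.counts < 0):
            raise UsageError("negative class count")
        with np.errstate(divide="ignore", invalid="ignore"):
            d = self.counts / self.areas
        self.densities = np.where(self.counts == 0, 0.0, d)
        if not np.all(np.isfinite(self.densities)):
            raise UsageError("droplets counted in a class with zero area")
        self.total_count = int(self.counts.sum())
        self.total_area = float(self.areas.sum())
        self.total_density = (
            self.total_count / self.total_area if self.total_area > 0 else 0.0
        )


def build_profile(
    records: list[RadialRecord], areas_mm2: np.ndarray, slice_id: str
) -> ClassProfile:
    """Tally one slice's radial records into a class profile.

    Zero-droplet classes get density 0; a class holding droplets must have
    a positive area.
    """
    counts = np.zeros(N_CLASSES, dtype=np.int64)
    for rec in records:
        counts[rec.class_index - 1] += 1
    return ClassProfile(slice_id=slice_id, counts=counts, areas=np.asarray(areas_mm2))


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves going up (display convention)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class FactorSummary:
    """One factor level's slice count, droplet sum and per-slice statistics."""

    factor: str
    level: str
    n_slices: int
    sum_droplets: int
    mean_per_slice: float
    sd_per_slice: float
    mean_density: float
    sd_density: float
    single_slice: bool = False  # SD undefined at n = 1, reported as 0

    @property
    def display_mean(self) -> int:
        """Mean droplets per slice, rounded half-up for tabulation."""
        return round_half_up(self.mean_per_slice)


_LEVEL_ORDER = {
    "clone": list(CLONES),
    "classification": ["thin", "thick"],
    "fraction": list(FRACTIONS),
    "horizon": list(HORIZONS),
}


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def summarize_factor(
    profiles: list[ClassProfile], metas: dict[str, SliceMeta], factor: str
) -> list[FactorSummary]:
    """Aggregate per-slice totals by the levels of one factor.

    Per level: number of slices, sum of droplet counts, mean and sample
    (n−1) SD of the per-slice total count, and mean/SD of the per-slice
    total density. Levels appear in canonical order; levels with no slices
    are omitted.
    """
    if factor not in FACTORS:
        raise UsageError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    by_level: dict[str, list[ClassProfile]] = {}
    for p in profiles:
        meta = metas.get(p.slice_id)
        if meta is None:
            raise MetadataError(f"no metadata for slice {p.slice_id!r}")
        by_level.setdefault(meta.level(factor), []).append(p)

    out: list[FactorSummary] = []
    for level in _LEVEL_ORDER[factor]:
        group = by_level.get(level)
        if not group:
            continue
        totals = np.array([p.total_count for p in group], dtype=np.float64)
        dens = np.array([p.total_density for p in group], dtype=np.float64)
        out.append(
            FactorSummary(
                factor=factor,
                level=level,
                n_slices=len(group),
                sum_droplets=int(totals.sum()),
                mean_per_slice=float(totals.mean()),
                sd_per_slice=_sample_sd(totals),
                mean_density=float(dens.mean()),
                sd_density=_sample_sd(dens),
                single_slice=len(group) == 1,
            )
        )
    return out


def class_distribution_matrix(
    profiles: list[ClassProfile],
    metas: dict[str, SliceMeta],
    factor: str,
    value: str = "count",
) -> pd.DataFrame:
    """Levels × 9 matrix of mean per-class counts (or densities).

    Entry (level, k) is the mean over that level's slices of the class-k
    count (``value="count"``) or density (``value="density"``).
    """
    if factor not in FACTORS:
        raise UsageError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    if value not in ("count", "density"):
        raise UsageError(f"value must be 'count' or 'density', got {value!r}")
    by_level: dict[str, list[ClassProfile]] = {}
    for p in profiles:
        by_level.setdefault(metas[p.slice_id].level(factor), []).append(p)
    rows, index = [], []
    for level in _LEVEL_ORDER[factor]:
        group = by_level.get(level)
        if not group:
            continue
        attr = "counts" if value == "count" else "densities"
        rows.append(np.mean([getattr(p, attr) for p in group], axis=0))
        index.append(level)
    return pd.DataFrame(rows, index=index, columns=[f"class_{k}" for k in range(1, 10)])
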