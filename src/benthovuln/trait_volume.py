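"""Convex-hull trait volumes and impacted-volume statistics.

The trait volume V of a set of FEs is the m-dimensional volume of the convex
hull of their coordinates in the selected trait space. The impacted fraction
of a record subset is V(hull of impacted FEs) / V(hull of all FEs). Subsets
are cut by severity class or minimum-percent threshold, driver class, region
(longitude banding of the Mediterranean) and year window; unbalanced survey
effort across regions or decades is handled by balanced resampling (n records
drawn without replacement, R repetitions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .trait_data import (
    ABIOTIC_DRIVERS,
    BIOTIC_DRIVERS,
    FunctionalEntity,
    MortalityRecord,
    ValidationError,
    impacted_fe_ids,
)
from .trait_space import TraitSpace

__all__ = [
    "DEFAULT_REGION_BOUNDS",
    "DRIVER_CLASSES",
    "VolumeResult",
    "ResampleSummary",
    "DriverYearCell",
    "hull_volume",
    "impacted_fraction",
    "subset_records",
    "assign_region",
    "heatmap_driver_class",
    "resample_volume",
    "driver_year_heatmap",
    "decade_summary",
]

# Western/Central/Eastern Mediterranean longitude cut lines (degrees east);
# Sicily Channel ~11.5, west Aegean ~22.
DEFAULT_REGION_BOUNDS = (11.5, 22.0)

# Twelve driver classes of the driver x year grid: each single abiotic driver
# plus same-class combinations, likewise for biotic, plus mixed-class events.
DRIVER_CLASSES = tuple(
    sorted(ABIOTIC_DRIVERS)
    + ["abiotic combination"]
    + sorted(BIOTIC_DRIVERS)
    + ["biotic combination", "abiotic x biotic"]
)


@dataclass(frozen=True)
class VolumeResult:
    """Impacted-volume outcome for one record subset."""

    descriptor: str
    n_fes_impacted: int
    n_fes_total: int
    hull_volume_global: float
    hull_volume_impacted: float
    fraction: float
    degenerate: bool


@dataclass
class ResampleSummary:
    """Balanced-resampling outcome for one group of records."""

    group: str
    n: int
    repetitions: int
    fractions: np.ndarray
    fe_counts: np.ndarray
    seed: int
    mean_fraction: float = field(init=False)
    sd_fraction: float = field(init=False)
    mean_fe_count: float = field(init=False)
    sd_fe_count: float = field(init=False)

    def __post_init__(self) -> None:
        ddof = 1 if len(self.fractions) > 1 else 0
        self.mean_fraction = float(np.mean(self.fractions))
        self.sd_fraction = float(np.std(self.fractions, ddof=ddof))
        self.mean_fe_count = float(np.mean(self.fe_counts))
        self.sd_fe_count = float(np.std(self.fe_counts, ddof=ddof))


@dataclass(frozen=True)
class DriverYearCell:
    """Impacted volume fraction for one driver class in one year."""

    driver_class: str
    year: int
    fraction: float
    n_fes_impacted: int


def hull_volume(points: np.ndarray) -> tuple[float, bool]:
    """Exact convex-hull volume of n points in m >= 2 dimensions.

    Returns ``(volume, degenerate)``; degenerate (volume 0) when there are
    fewer than m+1 points or the points are affinely dependent, rather than
    falling back to a lower-dimensional measure.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValidationError(f"points must be n x m with m >= 2, got shape {pts.shape}")
    if not np.isfinite(pts).all():
        raise ValidationError("non-finite coordinates")
    n, m = pts.shape
    if n < m + 1:
        return 0.0, True
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0, True
    return float(hull.volume), False


def impacted_fraction(
    space: TraitSpace,
    fes: Sequence[FunctionalEntity],
    impacted: set[str],
    descriptor: str = "",
) -> VolumeResult:
    """Ratio of the impacted-FE hull volume to the global hull volume.

    Both hulls use the first m_selected axes of the trait space. Impacted
    sets too small (or too flat) to span an m-dimensional body score 0 with
    the degenerate flag set.
    """
    labels = set(space.labels)
    stray = impacted - labels
    if stray:
        raise ValidationError(f"impacted FE ids not in trait space: {sorted(stray)}")
    coords = space.selected_coordinates()
    cache_key = ("global_volume", coords.shape[1])
    if cache_key in space._cache:
        v_global, deg_global = space._cache[cache_key]
    else:
        v_global, deg_global = hull_volume(coords)
        space._cache[cache_key] = (v_global, deg_global)
    if deg_global or v_global <= 0:
        raise ValidationError("global FE hull is degenerate; cannot normalize fractions")
    idx = [i for i, lab in enumerate(space.labels) if lab in impacted]
    if not idx:
        return VolumeResult(descriptor, 0, space.coordinates.shape[0], v_global, 0.0, 0.0, True)
    v_imp, deg = hull_volume(coords[idx])
    frac = 0.0 if deg else v_imp / v_global
    return VolumeResult(
        descriptor=descriptor,
        n_fes_impacted=len(idx),
        n_fes_total=space.coordinates.shape[0],
        hull_volume_global=v_global,
        hull_volume_impacted=v_imp,
        fraction=float(frac),
        degenerate=deg,
    )


def assign_region(longitude: float, bounds: tuple[float, float] = DEFAULT_REGION_BOUNDS) -> str:
    """Band a longitude into western / central / eastern Mediterranean."""
    lo, hi = bounds
    if lo >= hi:
        raise ValidationError(f"region bounds must increase, got {bounds}")
    if longitude < lo:
        return "western"
    if longitude <= hi:
        return "central"
    return "eastern"


def heatmap_driver_class(record: MortalityRecord) -> str:
    """One of the twelve driver x year grid classes for a record.

    Single-driver records fall in their driver's own class; multiple drivers
    of one class fall in that class's combination; drivers of both classes
    fall in the mixed 'abiotic x biotic' class.
    """
    a = record.drivers & ABIOTIC_DRIVERS
    b = record.drivers & BIOTIC_DRIVERS
    if a and b:
        return "abiotic x biotic"
    pool = a or b
    if len(pool) == 1:
        return next(iter(pool))
    return ("abiotic" if a else "biotic") + " combination"


def subset_records(
    records: Iterable[MortalityRecord],
    severity: str | None = None,
    min_percent: int | None = None,
    driver_class: str | None = None,
    drivers: set[str] | None = None,
    region: str | None = None,
    year_window: tuple[int, int] | None = None,
    region_bounds: tuple[float, float] = DEFAULT_REGION_BOUNDS,
) -> list[MortalityRecord]:
    """Records satisfying every given filter.

    ``min_percent`` keeps records with percent_mortality >= the threshold;
    the top bin of the severity gradient ('worse than 90%') is expressed as
    ``min_percent=100``. ``driver_class`` matches the abiotic/biotic/
    combination classification; ``drivers`` keeps records listing any of the
    given labels.
    """
    if year_window is not None and year_window[0] > year_window[1]:
        raise ValidationError(f"contradictory year window {year_window}")
    out = []
    for rec in records:
        if severity is not None and rec.severity != severity:
            continue
        if min_percent is not None and rec.percent_mortality < min_percent:
            continue
        if driver_class is not None and rec.driver_class != driver_class:
            continue
        if drivers is not None and not (rec.drivers & drivers):
            continue
        if region is not None and assign_region(rec.longitude, region_bounds) != region:
            continue
        if year_window is not None and not (year_window[0] <= rec.year <= year_window[1]):
            continue
        out.append(rec)
    return out


def resample_volume(
    records: Sequence[MortalityRecord],
    space: TraitSpace,
    fes: Sequence[FunctionalEntity],
    group: str = "",
    n: int = 100,
    repetitions: int = 1000,
    seed: int = 0,
) -> ResampleSummary:
    """Balanced resampling of a record group's impacted volume.

    Each repetition draws ``n`` records without replacement, maps them to
    impacted FEs, and records the impacted volume fraction and FE count.
    With ``n`` equal to the group size every repetition reproduces the
    full-group value exactly.
    """
    records = list(records)
    if len(records) < n:
        raise ValidationError(
            f"group {group!r} has {len(records)} records, fewer than subsample size {n}"
        )
    rng = np.random.default_rng(seed)
    fracs = np.empty(repetitions)
    counts = np.empty(repetitions, dtype=int)
    for r in range(repetitions):
        idx = rng.choice(len(records), size=n, replace=False)
        sub = [records[i] for i in idx]
        imp = impacted_fe_ids(sub, fes)
        res = impacted_fraction(space, fes, imp, descriptor=f"{group}:rep{r}")
        fracs[r] = res.fraction
        counts[r] = res.n_fes_impacted
    return ResampleSummary(
        group=group, n=n, repetitions=repetitions, fractions=fracs, fe_counts=counts, seed=seed
    )


def driver_year_heatmap(
    records: Sequence[MortalityRecord],
    space: TraitSpace,
    fes: Sequence[FunctionalEntity],
    years: Iterable[int] | None = None,
) -> list[DriverYearCell]:
    """Impacted volume fraction per driver class per year.

    Twelve driver classes over the year span give the driver x year grid
    (420 cells for a 35-year study). Years absent from the records yield
    zero-fraction cells.
    """
    records = list(records)
    if years is None:
        if not records:
            raise ValidationError("no records and no explicit year range")
        years = range(min(r.year for r in records), max(r.year for r in records) + 1)
    by_cell: dict[tuple[str, int], list[MortalityRecord]] = {}
    for rec in records:
        by_cell.setdefault((heatmap_driver_class(rec), rec.year), []).append(rec)
    cells = []
    for cls in DRIVER_CLASSES:
        for year in years:
            recs = by_cell.get((cls, year), [])
            if recs:
                imp = impacted_fe_ids(recs, fes)
                res = impacted_fraction(space, fes, imp, descriptor=f"{cls}:{year}")
                cells.append(DriverYearCell(cls, year, res.fraction, res.n_fes_impacted))
            else:
                cells.append(DriverYearCell(cls, year, 0.0, 0))
    return cells


def decade_summary(
    cells: Sequence[DriverYearCell],
    window: int = 10,
    start_year: int = 1986,
    by_class: bool = False,
) -> dict:
    """Mean impacted fraction and FE-count mean +/- sd per calendar window.

    Windows are aligned to ``start_year`` (1986-1995, 1996-2005, ... for
    window=10). With ``by_class`` the averages are further split by driver
    class. FE-count statistics pool the per-cell counts within the window.
    """
    if window not in (5, 10):
        raise ValidationError(f"window must be 5 or 10 years, got {window}")
    if not cells:
        raise ValidationError("no cells to summarize")

    def win(year: int) -> tuple[int, int]:
        k = (year - start_year) // window
        lo = start_year + k * window
        return (lo, lo + window - 1)

    keys = sorted({(win(c.year), c.driver_class if by_class else None) for c in cells})
    out = {}
    for (w, cls) in keys:
        sel = [c for c in cells if win(c.year) == w and (cls is None or c.driver_class == cls)]
        fr = np.array([c.fraction for c in sel])
        fc = np.array([c.n_fes_impacted for c in sel])
        label = f"{w[0]}-{w[1]}" + (f":{cls}" if cls else "")
        out[label] = {
            "window": w,
            "driver_class": cls,
            "mean_fraction": float(fr.mean()),
            "mean_fe_count": float(fc.mean()),
            "sd_fe_count": float(fc.std(ddof=1) if len(fc) > 1 else 0.0),
            "n_cells": len(sel),
        }
    return out
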