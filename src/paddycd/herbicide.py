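"""Herbicide budgeting from classified weed maps.

Site-specific weed management sprays only where weeds are mapped instead of
blanket-spraying the whole field. Given a classified map, the chain is:

    weed density (%)   = 100 · weed pixels / valid pixels
    coverage area (ha) = density · total area / 100
    estimated herbicide (ml) = density · farmers' blanket volume / 100
    expected reduction (%)   = 100 · (blanket − estimated) / blanket

so the expected reduction is exactly 100 − density: the fraction of the
blanket volume that never needed spraying. The blanket volume is a
field-survey input (farmers' practice), not something imagery can provide.

An ordinary least squares fit of reduction against weed coverage quantifies
the core temporal finding: as infestation spreads, the saving potential of
targeted spraying shrinks linearly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .raster import ClassRaster
from .scene import CLASS_NAMES, WEED

__all__ = [
    "HerbicidePlan", "RegressionResult", "class_density", "coverage_area",
    "estimated_herbicide", "expected_reduction", "plan_for_raster",
    "plan_series", "reduction_vs_coverage_regression",
]


@dataclass
class HerbicidePlan:
    date_tag: str
    densities: dict[str, float]  # class name -> % of valid pixels
    areas_ha: dict[str, float]
    total_area_ha: float
    farmers_total_ml: float
    estimated_ml: float
    reduction_percent: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def class_density(cr: ClassRaster,
                  mask: np.ndarray | None = None) -> dict[int, float]:
    """Per-class percentage of valid pixels. An optional extra ``mask``
    restricts the computation (e.g. to the untreated plots only); density
    definitions over the whole field vs the treatment area differ, so the
    caller chooses the denominator explicitly."""
    valid = cr.valid_mask if mask is None else (cr.valid_mask & mask)
    labels = cr.class_map[valid]
    total = labels.size
    if total == 0:
        raise ValueError("no valid pixels in the density mask")
    return {int(c): 100.0 * float((labels == c).sum()) / total
            for c in cr.class_codes}


def coverage_area(density_percent: float, total_area_ha: float) -> float:
    """Area covered by a class: density × total area / 100 (hectares)."""
    if density_percent < 0 or total_area_ha <= 0:
        raise ValueError("density must be >= 0 and total_area positive")
    return density_percent * total_area_ha / 100.0


def estimated_herbicide(weed_density_percent: float,
                        farmers_total_ml: float) -> float:
    """Volume needed to spray only the weed-covered fraction:
    density × blanket volume / 100."""
    if not 0.0 <= weed_density_percent <= 100.0:
        raise ValueError("weed density must lie in [0, 100]")
    if farmers_total_ml < 0:
        raise ValueError("farmers_total_ml must be >= 0")
    return weed_density_percent * farmers_total_ml / 100.0


def expected_reduction(farmers_total_ml: float, estimated_ml: float) -> float:
    """Saving over blanket practice: 100 · (blanket − estimated) / blanket.
    When the estimate comes from :func:`estimated_herbicide` this equals
    100 − weed density exactly."""
    if farmers_total_ml <= 0:
        raise ValueError("farmers_total_ml must be positive")
    if estimated_ml < 0 or estimated_ml > farmers_total_ml:
        raise ValueError("estimated volume must lie in [0, farmers_total]")
    return 100.0 * (farmers_total_ml - estimated_ml) / farmers_total_ml


def plan_for_raster(cr: ClassRaster, farmers_total_ml: float,
                    mask: np.ndarray | None = None) -> HerbicidePlan:
    """Full budgeting chain for one classified date."""
    dens = class_density(cr, mask=mask)
    valid = cr.valid_mask if mask is None else (cr.valid_mask & mask)
    total_area_ha = int(valid.sum()) * cr.pixel_size**2 / 10_000.0
    densities = {CLASS_NAMES[c]: d for c, d in dens.items()}
    areas = {name: coverage_area(d, total_area_ha)
             for name, d in densities.items()}
    weed_density = dens.get(WEED, 0.0)
    est = estimated_herbicide(weed_density, farmers_total_ml)
    red = expected_reduction(farmers_total_ml, est)
    return HerbicidePlan(
        date_tag=cr.date_tag, densities=densities, areas_ha=areas,
        total_area_ha=total_area_ha, farmers_total_ml=farmers_total_ml,
        estimated_ml=est, reduction_percent=red,
    )


def plan_series(rasters: list[ClassRaster], farmers_total_ml: float,
                mask: np.ndarray | None = None) -> pd.DataFrame:
    """One plan row per date, in tabular form for CSV export."""
    rows = []
    for cr in rasters:
        p = plan_for_raster(cr, farmers_total_ml, mask=mask)
        row = {"date": p.date_tag}
        row.update({f"density_{k}_percent": v for k, v in p.densities.items()})
        row.update({f"area_{k}_ha": v for k, v in p.areas_ha.items()})
        row["total_area_ha"] = p.total_area_ha
        row["farmers_total_ml"] = p.farmers_total_ml
        row["estimated_ml"] = p.estimated_ml
        row["reduction_percent"] = p.reduction_percent
        rows.append(row)
    return pd.DataFrame(rows)


def reduction_vs_coverage_regression(
        points: list[tuple[float, float]]) -> RegressionResult:
    """OLS of expected reduction (%) on weed coverage.

    R² is invariant under affine rescaling of the coverage axis, so
    coverage expressed in hectares or percent gives the same fit quality.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("coverage values are all equal; slope undefined")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue**2), n=len(points))
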