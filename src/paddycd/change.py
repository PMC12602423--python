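"""Post-classification change detection between thematic maps.

Two classified dates on the same grid are compared pixel-by-pixel. Each
pixel valid at *both* dates falls into one of nine ordered categories —
the 3×3 ordered pairs of (class at time 1, class at time 2):

    0 no change in paddy   1 paddy → soil   2 paddy → weed
    3 soil → paddy         4 no change in soil   5 soil → weed
    6 weed → paddy         7 weed → soil    8 no change in weed

so category code = 3·a + b for transition a → b. Counting categories gives
the k×k transition matrix (rows = time 1, columns = time 2); no empirical
reflectance threshold is involved anywhere — change is a discrete label
transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import ClassRaster
from .scene import CLASS_NAMES, NODATA, PADDY, SOIL, WEED

__all__ = [
    "CHANGE_CATEGORIES", "ChangeMap", "TransitionMatrix", "difference_maps",
    "transition_matrix", "weed_increase_count", "class_change_percent",
    "change_summary",
]

#: the nine legend names in category-code order (code = 3·from + to)
CHANGE_CATEGORIES = tuple(
    (f"No change in {CLASS_NAMES[a]}" if a == b
     else f"{CLASS_NAMES[a].capitalize()} to {CLASS_NAMES[b]}")
    for a in (PADDY, SOIL, WEED) for b in (PADDY, SOIL, WEED)
)

CHANGE_NODATA = 255


@dataclass
class ChangeMap:
    """Per-pixel change categories between two dates (joint-valid pixels)."""

    category_map: np.ndarray  # (H, W) uint8, codes 0..8, 255 nodata
    valid_mask: np.ndarray  # valid at both dates
    date_pair: tuple[str, str] = ("", "")
    pixel_size: float = 0.00913

    def category_counts(self) -> np.ndarray:
        cats = self.category_map[self.valid_mask]
        return np.bincount(cats, minlength=9)[:9]


@dataclass
class TransitionMatrix:
    """k×k pixel counts: entry (a, b) = pixels of class a at time 1 and
    class b at time 2, over pixels valid at both dates."""

    counts: np.ndarray
    class_codes: tuple[int, ...] = (PADDY, SOIL, WEED)
    date_pair: tuple[str, str] = ("", "")

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("transition counts must be >= 0")

    @property
    def valid_pixel_total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        """Per-class pixel counts at time 1."""
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        """Per-class pixel counts at time 2."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        names = [CLASS_NAMES[c].capitalize() for c in self.class_codes]
        return pd.DataFrame(self.counts, index=pd.Index(names, name=self.date_pair[0]),
                            columns=pd.Index(names, name=self.date_pair[1]))


def difference_maps(t1: ClassRaster, t2: ClassRaster) -> ChangeMap:
    """Pixel-wise differencing of two classified dates into change
    categories. Pixels invalid at either date are excluded."""
    if t1.class_map.shape != t2.class_map.shape:
        raise ValueError("rasters are not on the same grid")
    if t1.class_codes != t2.class_codes:
        raise ValueError("rasters use different class orderings")
    joint = t1.valid_mask & t2.valid_mask
    cat = np.full(t1.class_map.shape, CHANGE_NODATA, dtype=np.uint8)
    a = t1.class_map[joint].astype(np.int64)
    b = t2.class_map[joint].astype(np.int64)
    cat[joint] = (3 * a + b).astype(np.uint8)
    return ChangeMap(category_map=cat, valid_mask=joint,
                     date_pair=(t1.date_tag, t2.date_tag),
                     pixel_size=t1.pixel_size)


def transition_matrix(cm: ChangeMap) -> TransitionMatrix:
    counts = cm.category_counts().reshape(3, 3)
    return TransitionMatrix(counts=counts, date_pair=cm.date_pair)


def weed_increase_count(tm: TransitionMatrix) -> int:
    """Pixels that *became* weed: paddy→weed plus soil→weed."""
    if tuple(tm.class_codes) != (PADDY, SOIL, WEED):
        raise ValueError("expected class ordering paddy=0, soil=1, weed=2")
    return int(tm.counts[PADDY, WEED] + tm.counts[SOIL, WEED])


def class_change_percent(tm: TransitionMatrix) -> pd.DataFrame:
    """Each transition cell as a percentage of the joint-valid pixel total,
    plus per-destination-class aggregates of changed pixels."""
    total = tm.valid_pixel_total
    if total == 0:
        raise ValueError("no jointly valid pixels")
    pct = 100.0 * tm.counts / total
    rows = []
    for i, a in enumerate(tm.class_codes):
        for j, b in enumerate(tm.class_codes):
            rows.append({
                "from": CLASS_NAMES[a], "to": CLASS_NAMES[b],
                "pixels": int(tm.counts[i, j]), "percent": float(pct[i, j]),
                "changed": a != b,
            })
    table = pd.DataFrame(rows)
    gains = (table[table.changed].groupby("to", sort=False)["percent"].sum()
             .rename("gained_percent"))
    table = table.merge(gains, left_on="to", right_index=True, how="left")
    return table


def change_summary(rasters: list[ClassRaster],
                   pixel_size: float | None = None) -> pd.DataFrame:
    """Per-date, per-class coverage: pixel count, area in m² and hectares
    (1 ha = 10,000 m²). Areas are exact pixel_count × pixel_area; rounding
    is left to presentation."""
    if not rasters:
        raise ValueError("need at least one raster")
    rows = []
    for cr in rasters:
        px = pixel_size if pixel_size is not None else cr.pixel_size
        pixel_area = px * px
        counts = cr.class_counts()
        for code, count in counts.items():
            rows.append({
                "date": cr.date_tag, "class": CLASS_NAMES[code],
                "pixels": count, "area_m2": count * pixel_area,
                "area_ha": count * pixel_area / 10_000.0,
            })
    return pd.DataFrame(rows)
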