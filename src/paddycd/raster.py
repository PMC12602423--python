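"""Whole-raster inference and thematic-map post-processing.

A fitted per-pixel classifier is swept over a 5-band reflectance raster in
memory-efficient batches; masked (nodata) pixels skip prediction entirely
and stay nodata through every downstream step. The per-pixel label is the
argmax class (ties to the lowest class code) and the maximum probability is
kept as a confidence map.

Post-processing reduces per-pixel speckle with two standard thematic-map
operations: a sieve that dissolves connected components smaller than a
minimum area into their surroundings, and a k×k majority (modal) filter.
Both use 4-connectivity, matching the scene simulator's adjacency, and both
have their tie-breaks pinned down so an independent brute-force
implementation reproduces them bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .dfnn import FittedModel, _forward
from .scene import FOUR_CONNECTED, NODATA

__all__ = [
    "ClassRaster", "PostprocessConfig", "classify_raster", "sieve",
    "majority_filter", "write_class_raster", "read_class_raster",
    "write_reflectance", "read_reflectance",
]


@dataclass
class ClassRaster:
    """A classified date: thematic map + per-pixel confidence + mask."""

    class_map: np.ndarray  # (H, W) uint8, {0,1,2} valid, 255 nodata
    confidence: np.ndarray  # (H, W) float32, max class probability; NaN invalid
    valid_mask: np.ndarray  # (H, W) bool
    date_tag: str = ""
    pixel_size: float = 0.00913
    class_codes: tuple[int, ...] = (0, 1, 2)
    metadata: dict | None = None

    def __post_init__(self):
        if not (self.class_map.shape == self.confidence.shape
                == self.valid_mask.shape):
            raise ValueError("class_map, confidence and valid_mask shapes differ")

    def class_counts(self) -> dict[int, int]:
        labels = self.class_map[self.valid_mask]
        return {int(c): int((labels == c).sum()) for c in self.class_codes}


@dataclass(frozen=True)
class PostprocessConfig:
    """Speckle-removal parameters; recorded in output metadata so maps are
    auditable. min_object_pixels=0 and passes=0 disable the operations."""

    min_object_pixels: int = 5
    majority_kernel: int = 3
    passes: int = 1

    def __post_init__(self):
        if self.min_object_pixels < 0 or self.passes < 0:
            raise ValueError("min_object_pixels and passes must be >= 0")
        if self.majority_kernel < 1 or self.majority_kernel % 2 == 0:
            raise ValueError("majority_kernel must be an odd integer >= 1")


def classify_raster(model: FittedModel, reflectance: np.ndarray,
                    valid_mask: np.ndarray | None = None,
                    date_tag: str = "", pixel_size: float = 0.00913,
                    batch_size: int = 65536) -> ClassRaster:
    """Label every valid pixel of a (H, W, 5) reflectance raster.

    Only valid pixels are fed to the network (batched); results are
    identical to whole-image processing because per-pixel inference has no
    cross-pixel state. A fully masked raster returns all-nodata without a
    single model call.
    """
    reflectance = np.asarray(reflectance)
    if reflectance.ndim != 3 or reflectance.shape[2] != model.spec.input_dim:
        raise ValueError(f"expected (H, W, {model.spec.input_dim}) raster, "
                         f"got {reflectance.shape}")
    if model.scaler is None:
        raise ValueError("model has no scaler")
    h, w, _ = reflectance.shape
    if valid_mask is None:
        valid_mask = ~np.isnan(reflectance).any(axis=2)

    class_map = np.full((h, w), NODATA, dtype=np.uint8)
    confidence = np.full((h, w), np.nan, dtype=np.float32)

    rows, cols = np.nonzero(valid_mask)
    codes = np.asarray(model.class_codes)
    scaler = model.scaler
    for start in range(0, rows.size, batch_size):
        r = rows[start:start + batch_size]
        c = cols[start:start + batch_size]
        x = reflectance[r, c, :].astype(np.float64)
        x = (x - scaler.mean) / scaler.sd
        probs, _ = _forward(model.weights, x)
        idx = probs.argmax(axis=1)  # first maximum → lowest code on ties
        class_map[r, c] = codes[idx]
        confidence[r, c] = probs[np.arange(len(idx)), idx]

    return ClassRaster(class_map=class_map, confidence=confidence,
                       valid_mask=np.asarray(valid_mask, bool).copy(),
                       date_tag=date_tag, pixel_size=pixel_size,
                       class_codes=model.class_codes,
                       metadata={"batch_size": batch_size})


def _sieve_once(cm: np.ndarray, valid: np.ndarray,
                min_pixels: int) -> tuple[np.ndarray, int]:
    """One sieve pass: every 4-connected same-class component smaller than
    min_pixels is reassigned to the majority class among its valid boundary
    neighbors (majority of the input map; ties to the lowest class code).
    Components with no valid neighbors are left unchanged. Returns the new
    map and the number of undersized components seen."""
    out = cm.copy()
    n_small = 0
    classes = np.unique(cm[valid])
    for cls in classes:
        labeled, n_comp = ndimage.label(valid & (cm == cls),
                                        structure=FOUR_CONNECTED)
        if n_comp == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]  # skip background 0
        for comp_id in np.nonzero(sizes < min_pixels)[0] + 1:
            n_small += 1
            comp = labeled == comp_id
            boundary = ndimage.binary_dilation(comp, FOUR_CONNECTED) & ~comp & valid
            neighbor_classes = cm[boundary]
            if neighbor_classes.size == 0:
                continue
            counts = np.bincount(neighbor_classes)
            out[comp] = counts.argmax()  # argmax: lowest code wins ties
    return out, n_small


def sieve(cr: ClassRaster, cfg: PostprocessConfig) -> ClassRaster:
    """Remove thematic-map components smaller than ``cfg.min_object_pixels``.

    Passes repeat while they keep strictly reducing the number of
    undersized components; reassignment merges components, so this
    converges in a handful of passes, and the strict-decrease rule makes
    termination unconditional (a rare alternating configuration stops
    rather than cycling).
    """
    if cfg.min_object_pixels <= 1:
        return replace(cr, class_map=cr.class_map.copy(),
                       metadata={**(cr.metadata or {}), "sieve": 0})
    cm = cr.class_map.copy()
    valid = cr.valid_mask
    prev_small = np.inf
    while True:
        nxt, n_small = _sieve_once(cm, valid, cfg.min_object_pixels)
        if n_small == 0 or n_small >= prev_small or np.array_equal(nxt, cm):
            break
        cm = nxt
        prev_small = n_small
    meta = {**(cr.metadata or {}), "sieve": cfg.min_object_pixels}
    return replace(cr, class_map=cm, metadata=meta)


def _majority_once(cm: np.ndarray, valid: np.ndarray, k: int,
                   class_codes) -> np.ndarray:
    """One k×k modal-filter pass over valid pixels. The mode is taken over
    valid pixels in the window; a tie keeps the center pixel's class if it
    is among the tied classes, otherwise the lowest tied class code wins."""
    pad = k // 2
    counts = np.zeros(cm.shape + (len(class_codes),), dtype=np.int32)
    kernel = np.ones((k, k), dtype=np.int32)
    for ci, cls in enumerate(class_codes):
        ind = ((cm == cls) & valid).astype(np.int32)
        counts[:, :, ci] = ndimage.convolve(ind, kernel, mode="constant", cval=0)
    max_count = counts.max(axis=2)
    out = cm.copy()
    code_arr = np.asarray(class_codes, dtype=cm.dtype)
    winner = code_arr[counts.argmax(axis=2)]  # lowest tied code
    # does the center's own class reach the max count? then keep it
    center_idx = np.searchsorted(code_arr, np.where(valid, cm, class_codes[0]))
    center_count = np.take_along_axis(
        counts, center_idx[..., None], axis=2)[..., 0]
    keep_center = center_count == max_count
    out[valid] = np.where(keep_center, cm, winner)[valid]
    return out


def majority_filter(cr: ClassRaster, cfg: PostprocessConfig) -> ClassRaster:
    """Apply ``cfg.passes`` rounds of the k×k majority filter; masked pixels
    are never read as votes nor rewritten."""
    cm = cr.class_map.copy()
    for _ in range(cfg.passes):
        cm = _majority_once(cm, cr.valid_mask, cfg.majority_kernel,
                            cr.class_codes)
    meta = {**(cr.metadata or {}),
            "majority_kernel": cfg.majority_kernel, "passes": cfg.passes}
    return replace(cr, class_map=cm, metadata=meta)


# ---------------------------------------------------------------------------
# Raster I/O: multi-band float32 TIFF + uint8 class TIFF, with a JSON
# sidecar carrying pixel size, nodata policy and provenance metadata.
# ---------------------------------------------------------------------------

def write_reflectance(path: str | Path, reflectance: np.ndarray,
                      pixel_size: float, date_tag: str = "") -> None:
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(reflectance.astype(np.float32), 2, 0))
    sidecar = {"pixel_size_m": pixel_size, "date_tag": date_tag,
               "band_order": ["R", "G", "B", "RE", "NIR"], "nodata": "NaN"}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_reflectance(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    arr = np.moveaxis(tifffile.imread(path), 0, 2)
    meta = json.loads(path.with_suffix(".json").read_text())
    return arr, meta


def write_class_raster(path: str | Path, cr: ClassRaster,
                       confidence_path: str | Path | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, cr.class_map.astype(np.uint8))
    if confidence_path is not None:
        tifffile.imwrite(Path(confidence_path), cr.confidence.astype(np.float32))
    sidecar = {
        "pixel_size_m": cr.pixel_size,
        "date_tag": cr.date_tag,
        "class_codes": list(cr.class_codes),
        "class_names": {"0": "paddy", "1": "soil", "2": "weed"},
        "nodata": NODATA,
        "nodata_policy": "masked pixels skip prediction and are excluded "
                         "from all area totals",
        "metadata": cr.metadata or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_class_raster(path: str | Path,
                      confidence_path: str | Path | None = None) -> ClassRaster:
    path = Path(path)
    cm = tifffile.imread(path).astype(np.uint8)
    meta = json.loads(path.with_suffix(".json").read_text())
    if confidence_path is not None and Path(confidence_path).exists():
        conf = tifffile.imread(Path(confidence_path)).astype(np.float32)
    else:
        conf = np.where(cm != NODATA, 1.0, np.nan).astype(np.float32)
    return ClassRaster(
        class_map=cm, confidence=conf, valid_mask=cm != NODATA,
        date_tag=meta.get("date_tag", ""),
        pixel_size=meta.get("pixel_size_m", 0.00913),
        class_codes=tuple(meta.get("class_codes", (0, 1, 2))),
        metadata=meta.get("metadata"),
    )
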