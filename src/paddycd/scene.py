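"""Synthetic multi-date multispectral scene generator.

Emulates co-registered, radiometrically calibrated 5-band (R, G, B, RE, NIR)
reflectance scenes of a paddy field with three ground-cover classes —
paddy (0), soil (1), weed (2) — under two regimes: a weed-free treated field
(T0) and an infested untreated field (T1). Weed occurs in spatially
clustered patches that expand over time through a neighborhood contact
process, and paddy canopy closes over exposed soil, mirroring the dynamics
a UAV time series at ~34/41/47 days after sowing resolves.

Scenes are born co-registered on a common grid; there is no radiometric
panel calibration, vignetting or registration model here by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

PADDY, SOIL, WEED = 0, 1, 2
CLASS_NAMES = {PADDY: "paddy", SOIL: "soil", WEED: "weed"}
NODATA = 255  # class-map sentinel; reflectance sentinel is NaN
BAND_NAMES = ("R", "G", "B", "RE", "NIR")
BAND_COLUMNS = tuple(f"band_{b}" for b in BAND_NAMES)

#: 4-connected (von Neumann) structuring element shared by the scene
#: dynamics and the raster post-processing, so oracles can replicate both.
FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class SpectralSignature:
    """Per-class Gaussian reflectance model, band order R, G, B, RE, NIR."""

    class_id: int
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if mean.shape != (5,) or sd.shape != (5,):
            raise ValueError("mean and sd must be 5-vectors (R,G,B,RE,NIR)")
        if np.any(mean < 0) or np.any(mean > 1):
            raise ValueError("reflectance means must lie in [0, 1]")
        if np.any(sd < 0):
            raise ValueError("reflectance standard deviations must be >= 0")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)


def default_signatures() -> dict[int, SpectralSignature]:
    """Spectral signatures for paddy, soil and weed.

    Paddy and weed are both vigorous vegetation (high RE/NIR); they differ
    mainly in the red-edge/NIR ratio — the broadleaved weed reflects more
    strongly in the red edge and slightly less in the NIR than the rice
    canopy. Wet exposed soil is bright in the visible bands and dark in the
    NIR. Every class pair is separated by at least two pooled standard
    deviations in at least one band, so a trivial nearest-centroid rule is
    already highly accurate and classifier benchmarks on these scenes
    measure the pipeline, not the scene generator.
    """
    return {
        PADDY: SpectralSignature(
            PADDY,
            mean=np.array([0.04, 0.08, 0.03, 0.35, 0.55]),
            sd=np.array([0.010, 0.015, 0.010, 0.025, 0.030]),
        ),
        SOIL: SpectralSignature(
            SOIL,
            mean=np.array([0.12, 0.10, 0.08, 0.15, 0.10]),
            sd=np.array([0.020, 0.020, 0.015, 0.025, 0.025]),
        ),
        WEED: SpectralSignature(
            WEED,
            mean=np.array([0.05, 0.11, 0.04, 0.47, 0.47]),
            sd=np.array([0.010, 0.015, 0.010, 0.025, 0.030]),
        ),
    }


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, composition and noise model for one simulated scene.

    ``pixel_size`` defaults to 0.00913 m, the ground sampling distance of a
    20 m multirotor flight with a MicaSense RedEdge-class sensor.
    """

    height: int = 256
    width: int = 256
    pixel_size: float = 0.00913
    signatures: dict[int, SpectralSignature] = field(default_factory=default_signatures)
    initial_fractions: tuple[float, ...] = (0.60, 0.30, 0.10)
    patchiness: float = 8.0
    nodata_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("scene dimensions must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if abs(sum(self.initial_fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"initial_fractions must sum to 1, got {sum(self.initial_fractions)}"
            )
        if not 0 <= self.nodata_fraction < 1:
            raise ValueError("nodata_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class TransitionRates:
    """Per-step neighborhood transition probabilities for scene dynamics.

    ``weed_expansion_prob``: a valid non-weed pixel 4-adjacent to weed turns
    to weed. ``paddy_closure_prob``: a soil pixel 4-adjacent to paddy turns
    to paddy (canopy closure during tillering). ``suppression_prob``: a weed
    pixel 4-adjacent to paddy reverts to paddy (e.g. herbicide kill).
    """

    weed_expansion_prob: float = 0.25
    paddy_closure_prob: float = 0.10
    suppression_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("weed_expansion_prob", "paddy_closure_prob", "suppression_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")


@dataclass
class LabeledScene:
    """One acquisition date: reflectance cube + ground-truth class map + mask."""

    reflectance: np.ndarray  # (H, W, 5) float32, NaN where invalid
    class_map: np.ndarray  # (H, W) uint8, {0,1,2} valid, 255 nodata
    valid_mask: np.ndarray  # (H, W) bool
    date_tag: str = ""
    treatment: str = ""
    pixel_size: float = 0.00913

    def __post_init__(self):
        if not (
            self.reflectance.shape[:2]
            == self.class_map.shape
            == self.valid_mask.shape
        ):
            raise ValueError("reflectance, class_map and valid_mask shapes differ")
        if self.reflectance.ndim != 3 or self.reflectance.shape[2] != 5:
            raise ValueError("reflectance must be (H, W, 5)")
        on = self.class_map[self.valid_mask]
        if on.size and not np.isin(on, (PADDY, SOIL, WEED)).all():
            raise ValueError("valid pixels must carry class codes {0, 1, 2}")

    def class_fractions(self) -> dict[int, float]:
        """Realized per-class area fractions over valid pixels."""
        labels = self.class_map[self.valid_mask]
        n = labels.size
        return {c: float((labels == c).sum()) / n for c in (PADDY, SOIL, WEED)}


def _smooth_field(shape, sigma, rng):
    """Gaussian-smoothed white noise; the quantile level sets form patches
    of characteristic radius ~sigma."""
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")
    return noise


def simulate_class_map(config: SceneConfig) -> LabeledScene:
    """Simulate a spatially clustered class map (no reflectance yet).

    Two independent smoothed random fields are thresholded at quantiles:
    the first carves weed patches covering the weed fraction, the second
    splits the remainder between paddy and soil. Quantile thresholding makes
    realized fractions match the requested ones up to the granularity of one
    patch boundary, well inside ±3 percentage points at the default sizes.
    The returned scene carries NaN reflectance; see :func:`render_reflectance`.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.height, config.width)

    mask_field = _smooth_field(shape, config.patchiness / 2.0, rng)
    valid = mask_field >= np.quantile(mask_field, config.nodata_fraction)
    if config.nodata_fraction == 0:
        valid = np.ones(shape, dtype=bool)

    f_paddy, f_soil, f_weed = config.initial_fractions
    class_map = np.full(shape, NODATA, dtype=np.uint8)

    weed_field = _smooth_field(shape, config.patchiness, rng)
    split_field = _smooth_field(shape, config.patchiness, rng)

    vals = weed_field[valid]
    weed_thr = np.quantile(vals, 1.0 - f_weed) if f_weed > 0 else np.inf
    is_weed = valid & (weed_field >= weed_thr) if f_weed > 0 else np.zeros(shape, bool)

    rest = valid & ~is_weed
    rest_vals = split_field[rest]
    denom = f_paddy + f_soil
    paddy_share = f_paddy / denom if denom > 0 else 1.0
    paddy_thr = np.quantile(rest_vals, 1.0 - paddy_share) if rest_vals.size else np.inf
    is_paddy = rest & (split_field >= paddy_thr)
    if paddy_share >= 1.0:
        is_paddy = rest
    is_soil = rest & ~is_paddy

    class_map[is_paddy] = PADDY
    class_map[is_soil] = SOIL
    class_map[is_weed] = WEED

    reflectance = np.full(shape + (5,), np.nan, dtype=np.float32)
    return LabeledScene(
        reflectance=reflectance,
        class_map=class_map,
        valid_mask=valid,
        pixel_size=config.pixel_size,
    )


def render_reflectance(
    class_map: np.ndarray,
    signatures: dict[int, SpectralSignature],
    seed: int,
    valid_mask: np.ndarray | None = None,
    pixel_size: float = 0.00913,
    date_tag: str = "",
    treatment: str = "",
) -> LabeledScene:
    """Draw each valid pixel's 5-band reflectance from its class Gaussian.

    Values are clipped to the physical reflectance range [0, 1]; nodata
    pixels carry NaN. Deterministic given ``seed``.
    """
    class_map = np.asarray(class_map)
    if valid_mask is None:
        valid_mask = class_map != NODATA
    present = np.unique(class_map[valid_mask])
    missing = [int(c) for c in present if int(c) not in signatures]
    if missing:
        raise KeyError(f"no spectral signature for class code(s) {missing}")

    rng = np.random.default_rng(seed)
    shape = class_map.shape
    reflectance = np.full(shape + (5,), np.nan, dtype=np.float32)
    # one standard-normal draw per pixel/band, scaled per class; the draw
    # order is fixed (whole image at once) so results are seed-stable
    noise = rng.standard_normal(shape + (5,))
    for c in present:
        sig = signatures[int(c)]
        sel = valid_mask & (class_map == c)
        reflectance[sel] = np.clip(sig.mean + noise[sel] * sig.sd, 0.0, 1.0)

    out_map = np.where(valid_mask, class_map, NODATA).astype(np.uint8)
    return LabeledScene(
        reflectance=reflectance,
        class_map=out_map,
        valid_mask=valid_mask.copy(),
        date_tag=date_tag,
        treatment=treatment,
        pixel_size=pixel_size,
    )


def advance_scene(
    scene: LabeledScene, rates: TransitionRates, steps: int,
    signatures: dict[int, SpectralSignature] | None = None,
    date_tag: str | None = None,
) -> LabeledScene:
    """Advance the class map ``steps`` synchronous sweeps and re-render.

    Each sweep evaluates all pixels against the state at the start of the
    sweep (4-connected adjacency). Rule precedence per pixel: weed expansion
    first, then canopy closure, then suppression; a pixel changes at most
    once per sweep. With ``suppression_prob`` 0 weed pixels never leave the
    weed class, so the weed count is non-decreasing in ``steps``.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if signatures is None:
        signatures = default_signatures()
    rng = np.random.default_rng(rates.seed)
    cm = scene.class_map.copy()
    valid = scene.valid_mask

    for _ in range(steps):
        weed = valid & (cm == WEED)
        paddy = valid & (cm == PADDY)
        near_weed = ndimage.binary_dilation(weed, structure=FOUR_CONNECTED)
        near_paddy = ndimage.binary_dilation(paddy, structure=FOUR_CONNECTED)
        u = rng.random(cm.shape)

        expand = valid & ~weed & near_weed & (u < rates.weed_expansion_prob)
        close = (
            valid & (cm == SOIL) & near_paddy & ~expand
            & (u < rates.paddy_closure_prob)
        )
        suppress = weed & near_paddy & (u < rates.suppression_prob)

        nxt = cm.copy()
        nxt[expand] = WEED
        nxt[close] = PADDY
        nxt[suppress] = PADDY
        cm = nxt

    render_seed = int(rng.integers(0, 2**31 - 1))
    return render_reflectance(
        cm,
        signatures,
        seed=render_seed,
        valid_mask=valid,
        pixel_size=scene.pixel_size,
        date_tag=scene.date_tag if date_tag is None else date_tag,
        treatment=scene.treatment,
    )


def extract_training_samples(
    scenes: list[LabeledScene],
    per_class_counts: dict[tuple[str, int], int],
    seed: int,
) -> pd.DataFrame:
    """Randomly sample labeled pixels from scenes into a tabular sample set.

    ``per_class_counts`` maps (date_tag, class_code) -> requested count.
    Pixels are drawn without replacement from the valid pixels of that class
    in the scene with that date tag; the assembled table is then shuffled to
    remove any class/date ordering. Columns: band_R..band_NIR, label, date,
    treatment.
    """
    by_date = {s.date_tag: s for s in scenes}
    rng = np.random.default_rng(seed)
    chunks = []
    for (date_tag, class_code), count in sorted(per_class_counts.items()):
        if count == 0:
            continue
        if date_tag not in by_date:
            raise KeyError(f"no scene with date tag {date_tag!r}")
        sc = by_date[date_tag]
        rows, cols = np.nonzero(sc.valid_mask & (sc.class_map == class_code))
        if count > rows.size:
            raise ValueError(
                f"requested {count} pixels of class {class_code} at {date_tag}, "
                f"only {rows.size} available"
            )
        pick = rng.choice(rows.size, size=count, replace=False)
        spectra = sc.reflectance[rows[pick], cols[pick], :]
        chunk = pd.DataFrame(spectra.astype(np.float64), columns=list(BAND_COLUMNS))
        chunk["label"] = class_code
        chunk["date"] = date_tag
        chunk["treatment"] = sc.treatment
        chunks.append(chunk)

    if not chunks:
        return pd.DataFrame(
            columns=list(BAND_COLUMNS) + ["label", "date", "treatment"]
        )
    table = pd.concat(chunks, ignore_index=True)
    order = rng.permutation(len(table))
    return table.iloc[order].reset_index(drop=True)


def simulate_time_series(
    config: SceneConfig,
    rates: TransitionRates,
    date_tags: tuple[str, ...] = ("34DAS", "41DAS", "47DAS"),
    steps_between: int = 3,
    treatment: str = "T1",
) -> list[LabeledScene]:
    """Convenience: initial scene plus successive advances, one per date."""
    base = simulate_class_map(config)
    rng = np.random.default_rng(config.seed + 1)
    first = render_reflectance(
        base.class_map,
        config.signatures,
        seed=int(rng.integers(0, 2**31 - 1)),
        valid_mask=base.valid_mask,
        pixel_size=config.pixel_size,
        date_tag=date_tags[0],
        treatment=treatment,
    )
    scenes = [first]
    for i, tag in enumerate(date_tags[1:]):
        step_rates = replace(rates, seed=int(rng.integers(0, 2**31 - 1)))
        scenes.append(
            advance_scene(
                scenes[-1], step_rates, steps_between,
                signatures=config.signatures, date_tag=tag,
            )
        )
    return scenes
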