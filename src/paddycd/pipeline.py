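"""End-to-end run orchestration: simulate → sample → train → classify →
difference → herbicide plan, with per-stage derived seeds and a manifest.

One global seed fans out to per-stage seeds (stage name hashed with the
global seed) so any stage can be re-run independently yet reproducibly.
Every artifact lands in a run directory; `validate_outputs` re-opens the
artifacts and re-checks the pipeline's conservation invariants from disk.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import change as cd
from . import dfnn, herbicide, raster, samples, scene

logger = logging.getLogger("paddycd")

DEFAULT_DATES = ("34DAS", "41DAS", "47DAS")
DEFAULT_PAIRINGS = (("34DAS", "41DAS"), ("34DAS", "47DAS"))


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything one reproducible run needs; round-trips through YAML."""

    outdir: str = "runs/demo"
    seed: int = 0
    height: int = 128
    width: int = 128
    pixel_size: float = 0.00913
    patchiness: float = 6.0
    nodata_fraction: float = 0.02
    t1_fractions: tuple[float, float, float] = (0.55, 0.35, 0.10)
    t0_fractions: tuple[float, float, float] = (0.65, 0.35, 0.0)
    weed_expansion_prob: float = 0.25
    paddy_closure_prob: float = 0.10
    suppression_prob: float = 0.0
    steps_between: int = 3
    dates: tuple[str, ...] = DEFAULT_DATES
    pairings: tuple[tuple[str, str], ...] = DEFAULT_PAIRINGS
    samples_per_class: int = 1500
    train_dates: tuple[str, ...] = ("34DAS", "41DAS")
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 32
    learning_rate: float = 0.005
    min_object_pixels: int = 5
    majority_kernel: int = 3
    postprocess_passes: int = 1
    farmers_total_ml: float = 280.0

    def __post_init__(self):
        known = set(self.dates)
        for a, b in self.pairings:
            if a == b:
                raise ValueError(f"pairing ({a}, {b}) must reference distinct dates")
            if a not in known or b not in known:
                raise ValueError(f"pairing ({a}, {b}) references unknown date tags")
        for d in self.train_dates:
            if d not in known:
                raise ValueError(f"training date {d} not among dates {self.dates}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["t1_fractions"] = list(self.t1_fractions)
        d["t0_fractions"] = list(self.t0_fractions)
        d["dates"] = list(self.dates)
        d["train_dates"] = list(self.train_dates)
        d["pairings"] = [list(p) for p in self.pairings]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("t1_fractions", "t0_fractions", "dates", "train_dates"):
            if key in d:
                d[key] = tuple(d[key])
        if "pairings" in d:
            d["pairings"] = tuple(tuple(p) for p in d["pairings"])
        return cls(**d)


def _simulate_treatment(cfg: RunConfig, treatment: str) -> list[scene.LabeledScene]:
    fractions = cfg.t1_fractions if treatment == "T1" else cfg.t0_fractions
    sc_cfg = scene.SceneConfig(
        height=cfg.height, width=cfg.width, pixel_size=cfg.pixel_size,
        initial_fractions=fractions, patchiness=cfg.patchiness,
        nodata_fraction=cfg.nodata_fraction,
        seed=derive_seed(cfg.seed, f"scene-{treatment}"),
    )
    # the treated field has no weed to expand; closure still occurs
    expansion = cfg.weed_expansion_prob if treatment == "T1" else 0.0
    rates = scene.TransitionRates(
        weed_expansion_prob=expansion,
        paddy_closure_prob=cfg.paddy_closure_prob,
        suppression_prob=cfg.suppression_prob,
        seed=derive_seed(cfg.seed, f"rates-{treatment}"),
    )
    return scene.simulate_time_series(
        sc_cfg, rates, date_tags=cfg.dates,
        steps_between=cfg.steps_between, treatment=treatment,
    )


def _train_treatment(cfg: RunConfig, scenes: list[scene.LabeledScene],
                     treatment: str, outdir: Path):
    present = sorted({
        int(c) for s in scenes if s.date_tag in cfg.train_dates
        for c in np.unique(s.class_map[s.valid_mask])
    })
    counts = {(d, c): cfg.samples_per_class
              for d in cfg.train_dates for c in present}
    table = scene.extract_training_samples(
        scenes, counts, seed=derive_seed(cfg.seed, f"sample-{treatment}"))
    table.to_csv(outdir / f"samples_{treatment}.csv", index=False)

    split = samples.SplitSpec(seed=derive_seed(cfg.seed, f"split-{treatment}"))
    train_t, val_t, test_t = samples.shuffle_split(table, split)
    scaler = samples.fit_scaler(train_t)
    spec = dfnn.ModelSpec(n_classes=len(present))
    model = dfnn.build_model(spec, seed=derive_seed(cfg.seed, f"init-{treatment}"),
                             class_codes=tuple(present))
    tcfg = dfnn.TrainingConfig(
        learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs, patience=cfg.patience,
        seed=derive_seed(cfg.seed, f"train-{treatment}"),
    )
    fitted = dfnn.train(model, samples.apply_scaler(train_t, scaler),
                        samples.apply_scaler(val_t, scaler), tcfg, scaler=scaler)
    fitted.save(outdir / f"model_{treatment}")
    report = dfnn.evaluate(fitted, test_t)
    (outdir / f"evaluation_{treatment}.json").write_text(report.to_json())
    return fitted, report


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Any stage failure aborts with the stage name in the raised error; the
    manifest is written last, so its presence marks a complete run.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    manifest: dict = {"seed": cfg.seed, "stages": {}, "files": []}
    pp_cfg = raster.PostprocessConfig(
        min_object_pixels=cfg.min_object_pixels,
        majority_kernel=cfg.majority_kernel, passes=cfg.postprocess_passes)

    def record(name: str, t0: float):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        logger.info("stage %s done in %.2fs", name, time.time() - t0)

    for treatment in ("T0", "T1"):
        stage = f"simulate-{treatment}"
        t0 = time.time()
        try:
            scenes = _simulate_treatment(cfg, treatment)
        except Exception as e:  # pragma: no cover - defensive
            raise RuntimeError(f"stage {stage} failed: {e}") from e
        for s in scenes:
            p = outdir / f"scene_{treatment}_{s.date_tag}.tif"
            raster.write_reflectance(p, s.reflectance, s.pixel_size, s.date_tag)
            manifest["files"].append(p.name)
        record(stage, t0)

        stage = f"train-{treatment}"
        t0 = time.time()
        try:
            model, report = _train_treatment(cfg, scenes, treatment, outdir)
        except Exception as e:
            raise RuntimeError(f"stage {stage} failed: {e}") from e
        manifest["files"] += [f"samples_{treatment}.csv",
                              f"evaluation_{treatment}.json",
                              f"model_{treatment}/weights.npz"]
        manifest["stages"][f"evaluate-{treatment}"] = {
            "test_accuracy_percent": report.accuracy,
            "test_kappa": report.kappa,
        }
        record(stage, t0)

        stage = f"classify-{treatment}"
        t0 = time.time()
        classified = []
        for s in scenes:
            cr = raster.classify_raster(model, s.reflectance, s.valid_mask,
                                        date_tag=s.date_tag,
                                        pixel_size=s.pixel_size)
            cr = raster.majority_filter(raster.sieve(cr, pp_cfg), pp_cfg)
            base = outdir / f"class_{treatment}_{s.date_tag}.tif"
            conf = outdir / f"confidence_{treatment}_{s.date_tag}.tif"
            raster.write_class_raster(base, cr, confidence_path=conf)
            manifest["files"] += [base.name, conf.name]
            classified.append(cr)
        record(stage, t0)

        stage = f"change-{treatment}"
        t0 = time.time()
        by_date = {c.date_tag: c for c in classified}
        for a, b in cfg.pairings:
            cmap = cd.difference_maps(by_date[a], by_date[b])
            tm = cd.transition_matrix(cmap)
            _assert_conservation(tm, cmap, by_date[a], by_date[b])
            name = f"transition_{treatment}_{a}_{b}.csv"
            tm.to_frame().to_csv(outdir / name)
            manifest["files"].append(name)
        summary = cd.change_summary(classified)
        summary.to_csv(outdir / f"areas_{treatment}.csv", index=False)
        manifest["files"].append(f"areas_{treatment}.csv")
        record(stage, t0)

        if treatment == "T1":
            stage = "herbicide"
            t0 = time.time()
            plans = herbicide.plan_series(classified, cfg.farmers_total_ml)
            plans.to_csv(outdir / "herbicide_plan.csv", index=False)
            pts = list(zip(plans["area_weed_ha"], plans["reduction_percent"]))
            manifest["files"].append("herbicide_plan.csv")
            if len(pts) >= 2 and len({x for x, _ in pts}) > 1:
                reg = herbicide.reduction_vs_coverage_regression(pts)
                (outdir / "herbicide_regression.json").write_text(json.dumps({
                    "slope": reg.slope, "intercept": reg.intercept,
                    "r_squared": reg.r_squared, "n": reg.n}, indent=2))
                manifest["files"].append("herbicide_regression.json")
            record(stage, t0)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _assert_conservation(tm, cmap, cr1, cr2):
    joint = cr1.valid_mask & cr2.valid_mask
    if tm.valid_pixel_total != int(joint.sum()):
        raise AssertionError("transition total != joint-valid pixel count")
    for cr, totals in ((cr1, tm.row_totals()), (cr2, tm.col_totals())):
        labels = cr.class_map[joint]
        expected = np.array([(labels == c).sum() for c in (0, 1, 2)])
        if not np.array_equal(expected, totals):
            raise AssertionError("transition marginals != per-date class counts")


def validate_outputs(run_dir: str | Path) -> dict:
    """Re-open a finished run and re-check every module invariant from the
    files alone. Returns {check_name: {"passed": bool, "detail": str}}."""
    run_dir = Path(run_dir)
    checks: dict[str, dict] = {}

    def check(name: str, passed: bool, detail: str = ""):
        checks[name] = {"passed": bool(passed), "detail": detail}

    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        check("manifest_present", False, "manifest.json missing")
        return checks
    manifest = json.loads(manifest_path.read_text())
    missing = [f for f in manifest["files"] if not (run_dir / f).exists()]
    check("files_present", not missing,
          f"missing: {missing}" if missing else "all manifest files on disk")

    for treatment in ("T0", "T1"):
        rasters = {}
        for p in sorted(run_dir.glob(f"class_{treatment}_*.tif")):
            cr = raster.read_class_raster(
                p, confidence_path=run_dir / p.name.replace("class_", "confidence_"))
            rasters[cr.date_tag] = cr
        for p in sorted(run_dir.glob(f"transition_{treatment}_*.csv")):
            _, _, a, b = p.stem.split("_")
            frame = pd.read_csv(p, index_col=0)
            counts = frame.to_numpy()
            if a not in rasters or b not in rasters:
                check(f"{p.stem}_dates", False, "classified rasters missing")
                continue
            joint = rasters[a].valid_mask & rasters[b].valid_mask
            check(f"{p.stem}_total",
                  counts.sum() == joint.sum(),
                  f"matrix total {counts.sum()} vs joint-valid {joint.sum()}")
            labels1 = rasters[a].class_map[joint]
            row_ok = np.array_equal(
                counts.sum(axis=1)[: 3],
                np.array([(labels1 == c).sum() for c in range(counts.shape[0])]))
            check(f"{p.stem}_marginals", row_ok,
                  "row sums equal time-1 class counts" if row_ok else
                  "row sums differ from time-1 class counts")
            pct = 100.0 * counts / counts.sum() if counts.sum() else counts
            check(f"{p.stem}_percent_sum", abs(pct.sum() - 100.0) < 1e-9,
                  f"category percentages sum to {pct.sum():.12f}")

    plan_path = run_dir / "herbicide_plan.csv"
    if plan_path.exists():
        plans = pd.read_csv(plan_path)
        dens_cols = [c for c in plans.columns if c.startswith("density_")]
        sums = plans[dens_cols].sum(axis=1)
        check("density_sums", bool(np.allclose(sums, 100.0, atol=1e-9)),
              f"per-date density sums: {sums.tolist()}")
        ident = np.allclose(
            plans["reduction_percent"],
            100.0 - plans["density_weed_percent"], atol=1e-9)
        check("reduction_identity", bool(ident),
              "reduction == 100 - weed density on every date")
    return checks
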