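"""End-to-end orchestration: generate -> filter -> sample -> classify ->
split -> account -> assess.

A single global seed fans out to per-stage seeds through a stable
stage-name hash, so any stage can be re-run independently and two runs with
the same configuration produce byte-identical artifacts and manifest. The
manifest lists every written file with its SHA-256 digest plus per-stage
summary statistics (held-out kappa, per-year map kappas, area totals, net
deforestation/reforestation).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import accuracy, change, classify, filtering, io, sampling, splitting
from .scheme import DEFAULT_SCHEME, WOODY, ClassScheme
from .synthetic import (
    SceneConfig, default_signature, generate_ancillary, generate_truth,
    interpret_labels, synthesize_stack,
)

log = logging.getLogger("lulcpipe")

STAGES = ("generate", "filter", "sample", "classify", "split", "account",
          "assess")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    scene: SceneConfig = field(default_factory=lambda: SceneConfig(
        grid_rows=200, grid_cols=200))
    filter: filtering.FilterConfig = field(
        default_factory=filtering.FilterConfig)
    sampling: sampling.SamplingConfig = field(
        default_factory=sampling.SamplingConfig)
    ensemble: classify.EnsembleSpec = field(
        default_factory=classify.EnsembleSpec)
    out_dir: str | Path = "runs/default"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    interpretation_years: tuple[int, ...] | None = None
    n_secondary_validation: int = 191
    scheme: ClassScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        # stages are ordered; enabling a later stage requires the earlier ones
        self.stages = tuple(s for s in STAGES if s in self.stages)
        self.scene = _reseed(self.scene, stage_seed(self.seed, "generate"))
        if self.interpretation_years is None:
            y0, yn = self.scene.year_start, self.scene.year_end
            self.interpretation_years = tuple(sorted({
                y0 + 1, (y0 + yn) // 2 + 1, yn - 1}))


def _reseed(cfg, seed: int):
    from dataclasses import replace
    return replace(cfg, seed=seed)


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute the enabled stages in order; returns the manifest dict.

    Artifacts and ``manifest.json`` are written under ``config.out_dir``.
    With ``resume=True``, artifacts already present in ``out_dir`` are
    loaded so a later stage can run without recomputing earlier ones.
    A stage failure aborts the run with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}
    state: dict = {}
    if resume:
        state = load_state(out)
        mpath = out / "manifest.json"
        if mpath.exists():
            manifest = json.loads(mpath.read_text())

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": io.sha256_digest(path),
        }

    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, state, manifest, out, record)
        except Exception as exc:
            raise RuntimeError(
                f"stage '{stage}' failed: {exc}") from exc
        log.info("stage %s done in %.1f s", stage,
                 time.perf_counter() - t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _stage_generate(config, state, manifest, out, record):
    scene = config.scene
    truth = generate_truth(scene, config.scheme)
    sig = default_signature(scene.noise_sd)
    stack = synthesize_stack(truth, sig, scene)
    elevation, slope = generate_ancillary(truth, scene)
    state.update(truth=truth, stack=stack, elevation=elevation, slope=slope)
    params = {f"scene.{k}": v for k, v in vars(scene).items()}
    record("scene_config", io.write_flat_config(params, out / "scene.cfg"))
    np.savez_compressed(
        out / "state_truth.npz", fine_truth=truth.fine_truth,
        pixel_truth=truth.pixel_truth, woody_since=truth.woody_since,
        patch_id=truth.patch_id, years=truth.years,
        subgrid_factor=truth.subgrid_factor, pixel_size=truth.pixel_size,
        elevation=elevation, slope=slope)
    record("state_truth", out / "state_truth.npz")
    truth.change_log.to_csv(out / "change_log.csv", index=False)
    record("change_log", out / "change_log.csv")
    for i, y in enumerate(truth.years):
        p = io.write_ascii_grid(out / f"truth_{y}.asc", truth.pixel_truth[i],
                                scene.pixel_size)
        record(f"truth_{y}", p)
    record("stack", io.write_stack(stack, out / "stack.nc"))
    manifest["stages"]["generate"] = {
        "n_years": int(scene.n_years),
        "layers_per_variable": int(stack.n_layers),
        "grid": [scene.grid_rows, scene.grid_cols],
    }


def _stage_filter(config, state, manifest, out, record):
    filtered, flags = filtering.filter_stack(state["stack"], config.filter)
    features = filtering.annual_means(filtered, state["elevation"],
                                      state["slope"])
    state.update(filtered=filtered, flags=flags, features=features)
    p = out / "features.csv"
    features.to_csv(p, index=False, float_format="%.6f")
    record("features", p)
    manifest["stages"]["filter"] = {
        "n_feature_rows": int(len(features)),
        "n_flagged_ndvi": int(flags["ndvi"].sum()),
    }


def _stage_sample(config, state, manifest, out, record):
    truth = state["truth"]
    seed = stage_seed(config.seed, "sample")
    cands = pd.concat(
        [sampling.find_pure_pixels(truth, y)
         for y in config.interpretation_years], ignore_index=True)
    from dataclasses import replace
    scfg = replace(config.sampling, seed=seed)
    sites = sampling.spatial_filter(cands, scfg)
    labeled = interpret_labels(truth, sites, config.scene.label_error_rate,
                               seed=seed)
    table = sampling.build_training_table(labeled, state["features"])
    state.update(sites=labeled, training_table=table)
    p = out / "sites.csv"
    labeled.to_csv(p, index=False)
    record("sites", p)
    record("sites_geojson", io.sites_to_geojson(labeled, out / "sites.geojson"))
    p = out / "training_table.csv"
    table.to_csv(p, index=False, float_format="%.6f")
    record("training_table", p)
    manifest["stages"]["sample"] = {
        "n_candidates": int(len(cands)),
        "n_sites": int(len(sites)),
        "class_counts": {str(k): int(v) for k, v in
                         sampling.class_counts(table).items()},
    }


def _fit_and_score(config, state):
    """Train on the 80% stratified subset and score the held-out 20%."""
    from dataclasses import replace
    spec = replace(config.ensemble, seed=stage_seed(config.seed, "classify"))
    table = state["training_table"]
    train, test = classify.split_train_test(table, spec)
    model = classify.train_ensemble(train, spec)
    pred_test = classify.predict_table(model, test, spec)
    cm = accuracy.confusion(test["label"].to_numpy(), pred_test,
                            scheme=config.scheme)
    state.update(model=model, spec=spec, heldout_cm=cm,
                 n_train=len(train), n_test=len(test))
    return spec, model, cm


def _stage_classify(config, state, manifest, out, record):
    spec, model, cm = _fit_and_score(config, state)
    train_n, test_n = state["n_train"], state["n_test"]
    shape = state["truth"].shape
    maps = classify.predict_annual_maps(model, state["features"], shape,
                                        spec)
    state["annual_maps"] = maps
    for y, arr in maps.items():
        p = io.write_ascii_grid(out / f"lulc_raw_{y}.asc", arr,
                                config.scene.pixel_size)
        record(f"lulc_raw_{y}", p)
    per_year_kappa = {}
    truth = state["truth"]
    for i, y in enumerate(truth.years):
        cmy = accuracy.confusion(truth.pixel_truth[i].ravel(),
                                 maps[int(y)].ravel(), scheme=config.scheme)
        per_year_kappa[str(int(y))] = round(cmy.kappa, 6)
    summary = accuracy.kappa_summary(list(map(float,
                                              per_year_kappa.values())))
    manifest["stages"]["classify"] = {
        "heldout_kappa": round(cm.kappa, 6),
        "heldout_accuracy": round(cm.accuracy, 6),
        "heldout_category": accuracy.kappa_category(cm.kappa),
        "n_train": int(train_n), "n_test": int(test_n),
        "map_kappa_per_year": per_year_kappa,
        "map_kappa_mean": round(summary["mean"], 6),
        "map_kappa_sd": round(summary["sd"], 6),
    }


def _stage_split(config, state, manifest, out, record):
    refined = splitting.split_woody(state["annual_maps"])
    state["refined"] = refined
    for y in refined.years:
        p = io.write_ascii_grid(out / f"lulc_{y}.asc", refined.maps[y],
                                config.scene.pixel_size)
        record(f"lulc_{y}", p)
    val = splitting.validate_secondary(
        refined, state["truth"], config.n_secondary_validation,
        seed=stage_seed(config.seed, "split"))
    manifest["stages"]["split"] = {
        "n_refined_maps": len(refined.years),
        "years": [int(y) for y in refined.years],
        "secondary_agreement_percent":
            None if val["pooled_percent"] is None
            else round(val["pooled_percent"], 2),
        "secondary_n_scored": val["n_scored"],
    }


def _default_periods(years: tuple[int, ...]) -> tuple[tuple[int, int], ...]:
    """Two epochs split at 2010 when the record straddles it; short runs
    (< 5 mapped years, too few points for two trends) use one epoch."""
    y0, yn = years[0], years[-1]
    if yn - y0 < 4:
        return ((y0, yn),)
    mid = 2010 if y0 < 2010 < yn else (y0 + yn) // 2
    return ((y0, mid), (mid, yn))


def _stage_account(config, state, manifest, out, record):
    refined = state["refined"]
    series = change.class_area_series(refined, scheme=config.scheme)
    p = out / "area_series.csv"
    series.to_csv(p, index=False, float_format="%.4f")
    record("area_series", p)
    periods = _default_periods(refined.years)
    trends = change.epoch_trends(series, periods,
                                 seed=stage_seed(config.seed, "account"),
                                 scheme=config.scheme)
    p = out / "trends.csv"
    trends.to_csv(p, index=False, float_format="%.6f")
    record("trends", p)
    accounts = {}
    for (a, b) in periods:
        acct = change.transition_matrix(refined.maps[a], refined.maps[b],
                                        base_year=a, end_year=b,
                                        scheme=config.scheme)
        p = out / f"transitions_{a}_{b}.csv"
        acct.matrix.to_csv(p, float_format="%.4f")
        record(f"transitions_{a}_{b}", p)
        accounts[f"{a}-{b}"] = {
            "net_deforestation_km2": round(acct.net_deforestation_km2, 4),
            "net_reforestation_km2": round(acct.net_reforestation_km2, 4),
            "total_area_km2": round(acct.total_area, 4),
        }
    state["area_series"] = series
    manifest["stages"]["account"] = {
        "periods": [f"{a}-{b}" for a, b in periods],
        "accounts": accounts,
    }


def _stage_assess(config, state, manifest, out, record):
    if "heldout_cm" not in state:
        _fit_and_score(config, state)  # deterministic under the stage seed
    cm = state["heldout_cm"]
    p = out / "confusion_heldout.csv"
    cm.to_report().to_csv(p, float_format="%.6f")
    record("confusion_heldout", p)
    truth = state["truth"]
    sites = state["sites"]
    truth_labels = np.array([
        truth.pixel_truth[truth.year_index(int(s.year))][int(s.row),
                                                         int(s.col)]
        for s in sites.itertuples()])
    agree = accuracy.interpretation_agreement(truth_labels,
                                              sites["label"].to_numpy(),
                                              scheme=config.scheme)
    manifest["stages"]["assess"] = {
        "heldout_kappa": round(cm.kappa, 6),
        "heldout_kappa_category": accuracy.kappa_category(cm.kappa),
        "interpretation_kappa": round(agree["kappa"], 6),
        "interpretation_accuracy": round(agree["accuracy"], 6),
    }


def load_state(out_dir: str | Path) -> dict:
    """Reconstruct pipeline state from the artifacts present in a run
    directory (the resume path used by the CLI subcommands)."""
    out = Path(out_dir)
    state: dict = {}
    npz_path = out / "state_truth.npz"
    if npz_path.exists():
        with np.load(npz_path) as z:
            change_log = pd.DataFrame(
                columns=["year", "from_code", "to_code", "n_cells"])
            clpath = out / "change_log.csv"
            if clpath.exists():
                change_log = pd.read_csv(clpath)
            from .synthetic import TruthSchedule
            state["truth"] = TruthSchedule(
                years=z["years"], fine_truth=z["fine_truth"],
                pixel_truth=z["pixel_truth"], woody_since=z["woody_since"],
                patch_id=z["patch_id"], change_log=change_log,
                subgrid_factor=int(z["subgrid_factor"]),
                pixel_size=float(z["pixel_size"]))
            state["elevation"] = z["elevation"]
            state["slope"] = z["slope"]
    if (out / "stack.nc").exists():
        state["stack"] = io.read_stack(out / "stack.nc")
    if (out / "features.csv").exists():
        state["features"] = pd.read_csv(out / "features.csv")
    if (out / "sites.csv").exists():
        state["sites"] = pd.read_csv(out / "sites.csv")
    if (out / "training_table.csv").exists():
        state["training_table"] = pd.read_csv(out / "training_table.csv")
    raw = sorted(out.glob("lulc_raw_*.asc"))
    if raw:
        state["annual_maps"] = {
            int(p.stem.rsplit("_", 1)[1]): io.read_ascii_grid(p)[0]
            for p in raw}
    refined_paths = sorted(set(out.glob("lulc_*.asc")) - set(raw))
    if refined_paths and raw:
        maps = {int(p.stem.rsplit("_", 1)[1]): io.read_ascii_grid(p)[0]
                for p in refined_paths}
        input_years = tuple(sorted(state["annual_maps"]))
        history = np.zeros(next(iter(maps.values())).shape, dtype=np.uint32)
        for k, y in enumerate(input_years):
            history |= ((state["annual_maps"][y] == WOODY)
                        .astype(np.uint32) << np.uint32(k))
        state["refined"] = splitting.RefinedMaps(
            maps=maps, woody_history=history, input_years=input_years)
    return state


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "filter": _stage_filter,
    "sample": _stage_sample,
    "classify": _stage_classify,
    "split": _stage_split,
    "account": _stage_account,
    "assess": _stage_assess,
}


def imbalance_experiment(table: pd.DataFrame, spec: classify.EnsembleSpec,
                         majority_class: int = WOODY,
                         scheme: ClassScheme = DEFAULT_SCHEME) -> dict:
    """Sample-imbalance sensitivity check.

    The table is split once; the training side is duplicated with its
    majority class downsampled to the second-most-prevalent class size,
    and both models are scored on the *same* held-out 20% — a paired
    comparison, so the reported kappa difference reflects the imbalance
    effect rather than test-set resampling noise."""
    counts = sampling.class_counts(table)
    if majority_class not in counts.index or len(counts) < 2:
        raise ValueError("table lacks the majority class or a second class")
    train, test = classify.split_train_test(table, spec)
    second = int(sampling.class_counts(train)
                 .drop(index=majority_class).max())
    reduced = sampling.downsample_majority(train, majority_class, second,
                                           seed=spec.seed)
    out = {}
    for name, tbl in (("full", train), ("downsampled", reduced)):
        model = classify.train_ensemble(tbl, spec)
        pred = classify.predict_table(model, test, spec)
        cm = accuracy.confusion(test["label"].to_numpy(), pred,
                                scheme=scheme)
        out[name] = {"kappa": cm.kappa, "accuracy": cm.accuracy,
                     "n_train": len(tbl), "n_test": len(test)}
    out["kappa_difference"] = abs(out["full"]["kappa"]
                                  - out["downsampled"]["kappa"])
    return out


__all__ = ["RunConfig", "STAGES", "imbalance_experiment", "run_pipeline",
           "stage_seed"]
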