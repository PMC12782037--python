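"""End-to-end orchestration: one config, six stages, reproducible seeds.

Stages (dependency order): ``synthgen`` -> ``features`` -> ``assign`` ->
``build`` -> ``models`` -> ``evaluate``. Each stage writes plain files under
the output root so stages can also be run independently; within one
invocation intermediate objects are passed in memory. All randomness derives
from the config's root seed via named substreams, so identical config +
seed reproduces identical tables and metrics.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomod, datakit, evalkit, imfeat, megassign, synthgen

STAGES = ("synthgen", "features", "assign", "build", "models", "evaluate")


class ConfigError(ValueError):
    pass


class DependencyError(RuntimeError):
    """An upstream artifact required by a requested stage is missing."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_root": "runs/default",
    "synthgen": {
        "n_species": 8,
        "n_genera": 7,
        "n_families": 4,
        "n_orders": 3,
        "n_per_species": 12,
        "n_frames": 16,
        "image_height": 128,
        "image_width": 128,
        "px_per_mm": 9.0,
        "junk_rate": 0.05,
        "noise_sd": 2.0,
        "mass_sigma_log": 0.1,
        "length_sigma_log": 0.15,
        "p_noreads": 0.02,
        "p_mismatch": 0.01,
        "p_nospecies": 0.01,
        "p_repeat": 0.05,
        "write_images": False,
    },
    "features": {
        "threshold": "auto",
        "area_min_mm2": 1.5,
        "area_max_mm2": 1.0e6,
        "solidity_min": 0.2,
        "solidity_max": 1.0,
    },
    "assign": {"min_reads": 1000},
    "build": {"k": 5, "min_specimens_per_species": 5},
    "models": {
        "input_size": 64,
        "channels": [16, 32, 64, 64],
        "classify": {"rank": "species", "epochs": 50, "lr": 3e-3, "batch_size": 32},
        "regress": {"target_transform": "log1p", "epochs": 40, "lr": 3e-3, "batch_size": 32},
        "pretrained": {"enabled": True, "frozen": False, "epochs": 10, "folds": [0]},
        "linear": {
            "predictor_sets": [["A"], ["MFD"], ["P"], ["A", "MFD"], ["A", "MFD", "P"]],
            "target_transform": "log",
        },
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path: str | Path) -> dict:
    """YAML config merged over the defaults (config round-trips unchanged)."""
    try:
        user = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse config {path}: {e}") from e
    cfg = default_config()
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage implementations (each returns the in-memory artifacts it produced)


def stage_synthgen(cfg: dict, out: Path, ctx: dict) -> None:
    c = cfg["synthgen"]
    seed = int(cfg["seed"])
    taxonomy = synthgen.generate_taxonomy(
        c["n_species"], c["n_genera"], c["n_families"], c["n_orders"], seed
    )
    allom = synthgen.default_allometry(taxonomy, seed)
    allom = synthgen.AllometryParams(
        coeff_mg=allom.coeff_mg,
        exponent=allom.exponent,
        sigma_log=c["mass_sigma_log"],
    )
    lengths = synthgen.LengthParams(
        median_mm=synthgen.default_lengths(taxonomy).median_mm,
        sigma_log=c["length_sigma_log"],
    )
    specimens = synthgen.generate_specimens(taxonomy, c["n_per_species"], allom, lengths, seed)
    frames: list[synthgen.FrameImage] = []
    for sp in specimens:
        frames.extend(
            synthgen.render_frames(
                sp,
                c["n_frames"],
                (c["image_height"], c["image_width"]),
                c["px_per_mm"],
                c["junk_rate"],
                seed,
                noise_sd=c["noise_sd"],
            )
        )
    records, ledger = synthgen.generate_otu_table(
        specimens,
        taxonomy,
        synthgen.ReadParams(read_threshold=cfg["assign"]["min_reads"]),
        synthgen.FailureRates(
            p_noreads=c["p_noreads"],
            p_mismatch=c["p_mismatch"],
            p_nospecies=c["p_nospecies"],
            p_repeat=c["p_repeat"],
        ),
        seed,
    )
    spdf = synthgen.specimens_frame(specimens, allom, seed)
    otudf = synthgen.otu_frame(records)
    morphdf = synthgen.morphology_frame(specimens)
    spdf.to_csv(out / "specimens.csv", index=False)
    otudf.to_csv(out / "otu_table.tsv", sep="\t", index=False)
    morphdf.to_csv(out / "morphology.csv", index=False)
    ledger.to_csv(out / "truth_ledger.csv", index=False)
    if c.get("write_images"):
        for f in frames:
            d = out / "frames" / f.specimen_id
            d.mkdir(parents=True, exist_ok=True)
            imfeat.write_png(f, d / f"{f.camera_id}_{f.frame_index}.png")
    ctx.update(
        taxonomy=taxonomy,
        specimens=specimens,
        frames=frames,
        specimens_df=spdf,
        otu_df=otudf,
        morphology_df=morphdf,
        truth_ledger=ledger,
    )


def _load_frames_from_disk(cfg: dict, out: Path) -> list[synthgen.FrameImage]:
    fdir = out / "frames"
    if not fdir.is_dir():
        raise DependencyError("stage 'features' needs frames in memory or under out_root/frames (run 'synthgen' with write_images)")
    ppm = cfg["synthgen"]["px_per_mm"]
    frames = []
    for spdir in sorted(fdir.iterdir()):
        for png in sorted(spdir.glob("*.png")):
            cam, idx = png.stem.split("_")
            frames.append(imfeat.read_png(png, spdir.name, int(cam), int(idx), ppm))
    return frames


def stage_features(cfg: dict, out: Path, ctx: dict) -> None:
    c = cfg["features"]
    frames = ctx.get("frames") or _load_frames_from_disk(cfg, out)
    ctx["frames"] = frames
    feats = [imfeat.compute_frame_features(f, c["threshold"]) for f in frames]
    feats = imfeat.flag_nontarget(
        feats,
        area_bounds_mm2=(c["area_min_mm2"], c["area_max_mm2"]),
        solidity_bounds=(c["solidity_min"], c["solidity_max"]),
    )
    fdf = imfeat.features_table(feats)
    fdf.to_csv(out / "features.csv", index=False)
    ctx["features_df"] = fdf


def _require(ctx: dict, out: Path, key: str, filename: str, stage: str, reader):
    if key in ctx:
        return ctx[key]
    path = out / filename
    if not path.exists():
        raise DependencyError(f"stage '{stage}' needs {filename} (run earlier stages first)")
    val = reader(path)
    ctx[key] = val
    return val


def stage_assign(cfg: dict, out: Path, ctx: dict) -> None:
    otu = _require(ctx, out, "otu_df", "otu_table.tsv", "assign", lambda p: pd.read_csv(p, sep="\t", keep_default_na=False))
    morph = _require(ctx, out, "morphology_df", "morphology.csv", "assign", pd.read_csv)
    results, summary = megassign.assign_all(otu, morph, cfg["assign"]["min_reads"])
    adf = megassign.assignments_table(results)
    adf.to_csv(out / "assignments.csv", index=False)
    (out / "summary.json").write_text(json.dumps(megassign.summary_dict(summary), indent=1))
    ctx["assignments_df"] = adf
    ctx["assignment_summary"] = summary


def stage_build(cfg: dict, out: Path, ctx: dict) -> None:
    spdf = _require(ctx, out, "specimens_df", "specimens.csv", "build", pd.read_csv)
    adf = _require(ctx, out, "assignments_df", "assignments.csv", "build", lambda p: pd.read_csv(p, keep_default_na=False))
    fdf = _require(ctx, out, "features_df", "features.csv", "build", pd.read_csv)
    dataset = datakit.curate(spdf, adf, fdf, cfg["build"]["min_specimens_per_species"])
    folds = datakit.make_folds(dataset, cfg["build"]["k"], int(cfg["seed"]))
    datakit.write_manifest(dataset, folds, out / "dataset_manifest.json")
    ctx["dataset"] = dataset
    ctx["folds"] = folds


def stage_models(cfg: dict, out: Path, ctx: dict) -> None:
    if "dataset" not in ctx or "folds" not in ctx:
        raise DependencyError("stage 'models' needs the curated dataset (run 'build' first)")
    if "frames" not in ctx:
        ctx["frames"] = _load_frames_from_disk(cfg, out)
    c = cfg["models"]
    dataset: datakit.CuratedDataset = ctx["dataset"]
    folds: datakit.FoldSplit = ctx["folds"]
    seed = int(cfg["seed"])
    G = datakit.compute_global_max_dim(dataset)
    clean = dataset.clean_frames()
    clean_keys = set(zip(clean["specimen_id"], clean["camera_id"], clean["frame_index"]))
    store = biomod.build_frame_store(ctx["frames"], clean_keys, G, c["input_size"], seed)

    species_of = dict(zip(dataset.specimens["specimen_id"], dataset.specimens["species"]))
    rank = c["classify"]["rank"]
    label_of = dict(
        zip(dataset.specimens["specimen_id"], dataset.specimens[rank])
    )
    mass_of = dict(zip(dataset.specimens["specimen_id"], dataset.specimens["mass_mg"]))

    classifiers, cls_preds = {}, []
    regressors, reg_preds = {}, []
    for i in range(folds.k):
        tr, va, te = folds.train(i), folds.validation(i), folds.test(i)
        ccfg = biomod.TrainConfig(
            task="classify",
            rank=rank,
            epochs=c["classify"]["epochs"],
            lr=c["classify"]["lr"],
            batch_size=c["classify"]["batch_size"],
            seed=seed + i,
            input_size=c["input_size"],
            channels=tuple(c["channels"]),
        )
        clf = biomod.train_classifier(store, label_of, tr, va, ccfg)
        classifiers[i] = clf
        cls_preds.append(biomod.predict_frames(clf, store, te, i, label_of))

        rcfg = biomod.TrainConfig(
            task="regress",
            target_transform=c["regress"]["target_transform"],
            epochs=c["regress"]["epochs"],
            lr=c["regress"]["lr"],
            batch_size=c["regress"]["batch_size"],
            seed=seed + 100 + i,
            input_size=c["input_size"],
            channels=tuple(c["channels"]),
        )
        reg = biomod.fine_tune_regressor(None, store, mass_of, tr, va, rcfg)
        regressors[i] = reg
        reg_preds.append(biomod.predict_frames(reg, store, te, i, mass_of))

    pre_preds, pre_models = [], {}
    pc = c.get("pretrained", {})
    if pc.get("enabled"):
        for i in pc.get("folds", range(folds.k)):
            tr, va, te = folds.train(i), folds.validation(i), folds.test(i)
            rcfg = biomod.TrainConfig(
                task="regress",
                target_transform=c["regress"]["target_transform"],
                frozen_base=bool(pc.get("frozen", False)),
                epochs=pc["epochs"],
                lr=c["regress"]["lr"],
                batch_size=c["regress"]["batch_size"],
                seed=seed + 200 + i,
                input_size=c["input_size"],
                channels=tuple(c["channels"]),
            )
            pre = biomod.fine_tune_regressor(classifiers[i], store, mass_of, tr, va, rcfg)
            pre_models[i] = pre
            pre_preds.append(biomod.predict_frames(pre, store, te, i, mass_of))

    # linear baselines on clean frames joined to specimen masses
    frames_tbl = clean.merge(dataset.specimens[["specimen_id", "mass_mg"]], on="specimen_id")
    linear_preds: dict[str, list[pd.DataFrame]] = {}
    linear_models: dict[str, list[biomod.LinearModelSpec]] = {}
    for pset in c["linear"]["predictor_sets"]:
        spec = biomod.LinearModelSpec(tuple(pset), c["linear"]["target_transform"])
        per_fold = []
        fitted = []
        for i in range(folds.k):
            model = biomod.fit_linear(frames_tbl, spec, folds.train(i))
            fitted.append(model)
            pr = biomod.predict_linear(model, frames_tbl[frames_tbl["specimen_id"].isin(folds.test(i))])
            pr["fold"] = i
            per_fold.append(pr)
        linear_preds[spec.name] = per_fold
        linear_models[spec.name] = fitted

    cls_df = pd.concat(cls_preds, ignore_index=True)
    reg_df = pd.concat(reg_preds, ignore_index=True)
    cls_df.to_csv(out / "predictions_classify.csv", index=False)
    reg_df.to_csv(out / "predictions_regress.csv", index=False)
    if pre_preds:
        pd.concat(pre_preds, ignore_index=True).to_csv(out / "predictions_regress_pretrained.csv", index=False)
    ctx.update(
        store=store,
        classifiers=classifiers,
        regressors=regressors,
        pretrained_regressors=pre_models,
        cls_fold_preds=cls_preds,
        reg_fold_preds=reg_preds,
        pre_fold_preds=pre_preds,
        linear_fold_preds=linear_preds,
        linear_models=linear_models,
        label_of=label_of,
        mass_of=mass_of,
    )


def stage_evaluate(cfg: dict, out: Path, ctx: dict) -> None:
    if "cls_fold_preds" not in ctx:
        raise DependencyError("stage 'evaluate' needs fold predictions (run 'models' first)")
    dataset: datakit.CuratedDataset = ctx["dataset"]
    folds: datakit.FoldSplit = ctx["folds"]
    all_ids = list(dataset.specimens["specimen_id"])

    cls_all = evalkit.combine_folds(ctx["cls_fold_preds"], all_ids)
    cls_report = evalkit.classification_metrics(cls_all)
    reg_all = evalkit.combine_folds(ctx["reg_fold_preds"], all_ids)
    reg_report = evalkit.regression_metrics(reg_all)
    reg_specimen = evalkit.regression_metrics(reg_all, per_specimen=True)

    linear_reports = {}
    for name, per_fold in ctx["linear_fold_preds"].items():
        combined = evalkit.combine_folds(per_fold, all_ids)
        linear_reports[name] = evalkit.regression_metrics(combined)

    # intercept-only reference: per-fold training-mean prediction
    mass_of = ctx["mass_of"]
    mean_rows = []
    for i in range(folds.k):
        mu = float(np.mean([mass_of[s] for s in folds.train(i)]))
        te = reg_all[reg_all["fold"] == i].copy()
        te["pred_mass_mg"] = mu
        mean_rows.append(te)
    mean_report = evalkit.regression_metrics(evalkit.combine_folds(mean_rows, all_ids))

    rank = cfg["models"]["classify"]["rank"]
    grouped = {}
    if rank == "species":
        for target_rank in ("genus", "family", "order"):
            grouped[target_rank] = evalkit.group_confusion(
                cls_all, dataset.taxonomy_map(target_rank)
            )

    metrics = {
        "classification": {
            "rank": rank,
            "weighted_precision": cls_report.weighted_precision,
            "weighted_recall": cls_report.weighted_recall,
            "weighted_f1": cls_report.weighted_f1,
            "n_frames": cls_report.n_frames,
            "grouped_weighted_f1": {r: g.weighted_f1 for r, g in grouped.items()},
        },
        "regression_cnn": vars(reg_report),
        "regression_cnn_per_specimen": vars(reg_specimen),
        "regression_mean_baseline": vars(mean_report),
        "regression_linear": {k: vars(v) for k, v in linear_reports.items()},
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
    cls_report.confusion_pct.to_csv(out / f"confusion_{rank}.csv")
    for r, g in grouped.items():
        g.confusion_pct.to_csv(out / f"confusion_{r}.csv")
    evalkit.regression_table({**linear_reports, "cnn": reg_report, "mean": mean_report}).to_csv(
        out / "regression_table.csv", index=False
    )
    ctx.update(
        cls_report=cls_report,
        reg_report=reg_report,
        reg_specimen_report=reg_specimen,
        mean_report=mean_report,
        linear_reports=linear_reports,
        grouped_reports=grouped,
        metrics=metrics,
    )


_STAGE_FUNCS = {
    "synthgen": stage_synthgen,
    "features": stage_features,
    "assign": stage_assign,
    "build": stage_build,
    "models": stage_models,
    "evaluate": stage_evaluate,
}


def run_pipeline(cfg: dict, stages: list[str] | None = None, out_root: str | Path | None = None) -> dict:
    """Run the requested stages in dependency order; returns the context.

    The context holds every in-memory artifact plus ``manifest`` (config
    hash, stage list, output paths). Identical config + seed give identical
    outputs.
    """
    requested = list(stages) if stages else list(STAGES)
    bad = [s for s in requested if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stages {bad}; valid: {STAGES}")
    ordered = [s for s in STAGES if s in requested]
    out = Path(out_root if out_root is not None else cfg.get("out_root", "runs/default"))
    out.mkdir(parents=True, exist_ok=True)
    ctx: dict = {}
    for s in ordered:
        _STAGE_FUNCS[s](cfg, out, ctx)
    ctx["manifest"] = {
        "config_hash": config_hash(cfg),
        "stages": ordered,
        "out_root": str(out),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "run_manifest.json").write_text(json.dumps(ctx["manifest"], indent=1))
    return ctx
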