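"""End-to-end orchestration: generate -> prep -> fit -> evaluate -> ensemble -> screen.

``run_pipeline`` executes the whole sex-stratified workflow from a single
:class:`~strokescreen.config.RunConfig` and (optionally) persists every
table and model to an output directory: discrimination/calibration
results per model and follow-up window, disagreement statistics, the
serialized meta-trees with Gini importances, and the screening report.
The master seed fans out to per-stage seeds by stable hashing of stage
names, so adding a stage never perturbs earlier stages' randomness and a
persisted manifest reproduces every number exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .cohort import generate_cohort, save_cohort
from .ensemble import (
    classify_high_risk,
    find_disagreements,
    fit_meta_tree,
    gini_importance,
    make_meta_labels,
)
from .exceptions import StrokeScreenError
from .metrics import auroc, bootstrap_ci, hosmer_lemeshow, nam_dagostino
from .models import fit_binary, fit_cox
from .prep import (
    exclusion_report,
    make_binary_dataset,
    make_survival_dataset,
    split_cohort,
)
from .screening import compare_approaches

logger = logging.getLogger("strokescreen")

SEXES = ("M", "F")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    return zlib.crc32(f"{stage}:{master_seed}".encode()) & 0x7FFFFFFF


def _auroc_with_ci(pred, labels, n_bootstrap, seed):
    ci = bootstrap_ci(auroc, (np.asarray(pred), np.asarray(labels)),
                      n_resamples=n_bootstrap, seed=seed)
    return ci


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the full workflow; returns a nested results dictionary.

    If ``outdir`` is given, artifacts are written there (CSV tables, JSON
    records, serialized models, and a run manifest).  Any stage failure
    aborts with the stage name; a partial manifest is persisted first.
    """
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stage_seeds": {},
        "completed_stages": [],
    }

    def persist_manifest() -> None:
        if out is not None:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    def stage(name: str):
        seed = stage_seed(config.seed, name)
        manifest["stage_seeds"][name] = seed
        logger.info("stage %s (seed %d)", name, seed)
        return seed

    try:
        results = _run_stages(config, out, manifest, stage)
    except StrokeScreenError:
        persist_manifest()
        raise
    persist_manifest()
    return results


def _run_stages(config: RunConfig, out, manifest, stage) -> dict:
    horizon = config.generator.admin_horizon
    tau = config.high_risk_threshold
    full_iv = (0.0, horizon)
    intervals = list(config.intervals)
    if full_iv not in intervals:  # the screening stage needs the full window
        intervals.insert(0, full_iv)

    # ---- generate -------------------------------------------------------
    gen_cfg = dataclasses.replace(config.generator, seed=stage("generate"))
    cohort, truth = generate_cohort(gen_cfg)
    if out is not None:
        save_cohort(cohort, truth, out / "cohort.csv", out / "ground_truth.csv")
    manifest["completed_stages"].append("generate")

    # ---- prep -----------------------------------------------------------
    split_seed = stage("split")
    roles = split_cohort(cohort, config.split_fractions, seed=split_seed)
    exclusions = exclusion_report(cohort, roles, horizon)
    if out is not None:
        pd.DataFrame({"id": cohort["id"], "role": roles}).to_csv(
            out / "split.csv", index=False
        )
        exclusions.to_json(out / "exclusions.json", orient="records", indent=2)
    manifest["completed_stages"].append("prep")

    results: dict = {"exclusions": exclusions, "per_sex": {}}
    boot_b = config.n_bootstrap

    for sex in SEXES:
        sub = cohort[cohort["sex"] == sex]
        sub_roles = roles[sub.index]
        sexdir = out / sex if out is not None else None
        if sexdir is not None:
            sexdir.mkdir(exist_ok=True)

        # ---- fit --------------------------------------------------------
        fit_seed = stage(f"fit[{sex}]")
        surv_train = make_survival_dataset(sub, sub_roles, "train", horizon)
        surv_val = make_survival_dataset(sub, sub_roles, "validation", horizon)
        cox = fit_cox(surv_train, penalty=config.cox_penalty)

        binary = {}
        for interval in intervals:
            train = make_binary_dataset(sub, sub_roles, "train", interval, horizon)
            binary[interval] = {
                "lr": fit_binary("lr", train, seed=fit_seed),
                "gbt": fit_binary("gbt", train, seed=fit_seed, **config.gbt_params),
            }
        manifest["completed_stages"].append(f"fit[{sex}]")

        # ---- evaluate ---------------------------------------------------
        eval_seed = stage(f"evaluate[{sex}]")
        disc_rows = []
        calib_tables = {}
        for interval in intervals:
            val = make_binary_dataset(sub, sub_roles, "validation", interval, horizon)
            t0, t1 = interval
            full = interval == (0.0, horizon)
            # Cox handles every window from one fit
            cox_pred = (
                cox.predict_risk(val.features, horizon)
                if full
                else cox.predict_interval_risk(val.features, t0, t1)
            )
            model_preds = {"cox": cox_pred}
            for name, model in binary[interval].items():
                model_preds[name] = model.predict_risk(val.features)
            for name, pred in model_preds.items():
                ci = _auroc_with_ci(pred, val.label, boot_b, eval_seed)
                if name == "cox" and full:
                    cal = nam_dagostino(
                        cox.predict_risk(surv_val.features, horizon),
                        surv_val.time, surv_val.event, horizon,
                    )
                    chi_ci = bootstrap_ci(
                        lambda p, t, e: nam_dagostino(p, t, e, horizon).chi2,
                        (cox.predict_risk(surv_val.features, horizon),
                         surv_val.time, surv_val.event),
                        n_resamples=boot_b, seed=eval_seed + 1,
                    )
                else:
                    cal = hosmer_lemeshow(pred, val.label)
                    chi_ci = bootstrap_ci(
                        lambda p, l: hosmer_lemeshow(p, l).chi2,
                        (pred, np.asarray(val.label)),
                        n_resamples=boot_b, seed=eval_seed + 1,
                    )
                if full:
                    calib_tables[name] = cal
                disc_rows.append(
                    {
                        "sex": sex,
                        "model": name,
                        "interval": f"{t0:g}-{t1:g}",
                        "auroc": ci.point,
                        "auroc_lower": ci.lower,
                        "auroc_upper": ci.upper,
                        "chi2": cal.chi2,
                        "chi2_lower": chi_ci.lower,
                        "chi2_upper": chi_ci.upper,
                        "chi2_statistic": cal.statistic,
                    }
                )
        discrimination = pd.DataFrame(disc_rows)
        if sexdir is not None:
            discrimination.to_csv(sexdir / "discrimination.csv", index=False)
            discrimination.to_json(sexdir / "discrimination.json", orient="records", indent=2)
            for name, cal in calib_tables.items():
                cal.table.to_csv(sexdir / f"calibration_{name}.csv", index=False)
        manifest["completed_stages"].append(f"evaluate[{sex}]")

        # ---- ensemble ---------------------------------------------------
        stage(f"ensemble[{sex}]")
        val = make_binary_dataset(sub, sub_roles, "validation", full_iv, horizon)
        gbt9 = binary[full_iv]["gbt"]
        cox_labels = classify_high_risk(cox.predict_risk(val.features, horizon), tau)
        gbt_labels = classify_high_risk(gbt9.predict_risk(val.features), tau)
        dis = find_disagreements(cox_labels, gbt_labels)
        meta_labels = make_meta_labels(
            cox_labels[dis], gbt_labels[dis], np.asarray(val.label)[dis]
        )
        tree = fit_meta_tree(
            val.features.iloc[dis],
            meta_labels,
            max_depth=config.meta_tree_max_depth,
            min_samples_leaf=config.meta_tree_min_samples_leaf,
        )
        importances = gini_importance(tree)
        disagreement = {
            "n_validation": len(val.label),
            "n_disagreements": int(len(dis)),
            "disagreement_fraction": float(len(dis) / len(val.label)),
            "meta_label_counts": {
                "cox": int(np.sum(meta_labels == "cox")),
                "gbt": int(np.sum(meta_labels == "gbt")),
            },
            "tree_training_accuracy": tree.training_accuracy(),
        }
        if sexdir is not None:
            tree.to_json(sexdir / "meta_tree.json")
            importances.rename("gini_importance").to_csv(sexdir / "gini_importance.csv")
            (sexdir / "disagreement.json").write_text(json.dumps(disagreement, indent=2))
        manifest["completed_stages"].append(f"ensemble[{sex}]")

        # ---- screen -----------------------------------------------------
        screen_seed = stage(f"screen[{sex}]")
        test = make_binary_dataset(sub, sub_roles, "test", full_iv, horizon)
        report = compare_approaches(
            cox, gbt9, tree, test.features, test.label,
            horizon=horizon, tau=tau, n_bootstrap=boot_b, seed=screen_seed,
        )
        if sexdir is not None:
            report.table.to_csv(sexdir / "screening_report.csv", index=False)
            report.kappa.to_csv(sexdir / "kappa.csv")
            (sexdir / "confusion.json").write_text(
                json.dumps({k: v.as_dict() for k, v in report.confusions.items()}, indent=2)
            )
        manifest["completed_stages"].append(f"screen[{sex}]")

        results["per_sex"][sex] = {
            "cox": cox,
            "binary_models": binary,
            "discrimination": discrimination,
            "calibration": calib_tables,
            "meta_tree": tree,
            "gini_importance": importances,
            "disagreement": disagreement,
            "screening": report,
        }

    results["cohort"] = cohort
    results["truth"] = truth
    results["roles"] = roles
    return results
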