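"""Shared fixtures: one large cohort and a multi-seed study.

The multi-seed study reruns the full modelling workflow (without
bootstrap intervals) on ten independently generated 40,000-person
cohorts, once per session; several tests assert median behavior over its
records rather than re-simulating.
"""

from __future__ import annotations

import numpy as np
import pytest

from strokescreen.config import GeneratorConfig
from strokescreen.cohort import generate_cohort
from strokescreen.ensemble import (
    classify_high_risk,
    ensemble_predict,
    find_disagreements,
    fit_meta_tree,
    make_meta_labels,
)
from strokescreen.metrics import auroc
from strokescreen.models import fit_binary, fit_cox
from strokescreen.prep import make_binary_dataset, make_survival_dataset, split_cohort
from strokescreen.screening import confusion, screening_metrics

INTERVALS = ((0.0, 9.0), (0.0, 3.0), (3.0, 6.0), (6.0, 9.0))
TAU = 0.10


@pytest.fixture(scope="session")
def big_cohort():
    """A 100,000-person default cohort with its ground truth."""
    config = GeneratorConfig(n_individuals=100_000, seed=7)
    cohort, truth = generate_cohort(config)
    return config, cohort, truth


def _run_one(seed: int, n: int = 40_000) -> list[dict]:
    config = GeneratorConfig(n_individuals=n, seed=1000 + seed)
    cohort, _ = generate_cohort(config)
    roles = split_cohort(cohort, seed=2000 + seed)
    records = []
    for sex in ("M", "F"):
        sub = cohort[cohort["sex"] == sex]
        sub_roles = roles[sub.index]
        cox = fit_cox(make_survival_dataset(sub, sub_roles, "train"))
        val = {}
        gbt = {}
        interval_auroc = {}
        for iv in INTERVALS:
            train = make_binary_dataset(sub, sub_roles, "train", iv)
            val[iv] = make_binary_dataset(sub, sub_roles, "validation", iv)
            gbt[iv] = fit_binary("gbt", train, seed=0)
            if iv != (0.0, 9.0):
                interval_auroc[iv] = {
                    "cox": auroc(
                        cox.predict_interval_risk(val[iv].features, *iv), val[iv].label
                    ),
                    "lr": auroc(
                        fit_binary("lr", train).predict_risk(val[iv].features),
                        val[iv].label,
                    ),
                    "gbt": auroc(gbt[iv].predict_risk(val[iv].features), val[iv].label),
                }
        full = (0.0, 9.0)
        cox_pred = cox.predict_risk(val[full].features, 9.0)
        gbt_pred = gbt[full].predict_risk(val[full].features)
        cox_labels = classify_high_risk(cox_pred, TAU)
        gbt_labels = classify_high_risk(gbt_pred, TAU)
        dis = find_disagreements(cox_labels, gbt_labels)
        meta = make_meta_labels(
            cox_labels[dis], gbt_labels[dis], np.asarray(val[full].label)[dis]
        )
        tree = fit_meta_tree(val[full].features.iloc[dis], meta)

        test = make_binary_dataset(sub, sub_roles, "test", full)
        cox_t = classify_high_risk(cox.predict_risk(test.features, 9.0), TAU)
        gbt_t = classify_high_risk(gbt[full].predict_risk(test.features), TAU)
        ens_t = ensemble_predict(cox_t, gbt_t, test.features, tree)
        outcomes = np.asarray(test.label, dtype=bool)
        records.append(
            {
                "seed": seed,
                "sex": sex,
                "cox_auroc": auroc(cox_pred, val[full].label),
                "gbt_auroc": auroc(gbt_pred, val[full].label),
                "interval_auroc": interval_auroc,
                "disagreement_fraction": len(dis) / len(val[full].label),
                "n_disagreements": len(dis),
                "cox_accuracy": screening_metrics(confusion(cox_t, outcomes))["accuracy"],
                "ensemble_accuracy": screening_metrics(confusion(ens_t, outcomes))["accuracy"],
                "override_fraction": float(np.mean(ens_t != cox_t)),
                "test_disagreement_fraction": float(np.mean(cox_t != gbt_t)),
                "_detail": {
                    "val_cox_labels": cox_labels,
                    "val_gbt_labels": gbt_labels,
                    "val_outcomes": np.asarray(val[full].label, dtype=bool),
                    "meta_labels": meta,
                    "tree": tree,
                    "test_cox_labels": cox_t,
                    "test_gbt_labels": gbt_t,
                    "test_ensemble_labels": ens_t,
                    "test_features": test.features,
                },
            }
        )
    return records


@pytest.fixture(scope="session")
def study():
    """Ten-seed, 40,000-person replication of the modelling workflow."""
    records = []
    for seed in range(10):
        records.extend(_run_one(seed))
    return records
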