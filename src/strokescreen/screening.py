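"""Test-set comparison of Cox-only, GBT-only, and ensemble screening.

Produces the summary-metric table (sensitivity, specificity, PPV, NPV,
accuracy, each with a 95% percentile-bootstrap CI), the pairwise Cohen's
kappa matrix between approaches, and the underlying confusion matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptyDatasetError, UndefinedMetricError
from .metrics import bootstrap_ci
from .ensemble import classify_high_risk, ensemble_predict, MetaTree

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")
APPROACHES = ("cox_only", "gbt_only", "ensemble")


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn}


def confusion(pred_labels, outcomes) -> ConfusionMatrix:
    """2x2 counts; positive = screened high-risk, outcome = stroke."""
    pred = np.asarray(pred_labels, dtype=bool)
    out = np.asarray(outcomes, dtype=bool)
    if pred.shape != out.shape:
        raise UndefinedMetricError("prediction and outcome vectors differ in length")
    return ConfusionMatrix(
        tp=int(np.sum(pred & out)),
        fp=int(np.sum(pred & ~out)),
        tn=int(np.sum(~pred & ~out)),
        fn=int(np.sum(~pred & out)),
    )


def screening_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV, NPV, accuracy from a confusion matrix.

    A metric with a zero denominator is reported as None (undefined), not 0.
    """

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
        "ppv": ratio(cm.tp, cm.tp + cm.fp),
        "npv": ratio(cm.tn, cm.tn + cm.fn),
        "accuracy": ratio(cm.tp + cm.tn, cm.n) if cm.n > 0 else None,
    }


def cohens_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two binary labelings.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginal products.
    If both raters are constant and identical (p_e = 1), kappa is 1 by
    convention.
    """
    a = np.asarray(labels_a, dtype=bool)
    b = np.asarray(labels_b, dtype=bool)
    if a.shape != b.shape:
        raise UndefinedMetricError("label vectors differ in length")
    n = len(a)
    if n == 0:
        raise UndefinedMetricError("kappa undefined on empty input")
    p_o = np.mean(a == b)
    pa, pb = a.mean(), b.mean()
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _metric_fn(name: str):
    def fn(pred, out):
        value = screening_metrics(confusion(pred, out))[name]
        if value is None:
            raise UndefinedMetricError(f"{name} undefined on this resample")
        return value

    return fn


@dataclass
class ScreeningReport:
    """Table-shaped comparison of the three screening approaches."""

    table: pd.DataFrame  # rows: approach x metric with point + CI columns
    kappa: pd.DataFrame  # pairwise approach agreement
    confusions: dict[str, ConfusionMatrix]
    labels: dict[str, np.ndarray]

    def approach_metrics(self, approach: str) -> dict[str, float | None]:
        sub = self.table[self.table["approach"] == approach]
        return dict(zip(sub["metric"], sub["value"]))


def compare_approaches(
    cox_model,
    gbt_model,
    meta_tree: MetaTree,
    test_features: pd.DataFrame,
    test_outcomes,
    horizon: float = 9.0,
    tau: float = 0.10,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ScreeningReport:
    """Evaluate Cox-only, GBT-only, and ensemble screening on one test set.

    ``test_outcomes`` are horizon stroke indicators on a
    censoring-excluded test set.  Each metric gets a percentile bootstrap
    CI over resampled test individuals; agreement between approaches is
    summarized by Cohen's kappa.
    """
    outcomes = np.asarray(test_outcomes, dtype=bool)
    if len(outcomes) == 0:
        raise EmptyDatasetError("empty test set")
    cox_labels = classify_high_risk(cox_model.predict_risk(test_features, horizon), tau)
    gbt_labels = classify_high_risk(gbt_model.predict_risk(test_features, horizon), tau)
    labels = {
        "cox_only": cox_labels,
        "gbt_only": gbt_labels,
        "ensemble": ensemble_predict(cox_labels, gbt_labels, test_features, meta_tree),
    }

    rows = []
    confusions = {}
    for approach, pred in labels.items():
        confusions[approach] = confusion(pred, outcomes)
        point = screening_metrics(confusions[approach])
        for i, name in enumerate(METRIC_NAMES):
            if point[name] is None:
                rows.append(
                    {"approach": approach, "metric": name, "value": None,
                     "ci_lower": None, "ci_upper": None, "undefined": True}
                )
                continue
            ci = bootstrap_ci(
                _metric_fn(name),
                (pred, outcomes),
                n_resamples=n_bootstrap,
                seed=seed + i,
            )
            rows.append(
                {
                    "approach": approach,
                    "metric": name,
                    "value": ci.point,
                    "ci_lower": ci.lower,
                    "ci_upper": ci.upper,
                    "undefined": False,
                }
            )
    kappa = pd.DataFrame(
        [
            [cohens_kappa(labels[a], labels[b]) for b in APPROACHES]
            for a in APPROACHES
        ],
        index=list(APPROACHES),
        columns=list(APPROACHES),
    )
    return ScreeningReport(
        table=pd.DataFrame(rows), kappa=kappa, confusions=confusions, labels=labels
    )
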