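"""Discrimination and calibration metrics with bootstrap intervals.

Calibration is assessed within deciles of predicted risk: the
Hosmer-Lemeshow chi-squared for binary outcomes, and the Nam-D'Agostino
chi-squared for censored survival outcomes, where the observed decile risk
is one minus the within-decile Kaplan-Meier survival at the horizon.
Lower chi-squared means better calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import UndefinedMetricError
from .prep import BinaryDataset, SurvivalDataset

_EPS = 1e-10


@dataclass
class BootstrapCI:
    """Percentile bootstrap interval."""

    point: float
    lower: float
    upper: float
    n_resamples: int
    seed: int
    n_redrawn: int = 0

    def as_dict(self) -> dict:
        return {
            "point": self.point,
            "lower": self.lower,
            "upper": self.upper,
            "n_resamples": self.n_resamples,
        }


@dataclass
class CalibrationResult:
    """Decile calibration table and its chi-squared statistic.

    ``table`` has one row per risk group: size ``n``, mean predicted risk
    ``p_mean``, observed risk ``obs`` (event proportion, or 1 - KM at the
    horizon for survival data), observed events ``O`` and expected events
    ``E``.  ``flags`` records epsilon-guarded or merged groups.
    """

    table: pd.DataFrame
    chi2: float
    df: int
    statistic: str
    flags: list[str] = field(default_factory=list)
    ci: BootstrapCI | None = None

    @property
    def n(self) -> int:
        return int(self.table["n"].sum())


def auroc(scores, labels) -> float:
    """Area under the ROC curve, i.e. Mann-Whitney concordance.

    Equals (#concordant pairs + 0.5 #tied pairs) / (n1 * n0) over all
    case/non-case pairs.  Raises if only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUROC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as half-credit
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def risk_groups(pred, n_groups: int = 10) -> np.ndarray:
    """Group index (0..G-1) per observation, by deciles of predicted risk.

    Assignment is by rank with ties broken by stable input order; group
    sizes differ by at most one and sum to n.
    """
    pred = np.asarray(pred, dtype=float)
    order = np.argsort(pred, kind="stable")
    groups = np.empty(len(pred), dtype=int)
    for g, chunk in enumerate(np.array_split(order, n_groups)):
        groups[chunk] = g
    return groups


def hosmer_lemeshow(pred, labels, n_groups: int = 10) -> CalibrationResult:
    """Hosmer-Lemeshow chi-squared over predicted-risk deciles.

    chi2 = sum_g (O_g - n_g p_g)^2 / (n_g p_g (1 - p_g)), df = G - 2.
    A group whose mean prediction is exactly 0 or 1 is epsilon-guarded
    and flagged rather than dropped.
    """
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(pred) < n_groups:
        raise UndefinedMetricError(
            f"need at least {n_groups} observations for {n_groups} groups"
        )
    groups = risk_groups(pred, n_groups)
    rows, flags = [], []
    chi2 = 0.0
    for g in range(n_groups):
        m = groups == g
        n_g = int(m.sum())
        p_bar = float(pred[m].mean())
        o_g = float(labels[m].sum())
        e_g = n_g * p_bar
        var = n_g * p_bar * (1.0 - p_bar)
        if var <= 0.0:
            flags.append(f"group {g}: mean prediction {p_bar} epsilon-guarded")
            var = max(var, n_g * _EPS)
        chi2 += (o_g - e_g) ** 2 / var
        rows.append(
            {"group": g, "n": n_g, "p_mean": p_bar, "obs": o_g / n_g, "O": o_g, "E": e_g}
        )
    return CalibrationResult(
        table=pd.DataFrame(rows),
        chi2=float(chi2),
        df=n_groups - 2,
        statistic="hosmer_lemeshow",
        flags=flags,
    )


def km_survival_at(time, event, horizon: float) -> tuple[float, float]:
    """Kaplan-Meier survival and its Greenwood variance at ``horizon``.

    Product-limit estimate over event times up to and including the
    horizon.  Returns (S, var).  Closed-form and vector-free so it stays
    cheap inside bootstrap loops; verified against lifelines in tests.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    # events sort before censorings at tied times (standard KM convention)
    order = np.lexsort((1 - event, time))
    t = time[order]
    e = event[order]
    n = len(t)
    mask = (e == 1) & (t <= horizon)
    if not mask.any():
        return 1.0, 0.0
    # at-risk count just before each ordered observation
    at_risk = n - np.arange(n)
    ev_t = t[mask]
    ev_risk = at_risk[mask]
    # collapse tied event times
    uniq, start = np.unique(ev_t, return_index=True)
    d = np.diff(np.append(start, len(ev_t)))
    n_j = ev_risk[start]
    frac = 1.0 - d / n_j
    s = float(np.prod(frac))
    with np.errstate(divide="ignore", invalid="ignore"):
        green = np.where(n_j > d, d / (n_j * (n_j - d)), np.inf)
    var = s * s * float(np.sum(green))
    return s, var


def nam_dagostino(
    pred,
    time,
    event,
    horizon: float,
    n_groups: int = 10,
    greenwood: bool = False,
) -> CalibrationResult:
    """Nam-D'Agostino calibration chi-squared for survival predictions.

    Groups are deciles of predicted horizon risk; observed group risk is
    1 - KM(horizon) within the group.  The statistic is
    sum_g n_g (o_g - p_g)^2 / (p_g (1 - p_g)), df = G - 1.  With
    ``greenwood=True`` the denominator is the Greenwood variance of the
    KM estimate instead.  A group with nobody under observation at the
    horizon (and events not exhausting it) is merged with its neighbor
    and flagged.  With no censoring before the horizon the statistic
    coincides with the Hosmer-Lemeshow form.
    """
    pred = np.asarray(pred, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(pred) < n_groups:
        raise UndefinedMetricError(
            f"need at least {n_groups} observations for {n_groups} groups"
        )
    groups = risk_groups(pred, n_groups)
    # merge groups with no one at risk at the horizon into their neighbor
    member_sets = [np.flatnonzero(groups == g) for g in range(n_groups)]
    flags: list[str] = []

    def _valid(idx: np.ndarray) -> bool:
        s, _ = km_survival_at(time[idx], event[idx], horizon)
        reaches = (time[idx] >= horizon).any()
        exhausted = s == 0.0
        return bool(reaches or exhausted)

    g = 0
    while g < len(member_sets):
        if _valid(member_sets[g]) or len(member_sets) == 1:
            g += 1
            continue
        j = g + 1 if g + 1 < len(member_sets) else g - 1
        flags.append(f"group {g}: no one at risk at horizon; merged with neighbor")
        member_sets[min(g, j)] = np.concatenate(
            [member_sets[min(g, j)], member_sets[max(g, j)]]
        )
        del member_sets[max(g, j)]
        g = 0  # re-scan after a merge

    rows = []
    chi2 = 0.0
    for g, idx in enumerate(member_sets):
        n_g = len(idx)
        p_bar = float(pred[idx].mean())
        s, var_km = km_survival_at(time[idx], event[idx], horizon)
        o_g = 1.0 - s
        if greenwood:
            var = var_km if var_km > 0 else _EPS
            chi2 += (o_g - p_bar) ** 2 / var
        else:
            denom = p_bar * (1.0 - p_bar)
            if denom <= 0.0:
                flags.append(f"group {g}: mean prediction {p_bar} epsilon-guarded")
                denom = _EPS
            chi2 += n_g * (o_g - p_bar) ** 2 / denom
        rows.append(
            {
                "group": g,
                "n": n_g,
                "p_mean": p_bar,
                "obs": o_g,
                "O": n_g * o_g,
                "E": n_g * p_bar,
            }
        )
    return CalibrationResult(
        table=pd.DataFrame(rows),
        chi2=float(chi2),
        df=len(member_sets) - 1,
        statistic="nam_dagostino_greenwood" if greenwood else "nam_dagostino",
        flags=flags,
    )


def calibration_table(model, dataset, horizon: float | None = None, n_groups: int = 10):
    """Observed-vs-predicted decile table for a fitted model on a dataset.

    Survival datasets use the Nam-D'Agostino machinery (KM observed risk);
    binary datasets use Hosmer-Lemeshow.  The returned table's
    (p_mean, obs) pairs are the plotting coordinates of a calibration
    curve, one point per decile.
    """
    if isinstance(dataset, SurvivalDataset):
        h = dataset.horizon if horizon is None else horizon
        pred = model.predict_risk(dataset.features, h)
        return nam_dagostino(pred, dataset.time, dataset.event, h, n_groups)
    if isinstance(dataset, BinaryDataset):
        h = dataset.interval[1] if horizon is None else horizon
        pred = model.predict_risk(dataset.features, h)
        return hosmer_lemeshow(pred, dataset.label, n_groups)
    raise TypeError(f"unsupported dataset type {type(dataset).__name__}")


def bootstrap_ci(
    metric_fn,
    data,
    n_resamples: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapCI:
    """Percentile bootstrap CI for ``metric_fn`` over resampled individuals.

    ``data`` is an array or tuple of aligned arrays; ``metric_fn`` receives
    the resampled arrays positionally.  Resamples on which the metric is
    undefined (e.g. a single-class AUROC draw) are redrawn and counted.
    Deterministic given ``seed``.
    """
    if not isinstance(data, tuple):
        data = (data,)
    arrays = [np.asarray(a) for a in data]
    n = len(arrays[0])
    point = float(metric_fn(*arrays))
    rng = np.random.default_rng(seed)
    stats = np.empty(n_resamples)
    redrawn = 0
    max_attempts = 100 * n_resamples
    b = attempts = 0
    while b < n_resamples:
        if attempts >= max_attempts:
            raise UndefinedMetricError(
                "metric undefined on too many bootstrap resamples"
            )
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            stats[b] = metric_fn(*(a[idx] for a in arrays))
        except UndefinedMetricError:
            redrawn += 1
            continue
        b += 1
    lower, upper = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return BootstrapCI(
        point=point,
        lower=float(lower),
        upper=float(upper),
        n_resamples=n_resamples,
        seed=seed,
        n_redrawn=redrawn,
    )
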