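"""Cohort partitioning and dataset construction.

Implements the censoring inclusion/exclusion asymmetry between survival
and binary-classification tasks: stroke-free individuals censored before
the 9-year horizon are kept in the survival *training* data (a Cox model
handles right-censoring) but excluded from binary training data and from
every validation/test set, because their event status over the full
horizon is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyDatasetError
from . import cohort as _cohort

ROLES = ("train", "validation", "test")
DEFAULT_FRACTIONS = (0.85, 0.1275, 0.0225)


@dataclass
class SurvivalDataset:
    """Right-censored time-to-event data for one role."""

    features: pd.DataFrame
    time: np.ndarray
    event: np.ndarray
    horizon: float
    ids: np.ndarray
    role: str

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class BinaryDataset:
    """Binary stroke-in-interval data for one role and window [t0, t1)."""

    features: pd.DataFrame
    label: np.ndarray
    interval: tuple[float, float]
    ids: np.ndarray
    role: str

    def __len__(self) -> int:
        return len(self.label)


def _largest_remainder_quotas(n: int, fractions) -> list[int]:
    """Integer quotas summing to n, by largest-remainder rounding.

    Remainder ties are broken in role order (train, validation, test).
    """
    exact = [f * n for f in fractions]
    quotas = [int(np.floor(e)) for e in exact]
    short = n - sum(quotas)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(exact[i] - quotas[i]), i)
    )
    for i in remainders[:short]:
        quotas[i] += 1
    return quotas


def split_cohort(
    cohort: pd.DataFrame,
    fractions=DEFAULT_FRACTIONS,
    seed: int = 0,
) -> pd.Series:
    """Assign each individual to train / validation / test, per sex.

    Within each sex the cohort is uniformly permuted and sliced into
    exact largest-remainder quotas, so the printed fractions (default
    85% / 12.75% / 2.25%) are reproduced exactly at any n.  Deterministic
    given ``seed``.

    Returns a Series of role labels indexed like ``cohort``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"split fractions {fractions} must sum to 1")
    if len(fractions) != 3:
        raise ConfigurationError("expected three split fractions")
    rng = np.random.default_rng(seed)
    roles = pd.Series(index=cohort.index, dtype=object, name="role")
    for sex in ("M", "F"):
        idx = cohort.index[cohort["sex"] == sex].to_numpy()
        if len(idx) == 0:
            continue
        perm = rng.permutation(len(idx))
        quotas = _largest_remainder_quotas(len(idx), fractions)
        start = 0
        for role, q in zip(ROLES, quotas):
            roles.loc[idx[perm[start : start + q]]] = role
            start += q
    return roles


def feature_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Model design matrix: risk factors as recorded, plus noise features.

    The area code enters as a single numeric feature, the way an
    administrative site label is recorded; codes carry no ordinal meaning,
    so a linear model can exploit area only through the coarse ``urban``
    indicator while a tree model can partition codes.  The same matrix
    feeds every model family and the meta-tree, so no model sees
    privileged features.
    """
    cols = {}
    for f in ("age", "sbp"):
        cols[f] = cohort[f].to_numpy(dtype=float)
    for f in _cohort.BINARY_FIELDS:
        if f in cohort.columns:
            cols[f] = cohort[f].to_numpy(dtype=float)
    cols["area"] = cohort["area"].to_numpy(dtype=float)
    for c in cohort.columns:
        if c.startswith("x") and c[1:].isdigit():
            cols[c] = cohort[c].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=cohort.index)


def _role_mask(assignment: pd.Series, role: str) -> pd.Series:
    if role not in ROLES:
        raise ConfigurationError(f"role must be one of {ROLES}, got {role!r}")
    return assignment == role


def make_survival_dataset(
    cohort: pd.DataFrame,
    assignment: pd.Series,
    role: str,
    horizon: float = 9.0,
) -> SurvivalDataset:
    """Time-to-event dataset for one role.

    Training keeps right-censored stroke-free individuals; validation and
    test drop stroke-free individuals followed for less than ``horizon``
    (their horizon outcome is unknown).  Times are truncated at the
    horizon, with events after it recoded as censoring.
    """
    sub = cohort[_role_mask(assignment, role)]
    if role != "train":
        keep = (sub["event"] == 1) | (sub["time"] >= horizon)
        sub = sub[keep]
    time = np.minimum(sub["time"].to_numpy(dtype=float), horizon)
    event = sub["event"].to_numpy(dtype=int) & (sub["time"].to_numpy() <= horizon)
    return SurvivalDataset(
        features=feature_matrix(sub),
        time=time,
        event=event.astype(int),
        horizon=horizon,
        ids=sub["id"].to_numpy(),
        role=role,
    )


def make_binary_dataset(
    cohort: pd.DataFrame,
    assignment: pd.Series,
    role: str,
    interval: tuple[float, float],
    horizon: float = 9.0,
) -> BinaryDataset:
    """Stroke-in-window classification dataset for a half-open [t0, t1).

    Included individuals are event-free and under observation at t0 and
    observed through the window (or until their stroke); label 1 means a
    stroke in [t0, t1).  Stroke-free individuals censored before the
    horizon never appear, in any role.
    """
    t0, t1 = interval
    if not (0.0 <= t0 < t1 <= horizon):
        raise ConfigurationError(f"interval [{t0}, {t1}) must lie within [0, {horizon}]")
    sub = cohort[_role_mask(assignment, role)]
    time = sub["time"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=int).astype(bool)
    # censored stroke-free before horizon: excluded everywhere
    observed = event | (time >= horizon)
    at_risk_t0 = time > t0  # event-free and uncensored when the window opens
    keep = observed & at_risk_t0
    label = (event & (time < t1))[keep].astype(int)
    sub = sub[keep]
    if sub.empty:
        raise EmptyDatasetError(
            f"no individuals remain for role={role!r}, interval [{t0}, {t1})"
        )
    return BinaryDataset(
        features=feature_matrix(sub),
        label=label,
        interval=(t0, t1),
        ids=sub["id"].to_numpy(),
        role=role,
    )


def exclusion_report(
    cohort: pd.DataFrame, assignment: pd.Series, horizon: float = 9.0
) -> pd.DataFrame:
    """Per sex x role bookkeeping of cohort sizes, events, and exclusions.

    ``n_excluded`` counts stroke-free individuals censored before the
    horizon — those dropped from validation/test sets and from binary
    training data.
    """
    rows = []
    for sex in ("M", "F"):
        for role in ROLES:
            sub = cohort[(cohort["sex"] == sex) & (assignment == role)]
            censored = (sub["event"] == 0) & (sub["time"] < horizon)
            rows.append(
                {
                    "sex": sex,
                    "role": role,
                    "n": len(sub),
                    "n_events": int(sub["event"].sum()),
                    "n_excluded_censored": int(censored.sum()),
                }
            )
    return pd.DataFrame(rows)
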