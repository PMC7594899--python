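"""Tumour treatment-response statistics.

Covers the endpoint analysis of a flank-tumour irradiation experiment:
calliper-based tumour volumes, per-group growth curves with SEM, product-limit
(Kaplan-Meier) survival estimation, and an exact Mann-Whitney rank-sum test
suitable for the small group sizes (n = 6 per arm) typical of such studies.

Survival semantics: an animal reaching its humane endpoint is an event; an
animal alive at study close (day 35) is censored.  Growth curves include an
animal's measurements only up to its event day — later group means describe
the surviving animals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "tumour_volume",
    "growth_summary",
    "km_estimate",
    "rank_sum_exact",
    "per_day_rank_sum",
    "load_treatment_csv",
    "RankSumResult",
]

RECORD_COLUMNS = ["animal_id", "group", "day", "width_mm", "length_mm", "event_day", "event"]


def tumour_volume(width_mm, length_mm):
    """Calliper tumour volume in mm^3: (W^2 x L) / 2."""
    w = np.asarray(width_mm, dtype=float)
    l = np.asarray(length_mm, dtype=float)
    if (w < 0).any() or (l < 0).any():
        raise ValueError("width and length must be >= 0")
    v = w * w * l / 2.0
    return float(v) if v.ndim == 0 else v


def load_treatment_csv(path) -> pd.DataFrame:
    """Read per-animal measurements and derive volume_mm3.

    Expected columns: ``animal_id,group,day,width_mm,length_mm,event_day,event``.
    """
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"treatment CSV missing columns: {sorted(missing)}")
    df = df.copy()
    if df["event"].dtype == object:  # "True"/"False" strings
        df["event"] = df["event"].astype(str).str.strip().str.lower().isin(("true", "1", "yes"))
    else:
        df["event"] = df["event"].astype(bool)
    df["volume_mm3"] = tumour_volume(df["width_mm"].to_numpy(), df["length_mm"].to_numpy())
    return df


def growth_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group, per-day mean tumour volume and SEM over surviving animals.

    Measurements after an animal's event day are excluded (the group mean at
    a given day describes the animals still on study that day).
    """
    df = records.copy()
    if "volume_mm3" not in df.columns:
        df["volume_mm3"] = tumour_volume(df["width_mm"].to_numpy(), df["length_mm"].to_numpy())
    df = df[df["day"] <= df["event_day"]]
    out = (
        df.groupby(["group", "day"])["volume_mm3"]
        .agg(mean_volume_mm3="mean", sem_mm3="sem", n="count")
        .reset_index()
    )
    out["sem_mm3"] = out["sem_mm3"].fillna(0.0)
    return out


def km_estimate(event_days, event_flags) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival curve from event/censoring days.

    Returns ``(times, survival)`` defining a right-continuous step function
    with S(0) = 1; ``event_flags`` True marks an event (humane endpoint),
    False a censored animal.
    """
    days = np.asarray(event_days, dtype=float)
    flags = np.asarray(event_flags, dtype=bool)
    if days.shape != flags.shape or days.size == 0:
        raise ValueError("event_days and event_flags must be equal-length, non-empty")
    kmf = KaplanMeierFitter()
    kmf.fit(days, event_observed=flags)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    return times, surv


@dataclass(frozen=True)
class RankSumResult:
    """Mann-Whitney U (for group A) and exact two-sided permutation p-value."""

    u_statistic: float
    p_value: float
    n_a: int
    n_b: int


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group A by direct pair counting; ties count one half."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def rank_sum_exact(group_a, group_b, max_total: int = 20) -> RankSumResult:
    """Exact two-sided Mann-Whitney test by full permutation enumeration.

    Enumerates every assignment of the pooled observations into groups of
    the observed sizes and compares each U statistic's distance from the
    null mean n_a*n_b/2 with the observed one.  Handles ties exactly (the
    permutation null conditions on the observed values).  Restricted to
    n_a + n_b <= ``max_total`` to keep enumeration tractable.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    if n_a + n_b > max_total:
        raise ValueError(f"exact enumeration limited to {max_total} total observations")
    pooled = np.concatenate([a, b])
    u_obs = _u_statistic(a, b)
    mu = n_a * n_b / 2.0
    d_obs = abs(u_obs - mu)
    total, extreme = 0, 0
    idx = np.arange(pooled.size)
    for combo in itertools.combinations(idx, n_a):
        sel = np.zeros(pooled.size, dtype=bool)
        sel[list(combo)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        total += 1
        if abs(u - mu) >= d_obs - 1e-12:
            extreme += 1
    return RankSumResult(u_statistic=u_obs, p_value=extreme / total, n_a=n_a, n_b=n_b)


def per_day_rank_sum(records: pd.DataFrame, group_a: str = "control",
                     group_b: str = "irradiated") -> pd.DataFrame:
    """Per-day exact Mann-Whitney comparison of tumour volumes between groups.

    Applied to each measurement day where both groups have surviving animals;
    this is a per-day comparison, not a summary-statistic (e.g. AUC) test.
    """
    df = records.copy()
    if "volume_mm3" not in df.columns:
        df["volume_mm3"] = tumour_volume(df["width_mm"].to_numpy(), df["length_mm"].to_numpy())
    df = df[df["day"] <= df["event_day"]]
    rows = []
    for day, sub in df.groupby("day"):
        va = sub.loc[sub["group"] == group_a, "volume_mm3"].to_numpy()
        vb = sub.loc[sub["group"] == group_b, "volume_mm3"].to_numpy()
        if va.size == 0 or vb.size == 0:
            continue
        res = rank_sum_exact(va, vb)
        rows.append({"day": day, "u_statistic": res.u_statistic, "p_value": res.p_value,
                     "n_a": res.n_a, "n_b": res.n_b})
    return pd.DataFrame(rows)
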