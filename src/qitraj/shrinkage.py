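"""Empirical-Bayes logit shrinkage of area proportions toward parent regions.

Each area's continuity-corrected logit is combined with the pooled logit of its
parent region through a precision weight, stabilizing proportions in areas with
few cases.  For an area j with r events among n cases:

    raw logit       SMA_j  = log((r + 0.5) / (n - r + 0.5))
    squared SE      s_j^2  = (n + 1)(n + 2) / (n (r + 1)(n - r + 1))
    region logit    Pref   = same corrected logit on region-pooled (r, n)
    between-area    t^2    = sample variance (denominator k-1) of the k member
                             raw logits in the region for that period
    weight          w_j    = (1/s_j^2) / (1/s_j^2 + 1/t^2) = t^2 / (t^2 + s_j^2)
    shrunk logit    SMA_j* = w_j SMA_j + (1 - w_j) Pref

The algebraic form t^2/(t^2 + s^2) is used so that t^2 = 0 gives w = 0 (full
shrinkage to the region) without dividing by zero.  A singleton region (one
member with cases) has no between-area variance; its area keeps its raw logit
(w = 1).  Natural logarithm throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import DomainError
from .synthetic import validate_panel

ZERO_CASE_POLICIES = ("region-fill", "drop-area", "error")

RESULT_COLUMNS = [
    "area_id", "region_id", "period", "r", "n",
    "raw_logit", "se2", "region_logit", "t2", "weight",
    "shrunk_logit", "shrunk_prop", "policy",
]


def raw_logit(r, n):
    """Continuity-corrected logit log((r+0.5)/(n-r+0.5)) of r events in n cases."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(r < 0) or np.any(n < 0) or np.any(r > n):
        raise DomainError("raw_logit requires 0 <= r <= n")
    out = np.log((r + 0.5) / (n - r + 0.5))
    return out if out.ndim else float(out)


def logit_se_squared(r, n):
    """Squared standard error of the corrected logit: (n+1)(n+2)/(n(r+1)(n-r+1)).

    Undefined at n = 0 (the denominator contains n); the caller's zero-case
    policy decides what happens to such cells.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(r < 0) or np.any(r > n):
        raise DomainError("logit_se_squared requires 0 <= r <= n")
    if np.any(n < 1):
        raise DomainError("logit_se_squared requires n >= 1 (apply the zero-case policy first)")
    out = (n + 1.0) * (n + 2.0) / (n * (r + 1.0) * (n - r + 1.0))
    return out if out.ndim else float(out)


def region_logit(pooled_r, pooled_n):
    """Corrected logit of the region-pooled counts (same formula as raw_logit)."""
    return raw_logit(pooled_r, pooled_n)


def inter_area_variance(member_logits):
    """Between-area variance t² of the member raw logits, denominator k-1.

    Returns ``None`` for a single member (the formula needs k >= 2; the caller
    applies the no-shrink policy).  Raises on empty input.
    """
    m = np.asarray(member_logits, dtype=float)
    if m.size == 0:
        raise DomainError("inter_area_variance requires at least one member logit")
    if m.size == 1:
        return None
    mean = m.sum() / m.size
    return float(((m - mean) ** 2).sum() / (m.size - 1))


def shrinkage_weight(s2, t2):
    """Precision weight w = t²/(t²+s²) on the area's own estimate; in [0, 1]."""
    s2 = np.asarray(s2, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(s2 <= 0):
        raise DomainError("shrinkage_weight requires s2 > 0")
    if np.any(t2 < 0):
        raise DomainError("shrinkage_weight requires t2 >= 0")
    out = t2 / (t2 + s2)
    return out if out.ndim else float(out)


def shrink_area(raw, region, w):
    """Convex combination w·raw + (1-w)·region of the two logits."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise DomainError("shrink_area requires 0 <= w <= 1")
    out = w * np.asarray(raw, dtype=float) + (1.0 - w) * np.asarray(region, dtype=float)
    return out if out.ndim else float(out)


def shrink_panel(panel: pd.DataFrame, zero_case: str = "region-fill") -> pd.DataFrame:
    """Apply the shrinkage estimator to every (area, period) cell of a panel.

    t² and the pooled region logit are computed per (region, period) from the
    member areas; pooled counts include the index area itself.

    Parameters
    ----------
    panel : long frame with columns ``area_id, region_id, period, r, n``.
    zero_case : what to do with cells where n = 0 (s² undefined):
        ``"region-fill"`` — keep the cell with weight 0 (shrunk value = region
        pooled logit, its natural limit); ``"drop-area"`` — remove every area
        with any zero-case cell; ``"error"`` — raise, listing the cells.

    Returns
    -------
    DataFrame with one row per remaining (area, period):
    ``area_id, region_id, period, r, n, raw_logit, se2, region_logit, t2,
    weight, shrunk_logit, shrunk_prop, policy``.  ``policy`` flags rows where a
    fallback was applied ("zero-case-region-fill" or "singleton-no-shrink").
    """
    if zero_case not in ZERO_CASE_POLICIES:
        raise DomainError(f"unknown zero-case policy {zero_case!r}; choose from {ZERO_CASE_POLICIES}")
    validate_panel(panel)
    df = panel[["area_id", "region_id", "period", "r", "n"]].copy()

    zero_mask = df["n"] == 0
    if zero_mask.any():
        if zero_case == "error":
            cells = df.loc[zero_mask, ["area_id", "period"]].itertuples(index=False)
            raise DomainError(
                "zero-case cells (n=0) with policy 'error': "
                + ", ".join(f"({a}, {p})" for a, p in list(cells)[:10])
            )
        if zero_case == "drop-area":
            bad_areas = df.loc[zero_mask, "area_id"].unique()
            df = df[~df["area_id"].isin(bad_areas)].copy()
            zero_mask = df["n"] == 0

    df = df.sort_values(["region_id", "period", "area_id"], kind="mergesort").reset_index(drop=True)
    r = df["r"].to_numpy(dtype=float)
    n = df["n"].to_numpy(dtype=float)
    zero = n == 0

    df["raw_logit"] = np.log((r + 0.5) / (n - r + 0.5))
    se2 = np.full(len(df), np.nan)
    se2[~zero] = (n[~zero] + 1.0) * (n[~zero] + 2.0) / (
        n[~zero] * (r[~zero] + 1.0) * (n[~zero] - r[~zero] + 1.0)
    )
    df["se2"] = se2

    grp = df.groupby(["region_id", "period"], sort=False)
    pooled_r = grp["r"].transform("sum").to_numpy(dtype=float)
    pooled_n = grp["n"].transform("sum").to_numpy(dtype=float)
    df["region_logit"] = np.log((pooled_r + 0.5) / (pooled_n - pooled_r + 0.5))

    # t² from members with cases only; a zero-case cell carries no own estimate
    m = df["raw_logit"].where(~zero)  # NaN where n = 0
    mgrp = m.groupby([df["region_id"], df["period"]], sort=False)
    member_k = mgrp.transform("count").to_numpy()
    member_mean = mgrp.transform("sum").to_numpy() / np.where(member_k > 0, member_k, np.nan)
    ssq = ((m - member_mean) ** 2).groupby([df["region_id"], df["period"]], sort=False).transform("sum").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        df["t2"] = np.where(member_k > 1, ssq / (member_k - 1), np.nan)

    singleton = (~zero) & (member_k == 1)
    regular = (~zero) & ~singleton

    weight = np.zeros(len(df))
    t2 = df["t2"].to_numpy()
    weight[regular] = t2[regular] / (t2[regular] + se2[regular])
    weight[singleton] = 1.0
    weight[zero] = 0.0
    df["weight"] = weight

    df["shrunk_logit"] = weight * df["raw_logit"].to_numpy() + (1.0 - weight) * df["region_logit"].to_numpy()
    # a zero-case cell takes the region value exactly (its raw logit is vacuous)
    df.loc[zero, "shrunk_logit"] = df.loc[zero, "region_logit"]
    df["shrunk_prop"] = expit(df["shrunk_logit"].to_numpy())

    policy = np.full(len(df), "", dtype=object)
    policy[zero] = "zero-case-region-fill"
    policy[singleton] = "singleton-no-shrink"
    df["policy"] = policy

    out = df.sort_values(["area_id", "period"], kind="mergesort").reset_index(drop=True)
    return out[RESULT_COLUMNS]
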