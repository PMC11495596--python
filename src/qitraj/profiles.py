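"""Post-hoc characterization of trajectory groups by area-level covariates.

Groups are profiled on modal (hard) class assignment: for every covariate the
per-group median and quartiles are reported, and for covariates observed in
two survey years the per-group medians and their difference.  Quartiles use
linear interpolation between order statistics (the "type 7" convention), so
{1, 2, 3} gives median 2 and quartiles (1.5, 2.5).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UnmatchedAreasError
from .synthetic import TREND_COVARIATES
from .trajectory import GroupAssignment

logger = logging.getLogger(__name__)


def _aligned_covariates(assignment: GroupAssignment, covariates: pd.DataFrame) -> pd.DataFrame:
    if assignment.area_ids is None:
        raise ConfigurationError("assignment carries no area_ids; fit with area_ids or attach them")
    cov = covariates.set_index("area_id")
    missing = [a for a in assignment.area_ids if a not in cov.index]
    if missing:
        raise UnmatchedAreasError(missing)
    out = cov.loc[list(assignment.area_ids)].copy()
    out["group"] = np.asarray(assignment.modal)
    return out


def _group_label(assignment: GroupAssignment, g: int) -> str:
    if assignment.names is not None:
        return assignment.names[g]
    return str(g)


def profile_groups(
    assignment: GroupAssignment,
    covariates: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-group covariate medians and quartiles under modal assignment.

    Parameters
    ----------
    assignment : fitted group assignment with ``area_ids`` attached.
    covariates : one row per area; must contain ``area_id`` plus numeric columns.
    columns : covariates to profile; default, every numeric column.

    Returns
    -------
    Long DataFrame with one row per (group, covariate):
    ``group, group_name, covariate, count, median, q1, q3``.
    Areas with a missing value are excluded per-covariate (count reflects the
    values used; exclusions are logged).

    Raises
    ------
    UnmatchedAreasError
        if an assigned area has no covariate row.
    """
    data = _aligned_covariates(assignment, covariates)
    if columns is None:
        columns = [c for c in data.columns if c != "group" and pd.api.types.is_numeric_dtype(data[c])]
    K = assignment.posterior.shape[1]
    rows = []
    for g in range(K):
        sub = data[data["group"] == g]
        for c in columns:
            vals = sub[c].dropna().to_numpy(dtype=float)
            n_excluded = len(sub) - len(vals)
            if n_excluded:
                logger.info("group %d covariate %s: %d areas excluded for missing values", g, c, n_excluded)
            if vals.size == 0:
                med = q1 = q3 = np.nan
            else:
                q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])  # type-7 interpolation
            rows.append({
                "group": g, "group_name": _group_label(assignment, g), "covariate": c,
                "count": int(vals.size), "median": med, "q1": q1, "q3": q3,
            })
    return pd.DataFrame(rows)


def trend_table(
    assignment: GroupAssignment,
    covariates: pd.DataFrame,
    variables: Sequence[str] = TREND_COVARIATES,
    years: tuple[int, int] = (2014, 2018),
) -> pd.DataFrame:
    """Per-group medians of two-survey-year covariates and their change.

    For each variable ``v`` the columns ``v_<year1>`` and ``v_<year2>`` must be
    present.  Returns one row per (group, variable) with the two medians and
    ``difference`` = median(year2) − median(year1).  Groups with no members
    yield a row with null medians and count 0.
    """
    y1, y2 = years
    for v in variables:
        for col in (f"{v}_{y1}", f"{v}_{y2}"):
            if col not in covariates.columns:
                raise ConfigurationError(f"covariates lack survey-year column '{col}'")
    data = _aligned_covariates(assignment, covariates)
    K = assignment.posterior.shape[1]
    rows = []
    for g in range(K):
        sub = data[data["group"] == g]
        for v in variables:
            m1 = sub[f"{v}_{y1}"].median() if len(sub) else np.nan
            m2 = sub[f"{v}_{y2}"].median() if len(sub) else np.nan
            rows.append({
                "group": g, "group_name": _group_label(assignment, g), "covariate": v,
                "count": int(len(sub)),
                f"median_{y1}": m1, f"median_{y2}": m2,
                "difference": m2 - m1 if len(sub) else np.nan,
            })
    return pd.DataFrame(rows)
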