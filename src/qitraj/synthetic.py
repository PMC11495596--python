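"""Synthetic claims-like panel generator.

The real analysis runs on an access-restricted national claims database, so
every downstream stage is exercised on simulated data that carries the latent
structure the method assumes: areas nested in parent regions, a small number of
latent trajectory groups with smooth mean curves on the logit scale, binomial
event counts on Poisson case denominators, and area covariates whose locations
shift with the latent group.

The generator is fully seeded: an identical :class:`~qitraj.config.SimulationConfig`
(including ``seed``) reproduces the output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .config import SimulationConfig
from .errors import MissingCellsError

PANEL_COLUMNS = ["area_id", "region_id", "period", "fiscal_year", "r", "n", "population"]

#: base covariate distributions: name -> (family, location, scale)
#: families: "lognormal" (location is log-median), "truncnorm0" (normal truncated at 0),
#: "clipped01" (normal clipped into [0, 1]).
_COVARIATE_SPECS = {
    "prop_aged_65plus": ("clipped01", 0.30, 0.05),
    "population_density": ("lognormal", np.log(300.0), 1.0),
    "unemployment_rate": ("clipped01", 0.045, 0.01),
    "taxable_income_per_capita": ("lognormal", np.log(1.3e6), 0.25),
    "physicians_per_100k": ("truncnorm0", 240.0, 60.0),
    "cardiologists_per_100k": ("truncnorm0", 10.0, 4.0),
    "dentists_per_100k": ("truncnorm0", 80.0, 20.0),
    "pharmacists_per_100k": ("truncnorm0", 170.0, 40.0),
    "general_hospitals_per_100k": ("truncnorm0", 7.0, 2.5),
    "emergency_hospitals_per_100k": ("truncnorm0", 3.5, 1.5),
    "general_hospital_beds_per_100k": ("truncnorm0", 1200.0, 300.0),
}

#: covariates observed in two survey years (2014 and 2018) for trend analysis
TREND_COVARIATES = [
    "physicians_per_100k",
    "cardiologists_per_100k",
    "general_hospitals_per_100k",
    "emergency_hospitals_per_100k",
]


@dataclass(frozen=True)
class TruthTable:
    """Latent ground truth kept aside for recovery testing.

    ``assignments`` maps ``area_id`` to the true group index; ``group_logit_curves``
    holds the true per-group mean logit per period; ``group_probs`` the mixing shares.
    """

    assignments: pd.DataFrame  # columns: area_id, group
    group_logit_curves: np.ndarray  # (K, T)
    group_probs: np.ndarray  # (K,)

    def labels_for(self, area_ids) -> np.ndarray:
        lookup = self.assignments.set_index("area_id")["group"]
        return lookup.loc[list(area_ids)].to_numpy()


def _draw_covariate(rng, family, loc, scale, size):
    if family == "lognormal":
        return np.exp(rng.normal(loc, scale, size=size))
    if family == "truncnorm0":
        a = (0.0 - loc) / scale  # truncate at zero
        return truncnorm.rvs(a, np.inf, loc=loc, scale=scale, size=size, random_state=rng)
    if family == "clipped01":
        return np.clip(rng.normal(loc, scale, size=size), 0.0, 1.0)
    raise ValueError(family)


def simulate_panel(config: SimulationConfig) -> tuple[pd.DataFrame, TruthTable, pd.DataFrame]:
    """Simulate an area-period panel, its latent truth, and area covariates.

    Returns
    -------
    panel : DataFrame with columns ``area_id, region_id, period, fiscal_year, r, n, population``,
        one row per (area, period).  ``r`` is the event count (primary PCI within one day
        of admission), ``n`` the case count (AMI hospitalizations).
    truth : :class:`TruthTable`
    covariates : DataFrame with one row per area.
    """
    rng = np.random.default_rng(config.seed)
    K = config.n_groups
    n_areas, n_regions, n_periods = config.n_areas, config.n_regions, config.n_periods

    area_ids = np.array([f"A{i:04d}" for i in range(1, n_areas + 1)])
    # first one area per region, remaining areas assigned uniformly
    region_idx = np.concatenate(
        [np.arange(n_regions), rng.integers(0, n_regions, size=n_areas - n_regions)]
    )
    region_ids = np.array([f"R{j + 1:02d}" for j in region_idx])

    groups = rng.choice(K, size=n_areas, p=np.asarray(config.group_probs))
    area_effects = rng.normal(0.0, config.area_random_sd, size=n_areas)
    population = np.exp(rng.normal(config.population_log_mean, config.population_log_sd, size=n_areas))

    curves = np.asarray(config.group_logit_curves, dtype=float)  # (K, T)
    true_logit = curves[groups] + area_effects[:, None]  # (areas, T)
    true_prop = expit(true_logit)

    lam = population * config.case_rate_per_100k / 100_000.0
    n_it = rng.poisson(lam[:, None], size=(n_areas, n_periods))
    r_it = rng.binomial(n_it, true_prop)

    panel = pd.DataFrame(
        {
            "area_id": np.repeat(area_ids, n_periods),
            "region_id": np.repeat(region_ids, n_periods),
            "period": np.tile(np.arange(n_periods), n_areas),
            "fiscal_year": np.tile(config.start_year + np.arange(n_periods), n_areas),
            "r": r_it.ravel(),
            "n": n_it.ravel(),
            "population": np.repeat(population, n_periods),
        }
    )

    truth = TruthTable(
        assignments=pd.DataFrame({"area_id": area_ids, "group": groups}),
        group_logit_curves=curves,
        group_probs=np.asarray(config.group_probs),
    )

    covariates = _simulate_covariates(rng, config, area_ids, groups, population)
    return panel, truth, covariates


def _simulate_covariates(rng, config, area_ids, groups, population) -> pd.DataFrame:
    n_areas = len(area_ids)
    cov = {"area_id": area_ids, "population": population}
    for name, (family, loc, scale) in _COVARIATE_SPECS.items():
        base = _draw_covariate(rng, family, loc, scale, n_areas)
        shifts = config.covariate_effects.get(name)
        if shifts is not None:
            # group shifts act multiplicatively (additive on the log scale)
            base = base * np.exp(np.asarray(shifts)[groups])
        cov[name] = base
    # two survey years around the base value for the trend covariates:
    # a small downward tilt in 2014 and upward in 2018 mimics slow supply growth
    for name in TREND_COVARIATES:
        base = cov[name]
        cov[f"{name}_2014"] = base * np.exp(rng.normal(-0.02, 0.02, size=n_areas))
        cov[f"{name}_2018"] = base * np.exp(rng.normal(0.02, 0.02, size=n_areas))
    return pd.DataFrame(cov)


def validate_panel(panel: pd.DataFrame) -> None:
    """Check the structural invariants of an area-period panel.

    Raises ``ValueError`` on: r out of [0, n], duplicated (area, period) cells,
    or an area mapped to more than one region.
    """
    required = {"area_id", "region_id", "period", "r", "n"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns: {sorted(missing)}")
    if (panel["r"] < 0).any() or (panel["n"] < 0).any() or (panel["r"] > panel["n"]).any():
        bad = panel[(panel["r"] < 0) | (panel["n"] < 0) | (panel["r"] > panel["n"])]
        raise ValueError(f"panel violates 0 <= r <= n on {len(bad)} rows")
    dup = panel.duplicated(subset=["area_id", "period"])
    if dup.any():
        raise ValueError(f"duplicated (area_id, period) cells: {panel.loc[dup, ['area_id', 'period']].values.tolist()[:5]}")
    nreg = panel.groupby("area_id")["region_id"].nunique()
    if (nreg > 1).any():
        raise ValueError(f"areas mapped to multiple regions: {list(nreg[nreg > 1].index[:5])}")


def panel_to_matrix(
    panel: pd.DataFrame, values
) -> tuple[np.ndarray, list, np.ndarray]:
    """Pivot per-record values into an (areas × periods) trajectory matrix.

    Parameters
    ----------
    panel : panel frame (defines the (area, period) grid).
    values : sequence aligned with ``panel`` rows, e.g. shrunk proportions.

    Returns
    -------
    Y : float matrix, rows sorted by ``area_id``, columns sorted by ``period``.
    area_ids : row labels.
    periods : column labels.

    Raises
    ------
    MissingCellsError
        if any (area, period) cell of the full grid is absent.
    """
    frame = panel[["area_id", "period"]].copy()
    frame["value"] = np.asarray(values, dtype=float)
    wide = frame.pivot(index="area_id", columns="period", values="value").sort_index()
    wide = wide[sorted(wide.columns)]
    if wide.isna().any().any():
        cells = [
            (area, period)
            for area, row in wide.iterrows()
            for period, v in row.items()
            if pd.isna(v)
        ]
        raise MissingCellsError(cells)
    return wide.to_numpy(), list(wide.index), np.asarray(sorted(wide.columns))
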