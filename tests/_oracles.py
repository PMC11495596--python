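"""Independent reference implementations used as test oracles.

Everything here is deliberately written as slow, scalar, loop-based Python
directly from the formula definitions, independent of the package's vectorized
code paths.
"""

import math

import numpy as np
import pandas as pd


def scalar_shrink(panel: pd.DataFrame) -> pd.DataFrame:
    """Loop-based shrinkage of a panel, composing the scalar formulas cell by cell.

    Implements: corrected logit log((r+0.5)/(n-r+0.5)); s² = (n+1)(n+2)/(n(r+1)(n-r+1));
    pooled-region logit; t² = Σ(m_j - M)²/(k-1) over members with n >= 1;
    w = t²/(t²+s²); shrunk = w·raw + (1-w)·pooled.  Zero-case cells take the
    region value with w = 0; a singleton member keeps its raw logit (w = 1).
    """
    rows = []
    for (region, period), g in panel.groupby(["region_id", "period"]):
        members = [(r, n) for r, n in zip(g["r"], g["n"]) if n > 0]
        m = [math.log((r + 0.5) / (n - r + 0.5)) for r, n in members]
        k = len(m)
        pooled_r, pooled_n = float(g["r"].sum()), float(g["n"].sum())
        pref = math.log((pooled_r + 0.5) / (pooled_n - pooled_r + 0.5))
        if k > 1:
            M = sum(m) / k
            t2 = sum((x - M) ** 2 for x in m) / (k - 1)
        else:
            t2 = None
        for _, row in g.iterrows():
            r, n = float(row["r"]), float(row["n"])
            raw = math.log((r + 0.5) / (n - r + 0.5))
            if n == 0:
                s2, w, shrunk = math.nan, 0.0, pref
            elif k == 1:
                s2 = (n + 1) * (n + 2) / (n * (r + 1) * (n - r + 1))
                w, shrunk = 1.0, raw
            else:
                s2 = (n + 1) * (n + 2) / (n * (r + 1) * (n - r + 1))
                w = t2 / (t2 + s2)
                shrunk = w * raw + (1 - w) * pref
            rows.append({
                "area_id": row["area_id"], "period": period,
                "raw_logit": raw, "se2": s2, "region_logit": pref,
                "t2": math.nan if t2 is None else t2, "weight": w,
                "shrunk_logit": shrunk,
                "shrunk_prop": 1.0 / (1.0 + math.exp(-shrunk)),
            })
    return pd.DataFrame(rows).sort_values(["area_id", "period"]).reset_index(drop=True)


def random_panel(rng, n_regions=3, n_areas=8, n_periods=3, max_n=300, zero_frac=0.0):
    """A small random but valid area-period panel for property tests."""
    region_idx = np.concatenate([
        np.arange(n_regions), rng.integers(0, n_regions, size=n_areas - n_regions)
    ])
    base_p = rng.uniform(0.05, 0.95, size=n_areas)
    recs = []
    for i in range(n_areas):
        for t in range(n_periods):
            n = int(rng.integers(1, max_n))
            if zero_frac and rng.random() < zero_frac:
                n = 0
            r = int(rng.binomial(n, base_p[i])) if n else 0
            recs.append({
                "area_id": f"A{i:03d}", "region_id": f"R{region_idx[i]:02d}",
                "period": t, "r": r, "n": n,
            })
    return pd.DataFrame(recs)


def pooled_ols_beta(Y, B):
    """Least-squares coefficients of the pooled trajectories on basis B."""
    ybar = np.asarray(Y).mean(axis=0)
    beta, *_ = np.linalg.lstsq(B, ybar, rcond=None)
    return beta
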