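"""Shadow-resistance ranking of vegetation indices.

Each acquisition time defines a shadow scenario ("case").  Within a case,
every VI is scored by the best R^2 of least-squares curve fits of
chlorophyll on the VI (calibration direction, family {linear, quadratic});
per-case ranks (1 = highest R^2) are summed across cases, and the smallest
summed rank marks the VI most resistant to shadow variation.  Also provides
baseline-referenced rate-of-change curves and the disturbance-sensitivity
sweep.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spectral_indices import BAND_NAMES, compute_all, vi_names

__all__ = [
    "fit_vi_cab_r2",
    "rank_vis",
    "ranking_from_lut",
    "rate_of_change",
    "disturbance_sensitivity",
    "FIT_FAMILIES",
]

FIT_FAMILIES = ("linear", "quadratic")

_FAMILY_DEGREE = {"linear": 1, "quadratic": 2}


def fit_vi_cab_r2(vi, cab, families=FIT_FAMILIES) -> float:
    """Best R^2 over the fit-family set of cab regressed on the VI.

    Non-finite pairs are dropped.  Zero variance in cab returns 0 by
    convention.  Requires >= 3 finite pairs.
    """
    vi = np.asarray(vi, float)
    cab = np.asarray(cab, float)
    mask = np.isfinite(vi) & np.isfinite(cab)
    vi, cab = vi[mask], cab[mask]
    if vi.size < 3:
        raise ValueError(f"need >= 3 finite pairs, got {vi.size}")
    ss_tot = float(np.sum((cab - cab.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    if np.ptp(vi) == 0.0:
        return 0.0
    best = 0.0
    for family in families:
        deg = _FAMILY_DEGREE[family]
        coeffs = np.polyfit(vi, cab, deg)
        resid = cab - np.polyval(coeffs, vi)
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        best = max(best, r2)
    return float(np.clip(best, 0.0, 1.0))


def rank_vis(r2_table: pd.DataFrame) -> pd.DataFrame:
    """Rank VIs per case and sum ranks across cases.

    Parameters
    ----------
    r2_table : DataFrame
        Index = VI names (registry order defines tie-breaking), columns =
        case identifiers, values = R^2.  Missing cells are an error.

    Returns
    -------
    DataFrame indexed by VI, sorted ascending by ``summed_rank``, with
    ``r2_<case>`` and ``rank_<case>`` columns plus ``summed_rank``.
    """
    if r2_table.isna().any().any():
        bad = r2_table.isna().stack()
        bad = list(bad[bad].index[:5])
        raise ValueError(f"R^2 table has missing cells, e.g. {bad}")

    out = pd.DataFrame(index=r2_table.index)
    summed = np.zeros(len(r2_table), dtype=int)
    for case in r2_table.columns:
        r2 = r2_table[case].to_numpy(float)
        # stable argsort on descending R^2 -> ties keep registry order
        order = np.argsort(-r2, kind="stable")
        ranks = np.empty(len(r2), dtype=int)
        ranks[order] = np.arange(1, len(r2) + 1)
        out[f"r2_{case}"] = r2
        out[f"rank_{case}"] = ranks
        summed += ranks
    out["summed_rank"] = summed
    return out.sort_values("summed_rank", kind="stable")


def ranking_from_lut(
    lut: pd.DataFrame,
    names=None,
    target: str = "cab",
    case_column: str = "time",
    families=FIT_FAMILIES,
) -> pd.DataFrame:
    """Compute the per-case R^2 table from a LUT and rank it.

    Each distinct value of ``case_column`` (the acquisition time) is one
    shadow scenario; all parameter levels at that time are pooled.
    """
    names = list(names) if names is not None else vi_names()
    vis = compute_all(lut[list(BAND_NAMES)])
    cases = sorted(lut[case_column].unique())
    r2 = pd.DataFrame(index=names, columns=cases, dtype=float)
    for case in cases:
        mask = (lut[case_column] == case).to_numpy()
        y = lut[target].to_numpy(float)[mask]
        for name in names:
            r2.loc[name, case] = fit_vi_cab_r2(
                vis[name].to_numpy()[mask], y, families=families
            )
    return rank_vis(r2)


def ranked_names(ranking: pd.DataFrame) -> list[str]:
    """VI names in ascending summed-rank order."""
    return list(ranking.index)


def rate_of_change(series: pd.Series, reference) -> pd.Series:
    """Absolute relative change of a per-time series vs a reference time.

    delta_t = |x_t - x_ref| / |x_ref|; the reference entry is exactly 0.
    """
    if reference not in series.index:
        raise KeyError(f"reference time {reference!r} not in series")
    x_ref = float(series.loc[reference])
    if x_ref == 0.0:
        raise ZeroDivisionError("reference value must be nonzero")
    out = (series.astype(float) - x_ref).abs() / abs(x_ref)
    out.loc[reference] = 0.0
    return out


def disturbance_sensitivity(
    lut: pd.DataFrame,
    target: str = "cab",
    nuisances=("lai", "shadow_fraction"),
    names=None,
    families=FIT_FAMILIES,
) -> pd.DataFrame:
    """Per-VI R^2 against the target and each nuisance factor.

    Returns a DataFrame indexed by VI with one ``r2_<factor>`` column per
    factor, sorted by descending target sensitivity.
    """
    names = list(names) if names is not None else vi_names()
    factors = [target, *nuisances]
    for f in factors:
        if lut[f].nunique() < 2:
            raise ValueError(f"factor {f!r} is degenerate (single level) in the LUT")
    vis = compute_all(lut[list(BAND_NAMES)])
    out = pd.DataFrame(index=names)
    for f in factors:
        y = lut[f].to_numpy(float)
        out[f"r2_{f}"] = [
            fit_vi_cab_r2(vis[n].to_numpy(), y, families=families) for n in names
        ]
    return out.sort_values(f"r2_{target}", ascending=False, kind="stable")


def render_ranking_report(ranking: pd.DataFrame) -> str:
    """Plain-text table mirroring the per-case R^2/rank layout."""
    cases = [c[3:] for c in ranking.columns if c.startswith("r2_")]
    lines = []
    header = ["VI".ljust(12)]
    for c in cases:
        header.append(f"case {c}".rjust(14))
    header.append("summed".rjust(8))
    lines.append("".join(header))
    for vi, row in ranking.iterrows():
        cells = [str(vi).ljust(12)]
        for c in cases:
            cells.append(f"{row[f'r2_{c}']:.3f} ({int(row[f'rank_{c}']):>2d})".rjust(14))
        cells.append(f"{int(row['summed_rank']):>8d}")
        lines.append("".join(cells))
    return "\n".join(lines)
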