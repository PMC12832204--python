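"""Variance decomposition of standardized dispersal metrics.

The four continuous dispersal metrics (mean distance, dispersion,
convex-hull area, density) are centred and scaled within standardization
groups, stacked into one long response, and decomposed with a three-way
ANOVA: fixed effects for decay scenario, metric and hour since release
(all treated as unordered factors), all two- and three-way interactions,
and the release event as a blocking factor (a fixed-effect stand-in for a
random intercept — deterministic and closed-form).  Type III sums of
squares are computed under sum-to-zero contrasts and effect sizes are
reported as partial eta^2 = SS_term / (SS_term + SS_residual).
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = ["standardize", "decompose_variance", "STANDARD_METRICS"]

#: metric columns entering the decomposition (the four continuous metrics)
STANDARD_METRICS = ("mean_distance_km", "dispersion_km2",
                    "hull_area_km2", "density_per_km2")

_GROUPINGS = {
    "metric-site": ("metric", "site"),
    "metric-site-scenario": ("metric", "site", "scenario"),
}


def standardize(metrics: pd.DataFrame, grouping: str = "metric-site",
                metric_columns=STANDARD_METRICS) -> pd.DataFrame:
    """Long table of z-scored metric values.

    ``grouping`` selects the standardization cells: ``"metric-site"``
    (default; scenario differences in level survive standardization) or
    ``"metric-site-scenario"`` (each scenario centred separately, which
    removes scenario main effects by construction).  Missing sentinel
    values propagate as missing.  Constant groups become all-zero and are
    flagged in the ``constant_group`` column; groups need at least two
    non-missing values.  The grouping choice is recorded in
    ``result.attrs["grouping"]``.
    """
    if grouping not in _GROUPINGS:
        raise ValueError(f"grouping must be one of {sorted(_GROUPINGS)}")
    id_cols = [c for c in ("site", "scenario", "event_id", "hour")
               if c in metrics.columns]
    if "site" not in id_cols:
        metrics = metrics.assign(site="all")
        id_cols = ["site"] + id_cols
    long = metrics.melt(id_vars=id_cols,
                        value_vars=[c for c in metric_columns
                                    if c in metrics.columns],
                        var_name="metric", value_name="value")

    keys = list(_GROUPINGS[grouping])
    zs, flags = [], []
    for _, grp in long.groupby(keys, sort=False):
        vals = grp["value"]
        ok = vals.notna()
        if ok.sum() < 2:
            raise ValueError(
                f"standardization group {dict(zip(keys, grp[keys].iloc[0]))} "
                "has fewer than 2 non-missing values"
            )
        sd = vals[ok].std(ddof=1)
        if sd == 0:
            z = pd.Series(np.where(ok, 0.0, np.nan), index=grp.index)
            flag = True
            warnings.warn("constant standardization group; z set to 0",
                          stacklevel=2)
        else:
            z = (vals - vals[ok].mean()) / sd
            flag = False
        zs.append(z)
        flags.append(pd.Series(flag, index=grp.index))
    long["z_value"] = pd.concat(zs).sort_index()
    long["constant_group"] = pd.concat(flags).sort_index()
    long.attrs["grouping"] = grouping
    return long


def _check_cells(table: pd.DataFrame, factors) -> None:
    counts = table.groupby(list(factors), observed=True).size()
    levels = [table[f].unique() for f in factors]
    full = set(itertools.product(*levels))
    present = set(counts.index if len(factors) > 1
                  else [(i,) for i in counts.index])
    empty = sorted(full - present)
    if empty:
        raise ValueError(
            f"design has empty {' x '.join(factors)} cells: {empty[:10]}"
            + (" ..." if len(empty) > 10 else "")
        )


def decompose_variance(table: pd.DataFrame,
                       include_event: bool = True) -> pd.DataFrame:
    """Type III ANOVA of the standardized long table.

    ``table`` is the output of :func:`standardize` (columns scenario,
    metric, hour, event_id, z_value).  Returns one row per model term
    (scenario, metric, hour, their interactions, optionally event, and
    the residual) with sum of squares, degrees of freedom, F, p and
    partial eta^2.
    """
    needed = {"scenario", "metric", "hour", "z_value"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"long table missing columns: {sorted(missing)}")
    data = table.dropna(subset=["z_value"]).copy()
    data["hour"] = data["hour"].astype(str)  # hour as unordered factor

    # factors with a single level carry no variance and are dropped (this
    # also lets a one-factor table collapse to a plain one-way ANOVA)
    factors = [f for f in ("scenario", "metric", "hour")
               if data[f].nunique() > 1]
    if not factors:
        raise ValueError("no factor with more than one level")
    _check_cells(data, tuple(factors))

    formula = "z_value ~ " + " * ".join(f"C({f}, Sum)" for f in factors)
    if include_event:
        if "event_id" not in data.columns:
            raise ValueError("long table has no event_id column")
        formula += " + C(event_id, Sum)"
    model = smf.ols(formula, data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # F of aliased terms can warn
        aov = anova_lm(model, typ=3)

    pretty = {
        "C(scenario, Sum)": "scenario",
        "C(metric, Sum)": "metric",
        "C(hour, Sum)": "hour",
        "C(scenario, Sum):C(metric, Sum)": "scenario:metric",
        "C(scenario, Sum):C(hour, Sum)": "scenario:hour",
        "C(metric, Sum):C(hour, Sum)": "metric:hour",
        "C(scenario, Sum):C(metric, Sum):C(hour, Sum)": "scenario:metric:hour",
        "C(event_id, Sum)": "event",
        "Residual": "Residual",
    }
    ss_res = float(aov.loc["Residual", "sum_sq"])
    rows = []
    for term, r in aov.iterrows():
        if term == "Intercept":
            continue
        name = pretty.get(term, term)
        ss = float(r["sum_sq"])
        eta = ss / (ss + ss_res) if name != "Residual" else np.nan
        rows.append({
            "term": name,
            "sum_sq": ss,
            "df": float(r["df"]),
            "F": float(r["F"]) if np.isfinite(r.get("F", np.nan)) else np.nan,
            "p": float(r["PR(>F)"]) if np.isfinite(r.get("PR(>F)", np.nan))
                 else np.nan,
            "partial_eta2": eta,
        })
    return pd.DataFrame(rows)
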