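"""Conditioned summary statistics over simulated community tables.

These operations reduce a simulation table (one row per community) to the
headline quantities of the analysis: conditioned six-number summaries of the
physical parameters, the distribution of communities over lysogeny ranges,
per-rank contributions to the lysogen pool, the fraction of communities with
virus-to-microbe ratio below a threshold, and a binned-median trend smoother
used for lysogeny-vs-density curves.

Threshold semantics: named conditioning thresholds such as "lysogeny >= 25%"
are inclusive; the qualifying floor "lysogeny above 1%" is strict.
Quantiles use linear interpolation between order statistics (the numpy
default), so summary tables are well-defined to the printed precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DomainError, UsageError

__all__ = [
    "SUMMARY_FEATURES",
    "condition_on_lysogeny",
    "summary_table",
    "lysogeny_bins",
    "rank_contributions",
    "vmr_fraction_below",
    "binned_smoother",
]

#: Default features summarized in the conditioned tables, with display units.
SUMMARY_FEATURES = {
    "bacteria_conc": "cells/ml",
    "phage_conc": "phages/ml",
    "adsorption_rate": "ml/h",
    "commitment_time": "h",
    "coi_rank1": "-",
    "coi_rank2": "-",
    "coi_rank3": "-",
}

_SUMMARY_COLUMNS = ["Min", "1st Qu", "Median", "Mean", "3rd Qu", "Max"]


def condition_on_lysogeny(results: pd.DataFrame, threshold_percent: float,
                          strict: bool = False) -> pd.DataFrame:
    """Communities whose percent lysogeny reaches the threshold.

    Inclusive (>=) by default; ``strict=True`` applies the strict ``>`` used
    for the 1%-lysogeny qualifying floor.
    """
    if not (0 <= threshold_percent <= 100):
        raise UsageError(f"threshold must be in [0, 100], got {threshold_percent!r}")
    lys = results["percent_lysogeny"]
    mask = lys > threshold_percent if strict else lys >= threshold_percent
    return results.loc[mask]


def summary_table(subset: pd.DataFrame, features=None) -> pd.DataFrame:
    """Six-number summary (Min, 1st Qu, Median, Mean, 3rd Qu, Max) per feature.

    ``features`` defaults to the physical parameters and top-3 rank COI
    columns present in the subset.  Rows are features; a ``Unit`` column is
    prepended when the feature has a known unit.
    """
    if len(subset) == 0:
        raise DomainError("cannot summarize an empty community subset")
    if features is None:
        features = [f for f in SUMMARY_FEATURES if f in subset.columns]
    missing = [f for f in features if f not in subset.columns]
    if missing:
        raise UsageError(f"features not in table: {missing}")
    rows = {}
    for feat in features:
        v = subset[feat].to_numpy(dtype=float)
        rows[feat] = [v.min(), np.quantile(v, 0.25), np.quantile(v, 0.5),
                      v.mean(), np.quantile(v, 0.75), v.max()]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=_SUMMARY_COLUMNS)
    table.insert(0, "Unit", [SUMMARY_FEATURES.get(f, "") for f in features])
    table.index.name = "Feature"
    return table


def lysogeny_bins(results: pd.DataFrame, edges) -> pd.DataFrame:
    """Fraction of communities in each percent-lysogeny range.

    Bins are left-closed and right-open except the last, which is closed so
    100% falls in the top bin.  Edges must be strictly increasing and span
    the data's [0, 100] domain.  Fractions sum to 1.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise UsageError("edges must be a strictly increasing 1-D array")
    lys = results["percent_lysogeny"].to_numpy(dtype=float)
    if np.any(lys < edges[0]) or np.any(lys > edges[-1]):
        raise UsageError("edges do not span the observed lysogeny values")
    counts, _ = np.histogram(lys, bins=edges)  # numpy closes the last bin
    fractions = counts / counts.sum()
    labels = [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-2], edges[1:-1])]
    labels.append(f"[{edges[-2]:g}, {edges[-1]:g}]")
    return pd.DataFrame({"bin": labels, "lower": edges[:-1], "upper": edges[1:],
                         "fraction": fractions})


def rank_contributions(results: pd.DataFrame, top_k: int = 3,
                       floor_percent: float = 1.0) -> pd.DataFrame:
    """Mean and SD of each leading rank's share of the lysogen pool.

    Averages the per-community contribution fractions (as percent) over
    communities with lysogeny strictly above ``floor_percent``.
    """
    cols = [f"contribution_rank{r}" for r in range(1, top_k + 1)]
    missing = [c for c in cols if c not in results.columns]
    if missing:
        raise UsageError(f"missing contribution columns: {missing}")
    qualifying = condition_on_lysogeny(results, floor_percent, strict=True)
    if len(qualifying) == 0:
        raise DomainError(f"no communities with lysogeny above {floor_percent}%")
    data = qualifying[cols].to_numpy(dtype=float) * 100.0
    return pd.DataFrame({
        "rank": np.arange(1, top_k + 1),
        "mean_percent": data.mean(axis=0),
        "sd_percent": data.std(axis=0, ddof=1) if len(qualifying) > 1
        else np.zeros(top_k),
    })


def vmr_fraction_below(results: pd.DataFrame, vmr_threshold: float = 1.0,
                       lysogeny_floor: float = 1.0) -> float:
    """Percent of qualifying communities with virus-to-microbe ratio below
    ``vmr_threshold``.

    Qualifying means percent lysogeny strictly above ``lysogeny_floor``.
    """
    qualifying = condition_on_lysogeny(results, lysogeny_floor, strict=True)
    if len(qualifying) == 0:
        raise DomainError(f"no communities with lysogeny above {lysogeny_floor}%")
    below = (qualifying["vmr"] < vmr_threshold).sum()
    return 100.0 * below / len(qualifying)


def binned_smoother(x_values, y_values, n_bins: int = 20) -> pd.DataFrame:
    """Binned-median trend of y against x, binned in log10 x.

    A simple, assumption-light stand-in for a smooth regression curve:
    splits log10(x) into ``n_bins`` equal-width bins and reports the median
    y and the bin-center x per nonempty bin.  Bin centers are monotone by
    construction.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size != y.size:
        raise UsageError("x_values and y_values must have equal length")
    if x.size < n_bins:
        raise DomainError(f"need at least {n_bins} points, got {x.size}")
    if np.any(x <= 0):
        raise DomainError("x_values must be strictly positive for log10 binning")
    logx = np.log10(x)
    edges = np.linspace(logx.min(), logx.max(), n_bins + 1)
    nudged = edges.copy()
    nudged[-1] = np.nextafter(nudged[-1], np.inf)  # include the max point
    idx = np.digitize(logx, nudged) - 1
    centers, medians, counts = [], [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        centers.append(10.0 ** ((edges[b] + edges[b + 1]) / 2))
        medians.append(float(np.median(y[mask])))
        counts.append(int(mask.sum()))
    return pd.DataFrame({"x_center": centers, "y_median": medians, "n": counts})
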