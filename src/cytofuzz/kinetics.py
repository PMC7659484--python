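"""Exponential growth-rate estimation and per-dataset normalization.

A culture in exponential phase satisfies c(t) = c1 * exp(G * (t - t1)), so a
single rate per condition follows from two bracketing timepoints:

    G = ln(c2 / c1) / (t2 - t1)        [hr^-1]

The rate window starts on day 3 (the post-thaw lag is excluded) and ends on
day 7, unless a dataset hit confluence by day 6 and declined afterwards, in
which case day 6 is the endpoint for that dataset.  Because replicate
experiments differ by a batch scale factor, rates are normalized to the mean
rate of their own dataset before any cross-condition comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import validate_design

HOURS_PER_DAY = 24.0
RATE_COLUMNS = ("dataset", "key", "rate_per_hr", "normalized_rate", "endpoint_day")


def growth_rate(c1, c2, t1, t2):
    """Exponential rate G = ln(c2/c1)/(t2-t1) in the units of 1/t.

    Concentrations must be positive and t2 > t1; a declining culture yields a
    negative rate.  Accepts scalars or arrays.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(c1 <= 0) or np.any(c2 <= 0):
        raise ValueError("concentrations must be > 0")
    if np.any(t2 <= t1):
        raise ValueError("t2 must exceed t1")
    out = np.log(c2 / c1) / (t2 - t1)
    return float(out) if out.ndim == 0 else out


def select_endpoint(day6: float, day7: float, density_threshold: float = 1.0e6) -> int:
    """Endpoint day for one condition: 6 if confluent by day 6 and declining.

    Day 6 is chosen when the day-6 concentration reaches ``density_threshold``
    (default 1e6 cells/mL) and the day-7 concentration is lower; otherwise 7.
    """
    for name, value in (("day6", day6), ("day7", day7)):
        if value is None or not np.isfinite(value):
            raise ValueError(f"missing {name} concentration")
    return 6 if (day6 >= density_threshold and day7 < day6) else 7


def compute_growth_table(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    density_threshold: float = 1.0e6,
    truncate_fraction: float = 0.25,
    start_day: int = 3,
) -> pd.DataFrame:
    """One growth rate per (dataset, condition) from a well-count table.

    Replicate wells are averaged (arithmetic mean of concentrations) at the
    start day and at the endpoint day before applying the two-point rate
    formula with t in hours.  The endpoint rule is applied per dataset: the
    whole dataset is truncated to day 6 when at least ``truncate_fraction`` of
    its conditions are confluent-and-declining, else day 7 is used.
    """
    validate_design(design)
    known = set(design["key"])
    present = set(counts["key"])
    unknown = sorted(present - known)
    if unknown:
        raise ValueError(f"conditions absent from design: {unknown}")

    # mean concentration per (dataset, key, day)
    means = (
        counts.groupby(["dataset", "key", "day"], sort=False)["cells_per_ml"]
        .mean()
        .unstack("day")
    )

    rows = []
    for ds, sub in means.groupby(level="dataset", sort=True):
        sub = sub.droplevel("dataset")
        for day in (start_day, 6, 7):
            if day not in sub.columns or sub[day].isna().any():
                missing = (
                    sub.index.tolist()
                    if day not in sub.columns
                    else sub.index[sub[day].isna()].tolist()
                )
                raise ValueError(
                    f"dataset {ds}: missing day-{day} counts for {missing}"
                )
        flags = [
            select_endpoint(row[6], row[7], density_threshold)
            for _, row in sub.iterrows()
        ]
        endpoint = 6 if np.mean([f == 6 for f in flags]) >= truncate_fraction else 7
        rates = growth_rate(
            sub[start_day].to_numpy(),
            sub[endpoint].to_numpy(),
            HOURS_PER_DAY * start_day,
            HOURS_PER_DAY * endpoint,
        )
        for key, rate in zip(sub.index, np.atleast_1d(rates)):
            rows.append((ds, key, float(rate), endpoint))
    return pd.DataFrame(rows, columns=["dataset", "key", "rate_per_hr", "endpoint_day"])


def normalize_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each rate by the mean rate of its dataset.

    Within every dataset the normalized rates then average to exactly 1.
    Requires at least two finite rates per dataset and a nonzero dataset mean.
    """
    out = table.reset_index(drop=True).copy()
    normalized = np.empty(len(out))
    for ds, sub in out.groupby("dataset"):
        rates = sub["rate_per_hr"].to_numpy(dtype=float)
        if np.sum(np.isfinite(rates)) < 2:
            raise ValueError(f"dataset {ds}: need >= 2 finite rates to normalize")
        mean = float(np.mean(rates))
        if mean == 0:
            raise ValueError(f"dataset {ds}: mean rate is 0, normalization undefined")
        normalized[sub.index] = rates / mean
    out["normalized_rate"] = normalized
    return out


def write_growth_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_growth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"key": str}, float_precision="round_trip")
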