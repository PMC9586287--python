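"""NOAEL record filtering and NOAEL-based points of departure.

In vivo study databases mix effect levels (NOAEL, LOAEL, BMD...), units and
exposure routes. Only rows with type "NOAEL", units "mg/kg-day" and an oral
route enter the point-of-departure calculation. With at least 20 retained
values the PoD is the empirical 5th percentile (type-2 estimator, i.e. the
discontinuous inverse CDF with averaging at discontinuities, as in R's
``quantile(type = 2)``); with fewer it is the lowest available value.

``quantile_type2`` defined here is the single quantile implementation used
everywhere in the package (AC50 5th percentiles, population Css 95th
percentiles, median MoEs).
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np

from .records import PodType, PoDResult

#: below this many NOAEL records the PoD falls back to the minimum value
MIN_RECORDS_FOR_PERCENTILE = 20
NOAEL_PERCENTILE = 0.05


def quantile_type2(values: Sequence[float], p: float) -> float:
    """Empirical quantile, discontinuous CDF with averaging at jumps.

    With the n values sorted, let j = floor(n*p) and g = n*p - j. Returns
    the average of order statistics j and j+1 when g == 0 (p falls exactly
    on a CDF discontinuity), otherwise order statistic j+1 (1-based).
    Matches R's ``quantile(type = 2)``.

    Parameters
    ----------
    values : sequence of float
        Non-empty sample.
    p : float
        Probability in the open interval (0, 1).
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("quantile_type2 requires a non-empty sample")
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    x = np.sort(x)
    n = x.size
    np_ = n * p
    j = math.floor(np_)
    g = np_ - j
    # guard against floating error when n*p is an exact integer
    if abs(g) < 1e-9 * max(1.0, np_):
        g = 0.0
    if j <= 0:
        return float(x[0])
    if j >= n:
        return float(x[-1])
    if g == 0.0:
        return float(0.5 * (x[j - 1] + x[j]))
    return float(x[j])


def _norm(s: object) -> str:
    return str(s).strip().lower()


def filter_records(
    records: "object",
    *,
    type_value: str = "NOAEL",
    units_value: str = "mg/kg-day",
    route_value: str = "oral",
):
    """Keep rows with the required type, units and exposure route.

    ``records`` is a pandas DataFrame with columns ``type``, ``units`` and
    ``route`` (plus ``chem_id`` and ``value``). Matching is case-insensitive
    and whitespace-trimmed; semantics are otherwise the exact string filter.
    """
    import pandas as pd

    df = pd.DataFrame(records)
    if df.empty:
        return df
    mask = (
        (df["type"].map(_norm) == _norm(type_value))
        & (df["units"].map(_norm) == _norm(units_value))
        & (df["route"].map(_norm) == _norm(route_value))
    )
    return df.loc[mask].reset_index(drop=True)


def noael_pod(values: Sequence[float], chem_id: str = "") -> PoDResult:
    """NOAEL point of departure for one chemical.

    5th percentile (type 2) of the retained NOAELs when at least
    ``MIN_RECORDS_FOR_PERCENTILE`` values are available, otherwise the
    lowest available value.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("noael_pod requires at least one NOAEL value")
    n = len(vals)
    if n >= MIN_RECORDS_FOR_PERCENTILE:
        pod = quantile_type2(vals, NOAEL_PERCENTILE)
        note = f"5th percentile (type 2) of {n} NOAELs"
    else:
        pod = min(vals)
        note = f"minimum of {n} NOAELs (<{MIN_RECORDS_FOR_PERCENTILE} records)"
    return PoDResult(
        chem_id=chem_id,
        pod_type=PodType.NOAEL,
        pod=pod,
        n_records_used=n,
        method_note=note,
    )


def noael_pods_from_table(records) -> tuple[list[PoDResult], list[str]]:
    """Per-chemical PoDs from a raw NOAEL table.

    Filters the table, groups by ``chem_id`` and applies :func:`noael_pod`.
    Chemicals with no surviving records are omitted (their ids are returned
    in the second element for the run report), never a crash.
    """
    import pandas as pd

    df = pd.DataFrame(records)
    if df.empty:
        return [], []
    kept = filter_records(df)
    all_ids = sorted(df["chem_id"].astype(str).unique())
    pods = []
    for chem_id, grp in kept.groupby("chem_id", sort=True):
        pods.append(noael_pod(grp["value"].tolist(), chem_id=str(chem_id)))
    covered = {p.chem_id for p in pods}
    dropped = [c for c in all_ids if c not in covered]
    return pods, dropped
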