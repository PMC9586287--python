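"""Margin-of-exposure computation, ranking and category summaries.

MoE = PoD / SEEM95: a point of departure (TTC, OED or NOAEL based, all in
mg/kg-bw/d) divided by the upper 95% confidence bound on the median
population exposure estimate. MoE < 1 (strictly) flags a chemical whose
conservative hazard threshold is already exceeded by its estimated
exposure, i.e. a prioritization hit.

Exposure selection prefers the newer consensus model (SEEM3) and falls back
to SEEM2 where SEEM3 has no estimate.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .pod import quantile_type2
from .records import ExposureEstimate, MoEResult, PodType, PoDResult, TTCCategory

#: TTC thresholds are stated in µg/kg-bw/d; PoDs and exposures in mg/kg-bw/d
UG_TO_MG = 1.0 / 1000.0


def ttc_pod(ttc_ug_per_kg_d: float, chem_id: str = "") -> PoDResult:
    """Convert a TTC threshold (µg/kg-bw/d) into a PoD (mg/kg-bw/d).

    The µg->mg conversion happens exactly once in the package, here.
    """
    if ttc_ug_per_kg_d <= 0:
        raise ValueError("TTC value must be positive")
    return PoDResult(
        chem_id=chem_id,
        pod_type=PodType.TTC,
        pod=ttc_ug_per_kg_d * UG_TO_MG,
        n_records_used=1,
        method_note="TTC threshold / 1000 (µg->mg)",
    )


def select_exposure(
    seem3_row: Optional[ExposureEstimate] = None,
    seem2_row: Optional[ExposureEstimate] = None,
) -> ExposureEstimate:
    """SEEM3 estimate when available, otherwise SEEM2."""
    if seem3_row is not None:
        return seem3_row
    if seem2_row is not None:
        return seem2_row
    raise ValueError("no exposure estimate available (neither SEEM3 nor SEEM2)")


def select_exposures(
    rows: Iterable[ExposureEstimate],
) -> tuple[dict[str, ExposureEstimate], list[str]]:
    """One estimate per chemical with the SEEM3-first rule.

    Returns the per-chemical selection and the ids of chemicals with no
    usable row (callers log these; they are excluded from MoE tables).
    """
    by_chem: dict[str, dict[str, ExposureEstimate]] = {}
    for row in rows:
        by_chem.setdefault(row.chem_id, {})[row.source.upper()] = row
    selected: dict[str, ExposureEstimate] = {}
    missing: list[str] = []
    for chem_id, sources in sorted(by_chem.items()):
        try:
            selected[chem_id] = select_exposure(
                sources.get("SEEM3"), sources.get("SEEM2")
            )
        except ValueError:
            missing.append(chem_id)
    return selected, missing


def compute_moe(
    pod: PoDResult,
    exposure: ExposureEstimate,
    ttc_category: Optional[TTCCategory] = None,
) -> MoEResult:
    """MoE = PoD / upper-95 exposure; lt1 uses strict less-than."""
    if pod.pod <= 0:
        raise ValueError(f"PoD must be positive, got {pod.pod}")
    if exposure.upper95 <= 0:
        raise RuntimeError(
            f"upper95 exposure must be positive for {exposure.chem_id}"
        )
    moe = pod.pod / exposure.upper95
    return MoEResult(
        chem_id=pod.chem_id,
        pod_type=pod.pod_type,
        pod=pod.pod,
        exposure_upper95=exposure.upper95,
        moe=moe,
        lt1=moe < 1.0,
        ttc_category=ttc_category,
    )


def rank_by_moe(results: Sequence[MoEResult], top_n: int) -> list[MoEResult]:
    """Ascending by MoE (smallest margin first); ties broken by chem_id."""
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    if not results:
        raise ValueError("rank_by_moe requires at least one result")
    ordered = sorted(results, key=lambda r: (r.moe, r.chem_id))
    out = []
    for i, r in enumerate(ordered[:top_n], start=1):
        out.append(
            MoEResult(
                chem_id=r.chem_id,
                pod_type=r.pod_type,
                pod=r.pod,
                exposure_upper95=r.exposure_upper95,
                moe=r.moe,
                lt1=r.lt1,
                rank=i,
                ttc_category=r.ttc_category,
            )
        )
    return out


def summarize_by_category(results: Sequence[MoEResult]):
    """Per-TTC-category counts, MoE<1 counts and median MoEs, plus Total.

    Returns a pandas DataFrame with one row per category present and a
    final Total row. Percentages are of the grand total (``pct``) and of
    the category (``pct_lt1``); medians use the type-2 quantile.
    """
    import pandas as pd

    rows = []
    total = len(results)
    by_cat: dict[str, list[MoEResult]] = {}
    for r in results:
        key = r.ttc_category.value if r.ttc_category else "UNASSIGNED"
        by_cat.setdefault(key, []).append(r)
    order = [c.value for c in TTCCategory] + ["UNASSIGNED"]
    for cat in order:
        if cat not in by_cat:
            continue
        group = by_cat[cat]
        n = len(group)
        n_lt1 = sum(1 for r in group if r.lt1)
        rows.append(
            {
                "category": cat,
                "n": n,
                "pct": 100.0 * n / total if total else 0.0,
                "n_lt1": n_lt1,
                "pct_lt1": 100.0 * n_lt1 / n if n else 0.0,
                "median_moe": quantile_type2([r.moe for r in group], 0.5),
            }
        )
    n_lt1_total = sum(1 for r in results if r.lt1)
    rows.append(
        {
            "category": "Total",
            "n": total,
            "pct": 100.0 if total else 0.0,
            "n_lt1": n_lt1_total,
            "pct_lt1": 100.0 * n_lt1_total / total if total else 0.0,
            "median_moe": (
                quantile_type2([r.moe for r in results], 0.5) if total else float("nan")
            ),
        }
    )
    return pd.DataFrame(rows)
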