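"""End-to-end screening runs: classify -> assign -> OED -> PoD -> MoE.

``run_pipeline`` executes the whole workflow from input CSV paths and a run
configuration, returning all output tables plus a run report that tracks
chemical counts at every stage (how many parsed, classified, had exposure,
had each PoD type), the configuration echo and the software version — enough
to reproduce any output exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .classify import load_alerts, profile_chemical
from .io import (
    read_bioactivity,
    read_chemicals,
    read_exposures,
    read_noael,
    read_pk,
    write_outputs,
)
from .ivive import PKInput, load_physiology, oed_for_chemical
from .moe import compute_moe, rank_by_moe, select_exposures, summarize_by_category, ttc_pod
from .pod import noael_pods_from_table
from .records import PodType, StructuralProfile, TTCAssignment
from .ttc import assign_all


class ConfigurationError(ValueError):
    pass


@dataclass
class RunConfig:
    chemicals: str
    exposure: str
    bioactivity: Optional[str] = None
    pk: Optional[str] = None
    noael: Optional[str] = None
    pod_types: tuple[str, ...] = ("TTC", "OED", "NOAEL")
    genotox_filter: bool = False
    apply_volatility_filter: bool = False
    cramer_extensions: bool = False
    top_n: int = 25
    seed: int = 0
    n_samples: int = 1000
    physiology: Optional[str] = None
    alerts: Optional[str] = None
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw["pod_types"] = tuple(raw.get("pod_types", ("TTC", "OED", "NOAEL")))
        return cls(**raw)


def _chem_seed(master: int, chem_id: str) -> int:
    # stable per-chemical child seed, independent of processing order
    return (master * 1000003 + zlib.crc32(chem_id.encode())) % (2**31)


def _profiles_frame(profiles: list[StructuralProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chem_id": [p.chem_id for p in profiles],
            "is_carbamate_ester": [p.is_carbamate_ester for p in profiles],
            "is_organophosphate_ester": [p.is_organophosphate_ester for p in profiles],
            "genotoxic_alert": [p.genotoxic_alert for p in profiles],
            "genotoxic_alert_names": [
                ";".join(p.genotoxic_alert_names) for p in profiles
            ],
            "kroes_excluded": [p.kroes_excluded for p in profiles],
            "kroes_reason": [p.kroes_reason or "" for p in profiles],
            "cramer_class": [p.cramer_class.value for p in profiles],
            "volatile_flag": [
                "" if p.volatile_flag is None else str(p.volatile_flag).lower()
                for p in profiles
            ],
            "mw": [p.mw for p in profiles],
        }
    )


def _assignments_frame(assignments: list[TTCAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chem_id": [a.chem_id for a in assignments],
            "category": [a.category.value for a in assignments],
            "ttc_ug_per_kg_d": [a.ttc_ug_per_kg_d for a in assignments],
            "genotox_filter_applied": [a.genotox_filter_applied for a in assignments],
            "kroes_excluded": [a.kroes_excluded for a in assignments],
        }
    )


def run_pipeline(config: RunConfig) -> tuple[dict[str, pd.DataFrame], dict]:
    """Execute the full workflow; returns (tables, run_report).

    When ``config.out_dir`` is set, all tables and the report are also
    written to disk with deterministic formatting.
    """
    for pt in config.pod_types:
        PodType(pt)  # validate early
    if "OED" in config.pod_types and not (config.bioactivity and config.pk):
        raise ConfigurationError(
            "OED PoDs requested but bioactivity and/or pk table missing"
        )
    if "NOAEL" in config.pod_types and not config.noael:
        raise ConfigurationError("NOAEL PoDs requested but noael table missing")

    alerts = load_alerts(config.alerts)
    phys = load_physiology(config.physiology)

    records, rejects = read_chemicals(config.chemicals)
    profiles = [
        profile_chemical(r, alerts=alerts, cramer_extensions=config.cramer_extensions)
        for r in records
    ]
    assignments = assign_all(profiles, apply_genotox_filter=config.genotox_filter)
    by_id = {p.chem_id: p for p in profiles}
    assign_by_id = {a.chem_id: a for a in assignments}
    mw_by_id = {p.chem_id: p.mw for p in profiles}

    exposures, missing_exposure = select_exposures(read_exposures(config.exposure))

    volatile_excluded: list[str] = []
    if config.apply_volatility_filter:
        volatile_excluded = [
            p.chem_id for p in profiles if p.volatile_flag is True
        ]

    def in_scope(chem_id: str) -> bool:
        return (
            chem_id in exposures
            and chem_id in by_id
            and chem_id not in volatile_excluded
        )

    tables: dict[str, pd.DataFrame] = {
        "profiles": _profiles_frame(profiles),
        "assignments": _assignments_frame(assignments),
        "rejects": rejects,
    }
    counts = {
        "n_input": len(records) + len(rejects),
        "n_parsed": len(records),
        "n_rejected": len(rejects),
        "n_classified": len(profiles),
        "n_with_exposure": sum(1 for p in profiles if p.chem_id in exposures),
        "n_missing_exposure": len(
            [p for p in profiles if p.chem_id not in exposures]
        ),
        "n_volatile_excluded": len(volatile_excluded),
    }

    moe_tables: dict[str, list] = {}
    summaries = []
    tops = []

    def add_moe(pod_result, chem_id):
        exp = exposures[chem_id]
        cat = assign_by_id[chem_id].category if chem_id in assign_by_id else None
        return compute_moe(pod_result, exp, ttc_category=cat)

    if "TTC" in config.pod_types:
        results = [
            add_moe(ttc_pod(a.ttc_ug_per_kg_d, chem_id=a.chem_id), a.chem_id)
            for a in assignments
            if in_scope(a.chem_id)
        ]
        moe_tables["TTC"] = results
        counts["n_moe_ttc"] = len(results)

    if "OED" in config.pod_types:
        bio = read_bioactivity(config.bioactivity)
        pk = read_pk(config.pk).set_index("chem_id")
        ac50s = bio.groupby("chem_id")["ac50_uM"].apply(list)
        results = []
        oed_rows = []
        for chem_id in sorted(set(ac50s.index) & set(pk.index)):
            if not in_scope(chem_id):
                continue
            pk_row = pk.loc[chem_id]
            oed = oed_for_chemical(
                ac50s.loc[chem_id],
                PKInput(
                    chem_id=chem_id,
                    fup=float(pk_row["fup"]),
                    clint=float(pk_row["clint"]),
                    mw=float(mw_by_id[chem_id]),
                ),
                phys=phys,
                n_samples=config.n_samples,
                seed=_chem_seed(config.seed, chem_id),
            )
            oed_rows.append(
                {
                    "chem_id": chem_id,
                    "ac50_p5_uM": oed.ac50_p5,
                    "css95": oed.css95,
                    "oed_mg_kg_d": oed.oed,
                }
            )
            from .records import PoDResult

            results.append(
                add_moe(
                    PoDResult(
                        chem_id=chem_id,
                        pod_type=PodType.OED,
                        pod=oed.oed,
                        method_note="IVIVE: AC50 p5 / Css p95",
                    ),
                    chem_id,
                )
            )
        tables["oed"] = pd.DataFrame(
            oed_rows, columns=["chem_id", "ac50_p5_uM", "css95", "oed_mg_kg_d"]
        )
        moe_tables["OED"] = results
        counts["n_moe_oed"] = len(results)

    if "NOAEL" in config.pod_types:
        pods, dropped = noael_pods_from_table(read_noael(config.noael))
        results = [add_moe(p, p.chem_id) for p in pods if in_scope(p.chem_id)]
        tables["noael_pods"] = pd.DataFrame(
            {
                "chem_id": [p.chem_id for p in pods],
                "pod_type": ["NOAEL"] * len(pods),
                "pod": [p.pod for p in pods],
                "n_records_used": [p.n_records_used for p in pods],
                "method_note": [p.method_note for p in pods],
            }
        )
        moe_tables["NOAEL"] = results
        counts["n_moe_noael"] = len(results)
        counts["n_noael_no_valid_records"] = len(dropped)

    for pod_type, results in moe_tables.items():
        df = pd.DataFrame(
            {
                "chem_id": [r.chem_id for r in results],
                "pod_type": [r.pod_type.value for r in results],
                "pod": [r.pod for r in results],
                "exposure_upper95": [r.exposure_upper95 for r in results],
                "moe": [r.moe for r in results],
                "lt1": [r.lt1 for r in results],
                "ttc_category": [
                    r.ttc_category.value if r.ttc_category else "" for r in results
                ],
            }
        )
        tables[f"moe_{pod_type.lower()}"] = df
        if results:
            summary = summarize_by_category(results)
            summary.insert(0, "pod_type", pod_type)
            summaries.append(summary)
            top = rank_by_moe(results, config.top_n)
            tops.append(
                pd.DataFrame(
                    {
                        "pod_type": [pod_type] * len(top),
                        "rank": [r.rank for r in top],
                        "chem_id": [r.chem_id for r in top],
                        "moe": [r.moe for r in top],
                        "ttc_category": [
                            r.ttc_category.value if r.ttc_category else ""
                            for r in top
                        ],
                    }
                )
            )
    if summaries:
        tables["summary"] = pd.concat(summaries, ignore_index=True)
    if tops:
        tables["top_n"] = pd.concat(tops, ignore_index=True)

    report = {
        "software": {"name": "moescreen", "version": __version__},
        "config": {k: v for k, v in asdict(config).items()},
        "seed": config.seed,
        "alert_table_version": alerts.version,
        "aromaticity_model": "rdkit-default",
        "counts": counts,
        "missing_exposure_ids": missing_exposure[:100],
        "volatile_excluded_ids": volatile_excluded[:100],
    }
    if config.out_dir:
        write_outputs(tables, report, config.out_dir)
    return tables, report
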