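"""CSV readers/writers and the run report.

Conventions: UTF-8, comma-separated, header row required, '.' decimal
separator; floats are serialized with 6 significant digits; column order is
deterministic. CASRN is accepted in chemical lists but never used as a join
key — ``chem_id`` is canonical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .classify import SmilesParseError, parse_structure
from .records import ChemicalRecord, ExposureEstimate


class FormatError(ValueError):
    """A required column is missing or a table is malformed."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} table is missing column(s): {', '.join(missing)}")


def _opt_float(row, col) -> Optional[float]:
    if col not in row or pd.isna(row[col]):
        return None
    return float(row[col])


def read_chemicals(path: str | Path) -> tuple[list[ChemicalRecord], pd.DataFrame]:
    """Chemical list CSV -> validated records plus a rejects table.

    Rows whose SMILES cannot be parsed are collected into the returned
    rejects DataFrame (chem_id, smiles, reason) rather than aborting the run.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["chem_id", "smiles"], "chemicals")
    records: list[ChemicalRecord] = []
    rejects = []
    for _, row in df.iterrows():
        smiles = "" if pd.isna(row["smiles"]) else str(row["smiles"])
        try:
            parse_structure(smiles)
        except SmilesParseError as exc:
            rejects.append(
                {"chem_id": row["chem_id"], "smiles": smiles, "reason": str(exc)}
            )
            continue
        records.append(
            ChemicalRecord(
                chem_id=str(row["chem_id"]),
                smiles=smiles,
                casrn=str(row["casrn"]) if "casrn" in row and pd.notna(row.get("casrn")) else None,
                name=str(row["name"]) if "name" in row and pd.notna(row.get("name")) else None,
                mw=_opt_float(row, "mw"),
                bp_celsius=_opt_float(row, "bp_celsius"),
                vp_mmHg=_opt_float(row, "vp_mmHg"),
            )
        )
    return records, pd.DataFrame(rejects, columns=["chem_id", "smiles", "reason"])


def read_bioactivity(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["chem_id", "ac50_uM"], "bioactivity")
    df["chem_id"] = df["chem_id"].astype(str)
    return df


def read_pk(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["chem_id", "fup", "clint"], "pk")
    df["chem_id"] = df["chem_id"].astype(str)
    return df


def read_noael(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["chem_id", "type", "value", "units", "route"], "noael")
    df["chem_id"] = df["chem_id"].astype(str)
    return df


def read_exposures(path: str | Path) -> list[ExposureEstimate]:
    df = pd.read_csv(path)
    _require_columns(df, ["chem_id", "source", "median", "upper95"], "exposure")
    rows = []
    for _, row in df.iterrows():
        rows.append(
            ExposureEstimate(
                chem_id=str(row["chem_id"]),
                source=str(row["source"]).upper(),
                median=float(row["median"]),
                upper95=float(row["upper95"]),
            )
        )
    return rows


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV with 6-significant-digit floats."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")


def write_outputs(
    tables: dict[str, pd.DataFrame], report: dict, outdir: str | Path
) -> None:
    """Write every table as <name>.csv plus run_report.json under outdir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        write_csv(df, out / f"{name}.csv")
    with open(out / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
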