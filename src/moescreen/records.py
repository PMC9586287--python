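"""Core record types shared across the screening pipeline.

Every stage of the workflow consumes and produces plain dataclasses so that
tables can round-trip through CSV without loss. Units are fixed by
convention and named in the field: TTC values are in µg/kg-bw/d, every
point of departure (PoD) and exposure estimate is in mg/kg-bw/d, AC50s are
in µM, intrinsic clearance in µL/min/10⁶ hepatocytes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class TTCCategory(str, enum.Enum):
    """Structure-based threshold-of-toxicological-concern categories.

    Ordered from most to least conservative threshold: genotoxic alerts,
    anti-cholinesterase (organophosphate/carbamate esters), then the three
    Cramer classes (III = high presumed toxicity ... I = low).
    """

    GENOTOXIC = "GENOTOXIC"
    ANTICHOLINESTERASE = "ANTICHOLINESTERASE"
    CRAMER_III = "CRAMER_III"
    CRAMER_II = "CRAMER_II"
    CRAMER_I = "CRAMER_I"


class CramerClass(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"


class PodType(str, enum.Enum):
    TTC = "TTC"
    OED = "OED"
    NOAEL = "NOAEL"


@dataclass
class ChemicalRecord:
    """One chemical as read from an input list."""

    chem_id: str
    smiles: str
    casrn: Optional[str] = None
    name: Optional[str] = None
    mw: Optional[float] = None  # g/mol; computed from structure if absent
    bp_celsius: Optional[float] = None
    vp_mmHg: Optional[float] = None


@dataclass
class StructuralProfile:
    """All structure-derived flags plus the Cramer class with its trace.

    Flags are independent: a chemical may be simultaneously an
    organophosphate ester, carry a genotoxicity alert and be Kroes-excluded.
    ``cramer_trace`` records every decision-tree question visited, in order,
    as (question_id, answer) pairs.
    """

    chem_id: str
    is_carbamate_ester: bool
    is_organophosphate_ester: bool
    genotoxic_alert: bool
    genotoxic_alert_names: list[str]
    kroes_excluded: bool
    kroes_reason: Optional[str]
    cramer_class: CramerClass
    cramer_trace: list[tuple[str, bool]]
    volatile_flag: Optional[bool] = None  # None = unknown (no bp/vp data)
    mw: Optional[float] = None


@dataclass
class TTCAssignment:
    chem_id: str
    category: TTCCategory
    ttc_ug_per_kg_d: float
    genotox_filter_applied: bool
    kroes_excluded: bool = False


@dataclass
class PoDResult:
    """A point of departure in mg/kg-bw/d with provenance."""

    chem_id: str
    pod_type: PodType
    pod: float
    n_records_used: int = 1
    method_note: str = ""


@dataclass
class ExposureEstimate:
    chem_id: str
    source: str  # "SEEM3" | "SEEM2"
    median: float  # mg/kg-bw/d
    upper95: float  # mg/kg-bw/d


@dataclass
class MoEResult:
    chem_id: str
    pod_type: PodType
    pod: float
    exposure_upper95: float
    moe: float
    lt1: bool
    rank: Optional[int] = None
    ttc_category: Optional[TTCCategory] = None


@dataclass
class OEDResult:
    chem_id: str
    ac50_p5: float  # µM
    css95: float  # mg/L per (mg/kg-bw/d)
    oed: float  # mg/kg-bw/d
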