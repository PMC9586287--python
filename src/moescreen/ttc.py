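"""Threshold-of-toxicological-concern category and value assignment.

A structural profile maps to exactly one TTC category with a fixed human
exposure threshold (µg/kg-bw/d):

====================  ============  =========================================
category              TTC           trigger
====================  ============  =========================================
GENOTOXIC             0.0025        genotoxicity alert, filter enabled
ANTICHOLINESTERASE    0.3           carbamate or organophosphate ester group
CRAMER_III            1.5           Cramer class III
CRAMER_II             9             Cramer class II
CRAMER_I              30            Cramer class I
====================  ============  =========================================

Precedence is most-conservative-first: a genotoxicity alert (when the
filter is on) outranks the anti-cholinesterase flag, which outranks the
Cramer class. Kroes-excluded chemicals still receive an assignment — the
exclusion is carried as an annotation.
"""

from __future__ import annotations

from .records import CramerClass, StructuralProfile, TTCAssignment, TTCCategory

#: TTC thresholds, µg/kg-bw/d (kept as one table so updates are one line)
TTC_VALUES_UG_PER_KG_D: dict[TTCCategory, float] = {
    TTCCategory.GENOTOXIC: 0.0025,
    TTCCategory.ANTICHOLINESTERASE: 0.3,
    TTCCategory.CRAMER_III: 1.5,
    TTCCategory.CRAMER_II: 9.0,
    TTCCategory.CRAMER_I: 30.0,
}

_CRAMER_TO_CATEGORY = {
    CramerClass.I: TTCCategory.CRAMER_I,
    CramerClass.II: TTCCategory.CRAMER_II,
    CramerClass.III: TTCCategory.CRAMER_III,
}


def ttc_value(category: TTCCategory) -> float:
    """TTC threshold for a category, µg/kg-bw/d."""
    try:
        return TTC_VALUES_UG_PER_KG_D[TTCCategory(category)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown TTC category: {category!r}") from exc


def assign_category(
    profile: StructuralProfile, apply_genotox_filter: bool
) -> TTCAssignment:
    """Assign the TTC category and threshold for one structural profile.

    With the genotoxicity filter off, alert-carrying chemicals fall through
    to the anti-cholinesterase / Cramer logic unchanged, so toggling the
    filter never alters the assignment of chemicals without alerts.
    """
    if profile.cramer_class is None:
        raise RuntimeError(
            f"profile for {profile.chem_id!r} lacks a Cramer class"
        )
    if apply_genotox_filter and profile.genotoxic_alert:
        category = TTCCategory.GENOTOXIC
    elif profile.is_carbamate_ester or profile.is_organophosphate_ester:
        category = TTCCategory.ANTICHOLINESTERASE
    else:
        category = _CRAMER_TO_CATEGORY[CramerClass(profile.cramer_class)]
    return TTCAssignment(
        chem_id=profile.chem_id,
        category=category,
        ttc_ug_per_kg_d=ttc_value(category),
        genotox_filter_applied=apply_genotox_filter,
        kroes_excluded=profile.kroes_excluded,
    )


def assign_all(
    profiles: list[StructuralProfile], apply_genotox_filter: bool
) -> list[TTCAssignment]:
    return [assign_category(p, apply_genotox_filter) for p in profiles]
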