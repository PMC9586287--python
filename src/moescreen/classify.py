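"""Structure-derived hazard flags.

For each chemical this module derives, from the SMILES alone:

* anti-cholinesterase functional groups — carbamate esters (N-C(=O)-O-R)
  and organophosphate/thiophosphate esters (P(=O|=S) carrying at least one
  O/S-linked carbon ester);
* genotoxicity structural alerts, from a versioned YAML table of named
  SMARTS patterns;
* the Kroes-domain annotation (organometallics and high-potency-carcinogen
  classes for which a structure-class threshold is inappropriate) — an
  annotation only, never a drop;
* the Cramer class via the 33-question decision tree (:mod:`.cramer`);
* a volatility flag from boiling point / vapor pressure, where provided.

All flags are pure functions of the (canonicalized) structure. Salt or
mixture SMILES are reduced to their largest organic fragment first.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from . import cramer
from .records import ChemicalRecord, CramerClass, StructuralProfile

RDLogger.DisableLog("rdApp.*")  # parse failures are reported as exceptions

#: volatility cutoffs: boiling point below 260 °C or vapor pressure above
#: 0.1 mmHg marks a chemical as volatile (oral-route thresholds suspect)
BP_CUTOFF_CELSIUS = 260.0
VP_CUTOFF_MMHG = 0.1


class SmilesParseError(ValueError):
    """Raised for SMILES that cannot be parsed into a molecular graph."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"unparsable SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


def parse_structure(smiles: str) -> Chem.Mol:
    """Parse a SMILES string into a sanitized molecular graph.

    Multi-fragment inputs (salts, mixtures) are reduced to the largest
    fragment that contains carbon before classification.
    """
    if not smiles or not str(smiles).strip():
        raise SmilesParseError(smiles, "empty string")
    mol = Chem.MolFromSmiles(str(smiles).strip())
    if mol is None:
        raise SmilesParseError(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        organic = [
            f
            for f in frags
            if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
        ]
        pool = organic or list(frags)
        mol = max(pool, key=lambda f: f.GetNumHeavyAtoms())
        Chem.SanitizeMol(mol)
    return mol


def molecular_weight(mol: Chem.Mol) -> float:
    return float(Descriptors.MolWt(mol))


# --------------------------------------------------------------------------
# anti-cholinesterase functional groups

# carbamate ester: N-C(=O)-O-C, including O-N oxime carbamates
_CARBAMATE = Chem.MolFromSmarts("[NX3][CX3](=[OX1])[OX2][#6,#7]")
# organophosphate/thiophosphate ester: P(=O or =S) with >=1 O/S-carbon ester
_ORGANOPHOSPHATE = Chem.MolFromSmarts(
    "[PX4;$([PX4]=[OX1]),$([PX4]=[SX1])][OX2,SX2][#6]"
)


def detect_ache_groups(mol: Chem.Mol) -> tuple[bool, bool]:
    """(is_carbamate_ester, is_organophosphate_ester) by substructure match."""
    return (
        mol.HasSubstructMatch(_CARBAMATE),
        mol.HasSubstructMatch(_ORGANOPHOSPHATE),
    )


# --------------------------------------------------------------------------
# genotoxicity structural alerts


@dataclass(frozen=True)
class AlertTable:
    version: str
    patterns: tuple[tuple[str, Chem.Mol], ...]


def load_alerts(path: Optional[str] = None) -> AlertTable:
    """Load the named-SMARTS alert table (package default or a user file)."""
    if path is None:
        text = (
            resources.files("moescreen") / "data" / "genotox_alerts.yaml"
        ).read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    patterns = []
    for entry in raw["alerts"]:
        patt = Chem.MolFromSmarts(entry["smarts"])
        if patt is None:
            raise ValueError(
                f"invalid SMARTS for alert {entry['name']!r}: {entry['smarts']}"
            )
        patterns.append((entry["name"], patt))
    return AlertTable(version=str(raw.get("version", "?")), patterns=tuple(patterns))


_DEFAULT_ALERTS: Optional[AlertTable] = None


def default_alerts() -> AlertTable:
    global _DEFAULT_ALERTS
    if _DEFAULT_ALERTS is None:
        _DEFAULT_ALERTS = load_alerts()
    return _DEFAULT_ALERTS


def detect_genotoxic_alerts(
    mol: Chem.Mol, alerts: Optional[AlertTable] = None
) -> tuple[bool, list[str]]:
    """True plus the list of matching alert names if any pattern matches."""
    table = alerts or default_alerts()
    names = [name for name, patt in table.patterns if mol.HasSubstructMatch(patt)]
    return bool(names), names


# --------------------------------------------------------------------------
# Kroes domain gate (annotation only)

_HIGH_POTENCY_SMARTS = {
    "polyhalogenated dibenzodioxin": "c1ccc2c(c1)Oc1ccccc1O2",
    "polyhalogenated dibenzofuran": "c1ccc2c(c1)oc1ccccc12",
    "polyhalogenated biphenyl": "c1ccc(-c2ccccc2)cc1",
    "azoxy compound": "[NX2]=[NX3+][O-]",
    "aflatoxin-like bisfuran": "[#6]1[#6]=[#6][#8][#6]1[#8]",
}
_HIGH_POTENCY = {
    k: Chem.MolFromSmarts(v) for k, v in _HIGH_POTENCY_SMARTS.items()
}
_MIN_HALOGENS = {
    "polyhalogenated dibenzodioxin": 2,
    "polyhalogenated dibenzofuran": 2,
    "polyhalogenated biphenyl": 4,
}
_HALOGEN = Chem.MolFromSmarts("[F,Cl,Br,I]")

_METALS = cramer._METALS


def kroes_gate(mol: Chem.Mol) -> tuple[bool, Optional[str]]:
    """Chemicals outside the structure-class domain (never dropped).

    Flags organometallics (metal/metalloid covalently bonded to carbon) and
    high-potency-carcinogen classes (polyhalogenated dibenzodioxin / furan /
    biphenyl cores, azoxy compounds, aflatoxin-like bisfuranoids).
    """
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() in _METALS and any(
            n.GetAtomicNum() == 6 for n in atom.GetNeighbors()
        ):
            return True, "organometallic"
    n_halogen = len(mol.GetSubstructMatches(_HALOGEN))
    for name, patt in _HIGH_POTENCY.items():
        if not mol.HasSubstructMatch(patt):
            continue
        if n_halogen >= _MIN_HALOGENS.get(name, 0):
            return True, f"high-potency carcinogen class ({name})"
    return False, None


# --------------------------------------------------------------------------
# Cramer class and volatility


def classify_cramer(
    mol: Chem.Mol, extensions: bool = False
) -> tuple[CramerClass, list[tuple[str, bool]]]:
    """Cramer class with the ordered question/answer trace."""
    return cramer.classify(mol, extensions=extensions)


def volatility_flag(
    bp_celsius: Optional[float] = None, vp_mmHg: Optional[float] = None
) -> Optional[bool]:
    """True if bp < 260 °C or vp > 0.1 mmHg; None when both are absent."""
    if vp_mmHg is not None and vp_mmHg < 0:
        raise ValueError(f"vapor pressure must be non-negative, got {vp_mmHg}")
    if bp_celsius is None and vp_mmHg is None:
        return None
    if bp_celsius is not None and bp_celsius < BP_CUTOFF_CELSIUS:
        return True
    if vp_mmHg is not None and vp_mmHg > VP_CUTOFF_MMHG:
        return True
    return False


# --------------------------------------------------------------------------
# one-stop profile


def profile_chemical(
    record: ChemicalRecord,
    alerts: Optional[AlertTable] = None,
    cramer_extensions: bool = False,
) -> StructuralProfile:
    """Derive the full structural profile for one chemical record."""
    mol = parse_structure(record.smiles)
    carbamate, organophosphate = detect_ache_groups(mol)
    geno_flag, geno_names = detect_genotoxic_alerts(mol, alerts)
    excluded, reason = kroes_gate(mol)
    cls, trace = classify_cramer(mol, extensions=cramer_extensions)
    return StructuralProfile(
        chem_id=record.chem_id,
        is_carbamate_ester=carbamate,
        is_organophosphate_ester=organophosphate,
        genotoxic_alert=geno_flag,
        genotoxic_alert_names=geno_names,
        kroes_excluded=excluded,
        kroes_reason=reason,
        cramer_class=cls,
        cramer_trace=trace,
        volatile_flag=volatility_flag(record.bp_celsius, record.vp_mmHg),
        mw=record.mw if record.mw is not None else molecular_weight(mol),
    )
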