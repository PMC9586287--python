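"""Cramer structural decision tree for presumed oral toxicity.

The Cramer scheme sorts a structure into one of three classes — I (low),
II (intermediate), III (high presumed toxicity) — by walking a 33-question
decision tree of structural predicates: is it a normal body constituent,
does it carry functional groups associated with enhanced toxicity, does it
contain elements beyond C/H/O/N/divalent S, and branch-specific questions
for open-chain, carbocyclic, aromatic and heterocyclic skeletons, with a
common-in-food fallback near the leaves.

Each question here is a named, pure RDKit predicate. ``classify`` walks the
tree and returns the class together with the full ordered trace of
(question_id, answer) pairs, so any classification can be audited and
replayed question by question.

The engine implements the original scheme; the "with extensions" variant
adds a small number of documented extra rules and is off by default (see
``classify(..., extensions=True)``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

from rdkit import Chem
from rdkit.Chem import Descriptors

from .records import CramerClass

Mol = Chem.Mol

# --------------------------------------------------------------------------
# Curated canonical-SMILES lookup lists used by individual questions.
# Stored as input SMILES; canonicalized once at import.


def _canon_set(smiles: list[str]) -> frozenset[str]:
    out = set()
    for s in smiles:
        m = Chem.MolFromSmiles(s)
        if m is None:  # pragma: no cover - lists are static
            raise ValueError(f"bad SMILES in curated list: {s}")
        out.add(Chem.MolToSmiles(m))
    return frozenset(out)


#: normal constituents of the body (Q1)
BODY_CONSTITUENTS = _canon_set(
    [
        "NC(N)=O",  # urea
        "NCC(=O)O",  # glycine
        "CC(N)C(=O)O",  # alanine
        "CC(O)C(=O)O",  # lactic acid
        "CC(=O)C(=O)O",  # pyruvic acid
        "OC(=O)CC(O)(CC(=O)O)C(=O)O",  # citric acid
        "OC(=O)CCC(=O)O",  # succinic acid
        "CC(C)=O",  # acetone (ketone body)
        "CC(=O)O",  # acetic acid
        "CCCCCCCCCCCCCCCC(=O)O",  # palmitic acid
    ]
)

#: common carbohydrates and sugar alcohols (Q5)
COMMON_CARBOHYDRATES = _canon_set(
    [
        "OCC1OC(O)C(O)C(O)C1O",  # glucopyranose
        "OCC(O)C(O)C(O)C(O)C=O",  # open-chain glucose
        "OCC(O)C(O)C(O)C(O)CO",  # sorbitol
        "OCC1(O)OC(CO)C(O)C1O",  # fructofuranose
    ]
)

#: common terpene hydrocarbons / alcohols / ketones (Q25)
COMMON_TERPENES = _canon_set(
    [
        "CC(=C)C1CCC(C)=CC1",  # limonene
        "CC(C)C1CCC(C)CC1O",  # menthol
        "CC1=CCC2CC1C2(C)C",  # alpha-pinene
        "CC(=C)C1CCC(C)=CC1=O",  # carvone (2-carvone-like)
        "CC(C)=CCCC(C)=CCO",  # geraniol
    ]
)

#: simple saturated lactones / cyclic ethers common in food (Q14)
FOOD_CYCLIC = _canon_set(
    [
        "O=C1CCCO1",  # gamma-butyrolactone
        "CC1CCC(=O)O1",  # gamma-valerolactone
    ]
)

#: common components of food or close relatives (Q32)
COMMON_FOOD = _canon_set(
    [
        "CCO",  # ethanol
        "CCOC(C)=O",  # ethyl acetate
        "OCC(O)CO",  # glycerol
        "OC(=O)c1ccccc1",  # benzoic acid
        "O=Cc1ccccc1",  # benzaldehyde
        "CCCCCC(=O)O",  # hexanoic acid
        "CC(=O)OCC(COC(C)=O)OC(C)=O",  # triacetin
    ]
)

# --------------------------------------------------------------------------
# Functional groups "associated with enhanced toxicity" (Q2): reactive or
# historically high-concern moieties that short-circuit to Class III.

_ENHANCED_TOXICITY_SMARTS: dict[str, str] = {
    "nitro": "[$([NX3](=O)=O),$([NX3+](=O)[O-])]",
    "N-nitroso": "[NX3][NX2]=[OX1]",
    "diazo/diazonium": "[$([#6]=[NX2+]=[NX1-]),$([#6][NX2+]#[NX1])]",
    "azoxy": "[NX2]=[NX3+][O-]",
    "triazeno": "[NX3][NX2]=[NX2]",
    "quaternary nitrogen": "[NX4+]([#6])([#6])([#6])[#6]",
    "epoxide": "[CX4]1[OX2][CX4]1",
    "aziridine": "[CX4]1[NX3][CX4]1",
    "beta-lactone": "O=C1CCO1",
    "isocyanate/isothiocyanate": "[NX2]=C=[OX1,SX1]",
    "acyl halide": "[CX3](=[OX1])[F,Cl,Br,I]",
    "hydrazine": "[NX3;!$([NX3][CX3]=[OX1])][NX3;!$([NX3][CX3]=[OX1])]",
}

_ENHANCED_TOXICITY = {
    name: Chem.MolFromSmarts(s) for name, s in _ENHANCED_TOXICITY_SMARTS.items()
}

# common functional groups used for counting (several leaf questions)
_FG_SMARTS: dict[str, str] = {
    "hydroxyl": "[OX2H][#6;!$([CX3]=[OX1])]",
    "aldehyde": "[CX3H1](=[OX1])[#6]",
    "ketone": "[#6][CX3](=[OX1])[#6]",
    "carboxylic acid": "[CX3](=[OX1])[OX2H1]",
    "ester": "[CX3](=[OX1])[OX2][#6]",
    "ether": "[OX2]([#6;!$([CX3]=[OX1])])[#6;!$([CX3]=[OX1])]",
    "amide": "[NX3][CX3]=[OX1]",
    "amine": "[NX3;!$([NX3][CX3]=[OX1]);!$([NX3+])]",
    "sulfide/thiol": "[SX2]",
}
_FG = {name: Chem.MolFromSmarts(s) for name, s in _FG_SMARTS.items()}

_METALS = frozenset(
    [3, 4, 11, 12, 13, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31,
     32, 33, 37, 38, 39, 40, 41, 42, 44, 45, 46, 47, 48, 49, 50, 51, 52,
     55, 56, 57, 72, 73, 74, 75, 76, 77, 78, 79, 80, 81, 82, 83]
)

_ALLOWED_Z = frozenset([1, 6, 7, 8])  # H, C, N, O


# --------------------------------------------------------------------------
# predicate helpers


def _canon(mol: Mol) -> str:
    return Chem.MolToSmiles(mol)


def _is_divalent_sulfur(atom: Chem.Atom) -> bool:
    return (
        atom.GetAtomicNum() == 16
        and atom.GetTotalDegree() - atom.GetTotalNumHs() <= 2
        and atom.GetFormalCharge() == 0
        and all(b.GetBondType() == Chem.BondType.SINGLE for b in atom.GetBonds())
    )


def _exceptional_atoms(mol: Mol) -> list[Chem.Atom]:
    """Atoms outside C/H/O/N and divalent S."""
    out = []
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z in _ALLOWED_Z:
            continue
        if z == 16 and _is_divalent_sulfur(atom):
            continue
        out.append(atom)
    return out


def _n_matches(mol: Mol, patt) -> int:
    return len(mol.GetSubstructMatches(patt))


def _fg_types(mol: Mol) -> set[str]:
    return {name for name, patt in _FG.items() if mol.HasSubstructMatch(patt)}


def _fg_count(mol: Mol) -> int:
    return sum(_n_matches(mol, patt) for patt in _FG.values())


def _oxygens_common(mol: Mol) -> bool:
    """Every oxygen sits in a hydroxyl/ether/carbonyl/carboxyl/ester context."""
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 8:
            continue
        if atom.GetFormalCharge() != 0:
            return False
        nbrs = [n.GetAtomicNum() for n in atom.GetNeighbors()]
        if any(z == 8 for z in nbrs):  # peroxide
            return False
        if not all(z == 6 for z in nbrs):
            return False
    return True


def _ring_systems(mol: Mol) -> list[list[int]]:
    return [list(r) for r in mol.GetRingInfo().AtomRings()]


def _substituents_common(mol: Mol, ring_atoms: set[int]) -> bool:
    """Atoms outside the ring set are C/H or oxygen in a common context."""
    for atom in mol.GetAtoms():
        if atom.GetIdx() in ring_atoms:
            continue
        z = atom.GetAtomicNum()
        if z not in (1, 6, 8):
            return False
    return _oxygens_common(mol)


def _aromatic_carbocycles(mol: Mol) -> list[list[int]]:
    rings = []
    for ring in _ring_systems(mol):
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if all(a.GetIsAromatic() and a.GetAtomicNum() == 6 for a in atoms):
            rings.append(ring)
    return rings


def _heteroaromatic_rings(mol: Mol) -> list[list[int]]:
    rings = []
    for ring in _ring_systems(mol):
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if all(a.GetIsAromatic() for a in atoms) and any(
            a.GetAtomicNum() != 6 for a in atoms
        ):
            rings.append(ring)
    return rings


def _rings_fused(ring: list[int], others: list[list[int]]) -> bool:
    rs = set(ring)
    return any(len(rs & set(o)) >= 2 for o in others if set(o) != rs)


_LACTONE = Chem.MolFromSmarts("[CX3;R](=[OX1])[OX2;R]")


def _hazardous_lactone(mol: Mol) -> bool:
    """Lactone fused to another ring, or alpha,beta-unsaturated lactone."""
    rings = _ring_systems(mol)
    for match in mol.GetSubstructMatches(_LACTONE):
        c_idx, _, o_idx = match[0], match[1], match[-1]
        for ring in rings:
            rs = set(ring)
            if c_idx not in rs or o_idx not in rs:
                continue
            if _rings_fused(ring, rings):
                return True
            # conjugated C=C inside the lactone ring
            for bond in mol.GetBonds():
                if (
                    bond.GetBondType() == Chem.BondType.DOUBLE
                    and bond.GetBeginAtomIdx() in rs
                    and bond.GetEndAtomIdx() in rs
                    and bond.GetBeginAtom().GetAtomicNum() == 6
                    and bond.GetEndAtom().GetAtomicNum() == 6
                ):
                    return True
    return False


def _quaternary_carbon(mol: Mol) -> bool:
    return mol.HasSubstructMatch(
        Chem.MolFromSmarts("[CX4]([#6])([#6])([#6])[#6]")
    )


def _has_non_amide_nitrogen(mol: Mol) -> bool:
    amide = _FG["amide"]
    amide_n = {m[0] for m in mol.GetSubstructMatches(amide)}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 7 and atom.GetIdx() not in amide_n:
            return True
    return False


def _all_oxygens_in_esters(mol: Mol) -> bool:
    ester = Chem.MolFromSmarts("[CX3](=[OX1])[OX2][#6]")
    in_ester: set[int] = set()
    for match in mol.GetSubstructMatches(ester):
        for idx in match:
            if mol.GetAtomWithIdx(idx).GetAtomicNum() == 8:
                in_ester.add(idx)
    n_o = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 8)
    return n_o > 0 and len(in_ester) == n_o


def _carbon_count(mol: Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)


# --------------------------------------------------------------------------
# the 33 questions


def q1(mol: Mol) -> bool:
    "Normal constituent of the body (or an optical isomer of one)?"
    return _canon(mol) in BODY_CONSTITUENTS


def q2(mol: Mol) -> bool:
    "Contains functional groups associated with enhanced toxicity?"
    return any(mol.HasSubstructMatch(p) for p in _ENHANCED_TOXICITY.values())


def q3(mol: Mol) -> bool:
    "Contains elements other than C, H, O, N or divalent sulfur?"
    return len(_exceptional_atoms(mol)) > 0


def q4(mol: Mol) -> bool:
    "Exceptional elements present only as alkali/alkaline-earth salt counterions?"
    for atom in _exceptional_atoms(mol):
        if atom.GetAtomicNum() not in (3, 11, 12, 19, 20):
            return False
        if any(n.GetAtomicNum() == 6 for n in atom.GetNeighbors()):
            return False
    return True


def q5(mol: Mol) -> bool:
    "Simply branched acyclic aliphatic hydrocarbon, or a common carbohydrate?"
    if _canon(mol) in COMMON_CARBOHYDRATES:
        return True
    if mol.GetRingInfo().NumRings() > 0:
        return False
    if any(a.GetAtomicNum() != 6 for a in mol.GetAtoms()):
        return False
    return not _quaternary_carbon(mol)


def q6(mol: Mol) -> bool:
    "Contains a ring?"
    return mol.GetRingInfo().NumRings() > 0


def q7(mol: Mol) -> bool:
    "Heterocyclic (any ring atom other than carbon)?"
    ri = mol.GetRingInfo()
    return any(
        mol.GetAtomWithIdx(i).GetAtomicNum() != 6
        for ring in ri.AtomRings()
        for i in ring
    )


def q8(mol: Mol) -> bool:
    "Lactone fused to another ring, or an alpha,beta-unsaturated lactone?"
    return _hazardous_lactone(mol)


def q9(mol: Mol) -> bool:
    "Heteroaromatic ring present?"
    return len(_heteroaromatic_rings(mol)) > 0


def q10(mol: Mol) -> bool:
    "Fused heteroaromatic system, or more than one aromatic ring heteroatom?"
    het_rings = _heteroaromatic_rings(mol)
    all_rings = _ring_systems(mol)
    if any(_rings_fused(r, all_rings) for r in het_rings):
        return True
    n_het = sum(
        1
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetAtomicNum() != 6
    )
    return n_het >= 2


def q11(mol: Mol) -> bool:
    "Monocyclic single-heteroatom heteroaromatic with only common substituents?"
    het_rings = _heteroaromatic_rings(mol)
    if len(het_rings) != 1 or mol.GetRingInfo().NumRings() != 1:
        return False
    return _substituents_common(mol, set(het_rings[0]))


def q12(mol: Mol) -> bool:
    "Nitrogen in a non-aromatic ring?"
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        for i in ring:
            a = mol.GetAtomWithIdx(i)
            if a.GetAtomicNum() == 7 and not a.GetIsAromatic():
                return True
    return False


def q13(mol: Mol) -> bool:
    "Single 5- or 6-membered oxygen heterocycle with only common substituents?"
    rings = _ring_systems(mol)
    if len(rings) != 1 or len(rings[0]) not in (5, 6):
        return False
    het = [
        mol.GetAtomWithIdx(i)
        for i in rings[0]
        if mol.GetAtomWithIdx(i).GetAtomicNum() != 6
    ]
    if not het or any(a.GetAtomicNum() != 8 for a in het):
        return False
    return _substituents_common(mol, set(rings[0]))


def q14(mol: Mol) -> bool:
    "Simple saturated lactone or cyclic ether of a type common in food?"
    return _canon(mol) in FOOD_CYCLIC


def q15(mol: Mol) -> bool:
    "Single ring of six or fewer members?"
    rings = _ring_systems(mol)
    return len(rings) == 1 and len(rings[0]) <= 6


def q16(mol: Mol) -> bool:
    "Aromatic carbocyclic ring present?"
    return len(_aromatic_carbocycles(mol)) > 0


def q17(mol: Mol) -> bool:
    "Fused polycyclic aromatic carbocycles (naphthalene-like or larger)?"
    rings = _aromatic_carbocycles(mol)
    return any(_rings_fused(r, rings) for r in rings)


def q18(mol: Mol) -> bool:
    "Aromatic ring substituents limited to the common functional groups?"
    ring_atoms = {i for r in _aromatic_carbocycles(mol) for i in r}
    return _substituents_common(mol, ring_atoms)


def q19(mol: Mol) -> bool:
    "Open chain bearing only common functional groups on a simple skeleton?"
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z in (1, 6, 8):
            continue
        if z == 16 and _is_divalent_sulfur(atom):
            continue
        return False
    return _oxygens_common(mol)


def q20(mol: Mol) -> bool:
    "Contains sulfur?"
    return any(a.GetAtomicNum() == 16 for a in mol.GetAtoms())


def q21(mol: Mol) -> bool:
    "All sulfur present as simple thiol, sulfide or disulfide?"
    sulfurs = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 16]
    return bool(sulfurs) and all(_is_divalent_sulfur(a) for a in sulfurs)


def q22(mol: Mol) -> bool:
    "Quaternary carbon, three or more functional-group types, or non-amide N?"
    return (
        _quaternary_carbon(mol)
        or len(_fg_types(mol)) >= 3
        or _has_non_amide_nitrogen(mol)
    )


def q23(mol: Mol) -> bool:
    "Simple ester (mono-, di- or tri-) of common alcohols and acids?"
    if any(a.GetAtomicNum() not in (1, 6, 8) for a in mol.GetAtoms()):
        return False
    return _all_oxygens_in_esters(mol)


def q24(mol: Mol) -> bool:
    "At least four carbons with at most one functional-group type?"
    return _carbon_count(mol) >= 4 and len(_fg_types(mol)) <= 1


def q25(mol: Mol) -> bool:
    "A common terpene hydrocarbon, alcohol or ketone?"
    return _canon(mol) in COMMON_TERPENES


def q26(mol: Mol) -> bool:
    "Single 3-7 membered carbocyclic non-aromatic ring, common substituents?"
    rings = _ring_systems(mol)
    if len(rings) != 1 or not (3 <= len(rings[0]) <= 7):
        return False
    atoms = [mol.GetAtomWithIdx(i) for i in rings[0]]
    if any(a.GetAtomicNum() != 6 or a.GetIsAromatic() for a in atoms):
        return False
    return _substituents_common(mol, set(rings[0]))


def q27(mol: Mol) -> bool:
    "Ring of five or more members (little ring strain)?"
    rings = _ring_systems(mol)
    return bool(rings) and max(len(r) for r in rings) >= 5


def q28(mol: Mol) -> bool:
    "Substituents limited to hydrocarbon, hydroxyl or carbonyl?"
    return _fg_types(mol) <= {"hydroxyl", "ketone", "aldehyde"}


def q29(mol: Mol) -> bool:
    "Only ester/acid substituents of common acids (plus hydroxyl/carbonyl/ether)?"
    return _fg_types(mol) <= {
        "ester",
        "carboxylic acid",
        "hydroxyl",
        "ketone",
        "aldehyde",
        "ether",
    }


def q30(mol: Mol) -> bool:
    "At most three functional groups in total on the side chains?"
    return _fg_count(mol) <= 3


def q31(mol: Mol) -> bool:
    "Readily hydrolyzed or metabolized to innocuous products (heuristic)?"
    if Descriptors.MolWt(mol) > 1000:
        return False
    if any(a.GetAtomicNum() in (9, 15, 17, 35, 53) for a in mol.GetAtoms()):
        return False
    return mol.GetRingInfo().NumRings() <= 2


def q32(mol: Mol) -> bool:
    "Common component of food, or structurally closely related to one?"
    return _canon(mol) in COMMON_FOOD


def q33(mol: Mol) -> bool:
    "At most two functional-group types and twenty or fewer carbons?"
    return len(_fg_types(mol)) <= 2 and _carbon_count(mol) <= 20


# --------------------------------------------------------------------------
# tree wiring

Outcome = Union[str, CramerClass]  # next question id or a terminal class


@dataclass(frozen=True)
class Node:
    qid: str
    text: str
    predicate: Callable[[Mol], bool]
    yes: Outcome
    no: Outcome


def _n(qid, pred, yes, no) -> Node:
    return Node(qid, pred.__doc__ or qid, pred, yes, no)


I, II, III = CramerClass.I, CramerClass.II, CramerClass.III

#: the decision tree: every entry is reachable; terminal outcomes are classes
NODES: dict[str, Node] = {
    n.qid: n
    for n in [
        _n("Q1", q1, I, "Q2"),
        _n("Q2", q2, III, "Q3"),
        _n("Q3", q3, "Q4", "Q5"),
        _n("Q4", q4, "Q5", III),
        _n("Q5", q5, I, "Q6"),
        _n("Q6", q6, "Q7", "Q19"),
        _n("Q7", q7, "Q8", "Q16"),
        _n("Q8", q8, III, "Q9"),
        _n("Q9", q9, "Q10", "Q12"),
        _n("Q10", q10, III, "Q11"),
        _n("Q11", q11, II, III),
        _n("Q12", q12, III, "Q13"),
        _n("Q13", q13, "Q14", III),
        _n("Q14", q14, I, "Q15"),
        _n("Q15", q15, II, III),
        _n("Q16", q16, "Q17", "Q25"),
        _n("Q17", q17, III, "Q18"),
        _n("Q18", q18, "Q30", III),
        _n("Q19", q19, "Q20", "Q22"),
        _n("Q20", q20, "Q21", "Q31"),
        _n("Q21", q21, "Q31", II),
        _n("Q22", q22, III, "Q23"),
        _n("Q23", q23, I, "Q24"),
        _n("Q24", q24, "Q31", II),
        _n("Q25", q25, I, "Q26"),
        _n("Q26", q26, "Q27", III),
        _n("Q27", q27, "Q28", II),
        _n("Q28", q28, "Q31", "Q29"),
        _n("Q29", q29, II, III),
        _n("Q30", q30, "Q31", III),
        _n("Q31", q31, "Q32", II),
        _n("Q32", q32, I, "Q33"),
        _n("Q33", q33, I, II),
    ]
}

ROOT = "Q1"

# documented extension rules (off by default): additional reactive moieties
# routed straight to Class III before the main walk
_EXTENSION_SMARTS = {
    "alpha,beta-unsaturated amide": "[CX3]=[CX3][CX3](=[OX1])[NX3]",
    "michael-acceptor nitrile": "[CX3]=[CX3]C#N",
}
_EXTENSIONS = {k: Chem.MolFromSmarts(v) for k, v in _EXTENSION_SMARTS.items()}


def classify(mol: Mol, extensions: bool = False):
    """Walk the tree; return ``(CramerClass, trace)``.

    ``trace`` is the ordered list of (question_id, answer) pairs actually
    visited. With ``extensions=True`` the documented extra rules are checked
    first; a hit is recorded in the trace as ("EXT:<name>", True).
    """
    if extensions:
        for name, patt in _EXTENSIONS.items():
            if mol.HasSubstructMatch(patt):
                return CramerClass.III, [(f"EXT:{name}", True)]
    trace: list[tuple[str, bool]] = []
    cursor: Outcome = ROOT
    while not isinstance(cursor, CramerClass):
        node = NODES[cursor]
        answer = bool(node.predicate(mol))
        trace.append((node.qid, answer))
        cursor = node.yes if answer else node.no
        if len(trace) > len(NODES):  # pragma: no cover - tree is acyclic
            raise RuntimeError("Cramer tree walk did not terminate")
    return cursor, trace


def replay(mol: Mol, trace: list[tuple[str, bool]]) -> bool:
    """Re-evaluate each predicate named in a trace; True if answers match."""
    for qid, answer in trace:
        if qid.startswith("EXT:"):
            name = qid[4:]
            if bool(_EXTENSIONS[name].HasSubstructMatch) and bool(
                mol.HasSubstructMatch(_EXTENSIONS[name])
            ) != bool(answer):
                return False
            continue
        if bool(NODES[qid].predicate(mol)) != bool(answer):
            return False
    return True
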