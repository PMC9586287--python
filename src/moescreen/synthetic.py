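"""Synthetic chemical libraries and input tables with known ground truth.

Real margin-of-exposure screens draw on large external databases (curated
structure lists, high-throughput bioassay AC50s, in vitro PK measurements,
legacy NOAEL compilations, consensus exposure models). This module emulates
each of those inputs at desk scale so that every pipeline stage can be
tested end-to-end with known truth:

* chemicals are sampled from a hand-curated template panel of SMILES
  exemplars per TTC category, each validated once by a manual walk of the
  Cramer tree / alert tables before inclusion, so the classifier's expected
  output is known by construction;
* AC50s are lognormal; fup is logit-normal, Clint lognormal with an
  optional point mass at zero (non-metabolized chemicals);
* NOAEL sets can be generated "TTC-consistent": each chemical's generating
  distribution has its 5th percentile at exactly 100x its true TTC (the TTC
  derivation run in reverse), so the expected ordering TTC-PoD < NOAEL-PoD
  is known;
* exposures are lognormal medians with a fixed upper95/median factor.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import TTCCategory
from .ttc import TTC_VALUES_UG_PER_KG_D

#: z such that P(Z < z) = 0.05 for standard normal Z
_Z05 = -1.6448536269514722

# ---------------------------------------------------------------------------
# template panel: (smiles, kroes_excluded) per category. Labels were fixed by
# a manual walk of the documented decision tree and alert tables; the test
# suite re-derives every label from the classifier to keep panel and code in
# lock-step.

PANEL: dict[TTCCategory, list[tuple[str, bool]]] = {
    TTCCategory.CRAMER_I: [
        ("CCO", False),  # ethanol
        ("CC(C)O", False),  # isopropanol
        ("CCCCCC", False),  # hexane
        ("Cc1ccccc1", False),  # toluene
        ("OC(=O)c1ccccc1", False),  # benzoic acid
        ("CCOC(C)=O", False),  # ethyl acetate
        ("OCC(O)CO", False),  # glycerol
        ("CC(=C)C1CCC(C)=CC1", False),  # limonene
        ("OC1CCCCC1", False),  # cyclohexanol
        ("CCCCCCO", False),  # 1-hexanol
    ],
    TTCCategory.CRAMER_II: [
        ("O=Cc1ccco1", False),  # furfural
        ("CC(=O)c1ccco1", False),  # 2-acetylfuran
        ("c1ccncc1", False),  # pyridine
        ("Cc1ccccn1", False),  # 2-methylpyridine
        ("Cc1cccnc1", False),  # 3-methylpyridine
        ("O=C1CCC1", False),  # cyclobutanone
        ("O=C1CCCCO1", False),  # delta-valerolactone
        ("C1CCOC1", False),  # tetrahydrofuran
    ],
    TTCCategory.CRAMER_III: [
        ("c1ccc2ncccc2c1", False),  # quinoline
        ("c1cnccn1", False),  # pyrazine
        ("c1ccc2ccccc2c1", False),  # naphthalene
        ("C1COCCN1", False),  # morpholine
        ("C1CCNCC1", False),  # piperidine
        ("Clc1ccccc1", False),  # chlorobenzene
        ("ClCCCl", False),  # 1,2-dichloroethane
        ("CS(C)=O", False),  # dimethyl sulfoxide
        ("Cn1cnc2c1c(=O)n(C)c(=O)n2C", False),  # caffeine
        ("C[As](C)C", True),  # trimethylarsine (organometalloid)
        ("O1c2cc(Cl)c(Cl)cc2Oc2cc(Cl)c(Cl)cc12", True),  # 2,3,7,8-TCDD
    ],
    TTCCategory.GENOTOXIC: [
        ("O=[N+]([O-])c1ccccc1", False),  # nitrobenzene
        ("Cc1ccc([N+](=O)[O-])cc1", False),  # 4-nitrotoluene
        ("CN(C)N=O", False),  # N-nitrosodimethylamine
        ("Nc1ccccc1", False),  # aniline
        ("Nc1ccc2ccccc2c1", False),  # 2-naphthylamine
        ("c1ccc(/N=N/c2ccccc2)cc1", False),  # azobenzene
        ("OCC1CO1", False),  # glycidol
        ("COS(C)(=O)=O", False),  # methyl methanesulfonate
        ("C=CC=O", False),  # acrolein
        ("CNN", False),  # methylhydrazine
        ("[O-][n+]1ccccc1", False),  # pyridine N-oxide
    ],
    TTCCategory.ANTICHOLINESTERASE: [
        ("CCOP(=O)(OCC)OCC", False),  # triethyl phosphate
        ("COP(=O)(OC)OC", False),  # trimethyl phosphate
        ("CCCCOP(=O)(OCCCC)OCCCC", False),  # tributyl phosphate
        ("CNC(=O)Oc1cccc2ccccc12", False),  # carbaryl
        ("CNC(=O)Oc1ccccc1OC(C)C", False),  # propoxur
        ("CNC(=O)Oc1cccc2c1OC(C)(C)C2", False),  # carbofuran
        ("CNC(=O)ON=C(C)SC", False),  # methomyl
        ("CC(C)(SC)C=NOC(=O)NC", False),  # aldicarb
        ("CCOC(=O)CC(SP(=S)(OC)OC)C(=O)OCC", False),  # malathion
        ("CCOP(=S)(OCC)Oc1nc(Cl)c(Cl)cc1Cl", False),  # chlorpyrifos
    ],
}

#: default category proportions, loosely shaped like a real commerce library
#: (most chemicals land in Cramer III; genotoxic alerts are common; true
#: anti-cholinesterases are a small minority)
DEFAULT_MIX: dict[TTCCategory, float] = {
    TTCCategory.GENOTOXIC: 0.25,
    TTCCategory.ANTICHOLINESTERASE: 0.05,
    TTCCategory.CRAMER_III: 0.45,
    TTCCategory.CRAMER_II: 0.05,
    TTCCategory.CRAMER_I: 0.20,
}


@dataclass(frozen=True)
class SyntheticChemical:
    chem_id: str
    smiles: str
    mw: float
    truth_category: TTCCategory
    truth_kroes_excluded: bool


def _panel_mw() -> dict[str, float]:
    from .classify import molecular_weight, parse_structure

    return {
        smiles: molecular_weight(parse_structure(smiles))
        for entries in PANEL.values()
        for smiles, _ in entries
    }


_MW_CACHE: Optional[dict[str, float]] = None


def _mw(smiles: str) -> float:
    global _MW_CACHE
    if _MW_CACHE is None:
        _MW_CACHE = _panel_mw()
    return _MW_CACHE[smiles]


def generate_chemicals(
    n: int,
    category_mix: Optional[Mapping[TTCCategory, float]] = None,
    seed: int = 0,
) -> list[SyntheticChemical]:
    """Sample ``n`` chemicals from the template panel.

    ``category_mix`` maps categories to proportions summing to 1; panel
    members within a category are sampled uniformly with replacement.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    mix = dict(category_mix) if category_mix is not None else dict(DEFAULT_MIX)
    if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("category proportions must be >= 0 and sum to 1")
    cats = [TTCCategory(c) for c in mix]
    probs = np.asarray([mix[c] for c in mix], dtype=float)
    rng = np.random.default_rng(seed)
    cat_idx = rng.choice(len(cats), size=n, p=probs)
    chems = []
    width = max(5, len(str(n)))
    for i, ci in enumerate(cat_idx):
        cat = cats[int(ci)]
        entries = PANEL[cat]
        smiles, kroes = entries[int(rng.integers(0, len(entries)))]
        chems.append(
            SyntheticChemical(
                chem_id=f"CHEM-{i + 1:0{width}d}",
                smiles=smiles,
                mw=_mw(smiles),
                truth_category=cat,
                truth_kroes_excluded=kroes,
            )
        )
    return chems


def generate_bioactivity(
    chems: Sequence[SyntheticChemical],
    n_assays_range: tuple[int, int] = (1, 30),
    logmean: float = float(np.log(1.0)),
    logsd: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-chemical lognormal AC50 rows (chem_id, assay_id, ac50_uM)."""
    if not chems:
        raise ValueError("generate_bioactivity requires a non-empty chemical list")
    lo, hi = n_assays_range
    if not (1 <= lo <= hi <= 200):
        raise ValueError(f"n_assays_range must lie within [1, 200], got {n_assays_range}")
    if not (np.isfinite(logmean) and np.isfinite(logsd) and logsd >= 0):
        raise ValueError("lognormal parameters must be finite (logsd >= 0)")
    rng = np.random.default_rng(seed)
    rows = []
    for chem in chems:
        k = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        ac50 = np.exp(rng.normal(logmean, logsd, k)) if logsd > 0 else np.full(
            k, np.exp(logmean)
        )
        for j, v in enumerate(ac50, start=1):
            rows.append(
                {"chem_id": chem.chem_id, "assay_id": f"ASSAY-{j:03d}", "ac50_uM": float(v)}
            )
    return pd.DataFrame(rows)


def generate_pk(
    chems: Sequence[SyntheticChemical],
    seed: int = 0,
    fup_logit_mean: float = -2.0,
    fup_logit_sd: float = 1.0,
    clint_logmean: float = float(np.log(10.0)),
    clint_logsd: float = 1.0,
    zero_clint_fraction: float = 0.1,
) -> pd.DataFrame:
    """Logit-normal fup and lognormal Clint rows (chem_id, fup, clint).

    ``zero_clint_fraction`` puts a point mass at Clint = 0 for chemicals
    that are not hepatically metabolized.
    """
    if not chems:
        raise ValueError("generate_pk requires a non-empty chemical list")
    if not (0.0 <= zero_clint_fraction <= 1.0):
        raise ValueError("zero_clint_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    logits = rng.normal(fup_logit_mean, fup_logit_sd, len(chems))
    fup = 1.0 / (1.0 + np.exp(-logits))
    clint = np.exp(rng.normal(clint_logmean, clint_logsd, len(chems)))
    zero = rng.random(len(chems)) < zero_clint_fraction
    clint = np.where(zero, 0.0, clint)
    return pd.DataFrame(
        {
            "chem_id": [c.chem_id for c in chems],
            "fup": np.clip(fup, np.nextafter(0, 1), 1.0),
            "clint": clint,
        }
    )


def generate_noael_sets(
    chems: Sequence[SyntheticChemical],
    ttc_consistent: bool = True,
    seed: int = 0,
    n_range: tuple[int, int] = (1, 40),
    logsd: float = 1.0,
    logmean: float = float(np.log(50.0)),
    decoy_fraction: float = 0.2,
) -> pd.DataFrame:
    """Per-chemical NOAEL records (chem_id, type, value, units, route).

    With ``ttc_consistent=True`` each chemical's NOAELs are lognormal with
    the generating distribution's 5th percentile pinned at 100x its true
    TTC (in mg/kg-d) — the TTC derivation run in reverse, so the expected
    TTC-PoD < NOAEL-PoD ordering is known by construction. A
    ``decoy_fraction`` of additional rows carries a wrong type, units or
    route to exercise record filtering.
    """
    if not chems:
        raise ValueError("generate_noael_sets requires a non-empty chemical list")
    lo, hi = n_range
    if not (1 <= lo <= hi <= 40):
        raise ValueError(f"n_range must lie within [1, 40], got {n_range}")
    if not (0.0 <= decoy_fraction <= 1.0):
        raise ValueError("decoy_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    decoy_fields = [
        {"type": "LOAEL"},
        {"units": "ppm"},
        {"route": "inhalation"},
    ]
    for chem in chems:
        if ttc_consistent:
            ttc_mg = TTC_VALUES_UG_PER_KG_D[chem.truth_category] / 1000.0
            target_p5 = 100.0 * ttc_mg
            mu = float(np.log(target_p5) - _Z05 * logsd)
        else:
            mu = logmean
        k = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        values = np.exp(rng.normal(mu, logsd, k))
        for v in values:
            rows.append(
                {
                    "chem_id": chem.chem_id,
                    "type": "NOAEL",
                    "value": float(v),
                    "units": "mg/kg-day",
                    "route": "oral",
                }
            )
        n_decoys = int(round(decoy_fraction * k))
        for _ in range(n_decoys):
            row = {
                "chem_id": chem.chem_id,
                "type": "NOAEL",
                "value": float(np.exp(rng.normal(mu, logsd))),
                "units": "mg/kg-day",
                "route": "oral",
            }
            row.update(decoy_fields[int(rng.integers(0, len(decoy_fields)))])
            rows.append(row)
    return pd.DataFrame(rows)


def generate_exposures(
    chems: Sequence[SyntheticChemical],
    logmean: float = float(np.log(1e-6)),
    logsd: float = 2.0,
    upper95_factor: float = 10.0,
    seem2_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """One exposure row per chemical (chem_id, source, median, upper95).

    ``upper95 = median * upper95_factor``; a ``seem2_fraction`` of chemicals
    is labeled source=SEEM2 (fallback model), the rest SEEM3.
    """
    if not chems:
        raise ValueError("generate_exposures requires a non-empty chemical list")
    if upper95_factor < 1.0:
        raise ValueError(f"upper95_factor must be >= 1, got {upper95_factor}")
    if not (0.0 <= seem2_fraction <= 1.0):
        raise ValueError("seem2_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    medians = np.exp(rng.normal(logmean, logsd, len(chems)))
    seem2 = rng.random(len(chems)) < seem2_fraction
    return pd.DataFrame(
        {
            "chem_id": [c.chem_id for c in chems],
            "source": np.where(seem2, "SEEM2", "SEEM3"),
            "median": medians,
            "upper95": medians * upper95_factor,
        }
    )


@dataclass
class SyntheticBundle:
    """All five input tables plus the truth sidecar for one simulation."""

    chemicals: pd.DataFrame
    bioactivity: pd.DataFrame
    pk: pd.DataFrame
    noael: pd.DataFrame
    exposure: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_csv

        write_csv(self.chemicals, out / "chemicals.csv")
        write_csv(self.bioactivity, out / "bioactivity.csv")
        write_csv(self.pk, out / "pk.csv")
        write_csv(self.noael, out / "noael.csv")
        write_csv(self.exposure, out / "exposure.csv")
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def generate_bundle(
    n: int,
    seed: int = 0,
    ttc_consistent: bool = True,
    category_mix: Optional[Mapping[TTCCategory, float]] = None,
    noael_n_range: tuple[int, int] = (1, 40),
    **noael_kwargs,
) -> SyntheticBundle:
    """Generate the full set of input tables for ``n`` chemicals.

    Sub-generators receive independent child seeds derived from ``seed`` so
    the bundle is reproducible as a whole.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    chems = generate_chemicals(n, category_mix=category_mix, seed=seeds[0])
    chemicals = pd.DataFrame(
        {
            "chem_id": [c.chem_id for c in chems],
            "smiles": [c.smiles for c in chems],
            "mw": [c.mw for c in chems],
        }
    )
    truth = {
        c.chem_id: {
            "category": c.truth_category.value,
            "kroes_excluded": c.truth_kroes_excluded,
            "smiles": c.smiles,
        }
        for c in chems
    }
    return SyntheticBundle(
        chemicals=chemicals,
        bioactivity=generate_bioactivity(chems, seed=seeds[1]),
        pk=generate_pk(chems, seed=seeds[2]),
        noael=generate_noael_sets(
            chems,
            ttc_consistent=ttc_consistent,
            seed=seeds[3],
            n_range=noael_n_range,
            **noael_kwargs,
        ),
        exposure=generate_exposures(chems, seed=seeds[4]),
        truth=truth,
    )
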