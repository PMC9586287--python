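"""Steady-state in vitro-to-in vivo extrapolation (reverse dosimetry).

The oral equivalent dose (OED) is the constant daily oral intake whose
steady-state plasma concentration equals the in vitro bioactive
concentration. The plasma steady state under a 1 mg/kg-bw/d infusion is

    Css = (1/24) / ( GFR * fup  +  Q_l * fup * Cl_w / (Q_l + fup * Cl_w) )

i.e. the hourly dose rate divided by total plasma clearance: renal
filtration of unbound drug plus restrictive well-stirred hepatic clearance,
with 100% oral absorption and blood/plasma ratio 1. Cl_w is whole-body
intrinsic clearance, scaled up from the hepatocyte assay via
hepatocellularity and liver mass.

Population variability enters by Monte Carlo over the physiological
parameters (and fup / Clint); the conservative exposure-side summary is the
95th percentile Css, so

    OED (mg/kg-bw/d) = AC50_p5 (µM) * MW / 1000 / Css_p95.

The AC50 5th percentile and the Css 95th percentile both use the type-2
empirical quantile shared with the NOAEL module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .pod import quantile_type2
from .records import OEDResult

AC50_PERCENTILE = 0.05
CSS_PERCENTILE = 0.95


@dataclass(frozen=True)
class Physiology:
    """Adult-human physiology for the steady-state model.

    Units: gfr and q_liver in L/h/kg bw; hepatocellularity in 10^6 cells/g
    liver; liver_mass in g/kg bw. ``cv_*`` are lognormal coefficients of
    variation for the population Monte Carlo (0 switches a term off).
    """

    gfr: float = 0.1
    q_liver: float = 1.45
    hepatocellularity: float = 110.0
    liver_mass: float = 25.7
    cv_gfr: float = 0.2
    cv_q_liver: float = 0.2
    cv_hepatocellularity: float = 0.2
    cv_liver_mass: float = 0.2
    cv_fup: float = 0.3
    cv_clint: float = 0.3
    fup_floor: float = 0.005

    def __post_init__(self):
        for name in ("gfr", "q_liver", "hepatocellularity", "liver_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"physiology parameter {name} must be > 0")


@dataclass(frozen=True)
class PKInput:
    chem_id: str
    fup: float  # fraction unbound in plasma, (0, 1]
    clint: float  # µL/min/10^6 hepatocytes, >= 0
    mw: float  # g/mol


def load_physiology(path: Optional[str] = None) -> Physiology:
    """Physiology from a YAML file (package defaults when no path given)."""
    if path is None:
        text = (
            resources.files("moescreen") / "data" / "physiology.yaml"
        ).read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return Physiology(**yaml.safe_load(text))


def ac50_percentile(ac50s: Sequence[float], p: float = AC50_PERCENTILE) -> float:
    """Type-2 empirical quantile of a chemical's AC50 values (µM)."""
    vals = [float(v) for v in ac50s]
    if not vals:
        raise ValueError("ac50_percentile requires at least one AC50")
    if any(v <= 0 for v in vals):
        raise ValueError("AC50 values must be positive")
    return quantile_type2(vals, p)


def scale_clint(clint: float, phys: Physiology) -> float:
    """Hepatocyte assay clearance to whole-body clearance, L/h/kg bw.

    µL/min/10^6 cells x (10^6 cells/g liver) x (g liver/kg bw) x 60 min/h
    x 1e-6 L/µL.
    """
    if clint < 0:
        raise ValueError(f"clint must be >= 0, got {clint}")
    return clint * phys.hepatocellularity * phys.liver_mass * 60.0 * 1e-6


def apply_fup_floor(fup: float, phys: Physiology) -> float:
    if fup < phys.fup_floor:
        warnings.warn(
            f"fup {fup} below floor {phys.fup_floor}; floored",
            stacklevel=2,
        )
        return phys.fup_floor
    return min(fup, 1.0)


def css_unit_dose(fup: float, clint_whole: float, phys: Physiology) -> float:
    """Steady-state plasma concentration per unit dose rate, mg/L per mg/kg/d.

    Renal clearance GFR*fup plus restrictive well-stirred hepatic clearance;
    the daily dose is treated as a continuous infusion ((1/24) mg/kg/h).
    """
    if fup <= 0:
        raise RuntimeError("fup must be positive after flooring")
    hepatic = (
        phys.q_liver * fup * clint_whole / (phys.q_liver + fup * clint_whole)
        if clint_whole > 0
        else 0.0
    )
    clearance = phys.gfr * fup + hepatic  # L/h/kg
    return (1.0 / 24.0) / clearance


def css_population_p95(
    pk: PKInput,
    phys: Physiology,
    n_samples: int = 1000,
    seed: int = 0,
    percentile: float = CSS_PERCENTILE,
) -> float:
    """95th-percentile Css over a simulated population, mg/L per mg/kg-bw/d.

    Each of the ``n_samples`` virtual individuals draws physiology, fup and
    Clint lognormally around the stated means with the stated CVs (mean
    preserved; fup capped at 1, floored at ``fup_floor``).
    """
    if n_samples < 100:
        raise ValueError(f"n_samples must be >= 100, got {n_samples}")
    rng = np.random.default_rng(seed)

    def draw(mean: float, cv: float) -> np.ndarray:
        if cv <= 0 or mean == 0:
            return np.full(n_samples, mean)
        sigma2 = np.log1p(cv**2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), n_samples)

    gfr = draw(phys.gfr, phys.cv_gfr)
    q_liver = draw(phys.q_liver, phys.cv_q_liver)
    hep = draw(phys.hepatocellularity, phys.cv_hepatocellularity)
    liver = draw(phys.liver_mass, phys.cv_liver_mass)
    fup = np.clip(draw(pk.fup, phys.cv_fup), phys.fup_floor, 1.0)
    clint = draw(pk.clint, phys.cv_clint)

    clint_whole = clint * hep * liver * 60.0 * 1e-6
    hepatic = np.where(
        clint_whole > 0,
        q_liver * fup * clint_whole / (q_liver + fup * clint_whole),
        0.0,
    )
    css = (1.0 / 24.0) / (gfr * fup + hepatic)
    return quantile_type2(css.tolist(), percentile)


def oed_from_ac50(ac50_p5: float, mw: float, css95: float) -> float:
    """Oral equivalent dose, mg/kg-bw/d.

    AC50 (µM) x MW (g/mol) / 1000 converts to mg/L; dividing by the
    95th-percentile Css per unit dose gives the administered dose whose
    steady state matches the in vitro concentration.
    """
    if ac50_p5 <= 0 or mw <= 0:
        raise ValueError("ac50_p5 and mw must be positive")
    if css95 <= 0:
        raise RuntimeError("css95 must be positive")
    return (ac50_p5 * mw / 1000.0) / css95


def oed_for_chemical(
    ac50s: Sequence[float],
    pk: PKInput,
    phys: Optional[Physiology] = None,
    n_samples: int = 1000,
    seed: int = 0,
) -> OEDResult:
    """AC50 5th percentile -> population Css 95th percentile -> OED."""
    phys = phys or Physiology()
    pk = replace(pk, fup=apply_fup_floor(pk.fup, phys))
    p5 = ac50_percentile(ac50s)
    css95 = css_population_p95(pk, phys, n_samples=n_samples, seed=seed)
    return OEDResult(
        chem_id=pk.chem_id,
        ac50_p5=p5,
        css95=css95,
        oed=oed_from_ac50(p5, pk.mw, css95),
    )
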