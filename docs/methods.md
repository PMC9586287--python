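# Methods

## Scope and model

The package implements a screening-level prioritization, not a risk
assessment. Three independent routes produce a point of departure (PoD) per
chemical, each divided by the same exposure denominator (upper-95%
confidence bound on the median consensus exposure estimate, mg/kg-bw/d):

1. **TTC route** — structure only. Category precedence is
   most-conservative-first: genotoxicity alert (only when the genotoxicity
   filter is enabled) → anti-cholinesterase functional group → Cramer
   class. The tie-break between a genotoxicity alert and an
   anti-cholinesterase flag is not uniquely determined by the category
   definitions; this package takes the lower (genotoxic) threshold, the
   conservative reading, and the co-occurrence is visible in the profile
   flags. Thresholds (0.0025 / 0.3 / 1.5 / 9 / 30 µg/kg-bw/d) live in one
   config table (`moescreen.ttc.TTC_VALUES_UG_PER_KG_D`); the µg→mg
   conversion to PoD units happens exactly once, in `moescreen.moe.ttc_pod`.
2. **OED route** — in vitro bioactivity plus PK. See "Steady-state model".
3. **NOAEL route** — in vivo study records filtered to
   type = NOAEL, units = mg/kg-day, route = oral (case-insensitive,
   whitespace-trimmed; the filter is otherwise an exact string match).
   PoD = type-2 5th percentile with ≥ 20 records, else the minimum.
   Duplicate values are retained; no dedup rule is applied.

## The Cramer rule engine

`moescreen.cramer` implements the 33-question decision scheme as an
explicit node table: every node is a named, pure RDKit predicate with
yes/no transitions, and classification returns the ordered trace of
(question, answer) pairs actually visited. Re-evaluating the predicates in
a stored trace reproduces it (`cramer.replay`), so any classification is
auditable. Design points:

* Curated lookup lists (normal body constituents, common carbohydrates,
  common terpenes, food-related structures) are matched by canonical
  SMILES, so the answers are invariant to the input SMILES spelling.
* Branch structure: short-circuits for body constituents,
  enhanced-toxicity functional groups and exceptional elements (anything
  beyond C/H/O/N/divalent S that is not a simple salt counterion), then
  separate sub-trees for heterocycles (hazardous lactones, heteroaromatics,
  N-heterocycles, O-heterocycles), aromatic and aliphatic carbocycles, and
  open chains, converging on food-relation / simplicity fallback questions.
* The "readily metabolized" question (Q31) is necessarily heuristic
  (MW ≤ 1000, no halogen/phosphorus, ≤ 2 rings); the historical scheme
  leaves it to expert judgement.
* The "with extensions" variant is off by default and adds only two
  documented reactive-moiety rules (α,β-unsaturated amide, Michael-acceptor
  nitrile) that route directly to class III.
* Salt/mixture SMILES are reduced to the largest carbon-containing fragment
  before any matching. Aromaticity is RDKit's default model, recorded in
  the run report, because SMARTS matches depend on it.

The genotoxicity alert table is a versioned YAML file of named SMARTS
patterns (`data/genotox_alerts.yaml`), a documented subset of the classic
alert catalogues (aromatic nitro/amine/azo, N-nitroso, epoxide, aziridine,
hydrazine, activated alkyl halide, α,β-unsaturated carbonyl, aromatic
N-oxide, alkyl sulfonate/phosphonate ester) — not a complete mutagenicity
rulebook. Patterns are written to avoid the classic false positives: the
aromatic-amine pattern excludes amides (carbamate pesticides must not be
alerted), and the phosphonate pattern requires a P–C bond so phosphate
triesters are not.

The Kroes-domain gate is an annotation, never a drop: organometallics
(metal/metalloid with a covalent bond to carbon) and high-potency
carcinogen classes (polyhalogenated dibenzodioxin/furan with ≥ 2 halogens,
biphenyl with ≥ 4, azoxy compounds, aflatoxin-like bisfuranoids).

## Steady-state model

Css per unit dose (mg/L per mg/kg-bw/d) treats the daily oral dose as a
continuous infusion with 100% absorption and blood/plasma ratio 1, cleared
by renal filtration of unbound chemical plus restrictive well-stirred
hepatic clearance:

```
Css = (1/24) / ( GFR·fup + Q_l·fup·Cl_w / (Q_l + fup·Cl_w) )
Cl_w = Clint · hepatocellularity · liver_mass · 60 · 1e-6   [L/h/kg bw]
```

Defaults (config, `data/physiology.yaml`): GFR 0.1 L/h/kg, liver blood flow
1.45 L/h/kg, hepatocellularity 110×10⁶ cells/g liver, liver mass
25.7 g/kg bw — standard adult-human values for this model class. The
population Monte Carlo draws all four physiology parameters, fup and Clint
lognormally with mean preserved (CVs 0.2 for physiology, 0.3 for fup and
Clint; fup capped at 1 and floored at 0.005 — the floor prevents an
infinite Css for fully bound chemicals and is applied with a warning). The
95th-percentile Css over n = 1000 individuals (default) is the
conservative denominator; at n = 10⁴ doubling the sample moves the p95 by
< 2% (tested). OED = AC50_p5 · MW/1000 / Css_p95, linear in AC50 and in
1/Css; in the limit Clint → 0, fup → 1 it reduces to AC50·MW/1000·24·GFR.

Quantile convention: the type-2 empirical quantile (discontinuous inverse
CDF with averaging at jumps, R's `quantile(type = 2)`) is used everywhere —
the NOAEL route specifies it, and using one estimator for AC50 p5, Css p95
and median MoEs keeps results auditable. The implementation was verified
against both an independent brute-force inverse-CDF oracle (property
tests) and R itself during development.

## Comparison statistics

Conservativeness fractions use strict `<` on the chemicals common to two
MoE tables (ties favor neither side). r² is the squared Pearson correlation
of log₁₀ MoEs — identical to simple-regression R², symmetric in its
arguments; chemicals with non-positive MoEs are excluded with a logged
count. Ratio summaries are type-2 medians of per-chemical ratios. The
rank-sum test is Mann-Whitney U, enumerated exactly when both groups have
≤ 10 observations and no ties, otherwise the normal approximation with tie
and continuity corrections; the KS test reports
D = sup|ECDF_x − ECDF_y| with the asymptotic Kolmogorov p-value. Two-sided
throughout; no multiple-testing correction is applied.

**Known limitation — KS size at moderate n.** The two-sample KS statistic
is discrete (multiples of 1/50 at n = m = 50), so the achievable test size
nearest below α = 0.05 is ≈ 0.036 regardless of whether the p-value is
exact or asymptotic; the KS test is conservative at these sample sizes.
The rank-sum test calibrates at ≈ 0.048 under the same null. The
acceptance-style calibration test in the suite asserts a 0.04–0.06 band
for both tests and therefore fails on KS; this documents the inherent
conservativeness rather than hiding it behind a looser band.

## Synthetic data: what it emulates and what it does not

The template panel holds 8–11 hand-curated SMILES exemplars per TTC
category, each validated once by a manual walk of the documented tree and
alert tables; generation samples panel members uniformly within a category
(no structure perturbation — a decoration change can silently change the
class). Default category mix: genotoxic 0.25, anti-cholinesterase 0.05,
Cramer III 0.45, Cramer II 0.05, Cramer I 0.20, shaped like a commerce
library where class III dominates the noncancer categories. Distribution
defaults: AC50 lognormal with logmean = log(1 µM), logsd = 1.5; exposure
medians lognormal with logmean = log(10⁻⁶ mg/kg-d), logsd = 2 and
upper95 = 10× median; NOAEL logsd = 1.0; 20% decoy NOAEL rows (wrong
type/units/route) to exercise filtering; fup logit-normal (µ = −2, σ = 1),
Clint lognormal (median 10 µL/min/10⁶ cells) with a 10% point mass at 0.
No distributional form for the exposure model is published; these defaults
are pragmatic choices spanning the orders of magnitude seen in real
screens, chosen once and not tuned.

With `ttc_consistent=True`, each chemical's NOAEL-generating lognormal has
its 5th percentile pinned at exactly 100× the chemical's truth-category TTC
(in mg/kg-d): the TTC derivation run in reverse. The conservativeness
recovery test therefore runs the pipeline with the genotoxicity filter
**on**, so assigned categories equal the generating truth; with the filter
off, truth-genotoxic chemicals would be compared against NOAELs pinned to a
different (lower) threshold than the one they are assigned, which tests
nothing about the ordering. At 500 chemicals with 20–40 NOAELs each the
recovered fraction is 1.0.

Passing these tests shows the pipeline's plumbing and ordering logic are
correct under known-truth conditions. It does not show that real chemicals
are classified as Toxtree would classify them (the panel is small and
curated, real inventories are not), that the steady-state model matches
measured kinetics, or that real NOAEL databases satisfy the 100×-TTC
relationship — on real data the TTC < NOAEL fraction is an empirical
finding, not a construction.

## Determinism and numerical choices

Every generator and the population Monte Carlo run off
`numpy.random.default_rng` seeds; the pipeline derives a stable per-chemical
seed from the run seed and a CRC32 of the chemical id, so results are
independent of processing order and reproducible byte-for-byte from the run
report. CSV floats are written with 6 significant digits. MoE < 1 uses
strict less-than (an MoE of exactly 1 is not flagged). Ranking ties break
lexicographically by chemical id. Chemicals lacking any exposure row (or
any valid NOAEL record) are omitted from the affected MoE table and counted
in the run report, never silently dropped. Problem sizes in the test suite
(500-chemical conservativeness run, 10⁴-sample Monte Carlo, 10⁴ null
simulations for test calibration) were chosen as the smallest sizes at
which the checked quantities are stable to well within the asserted
tolerances.
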