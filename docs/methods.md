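# Methods

This note documents the model assumptions, default parameters, numerical
choices and known limitations of `feedsel`. Everything stated here is
computed by the package's tests or examples; nothing is an external claim.

## Traits and parameters

The breeding goal holds ten traits: fat yield (FY, kg/305 d), protein yield
(PY, kg), body condition score (BCS, 1–5 score), stature (STAT, cm), age at
first service (AFS, days), first service to conception (FSTC, days),
clinical ketosis (CK, 0/1 case), displaced abomasum (DA, 0/1 case), dry
matter intake (DMI, kg DM/day) and residual feed intake (RFI, kg DM/day).
Favorable direction is +1 for production and DMI, −1 for the fertility
intervals, diseases and RFI.

Per-trait genetic and phenotypic SDs, heritabilities and GEBV accuracies
are shipped as a CSV fixture (`feedsel/data/trait_params.csv`). The
consistency check h² ≈ (σ_g/σ_p)² is a warning rather than an error by
default: the shipped core-trait rows (FY, PY, BCS, STAT) fail it — their
σ values and h² estimates originate from different models/scales in the
source material — and the package preserves the values as published rather
than "fixing" either number. `consistency="strict"` upgrades the check to
an error for user-supplied fixtures.

## Correlation structure and the synthetic core block

Only the DMI and RFI rows of the 10×10 genetic and phenotypic correlation
matrices are available (with standard errors); the core 8×8 block is not.
`generate_core_correlations` fills the missing cells with seeded uniform
draws (default magnitude in [0, 0.30], random or constrained sign) and
restores validity by alternating eigenvalue clipping (floor 1e−6) with
re-imposition of the known cells.

Two facts about this construction, both verified in the test suite:

- The known **genetic** cells admit an exact positive-definite completion;
  they survive the repair bit-exactly and are identical across seeds.
- The known **phenotypic** cells do not: the (DMI, RFI, CK) phenotypic
  triple (0.82, 0.23, −0.32) already has a negative determinant, so *no*
  valid correlation matrix reproduces every published phenotypic cell. The
  repair therefore releases the pins on its final pass and records the
  largest movement of a known cell (`CorrelationSet.pin_deviation`;
  observed ≤ 0.008, an order of magnitude inside the published standard
  errors of 0.02–0.21). Movements beyond 0.10 raise instead.

Every downstream result that touches the core block depends on this
synthetic fill and is therefore model-relative: scenario outputs are
comparable across scenarios run on the same seed, not to published
absolute response tables. The SE-shrunk scenario variants move each known
feed-efficiency correlation toward zero by one standard error, clamping at
zero; by default both genetic and phenotypic rows are shrunk, with a
`which="g"|"p"|"both"` switch, since the source text says only that "the
genetic parameters were adjusted" without excluding the phenotypic rows.

PD repair is eigenvalue clipping at a configurable floor followed by
diagonal renormalisation, iterated to a fixed point so the operation is
idempotent; it is deterministic and label-preserving.

## Phenotype simulator

`simulate_phenotypes` emulates first-lactation records at desk scale. The
real analysis fits animal models with a numerator relationship matrix by
REML; this package instead uses paternal half-sib families with an
ANOVA/method-of-moments estimator (h² = 4σ̂²_sire/(σ̂²_sire + σ̂²_within)),
which preserves the testable quantity — heritability recovery — without a
pedigree REML engine.

The record model per trait is
mean + year-season effect (66 levels) + age-class effect (6 levels)
+ sire transmitting ability (covariance Σ_a/4) + herd-year effect
+ within-family residual (Σ_e + 3Σ_a/4). Heritability is defined against
the full phenotypic variance σ²_a + σ²_h + σ²_e, matching what the
half-sib estimator converges to when only the fixed factors are absorbed.

Default variance components derive from an energy-sink composition chosen
analytically (before any simulation) to land on the published scale:

    DMI = 0.32·ECM + 0.135·MBW + R

with ECM (σ_p 5.0 kg/day, h² 0.35), BW (σ_p 60 kg, h² 0.40, correlated
0.10 with ECM genetically and phenotypically) and an independent intake
residual R (σ_p 2.5 kg/day, h² 0.13, 10% herd-year). The BW^0.75
nonlinearity is linearised by the delta method at BW = 650 kg when
composing covariances; records use the exact power. Implied defaults:
σ_p(DMI) ≈ 3.26 kg/day, h²(DMI) ≈ 0.229, and the regression-derived RFI
has σ_p ≈ 2.5 with h² ≈ 0.13. Year-season and age-class effect SDs default
to 0.25 and 0.10 of each trait's σ_p.

What the generator does **not** emulate: multi-station standardisation,
multi-lactation/random-regression intake curves, selection or assortative
mating within the simulated population, pedigree structure beyond
half-sibs, and the ECM energy-correction formula (ECM is simulated
directly as a trait). Passing recovery tests therefore show the estimators
are correct under the stated generative model, not that real data meet
that model. The regression R² of the RFI model on simulated defaults
(~0.36) is a property of these choices, not a target.

`compute_rfi` fits DMI on an intercept, ECM and MBW by OLS (optionally
pre-adjusting herd-year means) and attaches R² and coefficients to the
returned table. Zero-variance regressors are dropped with a warning so
degenerate inputs (constant MBW) reduce to the smaller regression; rank
deficiency among varying regressors raises.

## Index machinery

Sources are one GEBV per trait. The default covariance convention is the
pseudo-phenotype treatment cov(GEBV_i, GEBV_j) = cov(GEBV_i, g_j) =
r_i r_j rg_ij σ_gi σ_gj, which makes P = G, reproduces the single-trait
closed form ΔG = i·r·σ_g, and implies b = v (asserted, and exploited to
avoid an ill-conditioned solve — P spans variances from 0.03² to 30.67²).
The alternative `convention="squared"` (r_i² on G's columns) is available
because the upstream software's internal convention is not published.

Restrictions: Kempthorne–Nordskog constrained weights
b = [I − P⁻¹G_r(G_r'P⁻¹G_r)⁻¹G_r']P⁻¹Gv. Holding by economic value:
responses are linear in v, so a single trait is held by bisection on a
±10⁴ bracket (tolerance 1e−8 in response units) and several traits by the
exact linear solve M_HH v_H = −M_HF v_F with M = G'P⁻¹G. Under P = G both
routes coincide; the tests check agreement to 1e−6 rather than assuming
it. Degenerate indices (σ_I = 0, e.g. all traits restricted) return zero
responses with an explicit flag instead of dividing by zero.

Selection intensity is i = φ(z_p)/p from the standard normal; progeny-test
accuracy r = √(n/(n+λ)), λ = (4−h²)/h², is provided for sensitivity runs
but the default treats a single GEBV source per pathway, since one genomic
accuracy per trait is what the parameter table supplies.

## Gene flow and pathways

Classes are B1–B5 and C1–C5 (class 1 = newborn, yearly steps, transmission
at the start of each step). The constructor splits newborn rows 0.5/0.5
between sire and dam sources: bull calves are sired by genomic bulls (ages
2–4, elite-dam matings) and born to elite cows (ages 2–5); heifer calves
mix 70% genomic (ages 2–4) and 30% proven (ages 4–5) sires over milking-
herd dams. Rows sum to exactly 1; the published rounded matrix is matched
within 0.005 per entry and kept as a regression fixture.

Generation intervals are not published; they derive from the age classes
(genomic bulls 3.0 y, proven 4.5 y, cows 3.0 y; sires-of-dams blend
0.7·3.0 + 0.3·4.5 = 3.45 y) and are config-exposed. Pathway selected
proportions come from the printed counts (7%, 7%, 10%, 85%). Annual
response is ΣΔG_path/ΣL_path.

Monetary totals price the annual response vector with each trait's
economic value times the discounted gene-flow expressions of a newborn
female (expressing classes C2–C4, discount rate 0.05/yr, horizon 15 yr —
defaults chosen as conventional breeding-program values, config-
overridable). The published monetary accounting is not available, so these
totals are explicitly model-relative; published-table contrasts are
computed on the embedded published report fixture instead.

## Scenarios and reporting

The catalog is BASE, {DMI,RFI}×{C,P,N}, each also in an `_SD` variant with
SE-shrunk correlations (14), plus RFI_P2–P5 (18 total). Favorable pressure
is +88.45 CAD on DMI and −88.45 on RFI, reversed for unfavorable; hold
scenarios zero the trait via the joint linear solve together with stature,
which is held in every scenario. Health/fertility economic values are the
literature constants (AFS 2.57, FSTC 6.86, CK 233, DA 707 CAD) with
negative sign; BCS carries no direct value by default (its published
weighting is unknown; config-driven override available).

Cumulative intake response over rounds supports linear and compound modes
(compound applies the per-round relative gain to a compounding base mean,
default 23 kg DM/day); the published 10-generation figures are treated as
report-fixture values because the exact compounding rule is not published.
Reports round half-even to 2 decimals, matching the published table's
presentation, and writing the embedded published fixture reproduces its
bytes exactly.

## Problem sizes

Defaults keep everything desk-scale: phenotype recovery tests use 300
sires × 30 daughters × 20 seeds (≈ 5.4M records total across the suite),
the grid-search index oracle enumerates ~8M weight vectors vectorised, and
the full 18-scenario catalog solves in well under a second. These sizes
were chosen so every property is estimable with comfortable margins (the
ANOVA SE of h² at 300×30 is ≈ 0.03 against the ±0.05 acceptance band).
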