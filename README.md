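# feedsel

Deterministic evaluation of feed-efficiency traits in a dairy-cattle
selection index.

Dairy breeding goals are slowly absorbing feed efficiency. The candidate
traits are **dry matter intake** (DMI, kg DM/day — indirect selection) and
**residual feed intake** (RFI — direct selection), where RFI is the residual
of the fixed linear regression of DMI on the energy sinks: energy-corrected
milk (ECM) and metabolic body weight (MBW = BW^0.75). A cow with negative
RFI eats less than her production and maintenance predict.

`feedsel` models what happens when either trait enters a ten-trait index
(fat and protein yield, body condition score, stature, age at first
service, first service to conception, clinical ketosis, displaced
abomasum, DMI, RFI) in a genomically driven breeding program. It is a
library for quantitative geneticists and breeding-program modellers; the
public face is the importable API plus the narrative scripts in
`examples/`.

## What it computes

**Selection index theory on GEBV sources.** With one genomic breeding value
per trait (accuracy r_i), sources x and aggregate genotype H = v'g, the
optimal index I = b'x has b = P⁻¹Gv with P = var(x), G = cov(x, g). Under
the pseudo-phenotype treatment P = G, so b = v, and responses per round are
ΔG = i·G'b/σ_I at selection intensity i = φ(z_p)/p. Zero-gain constraints
come two equivalent ways: the Kempthorne–Nordskog restricted index and
root-finding on a trait's economic value (used to hold stature constant in
every scenario).

**Gene flow.** A 10-class (sex × age) allele-flow matrix built from the
program structure — 30,000 genotyped bull calves, 2,100 genomic bulls (7%),
100 proven bulls, 500,000 heifer calves, 425,000 milking cows, 50,000 elite
dams, 70/30 genomic/proven herd matings — reproduces the published matrix
to printed rounding, propagates genes through time, and discounts lactation
expressions. Responses aggregate over the four pathways
(Rendel–Robertson: ΔG_annual = ΣΔG_path / ΣL_path).

**Economics.** Production traits are priced v = R − C1·DMP1 (fat 9.02,
protein 7.16 CAD/kg); intake traits carry the lactation feed cost of a
1 kg/day change (0.29 × 305 = 88.45 CAD), scaled 1–5× in the RFI
weight-scaling experiment.

**Scenarios.** The 14-scenario catalog (BASE and hold/positive/negative
pressure on DMI or RFI, each with estimated or SE-shrunk correlations) plus
RFI_P2–P5, producing a per-scenario report of annual responses in genetic
standard deviation units (SDU) and a model-relative monetary total.

**Synthetic data.** Only the feed-efficiency rows of the correlation
matrices are published; `feedsel.synthetic_data` completes the core-trait
block reproducibly (printed genetic cells preserved exactly, matrices
repaired to positive definiteness) and simulates half-sib phenotype records
whose derived RFI targets the published heritabilities (h² DMI 0.23, RFI
0.13). See `docs/methods.md` for what the generator does and does not
emulate.

## Worked example

```python
import feedsel as fs

params, _ = fs.load_parameter_fixtures(consistency="ignore")
corr = fs.generate_core_correlations(seed=2021)   # fill the unpublished block
results = fs.run_catalog(params, corr)
print(fs.scenarios.results_to_report(results).loc[["BASE", "RFI_P", "RFI_P5"]])
```

```
           FY    PY   BCS  STAT   AFS  FSTC    CK    DA   DMI   RFI  total_cad
scenario
BASE     0.32  0.18  0.05  -0.0 -0.06 -0.04 -0.02 -0.06  0.19  0.01     729.56
RFI_P    0.32  0.18  0.04   0.0 -0.04 -0.04 -0.02 -0.05  0.16 -0.01     730.88
RFI_P5   0.29  0.14 -0.02   0.0  0.03 -0.03 -0.01 -0.02  0.06 -0.09     836.00
```

Each row is one scenario's annual genetic gain per trait in SDU. Without
selection pressure (BASE) RFI drifts slightly unfavorably (+0.01 SDU/yr)
while intake rises with production. Favorable pressure on RFI (RFI_P)
reverses the drift at almost no cost elsewhere; quintupling the weight
(RFI_P5) pulls RFI to −0.09 SDU/yr but erodes fat and protein gain and
turns body condition score and fertility responses unfavorable — the
trade-off the weight-scaling experiment quantifies. Stature is held at zero
in every scenario by optimising its economic value. Monetary totals are
model-relative (this package's own gene-flow discounting; the unpublished
core-trait correlations are synthetic), so compare them across scenarios,
not to published accounting.

The other capabilities each have a short script: `examples/
economic_values.py`, `simulate_rfi_phenotypes.py`,
`selection_index_basics.py`, `gene_flow_structure.py`, `run_scenarios.py`.

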