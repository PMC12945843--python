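# hspscreen

Predictive preformulation screening of drug–excipient miscibility for
amorphous formulations (polymeric solid dispersions, mesoporous silica
carriers, co-amorphous systems), built around the case of cefdinir — a
poorly soluble, poorly permeable (BCS Class IV) cephalosporin — screened
against three polymers, a mesoporous silica and three amino-acid coformers.

It is written for formulation scientists who want the pencil-and-paper part
of preformulation as reproducible code: given Hansen solubility parameters
(from the literature or estimated by group contribution), it ranks candidate
stabilisers before any powder is made, and it checks the batch-sheet
arithmetic of the resulting formulations.

## The model

Each substance carries a Hansen triple (δd, δp, δh) in MPa^0.5 — dispersion,
polar and hydrogen-bonding components of the cohesive energy density — with
total parameter δt = √(δd² + δp² + δh²). Two indicators drive the screen:

* **Hansen interaction radius**
  Ra = √(4(δd1−δd2)² + (δp1−δp2)² + (δh1−δh2)²), the distance in Hansen
  space. Ra < 7 MPa^0.5 is read as miscible, Ra > 10 as immiscible,
  between as borderline.
* **Flory–Huggins interaction parameter**
  χ = Vm(δt,drug − δt,excipient)²/(RT), with Vm the drug molar volume in
  cm³/mol (estimated from Fedors group-contribution increments),
  R = 8.314 J/(mol·K) and T = 298 K. χ < 0.5 indicates thermodynamic
  miscibility; inorganic carriers (mesoporous silica) fall outside the
  lattice model and get χ = NA.

Hansen components and Vm can be estimated from a functional-group multiset
via bundled Hoftyzer–Van Krevelen and Fedors increment tables:
δd = ΣFd/V, δp = √(Σ n·Fp²)/V, δh = √(ΣEh/V), Vm = Σ n·Δv. A SMARTS-based
decomposer (optional, requires rdkit) derives the multiset from a SMILES
string.

Formulation arithmetic: percent yield, HPLC drug-content %, equimolar
coformer masses and % w/w drug loading.

## Worked example

```python
import hspscreen as h

fx = h.load_reference_substances()           # bundled published inputs
vm = h.cefdinir_molar_volume()               # Fedors estimate, cm3/mol
ctx = h.ChiContext(drug_molar_volume=vm)     # T = 298 K
report = h.screen(fx.drug, fx.excipients, ctx)
print(report.to_markdown())
```

prints (abridged):

```
Vm(drug) = 200.9 cm3/mol, T = 298.0 K; thresholds: Ra < 7 miscible, Ra > 10 immiscible, chi < 0.5 miscible.

| excipient | role | Ra | Ra class | delta_t | chi | chi class |
|---|---|---|---|---|---|---|
| L-phenylalanine | coformer | 2.03 | miscible | 23.04 | 0.061 | miscible |
| HPMC 606 | polymer | 2.03 | miscible | 22.93 | 0.046 | miscible |
| PVP K30 | polymer | 2.56 | miscible | 23.46 | 0.134 | miscible |
| L-tryptophan | coformer | 2.87 | miscible | 24.17 | 0.325 | miscible |
| Eudragit L100 | polymer | 4.53 | miscible | 21.16 | 0.084 | miscible |
| SBA-15 | mesoporous_carrier | 7.40 | borderline | 17.44 | NA | not_applicable |
| L-arginine | coformer | 8.76 | borderline | 28.11 | 2.858 | not_miscible |
```

Reading: all three polymers sit well inside the miscible band (Ra < 7) and
their χ values are far below 0.5 — HPMC 606 lowest among the polymers — so
any of them can host an amorphous dispersion of the drug. The silica carrier
sits at Ra = 7.40, outside the miscible range: it acts as a physical
(nanoconfinement) carrier, and χ is not applicable to it. L-arginine's high
polar/hydrogen-bonding components put it in the borderline band unless ionic
interactions are exploited.

The fixture also stores the Ra/χ values printed in the source tables; these
are not reproducible from the printed Hansen components under the stated
equations, so the report keeps them as provenance notes only (the full
`to_markdown()` output lists each discrepancy).

The same screen is available from a shell:

```
hspscreen screen                 # bundled fixture -> report.csv + summary.md
hspscreen estimate --fragments "CH3=1,CH2=1,OH=1"
hspscreen formulate              # batch totals, drug loading, molar ratios
hspscreen synth --n 20 --seed 1  # synthetic substances for pipeline testing
```

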