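# Methods

## Scope and model

`hspscreen` implements the desk stage of amorphous-formulation development:
deciding, before any processing, which stabiliser is likely to mix with a
drug. Two standard indicators are computed for every drug–excipient pair.

**Hansen interaction radius.** Substances are points in the
three-dimensional Hansen space (δd, δp, δh), each axis in MPa^0.5. The
distance

    Ra = sqrt(4 (δd1−δd2)² + (δp1−δp2)² + (δh1−δh2)²)

uses the conventional factor 4 on the dispersion axis and, despite some
printed renderings that drop it, the square root — the MPa^0.5 units of the
classification thresholds require it. Classification: Ra strictly below
`ra_miscible` (default 7 MPa^0.5) is miscible, strictly above
`ra_immiscible` (default 10) immiscible, otherwise borderline. Both
comparisons are strict, so a pair exactly at a cut-off lands in the
borderline band. Some screening practice quotes a tighter Ra < 5 rule; the
thresholds are a configurable value object, so that convention is one
constructor argument away.

**Flory–Huggins interaction parameter.** From the total parameters
δt = sqrt(δd² + δp² + δh²):

    χ = Vm (δt,drug − δt,excipient)² / (R T)

with Vm the molar volume of the **drug** in cm³/mol (the excipient's molar
volume does not enter this one-liquid approximation), R = 8.314 J/(mol·K)
and T = 298 K by default. MPa·cm³ = J keeps χ dimensionless. χ strictly
below 0.5 is classified miscible; χ exactly 0.5 is not. Inorganic carriers
(flagged `inorganic`, e.g. mesoporous silica SBA-15) are outside the
lattice-mixing picture and no group-contribution Vm exists for them, so
their χ is reported as not-applicable; Ra still ranks them. This χ is a
solubility-parameter estimate: it is necessarily non-negative and cannot
represent specific attractive interactions (χ < 0).

**Ranking.** Reports sort ascending by Ra, breaking ties by χ (absent χ
sorts last) and then name, which makes the order total and regeneration
byte-identical. `best_per_role` is the first-ranked excipient of each role;
Ra is the primary key because it exists for every pair including inorganic
carriers.

## Group-contribution estimation

The bundled `hvk-fedors` table combines Hoftyzer–Van Krevelen molar
attraction constants (Fd, Fp in MPa^0.5·cm³/mol; Eh in J/mol) with Fedors
volume increments Δv (cm³/mol):

    δd = Σ n·Fd / V      δp = sqrt(Σ n·Fp²) / V      δh = sqrt(Σ n·Eh / V)
    Vm = Σ n·Δv

These are the canonical published tables for this calculation; others
(Stefanis–Panayiotou, HSPiP) are out of scope. Several Fedors increments
are negative (CH −1.0, >C< −19.2, =C< −5.5 cm³/mol), so individual rows are
not sign-constrained; instead the total Vm of a fragment set must be
strictly positive, and a non-positive sum is rejected as implausible.
Amides are represented as carbonyl + amine-type nitrogen rows rather than a
composite CONH row, because δp aggregates as a root-sum-of-squares and a
composite polar constant would not be consistent with that rule.

The supported primary input is an explicit fragment multiset, so the
package runs without any chemistry dependency. `decompose_structure`
(optional, rdkit) maps a SMILES string to a multiset by SMARTS matching in
a fixed priority order — most specific patterns (carboxyl, ester, carbonyl)
first, then hybridisation/H-count patterns — with first-match-wins overlap
resolution and ties broken by table order, chosen for reproducibility over
cleverness. Every heavy atom must be claimed exactly once or a coverage
error lists the offending atoms; ring closures are counted per SSSR ring
(3–4-membered vs 5-plus) and consume no atoms; molecules containing
non-organic elements are rejected. Zwitterionisable molecules (amino acids)
are decomposed in neutral form, as increment tables are defined for neutral
groups.

For the bundled drug the decomposition of the cefdinir structure
(C14H13N5O5S2: aminothiazolyl hydroxyimino side chain, β-lactam fused to a
dihydrothiazine, carboxylic acid, vinyl group) is stored explicitly as
`CEFDINIR_FRAGMENTS`; the Fedors sum gives Vm = 200.9 cm³/mol, and the
rdkit decomposer reproduces the same multiset from `CEFDINIR_SMILES`.
Molar masses use IUPAC 2021 standard atomic weights rounded to 3 decimals,
parsed from Hill-notation formulas.

## Reference fixture and its known inconsistencies

The bundled fixture (plain CSV + YAML under `hspscreen/data/`, kept as text
so provenance is inspectable) carries the published screening inputs:
cefdinir (δd 17.29, δp 8.2, δh 11.2 MPa^0.5) plus seven excipients, and the
three batch compositions. The source tables' own Ra and χ columns are
stored as `printed_ra` / `printed_chi` **documentation fields only**: they
cannot be regenerated from the printed δ components under the stated
equations (cefdinir–PVP K30 recomputes to Ra = 2.56 vs printed 4.11;
L-arginine to 8.76 vs 4.77; the printed χ set implies mutually inconsistent
drug molar volumes, back-calculating to Vm between roughly 18 and 330
cm³/mol across rows). Whether different, unprinted δ inputs produced those
columns is not resolvable. The toolkit therefore always recomputes from the
printed components, never treats the printed Ra/χ as ground truth, and
emits one discrepancy note per affected pair in every report. Conclusions
that survive the inconsistency — all three polymers comfortably miscible by
both criteria, silica outside the miscible range, amino acids split with
L-arginine least favourable by Hansen distance — are the ones the test
suite asserts.

Exact reproduction of the printed δ components themselves from group
contributions is likewise not attempted (the source does not state which
increment tables produced them); the fixture carries the printed values
directly and the group-contribution path is validated against hand
arithmetic on its own bundled tables.

## Formulation arithmetic

Percent yield = 100·(dried product mass)/(initial batch mass); values above
100 % are physically possible (residual solvent, moisture) and warn rather
than fail. HPLC drug content = 100·(A_sample·C_standard)/(A_standard·C_nominal).
Equimolar mass converts a reference charge to the target substance by the
molar-mass ratio; molar masses default to the formula-based calculator but
accept overrides. Drug loading = 100·drug/(drug+carrier) w/w. The
stoichiometry checker reports the molar ratios a batch sheet actually
implies, normalised to the largest component: the nominally 1:1:1
co-amorphous batch (300 mg drug, 174.20 mg L-arginine, 165.19 mg
L-phenylalanine) actually weighs out 0.759 : 1.000 : 1.000 — the coformer
masses are each 1.00 mmol but the drug charge is 0.76 mmol — and the
checker reports, not resolves, that gap. The silica batch (300 mg drug on
507.2 mg SBA-15) recomputes to a loading of 37.17 %, 0.01 below the
commonly quoted rounded figure.

## Synthetic data

The generator draws Hansen triples component-wise from uniform
distributions over the envelope the reference excipients span (δd 15–19,
δp 3–15, δh 7–18 MPa^0.5) — uniform because no distributional information
exists beyond that envelope, making it the least-assumption choice. Roles
default to 40 % polymer / 40 % coformer / 20 % inorganic carrier; organic
substances get a uniform molar volume in 80–500 cm³/mol. All randomness
flows through one integer seed (`numpy.random.default_rng`), so a spec is a
complete recipe for its batch. Synthetic fragment multisets draw up to six
pattern-bearing labels with counts 1–4 and are anchored with enough
methylene groups to outweigh the worst-case draw of negative Fedors
increments, guaranteeing a positive Vm.

What the generator does **not** emulate: correlations between components
(real polymers do not sample δp and δh independently), molar-volume/HSP
covariation, and chemically consistent fragment sets. Passing property
tests on this population therefore demonstrates the mathematical invariants
(symmetry, additivity, monotonicity, determinism) on realistic magnitudes,
not predictive accuracy on real excipient libraries.

## Numerical conventions and problem sizes

All math is double precision; no iteration or optimisation is involved.
Reports round Ra/δt to 2 decimals and χ to 3 (matching conventional table
precision) while the API returns full precision; the oracle-equivalence
property is checked to 1e-9 absolute on Ra². Property suites run on
hypothesis-generated triples (seeded/derandomised) plus a deterministic
bulk population of 48 synthetic substances (1128 pairs) and 1000 fragment
draws — sizes chosen so the whole suite completes in a few seconds while
exercising every invariant well beyond the eight-substance case study.

## Known limitations

* The χ estimate inherits every limitation of the solubility-parameter
  route: temperature-independent, non-negative, blind to specific
  interactions; no χ(T) scans, melting-point-depression or simulation-based
  miscibility estimates are provided.
* No Hansen sphere fitting or RED (Ra/R0) computation: no experimental
  interaction radius R0 is involved in this workflow.
* The SMARTS decomposer targets small organic molecules; polymers must be
  supplied as repeat-unit fragment sets or literature HSP values, and
  charged/tautomeric forms are not modelled.
* Group-contribution δ values are scheme-dependent; agreement with any
  particular published table should not be expected beyond ~1 MPa^0.5.
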