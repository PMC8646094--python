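# icgsim

Whole-body physiologically based pharmacokinetic (PBPK) simulation of
indocyanine green (ICG) liver function tests, and of the physiological and
anthropometric sources of their inter-individual variability.

ICG is a plasma-protein-bound dye eliminated exclusively by the liver via
the sinusoidal transporter OATP1B3 and excreted into bile. After an
intravenous dose, the plasma disappearance curve yields the clinical
liver-function parameters: elimination rate constant k<sub>el</sub>, plasma
disappearance rate PDR = 100·k<sub>el</sub> [%/min], half-life
t<sub>1/2</sub> = ln 2 / k<sub>el</sub>, retention ratios R15/R20 [%],
clearance CL = Dose/AUC<sub>∞</sub> (bolus) or rate/C<sub>ss</sub>
(infusion), and the hepatic extraction ratio
ER = (C<sub>in</sub> − C<sub>out</sub>)/C<sub>in</sub>. These read-outs
confound true liver function with hepatic blood flow, cardiac output,
transporter abundance, liver volume, body weight and plasma bilirubin —
`icgsim` exists to quantify those confounders.

The package provides:

- **`icgsim.model`** — the ODE system: six flow-limited plasma pools
  (venous, lung, arterial, GI, rest, liver plasma) plus hepatocyte, bile and
  feces; Michaelis–Menten uptake competitively inhibited by bilirubin;
  single-parameter cirrhosis (functional tissue loss + portosystemic shunt,
  degrees 0.40/0.70/0.81 for mild/moderate/severe);
  body-weight scaling of flows and volumes; bolus and constant-infusion
  dosing.
- **`icgsim.pk`** — PK parameters from a simulated curve (log-linear
  k<sub>el</sub> fit, retention, AUC, clearance, extraction ratio).
- **`icgsim.population`** — a seeded synthetic cohort generator:
  survey-like anthropometry with age/BMI exclusions and oversampling,
  age-dependent correlated liver volume and hepatic blood flow, lognormal
  OATP1B3 abundance.
- **`icgsim.experiments`** — parameter scans across cirrhosis degrees,
  per-individual population ICG tests, stratified Tukey summaries,
  PK correlation fits, dose comparisons and single-factor contribution
  analyses.
- **`analysis/`** — numbered drivers that reproduce the study end to end
  and write their tables under `results/`.

See `docs/methods.md` for the model equations, parameter defaults and their
rationale, the generator's design, and known limitations.

## Worked example

```python
from icgsim import Individual, DoseProtocol, simulate, compute_pk
from icgsim.model import steady_state_extraction_ratio

ref = Individual()                      # 75 kg, all scalers 1.0, healthy
tc = simulate(ref, DoseProtocol(mode="bolus", bolus_dose=0.5))  # 0.5 mg/kg
pk = compute_pk(tc)
print(f"PDR {pk.pdr:.1f} %/min, t1/2 {pk.t_half:.2f} min, "
      f"R15 {pk.r15:.1f} %, CL {pk.cl:.0f} mL/min")
print(f"ER {steady_state_extraction_ratio(ref):.3f}")
```

prints

```
PDR 22.1 %/min, t1/2 3.14 min, R15 3.7 %, CL 490 mL/min
ER 0.850
```

i.e. a healthy reference test: a disappearance rate of ~22 %/min with ~4%
of the dye left after 15 min, a clearance of ~490 mL plasma/min, and 85% of
the ICG reaching the liver removed per pass — inside the healthy 0.6–0.9
extraction range. Mild/moderate/severe cirrhosis (`f_cirrhosis` =
0.40/0.70/0.81) reduce PDR to 12.4/6.0/3.7 %/min and raise R15 to
16/41/57% in a stepwise fashion.

The full analysis sequence:

```sh
python analysis/01_reference_test.py          # reference bolus + infusion test
python analysis/02_parameter_scans.py         # 6 factors x 4 cirrhosis degrees
python analysis/03_build_cohort.py            # synthetic cohort (default n=5,000)
python analysis/04_population_variability.py  # per-individual tests + stratification
python analysis/05_pk_correlations.py         # R20-t1/2 collapse, bolus vs infusion CL
python analysis/06_factor_contributions.py    # single-factor vs joint variability
```

Typical findings at n = 5,000: median clearance falls from ≈ 550 mL/min
(ages 18–40) to ≈ 410 mL/min (66–84); clearance rises with weight class
while PDR stays flat (body weight scales the cleared plasma volume, not the
rate); all R20/t<sub>1/2</sub> variability collapses onto
R20 = 100·2^(−20/t<sub>1/2</sub>) to within 0.03 percentage points; and
bolus and infusion clearance agree with slope ≈ 1.00.

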