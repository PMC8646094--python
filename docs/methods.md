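# Methods

## Model

`icgsim` implements a whole-body, physiologically based pharmacokinetic
(PBPK) model of indocyanine green (ICG), a plasma-protein-bound dye that is
removed from the circulation exclusively by the liver, exported into bile
and excreted with the feces. ICG is neither metabolised nor reabsorbed from
the gut (no enterohepatic recirculation), which makes its plasma
disappearance curve a direct read-out of hepatic uptake capacity and
hepatic perfusion — the basis of dynamic liver function tests.

### State and circulation

Nine amounts [mg] are tracked: six circulating plasma pools — venous blood,
lung, arterial blood, gastrointestinal tract (GI), rest-of-body, liver
plasma — plus hepatocyte, bile and feces. Because ICG is confined to plasma
by protein binding, the distribution volumes are plasma volumes, scaled
linearly with body weight (default 0.035 L/kg in total).

The circulation is flow-limited: venous → lung → arterial, after which the
cardiac plasma flow `Q` splits into the hepatic supply
`Q_hep = f_hep · Q · f_bloodflow` (default hepatic fraction `f_hep` = 0.25)
and the rest-of-body flow `Q − Q_hep`. The liver receives dual inflow:
a hepatic-artery share (25% of `Q_hep`) directly from arterial blood and a
portal share (75%) that first passes the GI pool. `Q` itself is the cardiac
output scaled by body weight, times (1 − hematocrit), times the individual's
`f_cardiac_output`.

### Hepatic elimination

Uptake from liver plasma into hepatocytes follows Michaelis–Menten kinetics
with competitive inhibition by plasma bilirubin (both species compete for
plasma-protein binding at the sinusoidal membrane):

    v = f_oatp1b3 · Vmax · V_liver,functional · C_li
        ─────────────────────────────────────────────
        Km · (1 + bil_ext / Ki) + C_li

Bilirubin changes slowly relative to the ~15 min test and enters as a
static level `bil_ext` on a relative scale (1.0 = normal). Hepatocyte →
bile and bile → feces transfer are first order (`k_bile`, `k_feces`); there
is no backflow, so the plasma subsystem is autonomous and the hepatic
amounts are feed-forward sinks.

### Cirrhosis

A single degree parameter couples the two lesions of cirrhosis: a fraction
`f_cirrhosis` of liver tissue is non-functional (scaling the uptake
capacity by `1 − f_cirrhosis`) and the same fraction of hepatic plasma flow
is shunted around the liver directly into venous blood, carrying the mixed
portal + arterial inflow concentration. Degrees 0.40 / 0.70 / 0.81 encode
mild / moderate / severe disease (Child–Turcotte–Pugh A/B/C); 0 is healthy
and 1 abolishes elimination entirely. Whether the shunt carries portal-only
or mixed blood is an open modelling choice; mixed blood is used here.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `bw_ref` | 75 | kg | reference body weight |
| `cardiac_output_ref` | 4.2 | L/min | deliberately low-normal; avoids needing an explicit circulation delay to reproduce realistic extraction ratios |
| `hematocrit` | 0.45 | – | converts blood to plasma flow |
| `hepatic_flow_fraction` | 0.25 | – | hepatic share of cardiac output |
| `arterial_fraction` | 0.25 | – | hepatic-artery share of liver inflow |
| plasma volume | 0.035 | L/kg | low-normal plasma volume; ICG distributes in plasma only |
| `fv_liver` | 0.021 | L/kg | liver volume per body weight (reference) |
| `hepatocyte_fraction` | 0.80 | – | functional share of liver volume |
| `vmax_uptake` | 285.694 | mg/min/L | calibrated (below) |
| `km_uptake` | 100 | mg/L | keeps clinical doses in the near-linear uptake regime |
| `ki_bil` | 10 | – | normal bilirubin depresses clearance by ~1% |
| `k_bile`, `k_feces` | 0.10, 0.05 | 1/min | biliary export and fecal transit; no effect on plasma kinetics (feed-forward) |

The kinetic constants are calibratable model defaults, not literature
measurements. `calibrate_vmax` inverts the flow/uptake competition of the
linearised liver — ER = CLint / (Q_hep + CLint) with
CLint = Vmax·V_func/Km_eff — to hit a target steady-state extraction ratio;
the frozen default targets ER = 0.85, mid-high in the healthy range
0.6–0.9, and yields a reference plasma disappearance rate of ≈ 22 %/min
(healthy clinical range ≈ 18–25 %/min). With `km_uptake` = 100 mg/L, PDR at
0.5 and 5.0 mg/kg differs by ≈ 0.6% for the reference subject, so dose
dependence emerges only under parameter variation.

## PK parameters

From each simulated curve the clinical parameters are computed exactly as
the analysis layer consumes them:

- `kel` [1/min]: least-squares slope of ln C vs t on a fit window of
  5–15 min post bolus (inside the mono-exponential phase, past the mixing
  transient; config-exposed). `PDR = 100·kel` and `t_1/2 = ln 2 / kel` are
  derived fields, so the identities hold bit-exactly.
- `R15`, `R20` [%]: retention relative to the back-extrapolated intercept
  C0 (not the observed maximum — robust to early mixing artifacts).
- `AUC_∞`: trapezoidal over the grid plus tail `C(t_end)/kel`;
  bolus clearance `CL = Dose/AUC_∞`; infusion clearance `CL = rate/C_ss`.
- Extraction ratio `ER = (C_in − C_out)/C_in`, flow-weighted across the
  liver including shunt flow, at verified steady state (relative change of
  plasma concentration below 1e−6 per minute over the final 10 min).
  Reported plasma concentration is venous — the clinical sampling default;
  no arterio-venous correction is applied.

## Virtual population

The generator emulates the covariate structure of a large adult health
survey without downloading any external data; every distribution parameter
is a config field and the defaults are artifact defaults, not measured
values.

- **Anthropometry.** Sex (p = 0.5), age from a mildly young-skewed Beta
  density over [18, 85), sex-specific normal heights (M 175.7 ± 7.4 cm,
  F 162.2 ± 6.8 cm), and BMI normal around an age-dependent mean that rises
  to mid-life and declines in old age, with SD 6.2 kg/m² (the documented
  adult survey dispersion) and women ≈ 1 BMI unit above men. Body weight is
  BMI·height². Female body weight is truncated at 100 kg, matching the
  stratified analysis in which no women above 100 kg occur.
- **Exclusions.** Minors (age < 18), obese subjects (BMI > 30) and
  top-coded ages (≥ 85) are removed and counted per rule; with the default
  dispersion roughly 30% of draws are excluded, comparable to adult obesity
  prevalence.
- **Oversampling.** The retained base subjects are resampled uniformly with
  replacement to the target size; replicates share anthropometry but
  receive fresh physiology and transporter draws, so each base subject
  occurs a few times with different liver volume / blood flow samples.
- **Physiology.** (liver volume per kg, hepatic blood flow per kg) are
  drawn from a bivariate normal whose means decline linearly with age —
  26 → 20 mL/kg and 19 → 12 mL/min/kg from age 20 to 84 — with 15% CV,
  correlation 0.5 and a floor at 20% of the age mean. The flow draw is
  normalised by the model's reference flow (14 mL/min/kg) to give
  `f_bloodflow`; the marginal correlation in a mixed-age cohort exceeds the
  configured 0.5 because both means decline with age.
- **Transporter.** `f_oatp1b3` is lognormal (median 1.0, log-SD 0.35),
  independent of age, sex and every other covariate.
- **Seeding.** A root seed spawns four named sub-streams (anthropometry,
  oversampling, physiology, transporter); identical config + seed give a
  byte-identical cohort table. Ethnicity is carried as a label but has no
  effect on any sampled quantity.

What the generator does *not* emulate: survey weights, true
anthropometric covariance beyond the age/sex structure above, obesity and
pediatric ranges, ethnicity-dependent transporter abundance, and any
correlation of OATP1B3 with body size. Passing population tests therefore
demonstrate internal consistency of the modelled mechanisms, not agreement
with any specific real cohort.

## Numerics

- Stiff-capable integration (LSODA), rtol 1e−8 / atol 1e−10, outputs on the
  requested sampling grid (default 0.1 min for bolus, 0.5 min for
  infusion). Boluses and priming doses enter venous blood as initial
  conditions, keeping the right-hand side smooth; infusions add a constant
  rate. Mass is conserved to well below 1e−6 relative.
- Tiny negative amounts within −1e−9 of the dose are clipped to zero;
  larger negativity raises a simulation error.
- A fitted `kel` below 1e−9 /min is treated as "no elimination" (flat
  curve): half-life infinite, AUC divergent, clearance zero.
- Steady-state verification uses the plasma subsystem only; hepatocyte and
  bile pools equilibrate on slower time constants but cannot influence
  plasma (no backflow).

## Problem sizes

The test suite and analysis drivers run scaled-down versions of the
full-scale (n = 100,000) population study: the stratified-variability
checks use a 20,000-subject cohort — sized so that cell-median noise
(≈ 1.25·CV/√n) is small against the 5% bands being tested, with subgroup
medians compared only where at least 500 subjects per compared group are
available, mirroring the design rationale that oversampling should
guarantee sufficient samples in every stratified subgroup. Parameter scans
use 21-point grids across four cirrhosis degrees; the analysis drivers
default to a 5,000-subject cohort. All sizes are config/CLI arguments.

## Known limitations

- No circulation delay: transit between liver outflow and re-entry is
  instantaneous, which is why the reference cardiac output sits at the low
  end of the physiological range. Individualised prediction of absolute
  hepatic blood flow would require a delay formulation.
- Bilirubin is a static level, not a dynamic species; the competitive-
  inhibition mechanism is an assumption supported by animal data.
- Kinetic constants are calibrated to reproduce clinical summary ranges,
  not fitted to individual-level data; absolute concentrations should be
  interpreted accordingly.
- The population generator is a parametric emulator; see above for the
  structure it does and does not reproduce.
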