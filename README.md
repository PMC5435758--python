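# gradedbold

Calibrated BOLD fMRI estimates the oxygen metabolism (CMRO2) underlying a
BOLD response by first measuring a calibration parameter **M** — the
ceiling BOLD signal change that would occur if all deoxyhaemoglobin were
removed — classically from a hypercapnia challenge under the assumption
that CO2 leaves CMRO2 unchanged. That *iso-metabolic* assumption is
contested: mild hypercapnia appears to depress basal CMRO2, which inflates
M and with it every downstream CMRO2 estimate.

`gradedbold` implements the graded-hypercapnia alternative: acquire BOLD
and CBF responses at **two or more** CO2 levels, assume the basal CMRO2
change is linear in the end-tidal CO2 rise,

```
ΔBOLD/BOLD₀ = M · [1 − (CBF/CBF₀)^(α−β) · (1 + κ·ΔP_ETCO₂)^β]
```

and solve the resulting system jointly for **M** and **κ** (the fractional
CMRO2 change per mmHg CO2, in %/mmHg) by bounded nonlinear least squares —
no literature value for the CMRO2 response needed. The package is aimed at
calibrated-fMRI researchers working with ROI-averaged dual-echo ASL data,
and contains:

- the Davis-type forward model and its inversion, with the three α/β
  exponent conventions in common use at 3 T (`model`);
- the (M, κ) estimator, an exact two-level root-finding oracle, the
  classical one-parameter iso-metabolic fit, and group statistics with
  boundary-hit exclusion and Wilcoxon signed-rank tests (`fit`);
- dual-echo ASL preprocessing: surround subtraction/averaging of
  interleaved tag/control volumes, two-echo R2\*, baseline detrending,
  steady-state block responses and end-tidal CO2 dose extraction, with
  optional NIfTI ROI averaging (`preprocess`);
- a synthetic-data generator with known ground truth emulating an 18-min,
  490-volume graded-CO2 session, plus parameter-recovery experiments
  (`simulate`);
- a CLI: `gradedbold simulate | preprocess | fit | group | recover`.

## Worked example

Fit one synthetic gray-matter-like session (truth: M = 8.6 %,
κ = −1.3 %/mmHg, CBF ratios 1.13/1.17 at +4.8/+8.4 mmHg) with every noise
source disabled:

```python
from gradedbold import (SimulationConfig, simulate_dualecho, extract_levels,
                        HypercapniaCalibration)

cfg = SimulationConfig(seed=42).exact()        # nuisance-free session
sim = simulate_dualecho(cfg)
levels = extract_levels(sim.series, sim.paradigm, sim.endtidal)
for lv in levels:
    print(f"dPETCO2 = {lv.delta_petco2:5.2f} mmHg   "
          f"BOLD = {100*lv.bold_frac:.3f} %   CBF ratio = {lv.cbf_ratio:.3f}")
print(HypercapniaCalibration(levels, pairing="empirical").fit().summary())
```

prints

```
dPETCO2 =  4.80 mmHg   BOLD = 1.218 %   CBF ratio = 1.130
dPETCO2 =  8.40 mmHg   BOLD = 1.740 %   CBF ratio = 1.170
Hypercapnia calibration fit
===========================
fit:            graded two-parameter
pairing:        empirical (alpha=0.14, beta=0.91)
levels:         2
M:              8.60 %
kappa:          -1.30 %/mmHg
residual norm:  2.708e-35
```

i.e. the full preprocessing + fitting chain returns the generating
parameters to machine precision. The steady-state responses (1.2 %/1.7 %
BOLD, 13 %/17 % CBF) are what the forward model produces from that truth.
With realistic noise the same chain run 100 times
(`recovery_experiment(SimulationConfig(seed=42), 100)`) gives

```
M = 8.2 ± 3.3 %  (truth 8.6),  kappa = -1.69 ± 1.28 %/mmHg  (truth -1.3)
iso-metabolic M = 13.8 %,  boundary hits: 6 %
```

which shows the method's headline property: ignoring the CMRO2 decrease
(κ < 0) inflates M — here from ~8 % to ~14 % — while the graded fit
removes that bias at the cost of per-session variance, which group
averaging across subjects then reduces.

The same chain from a shell:

```sh
gradedbold simulate --out session --seed 42 --exact
gradedbold preprocess --series session/dualecho.csv \
    --paradigm session/paradigm.json --endtidal session/endtidal.csv \
    --out levels.csv
gradedbold fit --levels levels.csv --pairing empirical --out results
```

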