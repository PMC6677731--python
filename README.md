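# icbsim

A reduced quantitative-systems-pharmacology (QSP) simulator of immune
checkpoint blockade — anti-CTLA-4, anti-PD-1 and anti-PD-L1 antibodies,
alone, combined or in sequence — in metastatic melanoma.  It is aimed at
modelers and pharmacometricians who want a mechanistic, fully inspectable
sandbox for checkpoint-therapy questions: how lymph-node T-cell priming,
effector trafficking, tumor killing and antibody pharmacokinetics combine
into the wide spectrum of clinical responses, and which patient parameters
separate responders from non-responders.

## The model in brief

One virtual patient is a stiff ODE system coupling four layers:

* **Priming (tumor-draining lymph node).**  Naive T cells associate with
  mature antigen-presenting cells (mAPCs) in three stages; the probability
  of a successful encounter over the contact window is

  *P1 = 1 − exp(−4π·D_T·Diff_T·mAPC·[T]·φ_NT·Antigen / (TClonality·S) · t_max)*,

  and activated cells expand up to 2^15-fold (three divisions a day for
  five days) before the effector flux, multiplied over ~32 draining nodes,
  enters the blood.

* **Trafficking.**  Effectors circulate through blood, lung, liver,
  spleen, GI tract, a peripheral lump, lymph nodes and the tumor, with
  reversible vascular binding, irreversible arrest (chemokine-scaled in the
  tumor), extravasation and lymphatic return; the tumor interstitium is
  absorbing.

* **Killing and the antigen cycle.**  Effector–target killing follows
  *dT/dt = −d·(E/T)^λ/(s+(E/T)^λ)·T*; every dying cancer cell releases
  ~100 antigens, which mature tumor APCs into mAPCs that drain back to the
  lymph nodes — a feed-forward loop that ignites or stalls depending on
  the kill/growth balance.

* **Checkpoints and drugs.**  Receptor–ligand axes (PD1–PDL1, PD1–PDL2,
  CD80–PDL1 at the killing synapse; CTLA4–CD80/CD86 at priming) bind at
  equilibrium in the synapse volume; simultaneous axes combine by the
  median-effect sum *f_a = S^m/(1+S^m)*, *S = Σ wᵢ (RO/RO_max)ᵢ*, which is
  ½ at full drug-free occupancy and falls as a blocking antibody (at its
  local PBPK-derived concentration) competes.  Tumor heterogeneity is a
  constant 2⁴-subtype lattice of independently distributed checkpoint
  expression.  Antibody PK is minimal-PBPK with zero-order infusions and,
  for anti-CTLA-4 only, target-mediated disposition.

Virtual clinical trials draw Latin-hypercube cohorts over the documented
physiological ranges (tumor diameter 15–80 mm, antigen strength 0.8–1.0,
T-cell clonality 10–130, lymph-node Tregs 5–35%, tumor Tregs 0–0.25%,
%PD-L1 40–90%) and classify each patient's best overall response with
RECIST-1.1-style thresholds (CR/PR/SD/NR).

See `docs/methods.md` for the full model description, parameter defaults
with units, numerical choices and limitations.

## Worked example

```python
from icbsim import ModelParams, PatientParameters, simulate, regimens

patient = PatientParameters(tumor_diameter_start=40.0, t_clonality=100.0,
                            pdl1_frac=0.8)
result = simulate(ModelParams(patient=patient), regimens.anti_pd1(3.0),
                  horizon=365.0)
change = result.percent_change()
print(f"baseline {result.baseline_diameter:.1f} mm, "
      f"best change {change.min():.1f}%, final {change[-1]:.1f}%")
print(f"peak tumor effector density {result.effector_density_tumor.max():.3g} cells/mL")
```

prints

```
baseline 40.0 mm, best change -99.9%, final -99.9%
peak tumor effector density 1.53e+08 cells/mL
```

— a favorable patient (high clonality, 80% PD-L1): under anti-PD-1
3 mg/kg every two weeks the killing loop ignites, effectors accumulate to
~1.5×10⁸ cells/mL of tumor, and the lesion shrinks below detectability
(complete response).  A cohort-level run:

```python
from icbsim.trials import sample_cohort, run_trial

trial = run_trial(sample_cohort(n=50, seed=1), regimens.anti_pd1(3.0))
print(trial.class_fractions(), round(trial.orr, 2), round(trial.any_response_rate, 2))
```

prints

```
{'NR': 0.5, 'SD': 0.12, 'PR': 0.06, 'CR': 0.32} 0.38 0.42
```

— about a third of virtual patients reach PR/CR under anti-PD-1
monotherapy while the majority progress, with response concentrated in
patients with many T-cell clones, high %PD-L1 and smaller tumors
(`icbsim.trials.responder_statistics` quantifies the separation).

The same machinery is exposed on the command line:

```bash
icbsim simulate --regimen src/icbsim/data/regimen_antipd1_q2w.yaml --horizon 365 --out run/
icbsim trial --regimen src/icbsim/data/regimen_antipd1_q2w.yaml --n 200 --seed 1 --out trial/
icbsim sensitivity --therapy src/icbsim/data/regimen_antipd1_q2w.yaml --n 100 --out sens.csv
icbsim export-sbml --out model.sbml.xml
```

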