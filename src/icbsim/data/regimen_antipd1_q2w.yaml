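# anti-PD-1 3 mg/kg every two weeks for one year
label: anti-PD-1 3 mg/kg Q2W
blocks:
  - drug: antiPD1
    dose: 3.0
    interval_days: 14
    n_doses: 26
    start_day: 0
    infusion_hours: 1.0
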