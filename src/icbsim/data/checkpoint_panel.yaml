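# Default checkpoint panel: literature-typical surrogate values, all
# overridable.  Densities are molecules per interacting cell pair in the
# immunological synapse; kd in molar; synapse_volume in liters.
# Checkpoint ectodomain affinities sit in the low-micromolar range; the
# synapse volume corresponds to a ~100 nm cleft over a few tens of um^2.
synapse_volume: 1.0e-15
hill_m: 2.0
killing_axes:           # cancer-cell / effector synapse
  PD1-PDL1:   {receptor_density: 3.0e+3, ligand_density: 8.0e+3, kd: 8.2e-6}
  PD1-PDL2:   {receptor_density: 3.0e+3, ligand_density: 2.0e+3, kd: 2.3e-6}
  CD80-PDL1:  {receptor_density: 1.0e+3, ligand_density: 8.0e+3, kd: 1.7e-6}
priming_axes:           # mAPC / T-cell priming synapse
  CTLA4-CD80: {receptor_density: 5.0e+2, ligand_density: 1.0e+3, kd: 4.0e-7}
  CTLA4-CD86: {receptor_density: 5.0e+2, ligand_density: 1.5e+3, kd: 2.6e-6}
cd28_axis:
  CD28-CD8086: {receptor_density: 5.0e+3, ligand_density: 1.0e+4, kd: 4.0e-6}
antibodies:             # kd_ab in molar; blocked axes are fixed by drug class
  antiPD1:   {kd_ab: 4.5e-9}
  antiPDL1:  {kd_ab: 1.0e-9}
  antiCTLA4: {kd_ab: 3.5e-9}
expression:             # tumor checkpoint expression fractions (PDL1 varied per patient)
  PD1: 0.05
  PDL1: 0.65
  PDL2: 0.10
  CD80: 0.05
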