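# Default DPD force field for the four-to-one coarse-grained lipid model.
# Nonbonded repulsions a_ij in kBT/r0; friction tiers in reduced units.
# Bonded parameters: L0 in r0, K2 in kBT/r0^2, theta0 in degrees, K3 in kBT.
# Bead indices inside templates are zero-based.
units:
  r0_nm: 0.71
  tau_ps: 143.0
  Nm: 4
temperature: 1.0
bead_types:
  W:  {charge_class: polar,    hbond_class: none}
  Q0: {charge_class: charged,  hbond_class: none}
  Qa: {charge_class: charged,  hbond_class: acceptor}
  Na: {charge_class: nonpolar, hbond_class: acceptor}
  C:  {charge_class: apolar,   hbond_class: none}
repulsion:
  labels: [W, Q0, Qa, Na, C]
  matrix:
    - [100,  98,  98, 102, 130]
    - [ 98, 110, 100, 102, 130]
    - [ 98, 100, 110, 102, 130]
    - [102, 102, 102, 100, 110]
    - [130, 130, 130, 110, 100]
friction_tiers:
  low: 4.5
  mid: 9.0
  high: 20.0
  low_max: 102.0   # a <= low_max        -> low
  mid_max: 110.0   # low_max < a <= mid_max -> mid; above -> high
templates:
  WATER:
    beads: [W]
    bonds: []
    angles: []
    chains: []
  DMPC:
    beads: [Q0, Qa, Na, C, C, C, Na, C, C, C]
    bonds:
      - [0, 1, 0.47, 512]
      - [1, 2, 0.47, 512]
      - [2, 6, 0.31, 512]
      - [2, 3, 0.59, 512]
      - [3, 4, 0.59, 512]
      - [4, 5, 0.59, 512]
      - [6, 7, 0.59, 512]
      - [7, 8, 0.59, 512]
      - [8, 9, 0.59, 512]
    angles:
      - [1, 2, 3, 180, 6]
      - [1, 2, 6, 120, 6]
      - [2, 3, 4, 180, 6]
      - [3, 4, 5, 180, 6]
      - [6, 7, 8, 180, 6]
      - [7, 8, 9, 180, 6]
    chains:
      - [3, 4, 5]
      - [7, 8, 9]
  DPPC:
    beads: [Q0, Qa, Na, C, C, C, C, Na, C, C, C, C]
    bonds:
      - [0, 1, 0.47, 512]
      - [1, 2, 0.47, 512]
      - [2, 7, 0.31, 512]
      - [2, 3, 0.59, 512]
      - [3, 4, 0.59, 512]
      - [4, 5, 0.59, 512]
      - [5, 6, 0.59, 512]
      - [7, 8, 0.59, 512]
      - [8, 9, 0.59, 512]
      - [9, 10, 0.59, 512]
      - [10, 11, 0.59, 512]
    angles:
      - [1, 2, 3, 180, 6]
      - [1, 2, 7, 120, 6]
      - [2, 3, 4, 180, 6]
      - [3, 4, 5, 180, 6]
      - [4, 5, 6, 180, 6]
      - [7, 8, 9, 180, 6]
      - [8, 9, 10, 180, 6]
      - [9, 10, 11, 180, 6]
    chains:
      - [3, 4, 5, 6]
      - [8, 9, 10, 11]
  DOPC:
    beads: [Q0, Qa, Na, C, C, C, C, Na, C, C, C, C]
    bonds:
      - [0, 1, 0.47, 512]
      - [1, 2, 0.47, 512]
      - [2, 7, 0.31, 512]
      - [2, 3, 0.59, 512]
      - [3, 4, 0.59, 512]
      - [4, 5, 0.59, 512]
      - [5, 6, 0.59, 512]
      - [7, 8, 0.59, 512]
      - [8, 9, 0.59, 512]
      - [9, 10, 0.59, 512]
      - [10, 11, 0.59, 512]
    angles:
      - [1, 2, 3, 180, 6]
      - [1, 2, 7, 120, 6]
      - [2, 3, 4, 180, 6]
      - [3, 4, 5, 180, 6]
      - [4, 5, 6, 120, 6]
      - [7, 8, 9, 180, 6]
      - [8, 9, 10, 180, 6]
      - [9, 10, 11, 120, 6]
    chains:
      - [3, 4, 5, 6]
      - [8, 9, 10, 11]
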