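# Default statistical-coil torsion library, version 1.
#
# Each residue class lists Ramachandran basins as
#   [phi_center_deg, psi_center_deg, width_deg, weight]
# where width is the circular standard deviation of the wrapped-Gaussian
# jitter applied around the basin center (the same width is used for phi
# and psi) and weights within a class sum to 1.
#
# Basin centers and weights emulate the full-database observed phi/psi
# occupancies that residue-specific trajectory sampling draws from (all
# residues of high-resolution structures, not coil regions only): an
# extended-beta basin, a polyproline-II basin, a right-handed alpha basin,
# and (for general residues and glycine) a left-handed alpha basin.
# Proline's phi is restricted near -63 deg and pre-proline residues
# disfavour the alpha-R basin.
version: "coil-1"
classes:
  general:
    - [-120.0, 135.0, 25.0, 0.20]
    - [-65.0, 145.0, 20.0, 0.25]
    - [-63.0, -42.0, 15.0, 0.45]
    - [57.0, 47.0, 15.0, 0.10]
  glycine:
    - [-120.0, 140.0, 30.0, 0.25]
    - [-65.0, 145.0, 25.0, 0.15]
    - [-63.0, -40.0, 20.0, 0.30]
    - [75.0, 25.0, 25.0, 0.30]
  proline:
    - [-63.0, 150.0, 15.0, 0.55]
    - [-63.0, -35.0, 15.0, 0.45]
  pre_proline:
    - [-120.0, 140.0, 25.0, 0.35]
    - [-65.0, 145.0, 20.0, 0.35]
    - [-63.0, -40.0, 15.0, 0.30]
class_of:
  default: general
  G: glycine
  P: proline
# assigned positionally, overriding class_of for residues followed by P
pre_proline_class: pre_proline
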