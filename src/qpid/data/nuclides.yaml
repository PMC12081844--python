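# Nuclide data used by the decay simulator and decay correction.
# Half-lives and dominant emissions are standard nuclide-chart values
# (ENSDF/NNDC); decay chains keep only the dominant path so that each
# parent decay yields its textbook charged-emission multiplicity
# (e.g. 4 alpha + 2 beta- per Ra-223 decay to stable Pb-207).
# Energies in keV, half-lives in seconds, branch fractions sum to 1.

nuclides:
  F-18:
    half_life_s: 6586.2          # 109.77 min
    branches:
      - mode: beta_plus
        fraction: 1.0
        beta_mean_kev: 249.8
        beta_endpoint_kev: 633.5
        daughter: O-18
  O-18:
    stable: true

  Zr-89:
    half_life_s: 282276.0        # 78.41 h
    branches:
      - mode: auger              # electron capture followed by 12.7 keV Auger K
        fraction: 0.77
        energy_kev: 12.7
        daughter: Y-89
      - mode: beta_plus
        fraction: 0.23
        beta_mean_kev: 395.5
        beta_endpoint_kev: 902.0
        daughter: Y-89
  Y-89:
    stable: true

  Th-227:
    half_life_s: 1615680.0       # 18.70 d
    branches:
      - mode: alpha
        fraction: 0.55
        energy_kev: 6038.0
        daughter: Ra-223
      - mode: alpha
        fraction: 0.45
        energy_kev: 5756.0
        daughter: Ra-223

  Ra-223:
    half_life_s: 987552.0        # 11.43 d
    branches:
      - mode: alpha
        fraction: 1.0
        energy_kev: 5716.0
        daughter: Rn-219
  Rn-219:
    half_life_s: 3.96
    branches:
      - mode: alpha
        fraction: 1.0
        energy_kev: 6819.0
        daughter: Po-215
  Po-215:
    half_life_s: 0.001781
    branches:
      - mode: alpha
        fraction: 1.0
        energy_kev: 7386.0
        daughter: Pb-211
  Pb-211:
    half_life_s: 2166.0          # 36.1 min
    branches:
      - mode: beta_minus
        fraction: 1.0
        beta_mean_kev: 471.0
        beta_endpoint_kev: 1372.0
        daughter: Bi-211
  Bi-211:
    half_life_s: 128.4           # 2.14 min
    branches:
      - mode: alpha
        fraction: 1.0
        energy_kev: 6622.0
        daughter: Tl-207
  Tl-207:
    half_life_s: 286.2           # 4.77 min
    branches:
      - mode: beta_minus
        fraction: 1.0
        beta_mean_kev: 493.0
        beta_endpoint_kev: 1418.0
        daughter: Pb-207
  Pb-207:
    stable: true

  # alpha calibration sources (single dominant line each)
  Pu-239:
    half_life_s: 760854000000.0
    branches:
      - mode: alpha
        fraction: 1.0
        energy_kev: 5144.0
        daughter: U-235
  U-235:
    stable: true
  Am-241:
    half_life_s: 13638106000.0
    branches:
      - mode: alpha
        fraction: 1.0
        energy_kev: 5485.0
        daughter: Np-237
  Np-237:
    stable: true
  Cm-244:
    half_life_s: 571195000.0
    branches:
      - mode: alpha
        fraction: 1.0
        energy_kev: 5804.0
        daughter: Pu-240
  Pu-240:
    stable: true
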