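{
 "NO2-": {
  "symbols": [
   "N",
   "O",
   "O"
  ],
  "coords_bohr": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    2.0365804666604053,
    0.0,
    -1.2860786674966351
   ],
   [
    -2.0365804666604053,
    0.0,
    -1.2860786674966351
   ]
  ],
  "charge": -1,
  "opt_params": [
   2.4086631844599267,
   115.4560594724752
  ],
  "e_opt_hartree": -205.01645489779946,
  "freqs_cm": [
   775.4711609347181,
   1382.570272137741,
   1422.6568783608825
  ],
  "evib_298_kcal": 5.181953293271576,
  "provenance": {
   "optimization": "B3LYP/6-31g**, Nelder-Mead on symmetry-internal parameters, this package",
   "hessian": "B3LYP/6-31g, central differences 0.01 bohr, this package",
   "dispersion": "none"
  }
 },
 "HNO2": {
  "symbols": [
   "H",
   "O",
   "N",
   "O"
  ],
  "coords_bohr": [
   [
    -0.39089517174540545,
    0.0,
    1.795841921498543
   ],
   [
    0.0,
    0.0,
    0.0
   ],
   [
    2.6947055437000733,
    0.0,
    0.0
   ],
   [
    3.4740903318294705,
    0.0,
    -2.0947057548224213
   ]
  ],
  "charge": 0,
  "opt_params": [
   1.8378920649225976,
   2.6947055437000733,
   2.2350017555370454,
   102.27984552111964,
   110.40890714883986
  ],
  "e_opt_hartree": -205.59914521196688,
  "freqs_cm": [
   486.4475698048058,
   627.2263484914702,
   889.6612850707232,
   1263.412453985695,
   1819.586127246732,
   3740.2796461769112
  ],
  "evib_298_kcal": 12.900845559401725,
  "provenance": {
   "optimization": "B3LYP/6-31g**, Nelder-Mead on symmetry-internal parameters, this package",
   "hessian": "B3LYP/6-31g, central differences 0.01 bohr, this package",
   "dispersion": "none"
  }
 },
 "NH3": {
  "symbols": [
   "N",
   "H",
   "H",
   "H"
  ],
  "coords_bohr": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    1.7569456396528358,
    0.0,
    -0.8025069033490354
   ],
   [
    -0.8784728198264175,
    1.521559557007656,
    -0.8025069033490354
   ],
   [
    -0.8784728198264187,
    -1.5215595570076554,
    -0.8025069033490354
   ]
  ],
  "charge": 0,
  "opt_params": [
   1.9315473876190483,
   103.9498523307552
  ],
  "e_opt_hartree": -56.506258639233444,
  "freqs_cm": [
   1119.3729000369926,
   1734.5672984497644,
   1734.7624823759008,
   3479.1860891564493,
   3618.880230193188,
   3618.94688400603
  ],
  "evib_298_kcal": 21.897412565135973,
  "provenance": {
   "optimization": "B3LYP/6-31g**, Nelder-Mead on symmetry-internal parameters, this package",
   "hessian": "B3LYP/6-31g, central differences 0.01 bohr, this package",
   "dispersion": "none"
  }
 },
 "NH4+": {
  "symbols": [
   "N",
   "H",
   "H",
   "H",
   "H"
  ],
  "coords_bohr": [
   [
    0.0,
    0.0,
    0.0
   ],
   [
    1.1222374559083312,
    1.1222374559083312,
    1.1222374559083312
   ],
   [
    -1.1222374559083312,
    -1.1222374559083312,
    1.1222374559083312
   ],
   [
    -1.1222374559083312,
    1.1222374559083312,
    -1.1222374559083312
   ],
   [
    1.1222374559083312,
    -1.1222374559083312,
    -1.1222374559083312
   ]
  ],
  "charge": 1,
  "opt_params": [
   1.9437722917900673
  ],
  "e_opt_hartree": -56.86024136064728,
  "freqs_cm": [
   1594.8491951131855,
   1595.645602154199,
   1595.6456032632925,
   1760.5325891225561,
   1761.4675819888378,
   3419.340641139582,
   3556.455085184971,
   3556.4711045959693,
   3556.4711075871664
  ],
  "evib_298_kcal": 32.02620724682139,
  "provenance": {
   "optimization": "B3LYP/6-31g**, Nelder-Mead on symmetry-internal parameters, this package",
   "hessian": "B3LYP/6-31g, central differences 0.01 bohr, this package",
   "dispersion": "none"
  }
 }
}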