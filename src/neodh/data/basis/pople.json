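{
  "sto-3g": {
    "H": [
      {"l": "s", "exps": [3.42525091, 0.62391373, 0.16885540],
       "coefs": [0.15432897, 0.53532814, 0.44463454]}
    ],
    "He": [
      {"l": "s", "exps": [6.36242139, 1.15892300, 0.31364979],
       "coefs": [0.15432897, 0.53532814, 0.44463454]}
    ],
    "C": [
      {"l": "s", "exps": [71.6168370, 13.0450960, 3.5305122],
       "coefs": [0.15432897, 0.53532814, 0.44463454]},
      {"l": "sp", "exps": [2.9412494, 0.6834831, 0.2222899],
       "cs": [-0.09996723, 0.39951283, 0.70115470],
       "cp": [0.15591627, 0.60768372, 0.39195739]}
    ],
    "N": [
      {"l": "s", "exps": [99.1061690, 18.0523120, 4.8856602],
       "coefs": [0.15432897, 0.53532814, 0.44463454]},
      {"l": "sp", "exps": [3.7804559, 0.8784966, 0.2857144],
       "cs": [-0.09996723, 0.39951283, 0.70115470],
       "cp": [0.15591627, 0.60768372, 0.39195739]}
    ],
    "O": [
      {"l": "s", "exps": [130.7093200, 23.8088610, 6.4436083],
       "coefs": [0.15432897, 0.53532814, 0.44463454]},
      {"l": "sp", "exps": [5.0331513, 1.1695961, 0.3803890],
       "cs": [-0.09996723, 0.39951283, 0.70115470],
       "cp": [0.15591627, 0.60768372, 0.39195739]}
    ]
  },
  "6-31g": {
    "H": [
      {"l": "s", "exps": [18.73113696, 2.825394365, 0.6401216923],
       "coefs": [0.03349460434, 0.2347269535, 0.8137573261]},
      {"l": "s", "exps": [0.1612777588], "coefs": [1.0]}
    ],
    "C": [
      {"l": "s",
       "exps": [3047.524880, 457.3695180, 103.9486850, 29.21015530,
                9.286662960, 3.163926960],
       "coefs": [0.001834737132, 0.01403732281, 0.06884262226,
                 0.2321844432, 0.4679413484, 0.3623119853]},
      {"l": "sp", "exps": [7.868272350, 1.881288540, 0.5442492580],
       "cs": [-0.1193324198, -0.1608541517, 1.143456438],
       "cp": [0.06899906659, 0.3164239610, 0.7443082909]},
      {"l": "sp", "exps": [0.1687144782], "cs": [1.0], "cp": [1.0]}
    ],
    "N": [
      {"l": "s",
       "exps": [4173.511460, 627.4579110, 142.9020930, 40.23432930,
                12.82021290, 4.390437010],
       "coefs": [0.001834772160, 0.01399462700, 0.06858655181,
                 0.2322408730, 0.4690699481, 0.3604551991]},
      {"l": "sp", "exps": [11.74056880, 2.439354700, 0.6828586475],
       "cs": [-0.1149611817, -0.1691174786, 1.145851947],
       "cp": [0.06757974388, 0.3239072959, 0.7408951398]},
      {"l": "sp", "exps": [0.2129394647], "cs": [1.0], "cp": [1.0]}
    ],
    "O": [
      {"l": "s",
       "exps": [5484.671660, 825.2349460, 188.0469580, 52.96450000,
                16.89757040, 5.799635340],
       "coefs": [0.001831074430, 0.01395017220, 0.06844507810,
                 0.2327143360, 0.4701928980, 0.3585208530]},
      {"l": "sp", "exps": [15.53961625, 3.599933586, 1.013761750],
       "cs": [-0.1107775495, -0.1480262627, 1.130767015],
       "cp": [0.07087426823, 0.3397528391, 0.7271585773]},
      {"l": "sp", "exps": [0.2700058226], "cs": [1.0], "cp": [1.0]}
    ]
  },
  "polarization_d": {"C": 0.8, "N": 0.8, "O": 0.8},
  "polarization_p": {"H": 1.1},
  "diffuse_sp": {"C": 0.0438, "N": 0.0639, "O": 0.0845},
  "diffuse_s": {"H": 0.036}
}
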