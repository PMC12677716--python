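{
  "_provenance": "4-Gaussian X-ray atomic scattering factor coefficients (a1-a4, b1-b4, c), International Tables for Crystallography Vol. C, Table 6.1.1.4 (Cromer-Mann parameterization). f(q) = sum_i a_i exp(-b_i (q/4pi)^2) + c, with q = 4 pi sin(theta)/lambda in 1/Angstrom and b_i in Angstrom^2. f(0) equals the element's electron number.",
  "H": {"a": [0.489918, 0.262003, 0.196767, 0.049879],
        "b": [20.6593, 7.74039, 49.5519, 2.20159],
        "c": 0.001305},
  "C": {"a": [2.31000, 1.02000, 1.58860, 0.865000],
        "b": [20.8439, 10.2075, 0.568700, 51.6512],
        "c": 0.215600},
  "N": {"a": [12.2126, 3.13220, 2.01250, 1.16630],
        "b": [0.005700, 9.89330, 28.9975, 0.582600],
        "c": -11.529},
  "O": {"a": [3.04850, 2.28680, 1.54630, 0.867000],
        "b": [13.2771, 5.70110, 0.323900, 32.9089],
        "c": 0.250800}
}
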