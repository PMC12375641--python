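# Default radiobiological model registry.
#
# d50_cgy is D50 for poisson_lq models and TD50(1) for lyman models.
# alpha_beta is in Gy (converted to cGy at load). gamma50 is absent for the
# poisson_lq rows: it is not part of the published parameter set and must be
# supplied via config (a documented default of 1.5 is applied otherwise;
# outputs record the value used).
models:
  - structure: PTV
    endpoint: "TCP Poisson-LQ"
    family: poisson_lq
    d50_cgy: 4920
    a: 9
    alpha_beta_gy: 10
  - structure: Lungs
    endpoint: "Symptomatic or Radiographic Pneumonitis (<=6 months)"
    family: lyman
    d50_cgy: 2190
    m: 0.80
    n: 0.37
    alpha_beta_gy: 3
  - structure: Lungs
    endpoint: "Symptomatic or Radiographic Fibrosis (>6 months)"
    family: lyman
    d50_cgy: 2880
    m: 0.5
    n: 0.34
    alpha_beta_gy: 3
  - structure: Esophagus
    endpoint: "Clinical stricture (NTCP Poisson-LQ)"
    family: poisson_lq
    d50_cgy: 6800
    alpha_beta_gy: 3
  - structure: Esophagus
    endpoint: "Esophagitis, grade >= 2"
    family: lyman
    d50_cgy: 5100
    m: 0.32
    n: 0.44
    alpha_beta_gy: 10
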