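strata:
- parity: multiparous
  n: 344001
  prevalence:
    age_ge40: 0.04539812384266325
    low_education: 0.60191394792457
    non_cohabiting: 0.028642358597794775
    dm: 0.007299397385472716
    hbp: 0.008287766605329636
    autoimmune: 0.002241272554440249
    ckd: 0.005372077406751725
    obesity: 0.12842113831064444
    previous_pe: 0.03897372391359327
    smoker: 0.1510547934453679
    multiple_pregnancy: 0.016351696652044615
    art: 0.015008677300356685
    gestational_diabetes: 0.008610440085929982
  adjusted_or:
    age_ge40: 1.73
    low_education: 1.2
    non_cohabiting: 1.24
    dm: 2.64
    hbp: 4.63
    autoimmune: 1.54
    ckd: 2.15
    obesity: 2.44
    previous_pe: 10.6
    smoker: 0.9
    multiple_pregnancy: 5.42
    art: 1.71
    gestational_diabetes: 1.85
  target_incidence: 0.02410167412304034
  exposure_corr: null
- parity: primiparous
  n: 282599
  prevalence:
    age_ge40: 0.016217325609786306
    low_education: 0.5553345907098044
    non_cohabiting: 0.060187757210747386
    dm: 0.006015590996429569
    hbp: 0.0073460981815222275
    autoimmune: 0.002176228507531874
    ckd: 0.004716931057788598
    obesity: 0.09938464042689464
    smoker: 0.2095088800738856
    multiple_pregnancy: 0.012222265471569255
    art: 0.039324272201954
    gestational_diabetes: 0.007300096603314237
  adjusted_or:
    age_ge40: 1.49
    low_education: 1.13
    non_cohabiting: 0.94
    dm: 4.29
    hbp: 4.07
    autoimmune: 1.12
    ckd: 1.34
    obesity: 2.56
    smoker: 0.83
    multiple_pregnancy: 4.27
    art: 1.17
    gestational_diabetes: 2.04
  target_incidence: 0.05566898679754705
  exposure_corr: null
pregnancies_per_mother_decay: 0.5
max_pregnancies_per_mother: 4
emit_multiple_birth_duplicates: false
seed: 0
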