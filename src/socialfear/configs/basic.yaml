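network:
  name: basic
  units:
  - name: MeA
    area: MeA
    sign: +
  - name: Hip1
    area: vHIP
    sign: +
  - name: Hip2
    area: vHIP
    sign: +
  - name: lPBN
    area: lPBN
    sign: +
  - name: MDT
    area: MDT
    sign: +
  - name: Hyp1
    area: VMHvl
    sign: +
  - name: Hyp2
    area: VMHvl
    sign: +
  - name: HypIN1
    area: VMHvl
    sign: '-'
  - name: HypIN2
    area: VMHvl
    sign: '-'
  - name: Pyr1
    area: mPFC
    sign: +
  - name: Pyr2
    area: mPFC
    sign: +
  - name: Pv
    area: mPFC
    sign: '-'
  - name: Som1
    area: mPFC
    sign: '-'
  - name: Som2
    area: mPFC
    sign: '-'
  - name: Som3
    area: mPFC
    sign: '-'
  - name: dPag1
    area: dPAG
    sign: +
  connections:
  - pre: MeA
    post: MDT
    weight: 3.0
    plastic: false
  - pre: lPBN
    post: Hyp1
    weight: 0.85
    plastic: false
  - pre: Hyp1
    post: HypIN2
    weight: 1.2
    plastic: false
  - pre: HypIN2
    post: Hyp2
    weight: -2.0
    plastic: false
  - pre: Hyp2
    post: HypIN1
    weight: 0.3
    plastic: false
  - pre: HypIN1
    post: Hyp1
    weight: -0.12
    plastic: false
  - pre: Pv
    post: Pyr1
    weight: -0.86
    plastic: false
  - pre: Som1
    post: Pv
    weight: -6.0
    plastic: false
  - pre: Som1
    post: Pyr2
    weight: -6.0
    plastic: false
  - pre: Pyr1
    post: Som2
    weight: 1.8
    plastic: false
  - pre: Som2
    post: Pyr2
    weight: -1.3
    plastic: false
  - pre: Pyr2
    post: Som3
    weight: 0.5
    plastic: false
  - pre: Som3
    post: Pyr1
    weight: -1.0
    plastic: false
  - pre: Hyp1
    post: dPag1
    weight: 2.5
    plastic: false
  - pre: Pyr2
    post: dPag1
    weight: -3.2
    plastic: false
    sign_exception: true
  - pre: MeA
    post: Hyp1
    weight: 0.0765
    plastic: true
    w_min: 0.0765
    w_max: 1.2
  - pre: Hip1
    post: Hyp1
    weight: 0.038
    plastic: true
    w_min: 0.038
    w_max: 1.2
  - pre: Hip2
    post: Hyp1
    weight: 0.038
    plastic: true
    w_min: 0.038
    w_max: 1.2
  - pre: MeA
    post: Hyp2
    weight: 0.5
    plastic: true
    w_min: 0.35
    w_max: 1.2
  - pre: Hip1
    post: Hyp2
    weight: 0.5
    plastic: true
    w_min: 0.35
    w_max: 1.2
  - pre: Hip2
    post: Hyp2
    weight: 0.5
    plastic: true
    w_min: 0.35
    w_max: 1.2
  - pre: MDT
    post: Pyr1
    weight: 0.85
    plastic: true
    w_min: 0.85
    w_max: 1.23
  - pre: MDT
    post: Pyr2
    weight: 1.2
    plastic: true
    w_min: 0.84
    w_max: 1.8
  - pre: MDT
    post: Pv
    weight: 1.7
    plastic: true
    w_min: 0.4
    w_max: 1.7
  input_channels:
    conspecific:
      MeA: 1.0
    context1:
      Hip1: 1.0
    context2:
      Hip2: 1.0
    defeat:
      lPBN: 1.0
      Som1: 1.0
  plasticity:
    alpha: 0.002
    theta: 0.5
    enabled: true
    alpha_overrides:
      MeA->Hyp1: 0.004
      Hip1->Hyp1: 0.004
      Hip2->Hyp1: 0.004
      MeA->Hyp2: 0.004
      Hip1->Hyp2: 0.004
      Hip2->Hyp2: 0.004
      MDT->Pyr2: 0.0012
      MDT->Pv: 0.0009
    theta_overrides: {}
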