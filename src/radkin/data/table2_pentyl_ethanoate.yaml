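title: 5-CQA and 5-FQA + HOO* kinetics in pentyl ethanoate
provenance: >
  Published per-channel inputs in the lipid-like medium pentyl ethanoate at
  298.15 K, where only the neutral forms exist and SET is not feasible.
  The published tunneling column prints 0.7 and 0.0 for some HAT rows, which
  is impossible for an Eckart correction (kappa >= 1 by construction); those
  factors are treated as opaque multiplicative corrections and the rows with
  0.0 are reproducible only through their supplied k_app.
options:
  temperature: 298.15
  rate_source: supplied
media:
  - name: pentyl ethanoate
    aqueous: false
    temperature: 298.15
    viscosity: 8.62e-4
compounds:
  - id: 5-CQA
    pka_values: [3.5, 8.449]
    states:
      - id: neutral
        net_charge: 0
        deprotonation_count: 0
    pathways:
      - state: neutral
        mechanism: HAT
        site: 12OH
        dG_activation: "8.7 kcal/mol"
        kappa: 0.7
        k_app: 1.80e6
      - state: neutral
        mechanism: HAT
        site: 13OH
        dG_activation: "5.7 kcal/mol"
        kappa: 0.0
        k_app: 2.90e5
        notes: printed correction 0.0; row carried via supplied k_app only.
      - state: neutral
        mechanism: RAF
        site: C8
        dG_activation: "19.7 kcal/mol"
        kappa: 1.5
        k_app: 3.40e-2
  - id: 5-FQA
    pka_values: [3.5, 9.316]
    states:
      - id: neutral
        net_charge: 0
        deprotonation_count: 0
    pathways:
      - state: neutral
        mechanism: HAT
        site: 13OH
        dG_activation: "7.9 kcal/mol"
        kappa: 0.0
        k_app: 4.10e4
        notes: printed correction 0.0; row carried via supplied k_app only.
      - state: neutral
        mechanism: RAF
        site: C8
        dG_activation: "16.0 kcal/mol"
        kappa: 1.5
        k_app: 1.60e1
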