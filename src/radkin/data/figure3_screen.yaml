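title: Thermodynamic screen of candidate channels (reaction Gibbs energies)
provenance: >
  Reaction Gibbs energies quoted as ranges in the published thermodynamic
  evaluation, stored as individual channel entries at the range endpoints.
  Each note records the medium and which endpoint the value is.  These
  entries feed the feasibility screen only; no activation energies are
  attached, so they never enter kinetics.
options:
  temperature: 298.15
  borderline_cutoff: "5.0 kcal/mol"
media:
  - name: water
    aqueous: true
    pH: 7.4
    viscosity: 8.91e-4
  - name: pentyl ethanoate
    aqueous: false
    viscosity: 8.62e-4
compounds:
  - id: 5-CQA
    pka_values: [3.5, 8.449]
    states:
      - {id: mono-anion, net_charge: -1, deprotonation_count: 1}
      - {id: dianion, net_charge: -2, deprotonation_count: 2}
      - {id: neutral, net_charge: 0, deprotonation_count: 0}
    pathways:
      - state: mono-anion
        mechanism: HAT
        site: aromatic-OH
        dG_reaction: "-13.0 kcal/mol"
        notes: water; most exergonic endpoint of the aromatic-OH HAT range.
      - state: mono-anion
        mechanism: HAT
        site: non-aromatic-OH
        dG_reaction: "45.1 kcal/mol"
        notes: water; upper endpoint of the non-aromatic-OH HAT range.
      - state: dianion
        mechanism: RAF
        site: C8
        dG_reaction: "2.1 kcal/mol"
        notes: water; almost isergonic, retained for kinetics.
      - state: mono-anion
        mechanism: SET
        dG_reaction: "29.3 kcal/mol"
        set_params: {dG0_set: "29.3 kcal/mol"}
        notes: water; mono-anion SET, strongly endergonic, excluded.
      - state: dianion
        mechanism: SET
        dG_reaction: "4.8 kcal/mol"
        set_params: {dG0_set: "4.8 kcal/mol"}
        notes: water; dianion SET, slightly endergonic, retained.
      - state: neutral
        mechanism: HAT
        site: phenolic-OH
        dG_reaction: "-6.9 kcal/mol"
        notes: pentyl ethanoate; exergonic endpoint of the phenolic HAT range.
      - state: neutral
        mechanism: RAF
        site: C8
        dG_reaction: "4.4 kcal/mol"
        notes: pentyl ethanoate; endergonic but retained for kinetics.
  - id: 5-FQA
    pka_values: [3.5, 9.316]
    states:
      - {id: mono-anion, net_charge: -1, deprotonation_count: 1}
      - {id: dianion, net_charge: -2, deprotonation_count: 2}
      - {id: neutral, net_charge: 0, deprotonation_count: 0}
    pathways:
      - state: mono-anion
        mechanism: HAT
        site: aromatic-OH
        dG_reaction: "-5.8 kcal/mol"
        notes: water; least exergonic endpoint of the aromatic-OH HAT range.
      - state: mono-anion
        mechanism: HAT
        site: non-aromatic-OH
        dG_reaction: "31.9 kcal/mol"
        notes: water; lower endpoint of the non-aromatic-OH HAT range.
      - state: dianion
        mechanism: RAF
        site: C8
        dG_reaction: "2.7 kcal/mol"
        notes: water; almost isergonic, retained for kinetics.
      - state: mono-anion
        mechanism: SET
        dG_reaction: "29.8 kcal/mol"
        set_params: {dG0_set: "29.8 kcal/mol"}
        notes: water; mono-anion SET, strongly endergonic, excluded.
      - state: dianion
        mechanism: SET
        dG_reaction: "2.0 kcal/mol"
        set_params: {dG0_set: "2.0 kcal/mol"}
        notes: water; dianion SET, slightly endergonic, retained.
      - state: neutral
        mechanism: HAT
        site: phenolic-OH
        dG_reaction: "-1.4 kcal/mol"
        notes: pentyl ethanoate; least exergonic endpoint of the phenolic HAT range.
      - state: neutral
        mechanism: RAF
        site: C8
        dG_reaction: "4.8 kcal/mol"
        notes: pentyl ethanoate; endergonic but retained for kinetics.
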