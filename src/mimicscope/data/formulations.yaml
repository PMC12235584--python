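# EV-mimicking artificial lipidic compositions: mass percentage per species.
# "mimic-1..3": base formulations; "ce-mimic-1..3": cholesterol-enriched
# variants (cholesterol raised to 30%, other species rebalanced); "3c": the
# earlier three-component reference formulation.
formulations:
  3c:
    label: "3C"
    species:
      cholesterol: 23.6
      DSPE-PEG(2000) amine: 6.6
      DOPC: 12.5
      18:1 PA: 57.3
  mimic-1:
    label: "Mimic 1"
    species:
      cholesterol: 13.0
      16:0 SM: 20.0
      DSPE-PEG(2000) amine: 16.0
      DOPC: 26.0
      18:1 PA: 25.0
  mimic-2:
    label: "Mimic 2"
    species:
      cholesterol: 13.0
      16:0 SM: 20.0
      DSPE-PEG(2000) amine: 16.0
      DOPC: 26.0
      16:0 PS: 25.0
  mimic-3:
    label: "Mimic 3"
    species:
      cholesterol: 13.0
      16:0 SM: 20.0
      DSPE-PEG(2000) amine: 10.0
      18:2 PE: 6.0
      DOPC: 26.0
      16:0 PS: 25.0
  ce-mimic-1:
    label: "CE Mimic 1"
    species:
      cholesterol: 30.0
      16:0 SM: 16.1
      DSPE-PEG(2000) amine: 12.9
      DOPC: 20.9
      18:1 PA: 20.1
  ce-mimic-2:
    label: "CE Mimic 2"
    species:
      cholesterol: 30.0
      16:0 SM: 16.1
      DSPE-PEG(2000) amine: 12.9
      DOPC: 20.9
      16:0 PS: 20.1
  ce-mimic-3:
    label: "CE Mimic 3"
    species:
      cholesterol: 30.0
      16:0 SM: 16.1
      DSPE-PEG(2000) amine: 8.0
      18:2 PE: 4.8
      DOPC: 20.9
      16:0 PS: 20.1
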