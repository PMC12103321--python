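{
  "version": "1.0",
  "comment": "Carbon fractions are recomputed from the formulas at load time; the stored values are a checksum. Densities in g/cm^3. Au doping of in-house PE/PP/PVC is ignored (dopant mass fraction unknown).",
  "materials": [
    {
      "name": "PS",
      "formula": "C8H8",
      "carbon_fraction": 0.9226,
      "density": 1.05,
      "description": "polystyrene repeat unit"
    },
    {
      "name": "PE",
      "formula": "CH2",
      "carbon_fraction": 0.8563,
      "density": 0.95,
      "description": "polyethylene repeat unit"
    },
    {
      "name": "PP",
      "formula": "C3H6",
      "carbon_fraction": 0.8563,
      "density": 0.905,
      "description": "polypropylene repeat unit"
    },
    {
      "name": "PVC",
      "formula": "C2H3Cl",
      "carbon_fraction": 0.3844,
      "density": 1.4,
      "description": "poly(vinyl chloride) repeat unit"
    },
    {
      "name": "PET",
      "formula": "C10H8O4",
      "carbon_fraction": 0.625,
      "density": 1.38,
      "description": "poly(ethylene terephthalate) repeat unit"
    },
    {
      "name": "cellulose",
      "formula": "C6H10O5",
      "carbon_fraction": 0.4445,
      "density": 1.5,
      "description": "anhydroglucose repeat unit (nanocellulose)"
    },
    {
      "name": "KHP",
      "formula": "C8H5KO4",
      "carbon_fraction": 0.4705,
      "density": 1.64,
      "description": "potassium hydrogen phthalate, TC calibrant"
    },
    {
      "name": "Na2CO3",
      "formula": "Na2CO3",
      "carbon_fraction": 0.1133,
      "density": 2.54,
      "description": "sodium carbonate, TIC calibrant"
    }
  ]
}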