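{
  "compartments": [
    {
      "id": "cytosol",
      "name": "cytosol",
      "parent": "liver"
    },
    {
      "id": "liver",
      "name": "liver cell",
      "parent": null
    },
    {
      "id": "mito",
      "name": "mitochondrion",
      "parent": "cytosol"
    }
  ],
  "format": "smda-network",
  "metabolites": [
    {
      "id": "accoa",
      "name": "Acetyl-CoA",
      "synonyms": []
    },
    {
      "id": "akg",
      "name": "2-Oxoglutarate",
      "synonyms": [
        "alpha-Ketoglutarate"
      ]
    },
    {
      "id": "cit",
      "name": "Citrate",
      "synonyms": []
    },
    {
      "id": "fum",
      "name": "Fumarate",
      "synonyms": []
    },
    {
      "id": "g6p",
      "name": "D-Glucose 6-phosphate",
      "synonyms": [
        "G6P"
      ]
    },
    {
      "id": "glc",
      "name": "D-Glucose",
      "synonyms": [
        "Glucose"
      ]
    },
    {
      "id": "icit",
      "name": "Isocitrate",
      "synonyms": []
    },
    {
      "id": "oaa",
      "name": "Oxaloacetate",
      "synonyms": []
    },
    {
      "id": "pyr",
      "name": "Pyruvate",
      "synonyms": []
    },
    {
      "id": "suc",
      "name": "Succinate",
      "synonyms": []
    },
    {
      "id": "succoa",
      "name": "Succinyl-CoA",
      "synonyms": []
    }
  ],
  "name": "tca-glycolysis-fixture",
  "pathways": [
    {
      "compartments": [
        "cytosol"
      ],
      "id": "glycolysis",
      "name": "Glycolysis",
      "reactions": [
        "hex",
        "glyc_lower"
      ]
    },
    {
      "compartments": [
        "mito"
      ],
      "id": "tca",
      "name": "TCA Cycle",
      "reactions": [
        "pdh",
        "cs",
        "aco",
        "idh",
        "kgdh",
        "scs",
        "sdh",
        "fum_mdh"
      ]
    }
  ],
  "pools": [
    {
      "compartment": "mito",
      "id": "pool:accoa@mito",
      "metabolite": "accoa"
    },
    {
      "compartment": "mito",
      "id": "pool:akg@mito",
      "metabolite": "akg"
    },
    {
      "compartment": "mito",
      "id": "pool:cit@mito",
      "metabolite": "cit"
    },
    {
      "compartment": "mito",
      "id": "pool:fum@mito",
      "metabolite": "fum"
    },
    {
      "compartment": "cytosol",
      "id": "pool:g6p@cytosol",
      "metabolite": "g6p"
    },
    {
      "compartment": "cytosol",
      "id": "pool:glc@cytosol",
      "metabolite": "glc"
    },
    {
      "compartment": "mito",
      "id": "pool:icit@mito",
      "metabolite": "icit"
    },
    {
      "compartment": "mito",
      "id": "pool:oaa@mito",
      "metabolite": "oaa"
    },
    {
      "compartment": "cytosol",
      "id": "pool:pyr@cytosol",
      "metabolite": "pyr"
    },
    {
      "compartment": "mito",
      "id": "pool:pyr@mito",
      "metabolite": "pyr"
    },
    {
      "compartment": "mito",
      "id": "pool:suc@mito",
      "metabolite": "suc"
    },
    {
      "compartment": "mito",
      "id": "pool:succoa@mito",
      "metabolite": "succoa"
    }
  ],
  "reactions": [
    {
      "collapsed_from": null,
      "enzymes": [
        "Aconitase"
      ],
      "id": "aco",
      "name": "aconitase",
      "participants": [
        {
          "pool": "pool:cit@mito",
          "role": "substrate"
        },
        {
          "pool": "pool:icit@mito",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [
        "Citrate Synthase"
      ],
      "id": "cs",
      "name": "citrate synthase",
      "participants": [
        {
          "pool": "pool:accoa@mito",
          "role": "substrate"
        },
        {
          "pool": "pool:oaa@mito",
          "role": "substrate"
        },
        {
          "pool": "pool:cit@mito",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [
        "Fumarase",
        "Malate dehydrogenase"
      ],
      "id": "fum_mdh",
      "name": "fumarase / malate dehydrogenase (lumped)",
      "participants": [
        {
          "pool": "pool:fum@mito",
          "role": "substrate"
        },
        {
          "pool": "pool:oaa@mito",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [
        "Pyruvate kinase"
      ],
      "id": "glyc_lower",
      "name": "lower glycolysis (lumped)",
      "participants": [
        {
          "pool": "pool:g6p@cytosol",
          "role": "substrate"
        },
        {
          "pool": "pool:pyr@cytosol",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [
        "Hexokinase"
      ],
      "id": "hex",
      "name": "hexokinase",
      "participants": [
        {
          "pool": "pool:glc@cytosol",
          "role": "substrate"
        },
        {
          "pool": "pool:g6p@cytosol",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [
        "Isocitrate dehydrogenase"
      ],
      "id": "idh",
      "name": "isocitrate dehydrogenase",
      "participants": [
        {
          "pool": "pool:icit@mito",
          "role": "substrate"
        },
        {
          "pool": "pool:akg@mito",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [
        "alpha-Ketoglutarate dehydrogenase"
      ],
      "id": "kgdh",
      "name": "alpha-ketoglutarate dehydrogenase",
      "participants": [
        {
          "pool": "pool:akg@mito",
          "role": "substrate"
        },
        {
          "pool": "pool:succoa@mito",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [
        "Pyruvate dehydrogenase"
      ],
      "id": "pdh",
      "name": "pyruvate dehydrogenase",
      "participants": [
        {
          "pool": "pool:pyr@mito",
          "role": "substrate"
        },
        {
          "pool": "pool:accoa@mito",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [
        "Succinyl-CoA synthetase"
      ],
      "id": "scs",
      "name": "succinyl-CoA synthetase",
      "participants": [
        {
          "pool": "pool:succoa@mito",
          "role": "substrate"
        },
        {
          "pool": "pool:suc@mito",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [
        "Succinate dehydrogenase"
      ],
      "id": "sdh",
      "name": "succinate dehydrogenase",
      "participants": [
        {
          "pool": "pool:suc@mito",
          "role": "substrate"
        },
        {
          "pool": "pool:fum@mito",
          "role": "product"
        }
      ],
      "reversible": false
    }
  ],
  "version": 1
}
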