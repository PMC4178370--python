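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
      "id": "adsuc",
      "name": "Adenylosuccinate",
      "synonyms": []
    },
    {
      "id": "arg",
      "name": "L-Arginine",
      "synonyms": [
        "Arginine"
      ]
    },
    {
      "id": "argsuc",
      "name": "Argininosuccinate",
      "synonyms": []
    },
    {
      "id": "asp",
      "name": "L-Aspartate",
      "synonyms": [
        "Aspartate"
      ]
    },
    {
      "id": "casp",
      "name": "N-Carbamoyl-L-aspartate",
      "synonyms": []
    },
    {
      "id": "cit",
      "name": "Citrulline",
      "synonyms": []
    },
    {
      "id": "cp",
      "name": "Carbamoyl phosphate",
      "synonyms": [
        "CP"
      ]
    },
    {
      "id": "fum",
      "name": "Fumarate",
      "synonyms": []
    },
    {
      "id": "imp",
      "name": "IMP",
      "synonyms": [
        "Inosine monophosphate"
      ]
    },
    {
      "id": "nh3",
      "name": "Ammonia",
      "synonyms": [
        "NH3"
      ]
    },
    {
      "id": "orn",
      "name": "Ornithine",
      "synonyms": []
    },
    {
      "id": "pi",
      "name": "Phosphate",
      "synonyms": [
        "Pi"
      ]
    },
    {
      "id": "urea",
      "name": "Urea",
      "synonyms": []
    }
  ],
  "name": "urea-cycle-fixture",
  "pathways": [
    {
      "compartments": [
        "cytosol"
      ],
      "id": "purine",
      "name": "Purine Biosynthesis",
      "reactions": [
        "adss"
      ]
    },
    {
      "compartments": [
        "cytosol",
        "mito"
      ],
      "id": "pyrimidine",
      "name": "Pyrimidine Biosynthesis",
      "reactions": [
        "atcase"
      ]
    },
    {
      "compartments": [
        "cytosol",
        "mito"
      ],
      "id": "urea_cycle",
      "name": "Urea Cycle",
      "reactions": [
        "cps1",
        "otc",
        "orn_transport",
        "cit_transport",
        "ass",
        "asl",
        "arg1"
      ]
    }
  ],
  "pools": [
    {
      "compartment": "cytosol",
      "id": "pool:adsuc@cytosol",
      "metabolite": "adsuc"
    },
    {
      "compartment": "cytosol",
      "id": "pool:arg@cytosol",
      "metabolite": "arg"
    },
    {
      "compartment": "cytosol",
      "id": "pool:argsuc@cytosol",
      "metabolite": "argsuc"
    },
    {
      "compartment": "cytosol",
      "id": "pool:asp@cytosol",
      "metabolite": "asp"
    },
    {
      "compartment": "cytosol",
      "id": "pool:casp@cytosol",
      "metabolite": "casp"
    },
    {
      "compartment": "cytosol",
      "id": "pool:cit@cytosol",
      "metabolite": "cit"
    },
    {
      "compartment": "mito",
      "id": "pool:cit@mito",
      "metabolite": "cit"
    },
    {
      "compartment": "mito",
      "id": "pool:cp@mito",
      "metabolite": "cp"
    },
    {
      "compartment": "cytosol",
      "id": "pool:fum@cytosol",
      "metabolite": "fum"
    },
    {
      "compartment": "cytosol",
      "id": "pool:imp@cytosol",
      "metabolite": "imp"
    },
    {
      "compartment": "mito",
      "id": "pool:nh3@mito",
      "metabolite": "nh3"
    },
    {
      "compartment": "cytosol",
      "id": "pool:orn@cytosol",
      "metabolite": "orn"
    },
    {
      "compartment": "mito",
      "id": "pool:orn@mito",
      "metabolite": "orn"
    },
    {
      "compartment": "mito",
      "id": "pool:pi@mito",
      "metabolite": "pi"
    },
    {
      "compartment": "cytosol",
      "id": "pool:urea@cytosol",
      "metabolite": "urea"
    }
  ],
  "reactions": [
    {
      "collapsed_from": null,
      "enzymes": [
        "Adenylosuccinate synthetase"
      ],
      "id": "adss",
      "name": "adenylosuccinate synthetase",
      "participants": [
        {
          "pool": "pool:imp@cytosol",
          "role": "substrate"
        },
        {
          "pool": "pool:asp@cytosol",
          "role": "substrate"
        },
        {
          "pool": "pool:adsuc@cytosol",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [
        "Arginase"
      ],
      "id": "arg1",
      "name": "arginase",
      "participants": [
        {
          "pool": "pool:arg@cytosol",
          "role": "substrate"
        },
        {
          "pool": "pool:urea@cytosol",
          "role": "product"
        },
        {
          "pool": "pool:orn@cytosol",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [
        "Argininosuccinate lyase"
      ],
      "id": "asl",
      "name": "argininosuccinate lyase",
      "participants": [
        {
          "pool": "pool:argsuc@cytosol",
          "role": "substrate"
        },
        {
          "pool": "pool:arg@cytosol",
          "role": "product"
        },
        {
          "pool": "pool:fum@cytosol",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [
        "Argininosuccinate synthetase"
      ],
      "id": "ass",
      "name": "argininosuccinate synthetase",
      "participants": [
        {
          "pool": "pool:cit@cytosol",
          "role": "substrate"
        },
        {
          "pool": "pool:asp@cytosol",
          "role": "substrate"
        },
        {
          "pool": "pool:argsuc@cytosol",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [
        "Aspartate transcarbamoylase"
      ],
      "id": "atcase",
      "name": "aspartate transcarbamoylase",
      "participants": [
        {
          "pool": "pool:cp@mito",
          "role": "substrate"
        },
        {
          "pool": "pool:asp@cytosol",
          "role": "substrate"
        },
        {
          "pool": "pool:casp@cytosol",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [],
      "id": "cit_transport",
      "name": "citrulline transporter",
      "participants": [
        {
          "pool": "pool:cit@mito",
          "role": "substrate"
        },
        {
          "pool": "pool:cit@cytosol",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [
        "Carbamoyl phosphate synthetase I"
      ],
      "id": "cps1",
      "name": "carbamoyl phosphate synthetase I",
      "participants": [
        {
          "pool": "pool:nh3@mito",
          "role": "substrate"
        },
        {
          "pool": "pool:cp@mito",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [],
      "id": "orn_transport",
      "name": "ornithine transporter",
      "participants": [
        {
          "pool": "pool:orn@cytosol",
          "role": "substrate"
        },
        {
          "pool": "pool:orn@mito",
          "role": "product"
        }
      ],
      "reversible": false
    },
    {
      "collapsed_from": null,
      "enzymes": [
        "Ornithine transcarbamoylase"
      ],
      "id": "otc",
      "name": "ornithine transcarbamoylase",
      "participants": [
        {
          "pool": "pool:cp@mito",
          "role": "substrate"
        },
        {
          "pool": "pool:orn@mito",
          "role": "substrate"
        },
        {
          "pool": "pool:cit@mito",
          "role": "product"
        },
        {
          "pool": "pool:pi@mito",
          "role": "product"
        }
      ],
      "reversible": false
    }
  ],
  "version": 1
}
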