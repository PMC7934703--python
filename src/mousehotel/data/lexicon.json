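{
  "version": "1.0",
  "categories": {
    "tumor_graft": {
      "Melanoma": ["2092003", "SCT", "Melanoma"]
    },
    "route": {
      "Subcutaneous": ["34206005", "SCT", "Subcutaneous route"],
      "Subcutaneous route": ["34206005", "SCT", "Subcutaneous route"]
    },
    "site": {
      "Flank": ["58602004", "SCT", "Flank"]
    },
    "laterality": {
      "Right": ["24028007", "SCT", "Right"],
      "Left": ["7771000", "SCT", "Left"]
    },
    "tissue": {
      "Skin": ["39937001", "SCT", "Skin"]
    },
    "taxon": {
      "Homo sapiens": ["337915000", "SCT", "Homo sapiens"],
      "Mus musculus": ["447612001", "SCT", "Mus musculus"]
    },
    "species": {
      "Mus musculus": ["447612001", "SCT", "Mus musculus"]
    },
    "strain": {
      "NOD.Cg-Prkdc<scid> Il2rg<tm1Wjl>/SzJ": ["3577020", "MGI", "NOD.Cg-Prkdc<scid> Il2rg<tm1Wjl>/SzJ"]
    }
  }
}
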