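{
  "cell_type": [
    {
      "canonical": "K562",
      "synonyms": ["K562", "K-562", "chronic myelogenous leukemia cell line", "CML cell line"]
    },
    {
      "canonical": "HEK293",
      "synonyms": ["HEK293", "HEK-293", "HEK293T", "HEK293FT", "human embryonic kidney 293"]
    },
    {
      "canonical": "SK-N-SH",
      "synonyms": ["SK-N-SH", "neuroblastoma cell line SK-N-SH"]
    },
    {
      "canonical": "A549",
      "synonyms": ["A549", "lung adenocarcinoma cell line"]
    },
    {
      "canonical": "HepG2",
      "synonyms": ["HepG2", "hepatocellular carcinoma cell line"]
    },
    {
      "canonical": "GM12878",
      "synonyms": ["GM12878", "lymphoblastoid cell line"]
    },
    {
      "canonical": "WTC11",
      "synonyms": ["WTC11", "WTC-11", "iPSC line WTC11"]
    },
    {
      "canonical": "cardiomyocyte",
      "synonyms": ["cardiomyocyte", "heart", "cardiac muscle cell"]
    }
  ],
  "molecule": [
    {
      "canonical": "NFKB1",
      "synonyms": ["NFKB1", "NF-kB", "nuclear factor kappa B"]
    },
    {
      "canonical": "mRNA",
      "synonyms": ["mRNA", "messenger RNA"]
    },
    {
      "canonical": "H3K27ac",
      "synonyms": ["H3K27ac", "histone H3 lysine 27 acetylation"]
    },
    {
      "canonical": "CTCF",
      "synonyms": ["CTCF", "CCCTC-binding factor"]
    }
  ],
  "species": [
    {
      "canonical": "Homo sapiens",
      "synonyms": ["Homo sapiens", "human"]
    },
    {
      "canonical": "Mus musculus",
      "synonyms": ["Mus musculus", "mouse"]
    },
    {
      "canonical": "Drosophila melanogaster",
      "synonyms": ["Drosophila melanogaster", "fruit fly"]
    },
    {
      "canonical": "Saccharomyces cerevisiae",
      "synonyms": ["Saccharomyces cerevisiae", "budding yeast", "yeast"]
    }
  ]
}
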