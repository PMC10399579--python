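{
  "prescreen": {"immune": "Immune", "non_immune": "Non_immune"},
  "tree": {
    "T": ["CD4_T", "CD8_T"],
    "B": ["Naive_B", "Memory_B", "Plasma"],
    "Monocyte": ["Classical_monocyte", "Non_classical_monocyte"],
    "Macrophage": ["M1_macrophage", "M2_macrophage"],
    "DC": ["pDC", "cDC"],
    "NK": ["NK_bright", "NK_dim"],
    "ILC": ["ILC1", "ILC2", "ILC3"],
    "Mast": [],
    "Neutrophil": [],
    "CD4_T": ["CD4_naive", "CD4_central_memory", "CD4_effector_memory", "Treg", "Tfh", "Th1", "Th2", "Th17"],
    "CD8_T": ["CD8_naive", "CD8_central_memory", "CD8_effector_memory", "CD8_cytotoxic", "CD8_exhausted"],
    "Naive_B": [],
    "Memory_B": [],
    "Plasma": [],
    "Classical_monocyte": [],
    "Non_classical_monocyte": [],
    "M1_macrophage": [],
    "M2_macrophage": [],
    "pDC": [],
    "cDC": [],
    "NK_bright": [],
    "NK_dim": [],
    "ILC1": [],
    "ILC2": [],
    "ILC3": [],
    "CD4_naive": [],
    "CD4_central_memory": [],
    "CD4_effector_memory": [],
    "Treg": [],
    "Tfh": [],
    "Th1": [],
    "Th2": [],
    "Th17": [],
    "CD8_naive": [],
    "CD8_central_memory": [],
    "CD8_effector_memory": [],
    "CD8_cytotoxic": [],
    "CD8_exhausted": []
  }
}
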