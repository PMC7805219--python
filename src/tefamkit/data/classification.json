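{
  "name": "",
  "children": [
    {
      "name": "Interspersed_Repeat",
      "children": [
        {
          "name": "Transposable_Element",
          "children": [
            {
              "name": "Class_I_Retrotransposition",
              "aliases": {"wicker": "Class_I", "curcio_derbyshire": "Class_1"},
              "children": [
                {
                  "name": "LTR",
                  "aliases": {"repeatmasker": "LTR", "wicker": "RL", "curcio_derbyshire": "DDE_LTR"},
                  "children": [
                    {"name": "Gypsy", "aliases": {"repeatmasker": "LTR/Gypsy", "repbase": "Gypsy", "wicker": "RLG"}},
                    {"name": "Copia", "aliases": {"repeatmasker": "LTR/Copia", "repbase": "Copia", "wicker": "RLC"}},
                    {"name": "Bel-Pao", "aliases": {"repeatmasker": "LTR/Pao", "repbase": "BEL", "wicker": "RLB"}},
                    {
                      "name": "ERV",
                      "aliases": {"repeatmasker": "LTR/ERV", "wicker": "RLR"},
                      "children": [
                        {"name": "ERV1", "aliases": {"repeatmasker": "LTR/ERV1", "repbase": "ERV1"}},
                        {"name": "ERVK", "aliases": {"repeatmasker": "LTR/ERVK", "repbase": "ERV2"}},
                        {"name": "ERVL", "aliases": {"repeatmasker": "LTR/ERVL", "repbase": "ERV3"}}
                      ]
                    },
                    {"name": "DIRS", "aliases": {"repeatmasker": "LTR/DIRS", "repbase": "DIRS", "wicker": "RYD", "curcio_derbyshire": "YR"}}
                  ]
                },
                {
                  "name": "LINE",
                  "aliases": {"repeatmasker": "LINE", "wicker": "RI", "curcio_derbyshire": "Target_primed"},
                  "children": [
                    {"name": "L1", "aliases": {"repeatmasker": "LINE/L1", "repbase": "L1", "wicker": "RIL", "curcio_derbyshire": "L1_group"}},
                    {"name": "L2", "aliases": {"repeatmasker": "LINE/L2", "repbase": "L2"}},
                    {"name": "CR1", "aliases": {"repeatmasker": "LINE/CR1", "repbase": "CR1"}},
                    {"name": "RTE", "aliases": {"repeatmasker": "LINE/RTE", "repbase": "RTE", "wicker": "RIR"}},
                    {"name": "R2", "aliases": {"repeatmasker": "LINE/R2", "repbase": "R2", "wicker": "RIR2"}},
                    {"name": "I-Jockey", "aliases": {"repeatmasker": "LINE/Jockey", "repbase": "Jockey", "wicker": "RIJ"}},
                    {"name": "Penelope", "aliases": {"repeatmasker": "LINE/Penelope", "repbase": "Penelope", "wicker": "RPP"}}
                  ]
                },
                {
                  "name": "SINE",
                  "aliases": {"repeatmasker": "SINE", "wicker": "RS"},
                  "children": [
                    {"name": "7SL-derived", "aliases": {"repeatmasker": "SINE/Alu", "repbase": "SINE1"}},
                    {"name": "tRNA-derived", "aliases": {"repeatmasker": "SINE/tRNA", "repbase": "SINE2", "wicker": "RST"}},
                    {"name": "5S-derived", "aliases": {"repeatmasker": "SINE/5S", "repbase": "SINE3", "wicker": "RSS"}}
                  ]
                },
                {
                  "name": "LINE-dependent_Retroposon",
                  "children": [
                    {"name": "SVA", "aliases": {"repeatmasker": "Retroposon/SVA", "repbase": "SVA"}},
                    {"name": "Retroposed_Gene", "aliases": {"repeatmasker": "Retroposon"}}
                  ]
                }
              ]
            },
            {
              "name": "Class_II_DNA_Transposition",
              "aliases": {"repeatmasker": "DNA", "wicker": "Class_II", "curcio_derbyshire": "Class_2"},
              "children": [
                {
                  "name": "Cut_and_Paste",
                  "aliases": {"wicker": "Subclass_1", "curcio_derbyshire": "DDE"},
                  "children": [
                    {
                      "name": "TIR",
                      "aliases": {"wicker": "DT"},
                      "children": [
                        {"name": "hAT", "aliases": {"repeatmasker": "DNA/hAT", "repbase": "hAT", "wicker": "DTA"}},
                        {"name": "Tc1-Mariner", "aliases": {"repeatmasker": "DNA/TcMar", "repbase": "Mariner/Tc1", "wicker": "DTT"}},
                        {"name": "Mutator", "aliases": {"repeatmasker": "DNA/MULE", "repbase": "MuDR", "wicker": "DTM"}},
                        {"name": "PIF-Harbinger", "aliases": {"repeatmasker": "DNA/PIF-Harbinger", "repbase": "Harbinger", "wicker": "DTH"}},
                        {"name": "PiggyBac", "aliases": {"repeatmasker": "DNA/PiggyBac", "repbase": "piggyBac", "wicker": "DTB"}},
                        {"name": "CACTA", "aliases": {"repeatmasker": "DNA/CMC-EnSpm", "repbase": "EnSpm/CACTA", "wicker": "DTC"}},
                        {"name": "Merlin", "aliases": {"repeatmasker": "DNA/Merlin", "repbase": "Merlin", "wicker": "DTE"}},
                        {"name": "P", "aliases": {"repeatmasker": "DNA/P", "repbase": "P", "wicker": "DTP"}},
                        {"name": "Transib", "aliases": {"repeatmasker": "DNA/CMC-Transib", "repbase": "Transib", "wicker": "DTR"}},
                        {"name": "Sola", "aliases": {"repeatmasker": "DNA/Sola", "repbase": "Sola"}},
                        {"name": "Zator", "aliases": {"repbase": "Zator"}},
                        {"name": "Ginger", "aliases": {"repbase": "Ginger"}}
                      ]
                    },
                    {"name": "Crypton", "aliases": {"repeatmasker": "DNA/Crypton", "repbase": "Crypton", "wicker": "DYC", "curcio_derbyshire": "Y_transposase"}}
                  ]
                },
                {
                  "name": "Rolling_Circle",
                  "aliases": {"curcio_derbyshire": "Y2"},
                  "children": [
                    {"name": "Helitron", "aliases": {"repeatmasker": "RC/Helitron", "repbase": "Helitron", "wicker": "DHH"}}
                  ]
                },
                {
                  "name": "Self_Synthesizing",
                  "children": [
                    {"name": "Maverick-Polinton", "aliases": {"repeatmasker": "DNA/Maverick", "repbase": "Polinton", "wicker": "DMM"}}
                  ]
                }
              ]
            }
          ]
        },
        {"name": "Pseudogene", "children": [{"name": "RNA", "children": []}, {"name": "DNA", "children": []}]},
        {"name": "Unknown"}
      ]
    },
    {
      "name": "Tandem_Repeat",
      "children": [
        {"name": "Satellite", "aliases": {"repeatmasker": "Satellite"}, "children": [
          {"name": "Centromeric", "aliases": {"repeatmasker": "Satellite/centr"}},
          {"name": "Acromeric", "aliases": {"repeatmasker": "Satellite/acro"}},
          {"name": "Telomeric", "aliases": {"repeatmasker": "Satellite/telo"}}
        ]},
        {"name": "Simple", "aliases": {"repeatmasker": "Simple_repeat"}},
        {"name": "Low_Complexity", "aliases": {"repeatmasker": "Low_complexity"}}
      ]
    },
    {
      "name": "Structural_RNA",
      "children": [
        {"name": "rRNA", "aliases": {"repeatmasker": "rRNA"}},
        {"name": "tRNA", "aliases": {"repeatmasker": "tRNA"}},
        {"name": "snRNA", "aliases": {"repeatmasker": "snRNA"}},
        {"name": "scRNA", "aliases": {"repeatmasker": "scRNA"}}
      ]
    },
    {"name": "Segmental_Duplication"},
    {"name": "Accidental_Expansion"}
  ]
}
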