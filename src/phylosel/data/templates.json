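{
  "_comment": "Downstream-tool capability tables and command templates. Flag spellings target: RAxML 8.2, RAxML-NG 1.2, IQ-TREE 2.2, PhyML 3.3, MrBayes 3.2, PAUP* 4a. Editing this file (not code) is the supported way to track new tool versions.",
  "raxml": {
    "dna_schemes": ["012345"],
    "dna_freqs": ["empirical", "ml"],
    "dna_het": ["G", "I+G"],
    "aa_matrices": ["DAYHOFF", "DCMUT", "JTT", "MTREV", "WAG", "RTREV", "CPREV", "VT", "BLOSUM62", "MTMAM", "LG", "MTART", "MTZOA", "HIVB", "HIVW", "JTTDCMUT", "FLU"],
    "aa_freqs": ["model", "empirical"],
    "aa_het": ["G", "I+G"],
    "command": "raxmlHPC-SSE3 -s {msa} -n best -p 2 -m {model}"
  },
  "raxml-ng": {
    "dna_schemes": ["000000", "010010", "010020", "012210", "010212", "012012", "012230", "010232", "012032", "012314", "012345"],
    "dna_freqs": ["equal", "empirical", "ml"],
    "dna_het": ["none", "I", "G", "I+G", "R"],
    "aa_matrices": ["DAYHOFF", "DCMUT", "JTT", "MTREV", "WAG", "RTREV", "CPREV", "VT", "BLOSUM62", "MTMAM", "LG", "MTART", "MTZOA", "HIVB", "HIVW", "JTTDCMUT", "FLU"],
    "aa_freqs": ["model", "empirical", "ml"],
    "aa_het": ["none", "I", "G", "I+G", "R"],
    "command": "raxml-ng --msa {msa} --model {model}"
  },
  "iqtree": {
    "dna_schemes": ["000000", "010010", "010020", "012210", "010212", "012012", "012230", "010232", "012032", "012314", "012345"],
    "dna_freqs": ["equal", "empirical", "ml"],
    "dna_het": ["none", "I", "G", "I+G", "R"],
    "aa_matrices": ["DAYHOFF", "DCMUT", "JTT", "MTREV", "WAG", "RTREV", "CPREV", "VT", "BLOSUM62", "MTMAM", "LG", "MTART", "MTZOA", "HIVB", "HIVW", "JTTDCMUT", "FLU"],
    "aa_freqs": ["model", "empirical", "ml"],
    "aa_het": ["none", "I", "G", "I+G", "R"],
    "command": "iqtree -s {msa} -m {model}"
  },
  "phyml": {
    "dna_schemes": ["000000", "010010", "010020", "012210", "010212", "012012", "012230", "010232", "012032", "012314", "012345"],
    "dna_freqs": ["equal", "empirical", "ml"],
    "dna_het": ["none", "I", "G", "I+G"],
    "aa_matrices": ["LG", "WAG", "JTT", "MTREV", "DAYHOFF", "DCMUT", "RTREV", "CPREV", "VT", "BLOSUM62", "MTMAM", "MTART", "HIVW", "HIVB", "FLU"],
    "aa_freqs": ["model", "empirical"],
    "aa_het": ["none", "I", "G", "I+G"],
    "command": "phyml -i {msa} {opts}"
  },
  "mrbayes": {
    "dna_schemes": ["000000", "010010", "012345"],
    "dna_freqs": ["equal", "empirical", "ml"],
    "dna_het": ["none", "I", "G", "I+G"],
    "aa_matrices": ["DAYHOFF", "JTT", "MTREV", "MTMAM", "WAG", "RTREV", "CPREV", "VT", "BLOSUM62", "LG"],
    "aa_freqs": ["model"],
    "aa_het": ["none", "I", "G", "I+G"],
    "command": "begin mrbayes; {opts} end;"
  },
  "paup": {
    "dna_schemes": ["000000", "010010", "012345"],
    "dna_freqs": ["equal", "empirical", "ml"],
    "dna_het": ["none", "I", "G", "I+G"],
    "aa_matrices": [],
    "aa_freqs": [],
    "aa_het": [],
    "command": "{opts}"
  }
}
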