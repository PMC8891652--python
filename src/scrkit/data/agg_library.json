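{
  "name": "agg-anticodon-binding-library",
  "positions": [
    {"name": "aaRS230", "kind": "codon", "degeneracy": "KMT", "parent": "Y"},
    {"name": "aaRS231", "kind": "codon", "degeneracy": "TNT", "parent": "C"},
    {"name": "aaRS232", "kind": "codon", "degeneracy": "MMG", "parent": "P"},
    {"name": "aaRS233", "kind": "codon", "degeneracy": "KYC", "parent": "A"},
    {"name": "aaRS261", "kind": "codon", "degeneracy": "NHH", "parent": "F"},
    {"name": "aaRS283", "kind": "codon", "degeneracy": "VDS", "parent": "H"},
    {"name": "aaRS284", "kind": "codon", "degeneracy": "BNT", "parent": "P"},
    {"name": "aaRS285", "kind": "codon", "degeneracy": "WBB", "parent": "M"},
    {"name": "aaRS286", "kind": "codon", "degeneracy": "VVW", "parent": "D"},
    {"name": "tRNA32", "kind": "nucleotide", "degeneracy": "N", "parent": "C"},
    {"name": "tRNA33", "kind": "nucleotide", "degeneracy": "T", "parent": "T"},
    {"name": "tRNA37", "kind": "nucleotide", "degeneracy": "N", "parent": "A"},
    {"name": "tRNA38", "kind": "nucleotide", "degeneracy": "N", "parent": "A"}
  ]
}
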