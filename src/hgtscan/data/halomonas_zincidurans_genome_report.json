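{
  "organism": "Halomonas zincidurans B6 (type strain)",
  "insdc_accession": "JNCK00000000",
  "contigs": {
    "JNCK01000001.1": 3546937,
    "JNCK01000002.1": 7823
  },
  "dna_coding_bp": 3153982,
  "dna_gc_bp": 2289453,
  "total_genes": 3392,
  "protein_coding_genes": 3325,
  "rna_genes": 67,
  "genes_with_function_prediction": 2916,
  "genes_in_cogs": 2764,
  "not_in_cogs": 628
}
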