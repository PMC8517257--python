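# The seven candidate statin-ADR variants: alleles, assigned genetic
# model, and the protective orientation used by the risk score.
# `maf` is the approximate European minor-allele frequency used as the
# synthetic-cohort default. Note the protective allele is recorded
# independently of which allele is the population minor allele (ABCB1
# rs1045642 C is protective yet sits near 0.5 frequency).
- rsid: rs1128503
  gene: ABCB1
  chrom: "7"
  pos: 87550285
  major_allele: C
  minor_allele: T
  protective_allele: T
  genetic_model: dominant
  maf: 0.42
- rsid: rs1045642
  gene: ABCB1
  chrom: "7"
  pos: 87509329
  major_allele: T
  minor_allele: C
  protective_allele: C
  genetic_model: recessive
  maf: 0.48
- rsid: rs4149056
  gene: SLCO1B1
  chrom: "12"
  pos: 21178615
  major_allele: T
  minor_allele: C
  protective_allele: C
  genetic_model: recessive
  maf: 0.16
- rsid: rs2306283
  gene: SLCO1B1
  chrom: "12"
  pos: 21176804
  major_allele: A
  minor_allele: G
  protective_allele: G
  genetic_model: dominant
  maf: 0.40
- rsid: rs12975366
  gene: LILRB5
  chrom: "19"
  pos: 54266313
  major_allele: T
  minor_allele: C
  protective_allele: C
  genetic_model: dominant
  maf: 0.40
- rsid: rs2740574
  gene: CYP3A4
  chrom: "7"
  pos: 99784473
  major_allele: A
  minor_allele: G
  protective_allele: G
  genetic_model: recessive
  maf: 0.05
- rsid: rs776746
  gene: CYP3A5
  chrom: "7"
  pos: 99672916
  major_allele: G
  minor_allele: A
  protective_allele: A
  genetic_model: dominant
  maf: 0.07
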