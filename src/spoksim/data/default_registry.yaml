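# Canonical Podospora strain registry: Spok gene content and Spok-block
# chromosome-arm locations per strain, with the killer/resistance model.
# Distances d are Morgans from the centromere of the given arm.
#
# The spok2_site distance is calibrated so that a Spok2 vs null cross yields
# the observed ~40.6% two-spored asci (FDS frequency); block-site distances
# are NOT published and are marked assumed: true — edit freely.
kill_capable:
  Spok1: true
  Spok2: true
  Spok3: true
  Spok4: true
  SpokPsi1: false
resistance_pairs:
  - [Spok1, Spok1]
  - [Spok2, Spok2]
  - [Spok3, Spok3]
  - [Spok4, Spok4]
  - [Spok2, Spok1]   # Spok1 resists all P. anserina homologs
  - [Spok3, Spok1]
  - [Spok4, Spok1]
  - [Spok1, Spok4]   # Spok4 resists Spok1
penetrance:
  Spok1: 1.0
  Spok2: 1.0
  Spok3: 1.0
  Spok4: 1.0
loci:
  spok2_site:   {chromosome: "5", arm: L, d: 0.738802, assumed: false}
  spok1_site:   {chromosome: "1", arm: L, d: 0.2, assumed: true}
  spokpsi1_site: {chromosome: "5", arm: R, d: 0.9, assumed: true}
  papks1:       {chromosome: "2", arm: L, d: 0.0, assumed: false}
  block_3L:     {chromosome: "3", arm: L, d: 0.04, assumed: true}
  block_5L:     {chromosome: "5", arm: L, d: 0.05, assumed: true}
  block_5R:     {chromosome: "5", arm: R, d: 0.07, assumed: true}
  block_4R:     {chromosome: "4", arm: R, d: 0.05, assumed: true}
strains:
  S:
    - {locus: spok2_site, alleles: [Spok2]}
  s:
    - {locus: spok2_site, alleles: [Spok2]}
  Us5:
    - {locus: spok2_site, alleles: [Spok2]}
  Wa63:
    - {locus: spok2_site, alleles: [Spok2]}
  Wa46:
    - {locus: spokpsi1_site, alleles: [SpokPsi1]}
  Wa47: []
  Wa21:
    - {locus: spok2_site, alleles: [Spok2]}
    - {locus: block_5R, alleles: [Spok3]}
  Wa28:
    - {locus: spok2_site, alleles: [Spok2]}
    - {locus: block_5R, alleles: [Spok3]}
  Wa53:
    - {locus: spok2_site, alleles: [Spok2]}
    - {locus: block_3L, alleles: [Spok3, Spok4]}
  Wa87:
    - {locus: spok2_site, alleles: [Spok2]}
    - {locus: block_3L, alleles: [Spok3, Spok4]}
    - {locus: spokpsi1_site, alleles: [SpokPsi1]}
  Wa58:
    - {locus: spok2_site, alleles: [Spok2]}
    - {locus: block_5L, alleles: [Spok3, Spok4]}
  Y:
    - {locus: block_3L, alleles: [Spok3, Spok4]}
  Wa100:
    - {locus: spok2_site, alleles: [Spok2]}
    - {locus: block_5L, alleles: [Spok4]}
    - {locus: spokpsi1_site, alleles: [SpokPsi1]}
  T_G:
    - {locus: block_3L, alleles: [Spok3, Spok3, Spok4]}
  T_D:
    - {locus: spok1_site, alleles: [Spok1]}
  # The strain table lists CBS237.71 with Spok2+Spok3, while the running text
  # says its genome carries both Spok3 and Spok4: both entries are provided,
  # neither silently preferred.
  CBS237.71:
    - {locus: spok2_site, alleles: [Spok2]}
    - {locus: block_4R, alleles: [Spok3]}
  CBS237.71-alt:
    - {locus: spok2_site, alleles: [Spok2]}
    - {locus: block_4R, alleles: [Spok3, Spok4]}
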