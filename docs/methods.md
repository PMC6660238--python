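# Methods

## The segregation model

*Podospora anserina* packages the eight post-meiotic nuclei of one meiosis
into four dikaryotic spores, pairing each meiosis-II product's mitotic copy
with its non-sister neighbour. `simulate_tetrad` follows that geometry
explicitly: per chromosome it builds four chromatids (two per homolog),
recombines them, segregates by centromere at meiosis I, separates sisters at
meiosis II, duplicates by mitosis, and packages the copies of the two
products sharing a meiosis-I pole into one spore. Consequences used
throughout: spores 1–2 (and 3–4) are genotypically identical before killing,
and a heteroallelic locus is either homoallelic in every spore (FDS) or
heteroallelic in every spore (SDS).

Crossovers per centromere-anchored interval of genetic length Δd are
Poisson-distributed with mean 2·Δd (so map distance d in Morgans equals the
expected number of exchanges per chromatid), with no crossover or chromatid
interference and no obligate chiasma — the simplest process consistent with
the segregation rules, chosen because nothing in the data constrains
interference. Each crossover exchanges the distal segment between one
uniformly chosen chromatid of each homolog, where homolog membership is the
strand's content at the crossover position (prior exchanges included). That
detail matters: choosing strands by centromere identity instead silently
turns some exchanges into no-ops and depresses two-locus recombination ~7%
below Haldane's function. With position-based choice the model satisfies,
exactly, the per-crossover SDS recursion s_k = ⅔·(1 − (−½)^k), hence

- SDS probability s(d) = ⅔·(1 − e^(−3d)), capped at ⅔ by random spindle
  attachment, inverted by `distance_for_fds` (FDS below ⅓ is unattainable);
- Haldane recombination r = ½·(1 − e^(−2Δd)) between linked loci.

Both are verified against the simulator at 10⁵ tetrads in the test suite.

A *Spok* block is one indivisible locus whose allele list is its gene
content (the block moves between genomes as a unit; within-block
recombination is not modelled). Mating type is not modelled: it never
changes a drive outcome, and paired reciprocal crosses collapse onto one
simulated cross. Five-spored asci (used experimentally only to isolate
monokaryons) are not modelled.

## Killing model

Let H be the set of kill-capable homologs present in the zygote (union of
both parents' alleles — killer expression is zygote-level, so a killer acts
even when all of its carriers die; this is the only convention that produces
the observed completely empty asci under same-locus mutual killing). A spore
is resistant to killer h iff any allele in either of its nuclei lists h in
its resistance profile; each unresisted h kills the spore with penetrance
q_h, independently across spores and homologs (default q = 1). Per-spore
independent penetrance is what generates three-spored asci; an ascus-level
alternative (`penetrance_scope="ascus"`), under which a killer is
all-or-nothing per ascus and three-spored asci cannot occur, is provided but
off by default. Multiple unresisted killers act as independent hazards (no
synergy is modelled).

The default resistance matrix is identity-only within *P. anserina*
(R(h,h)), plus the cross-species epistasis: *Spok1* resists *Spok2*–*Spok4*
and *Spok4* resists *Spok1*. Mutant alleles are attribute overrides on the
allele, not separate homologs: the nuclease-dead K240A (kills=false,
resists={Spok3}) and the strain-A *Spok2* (kills=false, resists={Spok2}).

For a single heteroallelic killer with FDS probability f and penetrance q
the ascus classes follow (P₂, P₃, P₄) = (f·q², 2·f·q·(1−q), rest), which the
trinomial MLE in `inference` inverts in closed form. A killing percentage of
~25% where ~40% is expected (as in crosses where only *Spok2* segregates but
three-spored asci are common) corresponds under the exclude-three-spored
reporting policy to q ≈ 0.72 (include-three-spored: q ≈ 0.79); penetrance is
left at 1.0 by default and exposed per homolog rather than asserted, since
no penetrance value is reported directly.

## Strain registry and calibration

The canonical registry (YAML, editable) transcribes each strain's *Spok*
content and block arm. Only one locus-centromere distance is calibratable
from reported numbers: the *Spok2* site, set to `distance_for_fds(0.406)` =
0.7388 M from the 40.6% two-spored asci of the s × Δ*Spok2* cross. Block
distances are unpublished; the defaults (3L 0.04, 5L 0.05, 5R 0.07, 4R 0.05
M — consistent with the ≳90% killing percentages of block-bearing strains —
plus the *Spok1* site at 0.2 M on an unlinked chromosome and the *SpokΨ1*
site subtelomeric at 0.9 M) are flagged `assumed: true` in the registry and
should be edited when real estimates exist. The knock-in locus (*PaPKS1*)
is set to d = 0 (tight centromere linkage). The registry carries both
published readings of the CBS237.71 genotype (block{Spok3} per the strain
table; `CBS237.71-alt` with block{Spok3,Spok4} per the genome description)
without preferring either.

## Interaction classification

`classify_interaction` follows the F1-backcross design: (a) no killing in
the direct cross → same type; (b) killing but no two-spored ascus within the
attempt budget (only empty asci) → mutual killing; (c) otherwise F1
monokaryons are backcrossed to both parents and selfed — killing against
both parents or in the self means mutual killing, against neither mutual
resistance, against exactly one means the other parent is dominant.
"Killing observed" is a killed-ascus (0- or 2-spored) fraction above 5% with
≥200 simulated asci, far below the ≥25% signals of real killing crosses and
far above Monte-Carlo noise at those sizes.

Two design choices stabilise the verdicts. F1 spores must be homoallelic at
every drive locus (the experimental protocol likewise selected F1 progeny
homoallelic for the killing locus); without this filter, a nucleus drawn
from a *Spok2*-heteroallelic spore (SDS of *Spok2* is ≈0.59) can carry the
blocks but not *Spok2* and spuriously kill the dominant parent. And five
independent F1 isolates are scored with a majority verdict (several F1
strains of both mating types were likewise used experimentally), so rare
recombinant F1s — e.g. *Spok2* separated from a same-arm block — are
outvoted. The two-sided failure mode this guards against: a single F1 would
misclassify Psk-7 × Psk-5 as mutual killing, while OR-pooling evidence
across F1s without majority would do the same.

`build_hierarchy` runs all pairs, collapses strains onto their *Psk* labels,
requires the dominance graph to be acyclic, and stratifies it by longest
path. On the canonical registry this reproduces the full categorical
hierarchy, including the apparent paradox of Psk-1 × Psk-7 (killing in the
direct cross — the two blocks can co-segregate away from two spores — yet
mutual resistance under the F1 design) and the Psk-5/Psk-S mutual-killing
exception.

## Introgression

Backcross lineages tag every locus with parent of origin. Selection takes
one nucleus per generation: from a surviving spore of a two-spored ascus
(drive selection), from a four-spored ascus, or alternating (ending on
two-spored, as in the extended backcross scheme). Nuclei retaining the
line's kill-capable content are preferred; this mirrors the fact that the
experimental alternating scheme kept the killer through all fourteen
backcrosses, and without it a four-spored-selected nucleus can lose the
killer and strand the next drive-selected generation.

Drive selection fixes the donor haplotype at the killer locus exactly (the
surviving spore must carry it) and, at the default marker grid (every 0.1 M
per arm), over the whole killer-to-centromere interval in one generation.
The interval-interior statement is exact only up to double crossovers: a
two-strand double crossover proximal to the killer leaves the ascus
two-spored while one surviving nucleus carries a recurrent-parent tract, and
a four-strand proximal double exchange can hand the killer to the recurrent
centromere. Both are O(d²) — ~10⁻⁴–10⁻³ per meiosis for a tightly linked
killer — which the dense-grid property test bounds (≥0.995 fixation);
markers at the default spacing never sample the interior of a ~0.04 M
interval. Unlinked donor markers halve per backcross generation, (½)^n.

Pooled allele frequencies weight each surviving spore by its two nuclei,
matching read-depth expectations of pooled sequencing of spore groups:
two-spored pools are fixed for the killer parent at the killer locus;
four-spored pools are exactly ½ everywhere (allele conservation per ascus).

## Sequence diversity

`windowed_pi` scores a site only if gap-free (N counts as a gap) and
bi-allelic; the per-site value 2·p̂·(1−p̂)·n/(n−1) equals the mean pairwise
mismatch over all C(n,2) sequence pairs, and the window value is the mean
over scored sites (invariant sites contribute 0). Sites with more than two
states are skipped by default (the statistic is defined per bi-allelic site)
or scored as full heterozygosity with the same correction under a flag;
window-width normalisation is likewise available by flag, since a mean over
valid sites was judged the more faithful default but the alternative is not
excluded by anything reported. Equivalence with a brute-force all-pairs
oracle is asserted over random gapped alignments. Coordinates are 0-based
half-open and stated in the TSV header. GC windows exclude N from the
denominator. dN/dS is out of scope (an off-the-shelf package's job).

## Synthetic data

The generators emulate the study's inputs, not its sequences: maps with
neutral 0.1-M marker grids plus the registry's *Spok* loci; trinomial ascus
counts at chosen (f, q, N); alignments with exactly planted bi-allelic
columns, gap columns and GC segments, returned with their ground truth so
every analysis stage closes the loop against a known answer. They share the
I/O formats of the analysis side (YAML registry, FASTA), are bit-reproducible
under a fixed seed, and default to the study's scales (e.g. the 130-of-2334
variable-site alignment). What they do not emulate: linkage disequilibrium
or phylogenetic structure among sequences, indel length variation, TE
content of the block, and real marker ascertainment — so passing tests show
the estimators and statistics are correct on model-generated data, not that
the model captures every feature of the sequenced strains.

## Numerical and testing choices

Simulated problem sizes were chosen to make Monte-Carlo checks decisive at
3 standard errors while keeping the default suite fast: 10⁵ tetrads for the
closed-form checks, 1000 asci per cross for classification (direct +
5 × 3 F1 crosses per pair), 10⁴ replicate lineages for backcross decay, 500
replicates for estimator bias. All randomness flows through
`numpy.random.Generator` seeds; identical seeds give identical ascus
streams. Known limitations: no crossover interference or gene conversion,
no within-block structure, no fertility/mating-type effects, penetrance
constant across genetic backgrounds, and the hierarchy is only as stable as
the 5%-killing detection threshold for crosses much smaller than ~200 asci.
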