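"""Drive-selected backcrossing drags a donor tract around the killer locus.

Emulates the recurrent-backcross scheme used to move spore-killer loci into
the reference background: each generation, a spore is taken from a
two-spored ascus (so it must carry the killer) and crossed back to the
recurrent parent.  The killer locus and the interval to its centromere stay
donor-derived in every lineage, while unlinked donor markers halve each
generation.  Also prints the pool-sequencing expectation for a single
cross: nuclei pooled from two-spored asci are fixed for the killer parent
at the killer locus, four-spored asci pool to 50:50.
"""

import spoksim as sp
from spoksim.introgression import (TWO_SPORED, FOUR_SPORED, BackcrossScheme,
                                   pooled_allele_frequency,
                                   simulate_backcross_series)

registry = sp.default_registry()
model = registry.model
gmap, _ = sp.generate_map_and_strains()  # includes the 0.1-M marker grid

donor = registry.genotype_of("Wa53")       # Psk-1: Spok block on 3L
recurrent = registry.genotype_of("S")
scheme = BackcrossScheme(donor=donor, recurrent=recurrent, generations=3,
                         policy=TWO_SPORED)
prof = simulate_backcross_series(scheme, gmap, model, n_replicates=1000,
                                 seed=8)
print("donor-allele frequency after 3 drive-selected backcrosses "
      "(1000 lineages):")
for name in ("block_3L", "m3L_0.1", "m3L_0.3", "m3L_1", "m6L_0.5"):
    locus = gmap.by_name[name]
    tag = "killer locus" if name == "block_3L" else (
        "linked marker" if name.startswith("m3L") else "unlinked marker")
    print(f"  {name:10s} (d={locus.d:4.2f} M, {tag}): {prof.at(locus):.3f}")
print("  expectation: 1.0 at the killer, (1/2)^3 = 0.125 unlinked")

wa87 = registry.genotype_of("Wa87")        # Psk-1 x Psk-5: Spok2 segregates
y = registry.genotype_of("Y")
two = pooled_allele_frequency(wa87, y, gmap, model, TWO_SPORED,
                              n_asci=2000, seed=9)
four = pooled_allele_frequency(wa87, y, gmap, model, FOUR_SPORED,
                               n_asci=1000, seed=10)
s2 = gmap.by_name["spok2_site"]
print(f"\npooled Wa87-allele frequency at the Spok2 locus "
      f"(Psk-1 x Psk-5 cross):")
print(f"  two-spored-ascus pool:  {two[s2]:.3f}  (killing fixes Spok2)")
print(f"  four-spored-ascus pool: {four[s2]:.3f}  (fully heterozygous)")
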