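"""Reconstruct the Psk killing hierarchy from Spok gene content alone.

Runs the F1-backcross interaction design over all pairs of one
representative strain per Psk type and assembles the verdicts into the
emergent dominance hierarchy: three-Spok strains (Psk-1, Psk-7) on top and
mutually resistant, two-Spok strains (Psk-2, Psk-5, Psk-8) mutually killing
in the middle, Psk-S (Spok2 only) above naive strains — with the Psk-5/Psk-S
mutual-killing exception (Psk-5 lacks Spok2, so each side kills the other).
"""

import spoksim as sp

registry = sp.default_registry()
model = registry.model
gmap, _ = sp.generate_map_and_strains(sp.MapSpec(marker_spacing=None))

strains = [registry.genotype_of(n)
           for n in ("Wa53", "Wa58", "Wa28", "Y", "Wa100", "S", "Wa46")]
print("strains:", {g.name: sp.psk_type_of(g) for g in strains})

hierarchy = sp.build_hierarchy(strains, gmap, model, n_asci=1000, seed=42)

print("\nlevels (0 = bottom of the killing hierarchy):")
for node, level in sorted(hierarchy.levels.items(), key=lambda kv: -kv[1]):
    print(f"  level {level}: {node}")
print("\ndominance edges (A -> B: A kills B's background, resists it):")
for a, b in sorted(hierarchy.dominance.edges):
    print(f"  {a} -> {b}")
print("\nmutual killing:", sorted(hierarchy.mutual_killing))
print("mutual resistance:", sorted(hierarchy.mutual_resistance))
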