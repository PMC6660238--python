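import pytest

import spoksim as sp


@pytest.fixture(scope="session")
def registry():
    return sp.default_registry()


@pytest.fixture(scope="session")
def model(registry):
    return registry.model


@pytest.fixture(scope="session")
def spok_map(registry):
    """Map holding only the *Spok* loci (no neutral markers)."""
    gmap, _ = sp.generate_map_and_strains(sp.MapSpec(marker_spacing=None),
                                          registry=registry)
    return gmap


@pytest.fixture(scope="session")
def marker_map(registry):
    """Default map: *Spok* loci plus the 0.1-M neutral marker grid."""
    gmap, _ = sp.generate_map_and_strains(registry=registry)
    return gmap


@pytest.fixture(scope="session")
def strains(registry):
    return {name: registry.genotype_of(name) for name in registry.strain_names}


def single_locus_cross(d, model, homolog="Spok3"):
    """Killer x null parents sharing a one-locus map at distance ``d``."""
    locus = sp.Locus("killer", "1", "L", d)
    gmap = sp.GeneticMap([locus])
    killer = sp.StrainGenotype("K", {locus: (model.allele(homolog),)})
    null = sp.StrainGenotype("N", {})
    return locus, gmap, killer, null
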