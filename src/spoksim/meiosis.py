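"""Tetrad-level meiosis with ordered segregation and dikaryotic spore packaging.

One *Podospora* meiosis produces four ordered products; a post-meiotic mitosis
doubles them to eight nuclei, which are packaged two-per-spore with their
non-sister mitotic neighbours.  A locus therefore shows first-division
segregation (FDS, no crossover between locus and centromere: homoallelic
spores) or second-division segregation (SDS: heteroallelic spores), and the
SDS frequency is an increasing function of the locus-centromere distance,
capped at 2/3 by random spindle attachment.

Crossovers are modelled per centromere-anchored interval as Poisson counts
with mean 2·Δd (d in Morgans), each exchange involving one uniformly chosen
chromatid of each homolog — no crossover or chromatid interference.  That
model implies the closed form s(d) = (2/3)·(1 − e^(−3d)) for the SDS
probability and Haldane's map function between linked loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genetics import ConfigError, GeneticMap, Locus, SpokAllele, StrainGenotype

FDS = "FDS"
SDS = "SDS"

#: spore i is packaged from the two meiosis-II products of one meiosis-I pole
SPORE_PRODUCTS = ((0, 1), (0, 1), (2, 3), (2, 3))


@dataclass
class Nucleus:
    """One haploid nucleus: allele lists and parent-of-origin tag per locus."""

    haplotype: Dict[Locus, Tuple[SpokAllele, ...]]
    origin: Dict[Locus, str]


@dataclass
class Ascus:
    """The 4-spore, 8-nucleus product of one simulated meiosis.

    ``products[p][i]`` is the parental origin (0 for p1, 1 for p2) of meiotic
    product ``p`` at map locus ``i``; products 0,1 share the first meiosis-I
    pole, products 2,3 the second.  Spore ``s`` holds the two mitotic copies
    of products ``SPORE_PRODUCTS[s]`` — hence pre-killing spores 1-2 are
    genotypically identical, as are spores 3-4.
    """

    p1: StrainGenotype
    p2: StrainGenotype
    gmap: GeneticMap
    products: List[List[int]]
    fds_by_locus: Dict[Locus, str]
    fates: List[str] = field(default_factory=lambda: ["unset"] * 4)

    @property
    def parents(self) -> Tuple[StrainGenotype, StrainGenotype]:
        return (self.p1, self.p2)

    def spore_origins(self, spore: int) -> Tuple[List[int], List[int]]:
        a, b = SPORE_PRODUCTS[spore]
        return self.products[a], self.products[b]

    def nucleus(self, product: int) -> Nucleus:
        parents = self.parents
        hap, orig = {}, {}
        for i, locus in enumerate(self.gmap.loci):
            par = parents[self.products[product][i]]
            hap[locus] = par.alleles_at(locus)
            orig[locus] = par.marker_at(locus)
        return Nucleus(haplotype=hap, origin=orig)

    def spore_nuclei(self, spore: int) -> Tuple[Nucleus, Nucleus]:
        a, b = SPORE_PRODUCTS[spore]
        return self.nucleus(a), self.nucleus(b)

    def spore_alleles(self, spore: int,
                      loci: Optional[Sequence[Locus]] = None
                      ) -> Tuple[SpokAllele, ...]:
        """Union of alleles carried by the spore's two nuclei at ``loci``."""
        parents = self.parents
        a, b = SPORE_PRODUCTS[spore]
        if loci is None:
            loci = self.gmap.loci
        out: List[SpokAllele] = []
        for locus in loci:
            i = self.gmap.index[locus]
            out.extend(parents[self.products[a][i]].alleles_at(locus))
            if self.products[b][i] != self.products[a][i]:
                out.extend(parents[self.products[b][i]].alleles_at(locus))
        return tuple(out)

    def is_heteroallelic(self, spore: int, locus: Locus) -> bool:
        a, b = SPORE_PRODUCTS[spore]
        i = self.gmap.index[locus]
        return self.products[a][i] != self.products[b][i]


def _heteroallelic_loci(p1: StrainGenotype, p2: StrainGenotype,
                        gmap: GeneticMap) -> List[int]:
    out = []
    for i, locus in enumerate(gmap.loci):
        if (p1.alleles_at(locus) != p2.alleles_at(locus)
                or p1.marker_at(locus) != p2.marker_at(locus)):
            out.append(i)
    return out


def simulate_tetrad(p1: StrainGenotype, p2: StrainGenotype,
                    gmap: GeneticMap, rng: np.random.Generator) -> Ascus:
    """Simulate one meiosis of the p1 × p2 zygote on a shared genetic map.

    Per chromosome: four chromatids (two per homolog) recombine with Poisson
    crossover counts per inter-locus interval; meiosis I segregates by
    centromere, meiosis II separates sisters, mitosis duplicates, and spores
    pair the copies of the two meiosis-II products that share a meiosis-I
    pole.  ``fds_by_locus`` records FDS/SDS at every heteroallelic locus.
    """
    if not isinstance(gmap, GeneticMap):
        raise ConfigError("gmap must be a GeneticMap")
    n = len(gmap.loci)
    products = [[0] * n, [0] * n, [1] * n, [1] * n]
    poisson = rng.poisson
    integers = rng.integers
    for _chrom, arms in gmap._plan:
        # chromatid rows 0,1 carry the p1 centromere; rows 2,3 the p2 one
        ch = None  # built lazily only if a crossover happens
        for start, end, deltas in arms:
            for j, delta in enumerate(deltas):
                if delta <= 0.0:
                    continue
                k = poisson(2.0 * delta)
                for _ in range(k):
                    if ch is None:
                        lo0 = arms[0][0]
                        hi0 = arms[-1][1]
                        ch = [products[0][lo0:hi0], products[1][lo0:hi0],
                              products[2][lo0:hi0], products[3][lo0:hi0]]
                    lo = start + j - arms[0][0]
                    hi = end - arms[0][0]
                    # one uniformly chosen chromatid of each homolog, where
                    # homolog membership is the strand's content at the
                    # crossover position (prior exchanges included) — this is
                    # what makes SDS follow s_k = 2/3*(1-(-1/2)^k) per
                    # crossover and pairwise recombination Haldane's r
                    zeros = [r for r in range(4) if ch[r][lo] == 0]
                    ones = [r for r in range(4) if ch[r][lo] == 1]
                    c1 = zeros[integers(0, 2)]
                    c2 = ones[integers(0, 2)]
                    ch[c1][lo:hi], ch[c2][lo:hi] = ch[c2][lo:hi], ch[c1][lo:hi]
        flip = integers(0, 2)
        lo0 = arms[0][0]
        hi0 = arms[-1][1]
        if ch is None:
            if flip:
                for p, val in zip(products, (1, 1, 0, 0)):
                    p[lo0:hi0] = [val] * (hi0 - lo0)
        else:
            order = (2, 3, 0, 1) if flip else (0, 1, 2, 3)
            for p, c in zip(products, order):
                p[lo0:hi0] = ch[c]
    fds = {}
    for i in _heteroallelic_loci(p1, p2, gmap):
        fds[gmap.loci[i]] = FDS if products[0][i] == products[1][i] else SDS
    return Ascus(p1=p1, p2=p2, gmap=gmap, products=products, fds_by_locus=fds)


def sds_probability(d: float) -> float:
    """Second-division segregation probability at centromere distance ``d``.

    Closed form implied by Poisson(2d) crossovers with no chromatid
    interference: s(d) = (2/3)·(1 − e^(−3d)); s(0) = 0 and s(∞) = 2/3 (random
    spindle attachment limit).  Matches ``simulate_tetrad`` empirically.
    """
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    return (2.0 / 3.0) * (1.0 - math.exp(-3.0 * d))


def distance_for_fds(f: float) -> float:
    """Centromere distance (Morgans) whose FDS frequency is ``f``.

    Inverts 1 − s(d) = f; used to calibrate the *Spok2* site to the observed
    ~40% spore-killing percentage.  FDS below 1/3 is unattainable (SDS is
    capped at 2/3 under the model).
    """
    if not (1.0 / 3.0 < f <= 1.0):
        raise ValueError(
            f"FDS frequency must be in (1/3, 1]; {f} is unattainable under "
            f"the 2/3 SDS ceiling")
    if f == 1.0:
        return 0.0
    return -math.log((3.0 * f - 1.0) / 2.0) / 3.0


def haldane_recombination(delta_d: float) -> float:
    """Haldane recombinant fraction r = ½·(1 − e^(−2Δd)) between linked loci."""
    if delta_d < 0:
        raise ValueError("map interval must be >= 0")
    return 0.5 * (1.0 - math.exp(-2.0 * delta_d))
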