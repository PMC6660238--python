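"""Recurrent-backcross introgression and pool-sequencing expectations.

The study's backcrossed killer strains were made by selecting a spore from a
two-spored ascus each generation and crossing it back to the reference
strain: the drive itself keeps the killer locus (and with it the
centromere-linked interval) from the donor parent, while unlinked donor
background halves every generation.  Pool-sequencing expectations follow the
same logic at the single-cross level: nuclei pooled from surviving spores of
two-spored asci are fixed for the killer parent around the killer locus,
whereas four-spored asci pool to 50:50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .genetics import GeneticMap, Locus, ResistanceModel, StrainGenotype
from .killing import ALIVE, apply_killing, ascus_class
from .meiosis import simulate_tetrad

TWO_SPORED = "two_spored"
FOUR_SPORED = "four_spored"
ALTERNATING = "alternating"

DONOR_TAG = "donor"
RECURRENT_TAG = "recurrent"


class SelectionImpossible(RuntimeError):
    """No qualifying ascus found within the attempt budget."""

    def __init__(self, message: str, generation: Optional[int] = None):
        super().__init__(message)
        self.generation = generation


@dataclass
class BackcrossScheme:
    """A recurrent-backcross design.

    ``policy`` selects the spore each generation: ``two_spored`` (a surviving
    spore of a two-spored ascus — the study's S5 scheme), ``four_spored``, or
    ``alternating`` (four- and two-spored in alternating generations, ending
    on two-spored — the study's S14 extension).
    """

    donor: StrainGenotype
    recurrent: StrainGenotype
    generations: int
    policy: str = TWO_SPORED

    def __post_init__(self):
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.policy not in (TWO_SPORED, FOUR_SPORED, ALTERNATING):
            raise ValueError(f"unknown policy {self.policy!r}")

    def generation_policy(self, generation: int) -> str:
        """Selection rule for generation ``generation`` (1-based)."""
        if self.policy != ALTERNATING:
            return self.policy
        # end on two_spored: last generation two_spored, previous four_spored, ...
        from_end = self.generations - generation
        return TWO_SPORED if from_end % 2 == 0 else FOUR_SPORED


@dataclass
class DonorProfile:
    """Per-marker donor-allele frequency across replicate backcross lineages."""

    frequencies: Dict[Locus, float]
    n_replicates: int
    scheme: Optional[BackcrossScheme] = None

    def at(self, locus: Locus) -> float:
        return self.frequencies[locus]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"locus": l.name, "chromosome": l.chromosome, "arm": l.arm,
             "d": l.d, "donor_freq": f}
            for l, f in self.frequencies.items()
        ]
        return pd.DataFrame(rows).sort_values(
            ["chromosome", "arm", "d"]).reset_index(drop=True)


def _select_nucleus(line: StrainGenotype, recurrent: StrainGenotype,
                    gmap: GeneticMap, model: ResistanceModel,
                    rng: np.random.Generator, want_class: int,
                    max_attempts: int, generation: int) -> StrainGenotype:
    """One nucleus of a (surviving) spore from an ascus of the wanted class.

    Nuclei retaining the line's kill-capable content are preferred: a spore
    taken from a four-spored ascus is heteroallelic at the drive locus, and
    the study's alternating scheme keeps the killer through every backcross
    (the final lines are homozygous killers), so the killer-carrying nucleus
    is the one propagated.
    """
    keep = line.kill_capable_homologs()
    for _ in range(max_attempts):
        ascus = simulate_tetrad(line, recurrent, gmap, rng)
        killed = apply_killing(ascus, model, rng)
        if ascus_class(killed) != want_class:
            continue
        candidates = []
        for spore in range(4):
            if killed.fates[spore] != ALIVE:
                continue
            for nuc in ascus.spore_nuclei(spore):
                candidates.append(nuc)
        keepers = [
            nuc for nuc in candidates
            if keep <= {a.homolog for al in nuc.haplotype.values()
                        for a in al if a.kills}
        ]
        pool = keepers or candidates
        nuc = pool[rng.integers(0, len(pool))]
        return StrainGenotype(
            name=f"{line.name}|G{generation}",
            alleles={l: al for l, al in nuc.haplotype.items() if al},
            markers=dict(nuc.origin),
        )
    raise SelectionImpossible(
        f"no {want_class}-spored ascus in {max_attempts} attempts at "
        f"generation {generation}", generation=generation)


def simulate_backcross_series(scheme: BackcrossScheme, gmap: GeneticMap,
                              model: ResistanceModel, n_replicates: int = 1,
                              seed=None, max_attempts: int = 500
                              ) -> DonorProfile:
    """Run replicate backcross lineages and profile donor-allele retention.

    Every map locus of the donor is origin-tagged; each generation crosses
    the current line to the recurrent parent, applies killing, and selects
    one nucleus according to the scheme's per-generation policy.  The profile
    is the frequency, across replicate lineages, with which the final line
    carries the donor tag at each locus.
    """
    rng = np.random.default_rng(seed)
    donor = scheme.donor.tagged(gmap, DONOR_TAG)
    recurrent = scheme.recurrent.tagged(gmap, RECURRENT_TAG)
    donor_counts = {l: 0 for l in gmap.loci}
    for _ in range(n_replicates):
        line = donor
        for gen in range(1, scheme.generations + 1):
            want = 2 if scheme.generation_policy(gen) == TWO_SPORED else 4
            line = _select_nucleus(line, recurrent, gmap, model, rng,
                                   want, max_attempts, gen)
        for l in gmap.loci:
            if line.marker_at(l) == DONOR_TAG:
                donor_counts[l] += 1
    freqs = {l: c / n_replicates for l, c in donor_counts.items()}
    return DonorProfile(frequencies=freqs, n_replicates=n_replicates,
                        scheme=scheme)


def pooled_allele_frequency(p1: StrainGenotype, p2: StrainGenotype,
                            gmap: GeneticMap, model: ResistanceModel,
                            ascus_selection: str, n_asci: int,
                            seed=None) -> Dict[Locus, float]:
    """Per-locus p1-origin frequency in pooled surviving-spore nuclei.

    Pools every nucleus of every surviving spore from asci of the selected
    class (``two_spored`` or ``four_spored``); each surviving spore
    contributes its two nuclei, matching the read-depth expectation of
    pooled sequencing of spore groups.
    """
    if ascus_selection not in (TWO_SPORED, FOUR_SPORED):
        raise ValueError(f"unknown ascus class {ascus_selection!r}")
    want = 2 if ascus_selection == TWO_SPORED else 4
    rng = np.random.default_rng(seed)
    n_loci = len(gmap.loci)
    p1_counts = np.zeros(n_loci)
    total = 0
    for _ in range(n_asci):
        ascus = simulate_tetrad(p1, p2, gmap, rng)
        killed = apply_killing(ascus, model, rng)
        if ascus_class(killed) != want:
            continue
        for spore in range(4):
            if killed.fates[spore] != ALIVE:
                continue
            a, b = ascus.spore_origins(spore)
            for i in range(n_loci):
                p1_counts[i] += (a[i] == 0) + (b[i] == 0)
            total += 2
    if total == 0:
        raise SelectionImpossible(
            f"no {ascus_selection} asci among {n_asci} simulated asci of "
            f"{p1.name} x {p2.name}")
    return {l: p1_counts[i] / total for i, l in enumerate(gmap.loci)}


def profile_frame(freqs: Dict[Locus, float]) -> pd.DataFrame:
    """Tidy frame (chromosome, arm, d, freq) from a per-locus frequency dict."""
    rows = [{"locus": l.name, "chromosome": l.chromosome, "arm": l.arm,
             "d": l.d, "freq": f} for l, f in freqs.items()]
    return pd.DataFrame(rows).sort_values(
        ["chromosome", "arm", "d"]).reset_index(drop=True)
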