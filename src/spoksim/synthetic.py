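"""Synthetic-data generators: every input the pipeline needs, no downloads.

Three generators close the loop for the analysis stages: (a) genetic maps
with neutral markers plus the canonical strain registry, (b) ascus-count
data drawn from the trinomial class distribution (f, q, N), and (c) small
nucleotide alignments with planted variable sites, gap columns and GC
segments, returned together with their ground truth.  All generators are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .crosses import expected_ascus_distribution
from .genetics import (GeneticMap, Locus, Registry, StrainGenotype,
                       default_registry)
from .inference import AscusCountData
from .seqdiv import Alignment


@dataclass
class MapSpec:
    """Map geometry: chromosomes, arm lengths (Morgans) and marker spacing.

    The default emulates the seven *P. anserina* chromosomes with 1-Morgan
    arms.  ``marker_spacing`` places neutral markers every 0.1 M per arm
    (at 0.1, 0.2, ...); ``marker_spacing=None`` emits *Spok* loci only.
    """

    n_chromosomes: int = 7
    arm_length: float = 1.0
    marker_spacing: Optional[float] = 0.1

    def __post_init__(self):
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.arm_length < 0:
            raise ValueError("arm length must be >= 0")
        if self.marker_spacing is not None and self.marker_spacing <= 0:
            raise ValueError("marker spacing must be positive")


def generate_map_and_strains(spec: Optional[MapSpec] = None,
                             registry: Optional[Registry] = None,
                             ) -> Tuple[GeneticMap, List[StrainGenotype]]:
    """Genetic map (neutral markers + *Spok* loci) and the registry strains.

    The *Spok2* site distance in the default registry is calibrated from the
    observed ~40.6% killing percentage (``distance_for_fds(0.406)``); block
    site distances are registry defaults flagged as assumed.  Markers that
    would collide with a *Spok* locus position are skipped.
    """
    spec = spec or MapSpec()
    registry = registry or default_registry()
    loci: List[Locus] = list(registry.loci.values())
    if spec.marker_spacing is not None:
        for c in range(1, spec.n_chromosomes + 1):
            for arm in ("L", "R"):
                occupied = {round(l.d, 9) for l in loci
                            if (l.chromosome, l.arm) == (str(c), arm)}
                k = 1
                while k * spec.marker_spacing <= spec.arm_length + 1e-12:
                    d = round(k * spec.marker_spacing, 9)
                    if d not in occupied:
                        loci.append(Locus(name=f"m{c}{arm}_{d:g}",
                                          chromosome=str(c), arm=arm, d=d))
                    k += 1
    gmap = GeneticMap(loci)
    strains = [registry.genotype_of(name) for name in registry.strain_names]
    return gmap, strains


def generate_ascus_counts(f: float, q: float, N: int, seed=None
                          ) -> AscusCountData:
    """Trinomial draw of (n2, n3, n4) from the single-killer class model."""
    if N < 1:
        raise ValueError("N must be >= 1")
    p2, p3, p4 = expected_ascus_distribution(f, q)
    rng = np.random.default_rng(seed)
    n2, n3, n4 = rng.multinomial(N, [p2, p3, p4])
    return AscusCountData(n2=int(n2), n3=int(n3), n4=int(n4))


@dataclass
class AlignmentSpec:
    """Planted-structure alignment: n sequences of length L.

    ``n_variable`` columns are made exactly bi-allelic (both states present,
    split drawn uniformly over 1..n-1 minor copies); ``gap_columns`` get a
    gap in one sequence (disjoint from variable columns, so the variable-site
    count stays exact); ``gap_fraction`` additionally scatters gaps uniformly;
    ``gc_segments`` are (start, end, gc) composition overrides.
    """

    n: int = 4
    L: int = 2334
    n_variable: int = 130
    gap_columns: int = 0
    gap_fraction: float = 0.0
    gc: float = 0.5
    gc_segments: Tuple[Tuple[int, int, float], ...] = ()

    def __post_init__(self):
        if self.n < 2 or self.L < 1:
            raise ValueError("need n >= 2 sequences and L >= 1")
        if self.n_variable + self.gap_columns > self.L:
            raise ValueError("more planted columns than alignment length")
        if not (0.0 <= self.gap_fraction <= 1.0):
            raise ValueError("gap_fraction must be in [0, 1]")
        for s, e, g in self.gc_segments:
            if not (0 <= s < e <= self.L and 0.0 <= g <= 1.0):
                raise ValueError(f"bad GC segment ({s}, {e}, {g})")


@dataclass
class AlignmentTruth:
    """Ground truth of a generated alignment, for closing-the-loop tests."""

    variable_columns: Tuple[int, ...]
    gap_columns: Tuple[int, ...]
    site_pi: Dict[int, float]  # per planted variable column, the site value
    gc_segments: Tuple[Tuple[int, int, float], ...]


def generate_alignment(spec: Optional[AlignmentSpec] = None, seed=None
                       ) -> Tuple[Alignment, AlignmentTruth]:
    """Alignment with exactly the requested planted structure + ground truth."""
    spec = spec or AlignmentSpec()
    rng = np.random.default_rng(seed)
    n, L = spec.n, spec.L
    # per-column GC probability
    gc_prob = np.full(L, spec.gc)
    for s, e, g in spec.gc_segments:
        gc_prob[s:e] = g
    is_gc = rng.random(L) < gc_prob
    half = rng.integers(0, 2, size=L).astype(bool)
    bases = np.where(is_gc, np.where(half, b"G", b"C"),
                     np.where(half, b"A", b"T"))
    matrix = np.tile(bases, (n, 1)).astype("S1")
    # planted columns: variable first, then gap columns, disjoint
    planted = rng.choice(L, size=spec.n_variable + spec.gap_columns,
                         replace=False)
    var_cols = np.sort(planted[:spec.n_variable])
    gap_cols = np.sort(planted[spec.n_variable:])
    site_pi: Dict[int, float] = {}
    alphabet = np.array([b"A", b"C", b"G", b"T"])
    for col in var_cols:
        ref = matrix[0, col]
        alt = rng.choice(alphabet[alphabet != ref])
        n_alt = int(rng.integers(1, n))  # both states present
        rows = rng.choice(n, size=n_alt, replace=False)
        matrix[rows, col] = alt
        p = max(n_alt, n - n_alt) / n
        site_pi[int(col)] = 2.0 * p * (1.0 - p) * n / (n - 1)
    for col in gap_cols:
        matrix[rng.integers(0, n), col] = b"-"
    if spec.gap_fraction > 0:
        scatter = rng.random((n, L)) < spec.gap_fraction
        matrix[scatter] = b"-"
    aln = Alignment(labels=[f"seq{i}" for i in range(n)], matrix=matrix)
    truth = AlignmentTruth(
        variable_columns=tuple(int(c) for c in var_cols),
        gap_columns=tuple(int(c) for c in gap_cols),
        site_pi=site_pi, gc_segments=spec.gc_segments)
    return aln, truth
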