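"""Whole-cross phenotyping, interaction classification and the *Psk* hierarchy.

A cross is phenotyped by its distribution over ascus classes; the
spore-killing percentage is the two-spored fraction (three-spored asci are
excluded from the denominator by default, as in the study).  Pairwise
interactions are classified with the F1-backcross design: an F1 monokaryon
is taken from a surviving spore of a two-spored ascus, backcrossed to both
parents and selfed, and the pattern of killing across those crosses yields
one of same-type, mutual killing, mutual resistance, or dominance.  Applied
to the canonical strain registry this reproduces the emergent killing
hierarchy of the *Psk* types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .genetics import GeneticMap, ResistanceModel, StrainGenotype, psk_type_of
from .killing import ALIVE, apply_killing, ascus_class
from .meiosis import Ascus, simulate_tetrad

SAME_TYPE = "same_type"
MUTUAL_KILLING = "mutual_killing"
MUTUAL_RESISTANCE = "mutual_resistance"
DOMINANCE = "dominance"
UNSTABLE = "unstable"

#: default decision rule for "killing observed" in a simulated cross:
#: killed-ascus fraction above 5% with at least 200 asci.
KILLING_THRESHOLD = 0.05
MIN_ASCI_FOR_CALL = 200


class NoF1Available(RuntimeError):
    """No two-spored ascus (hence no F1) within the attempt budget."""

    def __init__(self, message: str, saw_killed_asci: bool):
        super().__init__(message)
        self.saw_killed_asci = saw_killed_asci


@dataclass
class CrossResult:
    """Ascus-class counts of one simulated cross."""

    p1: str
    p2: str
    counts: Dict[int, int]  # class (0..4) -> count
    seed: Optional[int] = None

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def fraction(self, klass: int) -> float:
        return self.counts.get(klass, 0) / self.n

    @property
    def killing_pct(self) -> float:
        """Two-spored percentage, three-spored asci excluded (study policy)."""
        n2 = self.counts.get(2, 0)
        n4 = self.counts.get(4, 0)
        if n2 + n4 == 0:
            return 0.0
        return 100.0 * n2 / (n2 + n4)

    @property
    def killing_pct_include3(self) -> float:
        n2 = self.counts.get(2, 0)
        denom = sum(c for k, c in self.counts.items() if k in (2, 3, 4))
        if denom == 0:
            return 0.0
        return 100.0 * n2 / denom

    @property
    def killed_fraction(self) -> float:
        """Fraction of asci showing any killing (0- or 2-spored)."""
        return (self.counts.get(0, 0) + self.counts.get(2, 0)) / self.n

    def killing_observed(self, threshold: float = KILLING_THRESHOLD) -> bool:
        return self.killed_fraction > threshold


def simulate_cross(p1: StrainGenotype, p2: StrainGenotype, gmap: GeneticMap,
                   model: ResistanceModel, n_asci: int,
                   seed=None) -> CrossResult:
    """Simulate ``n_asci`` independent meioses of p1 × p2 and count classes."""
    if n_asci < 1:
        raise ValueError("n_asci must be >= 1")
    rng = np.random.default_rng(seed)
    counts = {k: 0 for k in range(5)}
    for _ in range(n_asci):
        killed = apply_killing(simulate_tetrad(p1, p2, gmap, rng), model, rng)
        counts[ascus_class(killed)] += 1
    return CrossResult(p1=p1.name, p2=p2.name, counts=counts,
                       seed=seed if isinstance(seed, int) else None)


def expected_ascus_distribution(f: float, q: float) -> Tuple[float, float, float]:
    """(P2, P3, P4) for a single heteroallelic killer locus.

    With FDS probability ``f`` and per-spore penetrance ``q``, killer-lacking
    spores occur only in FDS asci and come as a duplicate pair, so
    P2 = f·q², P3 = 2·f·q·(1−q), P4 = 1 − P2 − P3.
    """
    if not (0.0 <= f <= 1.0 and 0.0 <= q <= 1.0):
        raise ValueError("f and q must lie in [0, 1]")
    p2 = f * q * q
    p3 = 2.0 * f * q * (1.0 - q)
    return (p2, p3, 1.0 - p2 - p3)


def select_f1_from_two_spored(p1: StrainGenotype, p2: StrainGenotype,
                              gmap: GeneticMap, model: ResistanceModel,
                              rng: np.random.Generator,
                              max_attempts: int = 2000,
                              require_homoallelic: bool = True
                              ) -> StrainGenotype:
    """Haploid genotype of one nucleus of a surviving spore of a 2-spored ascus.

    Mirrors the study's isolation of F1 strains: spores homoallelic at the
    drive loci are preferred (the study explicitly selected F1 progeny
    homoallelic for the killing locus), and one nucleus is returned as the
    F1 monokaryon.  With ``require_homoallelic=False`` any surviving spore is
    accepted and a warning is issued when it was heteroallelic at a drive
    locus (the nucleus then holds only one of its two haplotypes).  Raises
    :class:`NoF1Available` when no acceptable two-spored ascus appears within
    ``max_attempts`` — e.g. same-type crosses (no killing) or same-locus
    mutual killers (only empty asci).
    """
    saw_killed = False
    drive_loci = sorted(set(p1.drive_loci()) | set(p2.drive_loci()),
                        key=lambda l: gmap.index[l])
    for _ in range(max_attempts):
        ascus = simulate_tetrad(p1, p2, gmap, rng)
        killed = apply_killing(ascus, model, rng)
        klass = ascus_class(killed)
        if klass in (0, 2):
            saw_killed = True
        if klass != 2:
            continue
        alive = [i for i in range(4) if killed.fates[i] == ALIVE]
        spore = alive[rng.integers(0, len(alive))]
        hetero = any(ascus.is_heteroallelic(spore, l) for l in drive_loci)
        if hetero:
            if require_homoallelic:
                continue
            warnings.warn(
                f"F1 spore from {p1.name} x {p2.name} was heteroallelic at a "
                f"drive locus; returning one nucleus", stacklevel=2)
        nuc = ascus.spore_nuclei(spore)[rng.integers(0, 2)]
        return StrainGenotype(
            name=f"F1({p1.name}x{p2.name})",
            alleles={l: al for l, al in nuc.haplotype.items() if al},
            markers=dict(nuc.origin),
        )
    raise NoF1Available(
        f"no acceptable two-spored ascus in {max_attempts} asci of "
        f"{p1.name} x {p2.name}", saw_killed_asci=saw_killed)


@dataclass
class InteractionCall:
    """Categorical pairwise interaction with its per-cross evidence."""

    p1: str
    p2: str
    verdict: str
    dominant: Optional[str] = None
    evidence: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.verdict == DOMINANCE and not self.dominant:
            raise ValueError("dominance verdict requires a dominant parent")
        if self.verdict != DOMINANCE and self.dominant is not None:
            raise ValueError("only dominance verdicts carry a dominant parent")


def classify_interaction(p1: StrainGenotype, p2: StrainGenotype,
                         gmap: GeneticMap, model: ResistanceModel,
                         n_asci: int = 1000, seed=None, n_f1: int = 5,
                         threshold: float = KILLING_THRESHOLD,
                         replicates: int = 1) -> InteractionCall:
    """Classify a pairwise interaction with the F1-backcross design.

    (a) No killing in the direct cross → same type.  (b) If killing occurs
    but no two-spored ascus yields an F1 (only empty asci) → mutual killing.
    (c) Otherwise ``n_f1`` independent F1 monokaryons (each from a spore
    homoallelic at the drive loci, as in the study) are backcrossed to both
    parents and selfed.  Per F1: killing in both backcrosses or in the self →
    mutual killing; in neither → mutual resistance; against exactly one
    parent → dominance of the other parent.  The verdict is the majority over
    F1 isolates (the study likewise scored several F1 strains of both mating
    types); without a majority, killing observed against both parents across
    isolates is called mutual killing, anything else ``unstable``.

    With ``replicates > 1`` the whole procedure is repeated on independent
    seeds; disagreement between replicates also yields ``unstable``.
    """
    if n_asci < MIN_ASCI_FOR_CALL:
        warnings.warn(
            f"n_asci={n_asci} is below {MIN_ASCI_FOR_CALL}; killing calls may "
            f"be noisy", stacklevel=2)
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    calls = [
        _classify_once(p1, p2, gmap, model, n_asci, child, n_f1, threshold)
        for child in ss.spawn(replicates)
    ]
    if replicates == 1:
        return calls[0]
    verdicts = {(c.verdict, c.dominant) for c in calls}
    if len(verdicts) == 1:
        return calls[0]
    return InteractionCall(
        p1=p1.name, p2=p2.name, verdict=UNSTABLE,
        evidence={"replicates": [(c.verdict, c.dominant, c.evidence)
                                 for c in calls]})


def _classify_once(p1, p2, gmap, model, n_asci, seed_seq, n_f1, threshold):
    rng = np.random.default_rng(seed_seq)
    direct = simulate_cross(p1, p2, gmap, model, n_asci, rng)
    evidence: Dict[str, object] = {"direct": dict(direct.counts)}
    if not direct.killing_observed(threshold):
        return InteractionCall(p1=p1.name, p2=p2.name, verdict=SAME_TYPE,
                               evidence=evidence)
    per_f1: List[Tuple[str, Optional[str]]] = []
    f1_records = []
    for _ in range(n_f1):
        try:
            f1 = select_f1_from_two_spored(p1, p2, gmap, model, rng)
        except NoF1Available as err:
            if not per_f1 and err.saw_killed_asci:
                evidence["f1"] = "none (killed asci only)"
                return InteractionCall(p1=p1.name, p2=p2.name,
                                       verdict=MUTUAL_KILLING,
                                       evidence=evidence)
            break
        b1 = simulate_cross(f1, p1, gmap, model, n_asci, rng)
        b2 = simulate_cross(f1, p2, gmap, model, n_asci, rng)
        selfx = simulate_cross(f1, f1, gmap, model, n_asci, rng)
        k1 = b1.killing_observed(threshold)
        k2 = b2.killing_observed(threshold)
        ks = selfx.killing_observed(threshold)
        if ks or (k1 and k2):
            per_f1.append((MUTUAL_KILLING, None))
        elif not k1 and not k2:
            per_f1.append((MUTUAL_RESISTANCE, None))
        else:
            per_f1.append((DOMINANCE, p1.name if k2 else p2.name))
        f1_records.append({
            "f1": sorted(a.label for a in f1.all_alleles()),
            "kill_backcross_p1": k1, "kill_backcross_p2": k2,
            "kill_self": ks, "verdict": per_f1[-1],
        })
    evidence["f1_crosses"] = f1_records
    if not per_f1:
        # killing seen in the direct cross but only non-two-spored killed asci
        return InteractionCall(p1=p1.name, p2=p2.name, verdict=MUTUAL_KILLING,
                               evidence=evidence)
    tally: Dict[Tuple[str, Optional[str]], int] = {}
    for v in per_f1:
        tally[v] = tally.get(v, 0) + 1
    (verdict, dominant), count = max(tally.items(), key=lambda kv: kv[1])
    if count > len(per_f1) / 2:
        return InteractionCall(p1=p1.name, p2=p2.name, verdict=verdict,
                               dominant=dominant, evidence=evidence)
    killed_p1 = any(r["kill_backcross_p1"] for r in f1_records)
    killed_p2 = any(r["kill_backcross_p2"] for r in f1_records)
    if killed_p1 and killed_p2:
        return InteractionCall(p1=p1.name, p2=p2.name, verdict=MUTUAL_KILLING,
                               evidence=evidence)
    return InteractionCall(p1=p1.name, p2=p2.name, verdict=UNSTABLE,
                           evidence=evidence)


@dataclass
class HierarchyGraph:
    """The emergent partial order of *Psk* types.

    ``dominance`` is a DAG (an edge A→B means A dominates B); mutual-killing
    and mutual-resistance pairs are undirected annotations; ``levels`` are
    longest-path strata of the dominance DAG (level 0 = bottom).
    """

    dominance: nx.DiGraph
    mutual_killing: List[Tuple[str, str]]
    mutual_resistance: List[Tuple[str, str]]
    same_type: List[Tuple[str, str]]
    calls: List[InteractionCall]
    levels: Dict[str, int] = field(default_factory=dict)

    def to_dot(self) -> str:
        lines = ["digraph psk_hierarchy {"]
        for node in self.dominance.nodes:
            lines.append(f'  "{node}" [label="{node}\\nlevel {self.levels[node]}"];')
        for a, b in self.dominance.edges:
            lines.append(f'  "{a}" -> "{b}";')
        for a, b in self.mutual_killing:
            lines.append(f'  "{a}" -> "{b}" [dir=both color=red '
                         f'label="mutual killing"];')
        for a, b in self.mutual_resistance:
            lines.append(f'  "{a}" -> "{b}" [dir=none color=blue '
                         f'label="mutual resistance"];')
        lines.append("}")
        return "\n".join(lines)


class HierarchyIntegrityError(RuntimeError):
    """A dominance cycle — the killer/resistance model violated a partial order."""


def build_hierarchy(genotypes: Sequence[StrainGenotype], gmap: GeneticMap,
                    model: ResistanceModel, n_asci: int = 1000,
                    seed=None, n_f1: int = 4) -> HierarchyGraph:
    """All-pairs interaction classification assembled into the *Psk* hierarchy.

    Nodes are *Psk* labels (strains of the same label collapse onto one
    node); levels are longest-path strata of the dominance DAG.
    """
    if len(genotypes) < 1:
        raise ValueError("at least one genotype required")
    labels = {g.name: psk_type_of(g) for g in genotypes}
    graph = nx.DiGraph()
    for g in genotypes:
        graph.add_node(labels[g.name])
    mutual_k, mutual_r, same = [], [], []
    calls = []
    ss = np.random.SeedSequence(seed)
    pairs = [(i, j) for i in range(len(genotypes))
             for j in range(i + 1, len(genotypes))]
    for (i, j), child in zip(pairs, ss.spawn(max(1, len(pairs)))):
        a, b = genotypes[i], genotypes[j]
        call = classify_interaction(a, b, gmap, model, n_asci=n_asci,
                                    seed=child, n_f1=n_f1)
        calls.append(call)
        la, lb = labels[a.name], labels[b.name]
        if la == lb:
            continue
        if call.verdict == DOMINANCE:
            graph.add_edge(labels[call.dominant],
                           lb if call.dominant == a.name else la)
        elif call.verdict == MUTUAL_KILLING:
            mutual_k.append((la, lb))
        elif call.verdict == MUTUAL_RESISTANCE:
            mutual_r.append((la, lb))
        elif call.verdict == SAME_TYPE:
            same.append((la, lb))
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise HierarchyIntegrityError(f"dominance cycle: {cycle}")
    levels = {}
    for node in nx.topological_sort(graph.reverse()):
        succ = list(graph.successors(node))
        levels[node] = 0 if not succ else 1 + max(levels[s] for s in succ)
    return HierarchyGraph(dominance=graph, mutual_killing=mutual_k,
                          mutual_resistance=mutual_r, same_type=same,
                          calls=calls, levels=levels)
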