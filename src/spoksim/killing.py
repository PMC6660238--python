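"""Spore-killing calculus applied to a simulated ascus.

Killer expression is zygote-level: every kill-capable homolog present in the
cross acts on every spore that carries no resistant allele, even if all of
the killer's own carriers die too (mutual killing between drivers at one
locus empties the ascus).  One resistant allele in either nucleus of the
dikaryotic spore suffices to protect it.  Incomplete penetrance q < 1 is a
per-spore, per-homolog independent Bernoulli by default (this is what
generates three-spored asci); an ascus-level alternative is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np

from .genetics import ResistanceModel, SpokAllele, StrainGenotype
from .meiosis import Ascus

ALIVE = "alive"
DEAD = "dead"


class UnresolvedFatesError(RuntimeError):
    """Ascus class queried before killing was applied."""


@dataclass
class KilledAscus:
    """An ascus with resolved spore fates."""

    ascus: Ascus
    fates: Tuple[str, str, str, str]

    @property
    def n_alive(self) -> int:
        return sum(f == ALIVE for f in self.fates)


def is_resistant(carried: Iterable[SpokAllele], killer_homolog: str,
                 model: ResistanceModel) -> bool:
    """True iff some carried allele withstands ``killer_homolog``.

    An allele's own ``resists`` profile is authoritative (mutants such as the
    nuclease-dead K240A override the model matrix); alleles built from the
    model carry the model's resistance row.
    """
    return any(killer_homolog in a.resists for a in carried)


def zygote_killers(p1: StrainGenotype, p2: StrainGenotype) -> frozenset:
    """Kill-capable homologs present in the zygote (union of parental alleles)."""
    return p1.kill_capable_homologs() | p2.kill_capable_homologs()


def apply_killing(ascus: Ascus, model: ResistanceModel,
                  rng: Optional[np.random.Generator] = None,
                  penetrance_scope: str = "spore") -> KilledAscus:
    """Resolve spore fates under the killer/resistance model.

    ``penetrance_scope='spore'`` (default): each unresisted killer homolog
    kills each sensitive spore independently with probability q — partial
    killing within an ascus yields three-spored asci.
    ``penetrance_scope='ascus'``: each killer is active with probability q in
    the whole ascus and then kills every sensitive spore.
    """
    if penetrance_scope not in ("spore", "ascus"):
        raise ValueError(f"unknown penetrance scope {penetrance_scope!r}")
    p1, p2 = ascus.parents
    killers = sorted(zygote_killers(p1, p2))
    drive_loci = sorted(set(p1.drive_loci()) | set(p2.drive_loci()),
                        key=lambda l: ascus.gmap.index[l])
    needs_rng = any(model.q(h) < 1.0 for h in killers)
    if needs_rng and rng is None:
        raise ValueError("rng required when any penetrance < 1")
    active = {h: True for h in killers}
    if penetrance_scope == "ascus" and needs_rng:
        active = {h: (model.q(h) >= 1.0 or rng.random() < model.q(h))
                  for h in killers}
    fates: List[str] = []
    for spore in range(4):
        carried = ascus.spore_alleles(spore, drive_loci)
        dead = False
        for h in killers:
            if is_resistant(carried, h, model):
                continue
            if penetrance_scope == "ascus":
                if active[h]:
                    dead = True
            else:
                q = model.q(h)
                if q >= 1.0 or rng.random() < q:
                    dead = True
        fates.append(DEAD if dead else ALIVE)
    return KilledAscus(ascus=ascus, fates=tuple(fates))


def ascus_class(killed: KilledAscus) -> int:
    """Number of surviving spores (the 0- to 4-spored ascus class)."""
    if any(f not in (ALIVE, DEAD) for f in killed.fates):
        raise UnresolvedFatesError("spore fates not resolved")
    return killed.n_alive
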