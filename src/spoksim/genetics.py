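"""Domain types for *Spok* meiotic-drive genetics.

*Podospora anserina* strains are haploid; each carries zero or more *Spok*
spore-killer genes, either at a gene's standard chromosomal site (*Spok1*,
*Spok2*) or inside the mobile *Spok* block, a large non-recombining region
that sits at different chromosome-arm positions in different strains and can
hold *Spok3* and/or *Spok4*.  A single SPOK protein performs both killing
(nuclease domain) and resistance (kinase domain), so each allele is described
by a kill flag and a resistance profile over killer homologs.

The canonical strain registry transcribed from the study's strain table ships
as an editable YAML file (``spoksim/data/default_registry.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import yaml

HOMOLOGS = ("Spok1", "Spok2", "Spok3", "Spok4", "SpokPsi1")


class RegistryError(KeyError):
    """Lookup of an unknown strain or locus in a registry."""


class ConfigError(ValueError):
    """Structurally invalid registry / model configuration."""


@dataclass(frozen=True)
class SpokAllele:
    """One *Spok* allele: killer identity, kill competence and resistance set.

    ``resists`` is the set of killer homologs this allele defends its carrier
    spore against.  A kill-capable allele must resist its own homolog (a
    killer never kills its carrier); violating input is rejected.
    """

    homolog: str
    kills: bool
    resists: frozenset = frozenset()
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "resists", frozenset(self.resists))
        if self.kills and self.homolog not in self.resists:
            raise ConfigError(
                f"kill-capable allele {self.label or self.homolog} must resist "
                f"its own homolog {self.homolog}"
            )

    def __str__(self):  # pragma: no cover - cosmetic
        return self.label or self.homolog


@dataclass(frozen=True, order=True)
class Locus:
    """A mapped position: chromosome, arm and distance to the centromere.

    ``d`` is the genetic distance in Morgans from the centromere of the arm
    the locus sits on.  A *Spok* block occupies exactly one locus (it moves
    in the genome as a unit and does not recombine internally).
    """

    name: str
    chromosome: str
    arm: str  # "L" or "R"
    d: float

    def __post_init__(self):
        if self.arm not in ("L", "R"):
            raise ConfigError(f"locus {self.name}: arm must be 'L' or 'R'")
        if self.d < 0:
            raise ConfigError(f"locus {self.name}: d must be >= 0")


class GeneticMap:
    """Ordered loci grouped per chromosome arm, sorted by centromere distance."""

    def __init__(self, loci: Iterable[Locus]):
        loci = tuple(loci)
        names = [l.name for l in loci]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate locus names in map")
        arms: Dict[Tuple[str, str], List[Locus]] = {}
        for l in loci:
            arms.setdefault((l.chromosome, l.arm), []).append(l)
        for key, group in arms.items():
            group.sort(key=lambda l: l.d)
            for a, b in zip(group, group[1:]):
                if not (b.d > a.d):
                    raise ConfigError(
                        f"loci {a.name} and {b.name} on {key} not strictly "
                        f"ordered by d"
                    )
        # global order: by chromosome, then arm, then d — stable across runs
        self.loci: Tuple[Locus, ...] = tuple(
            l for key in sorted(arms) for l in arms[key]
        )
        self.arms: Dict[Tuple[str, str], Tuple[Locus, ...]] = {
            key: tuple(group) for key, group in arms.items()
        }
        self.index: Dict[Locus, int] = {l: i for i, l in enumerate(self.loci)}
        self.by_name: Dict[str, Locus] = {l.name: l for l in self.loci}
        self._plan = self._build_plan()

    def _build_plan(self):
        """Per-chromosome simulation plan: contiguous arm slices + interval lengths."""
        chroms: Dict[str, list] = {}
        pos = 0
        # self.loci is grouped by (chromosome, arm) and sorted by d
        for key in sorted(self.arms):
            chrom, _arm = key
            group = self.arms[key]
            start = self.index[group[0]]
            deltas = []
            prev = 0.0
            for l in group:
                deltas.append(l.d - prev)
                prev = l.d
            chroms.setdefault(chrom, []).append((start, start + len(group), deltas))
            pos += len(group)
        return [(chrom, arms) for chrom, arms in sorted(chroms.items())]

    def __len__(self):
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __eq__(self, other):
        return isinstance(other, GeneticMap) and self.loci == other.loci

    def __hash__(self):
        return hash(self.loci)


@dataclass
class StrainGenotype:
    """Haploid genotype: allele lists per locus plus optional origin tags.

    ``alleles`` maps a Locus to the tuple of SpokAllele it carries there (an
    absent locus or empty tuple is the null allele; a block locus may carry
    several genes, e.g. Spok3+Spok4, or two Spok3 copies).  ``markers`` maps
    loci to a parent-of-origin tag used for introgression tracking.
    """

    name: str
    alleles: Dict[Locus, Tuple[SpokAllele, ...]] = field(default_factory=dict)
    markers: Dict[Locus, str] = field(default_factory=dict)

    def __post_init__(self):
        self.alleles = {
            loc: tuple(al) for loc, al in self.alleles.items() if len(al) > 0
        }

    def alleles_at(self, locus: Locus) -> Tuple[SpokAllele, ...]:
        return self.alleles.get(locus, ())

    def marker_at(self, locus: Locus) -> str:
        """Origin tag at a locus; defaults to the strain's own name."""
        return self.markers.get(locus, self.name)

    def all_alleles(self) -> Tuple[SpokAllele, ...]:
        return tuple(a for al in self.alleles.values() for a in al)

    def kill_capable_homologs(self) -> frozenset:
        return frozenset(a.homolog for a in self.all_alleles() if a.kills)

    def drive_loci(self) -> Tuple[Locus, ...]:
        return tuple(self.alleles)

    def tagged(self, gmap: GeneticMap, tag: str) -> "StrainGenotype":
        """Copy of this genotype with every map locus origin-tagged ``tag``."""
        return StrainGenotype(
            name=self.name,
            alleles=dict(self.alleles),
            markers={loc: tag for loc in gmap.loci},
        )


@dataclass
class ResistanceModel:
    """Killer/resistance calculus: who can kill, who withstands whom, and how often.

    ``resistance[(h, g)]`` is True when a carried allele of homolog ``g``
    protects a spore from killer homolog ``h``.  ``penetrance[h]`` is the
    per-spore probability that an unresisted killer ``h`` actually kills
    (q < 1 produces three-spored asci).
    """

    kill_capable: Dict[str, bool]
    resistance: Dict[Tuple[str, str], bool]
    penetrance: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for h, capable in self.kill_capable.items():
            if capable and not self.resistance.get((h, h), False):
                raise ConfigError(f"kill-capable homolog {h} must self-resist")
        for h, q in self.penetrance.items():
            if not (0.0 <= q <= 1.0):
                raise ConfigError(f"penetrance of {h} must be in [0, 1], got {q}")

    def resists(self, killer: str, carried: str) -> bool:
        return self.resistance.get((killer, carried), False)

    def q(self, homolog: str) -> float:
        return self.penetrance.get(homolog, 1.0)

    def resistance_row(self, carried: str) -> frozenset:
        """Killers that an allele of ``carried`` defends against."""
        return frozenset(h for (h, g) in self.resistance
                         if g == carried and self.resistance[(h, g)])

    def allele(self, homolog: str, label: str = "") -> SpokAllele:
        """Build the model's default allele of ``homolog``."""
        return SpokAllele(
            homolog=homolog,
            kills=self.kill_capable.get(homolog, False),
            resists=self.resistance_row(homolog),
            label=label or homolog,
        )


def default_resistance_model() -> ResistanceModel:
    """The study's resistance model for the four functional *Spok* homologs.

    Within *P. anserina* the homologs do not interact: resistance is
    identity-only (R(h,h)).  Across species, *Spok1* resists all of
    Spok1..Spok4, and *Spok4* additionally resists *Spok1*.  All functional
    homologs are kill-capable with full penetrance; *SpokPsi1* is a
    pseudogene (no killing, no resistance).
    """
    resistance = {}
    for h in ("Spok1", "Spok2", "Spok3", "Spok4"):
        resistance[(h, h)] = True
    for h in ("Spok2", "Spok3", "Spok4"):
        resistance[(h, "Spok1")] = True  # Spok1 resists everything
    resistance[("Spok1", "Spok4")] = True  # Spok4 resists Spok1
    return ResistanceModel(
        kill_capable={
            "Spok1": True, "Spok2": True, "Spok3": True, "Spok4": True,
            "SpokPsi1": False,
        },
        resistance=resistance,
        penetrance={h: 1.0 for h in ("Spok1", "Spok2", "Spok3", "Spok4")},
    )


def spok3_k240a(label: str = "Spok3-K240A") -> SpokAllele:
    """Nuclease-dead *Spok3* point mutant: no killing, resistance retained."""
    return SpokAllele("Spok3", kills=False, resists={"Spok3"}, label=label)


def spok2_strain_a(label: str = "Spok2-strainA") -> SpokAllele:
    """The French strain A allele of *Spok2*: resistance without killing."""
    return SpokAllele("Spok2", kills=False, resists={"Spok2"}, label=label)


# ---------------------------------------------------------------------------
# registry (text config) handling


def _model_from_config(cfg: Mapping) -> ResistanceModel:
    pairs = {(k, c): True for k, c in cfg.get("resistance_pairs", [])}
    return ResistanceModel(
        kill_capable=dict(cfg.get("kill_capable", {})),
        resistance=pairs,
        penetrance={h: float(q) for h, q in cfg.get("penetrance", {}).items()},
    )


def _allele_from_config(entry, model: ResistanceModel) -> SpokAllele:
    if isinstance(entry, str):
        return model.allele(entry)
    return SpokAllele(
        homolog=entry["homolog"],
        kills=bool(entry["kills"]),
        resists=frozenset(entry.get("resists", [])),
        label=entry.get("label", ""),
    )


class Registry:
    """Strain registry + resistance model, loadable from a YAML text config."""

    def __init__(self, model: ResistanceModel, loci: Dict[str, Locus],
                 strains: Dict[str, List[Tuple[str, List[SpokAllele]]]],
                 locus_meta: Optional[Dict[str, dict]] = None):
        self.model = model
        self.loci = loci
        self._strains = strains
        self.locus_meta = locus_meta or {}

    @property
    def strain_names(self) -> Tuple[str, ...]:
        return tuple(self._strains)

    def genotype_of(self, strain_name: str) -> StrainGenotype:
        if strain_name not in self._strains:
            raise RegistryError(
                f"unknown strain {strain_name!r}; known strains: "
                f"{', '.join(self._strains)}"
            )
        alleles: Dict[Locus, Tuple[SpokAllele, ...]] = {}
        for locus_name, allele_list in self._strains[strain_name]:
            if locus_name not in self.loci:
                raise RegistryError(f"strain {strain_name}: unknown locus "
                                    f"{locus_name!r}")
            alleles[self.loci[locus_name]] = tuple(allele_list)
        return StrainGenotype(name=strain_name, alleles=alleles)

    def to_config(self) -> dict:
        cfg = {
            "kill_capable": dict(self.model.kill_capable),
            "resistance_pairs": sorted(
                [list(k) for k, v in self.model.resistance.items() if v]
            ),
            "penetrance": dict(self.model.penetrance),
            "loci": {
                name: {
                    "chromosome": loc.chromosome, "arm": loc.arm,
                    "d": float(loc.d), **self.locus_meta.get(name, {}),
                }
                for name, loc in self.loci.items()
            },
            "strains": {
                strain: [
                    {
                        "locus": locus_name,
                        "alleles": [
                            {
                                "homolog": a.homolog, "kills": a.kills,
                                "resists": sorted(a.resists), "label": a.label,
                            }
                            for a in allele_list
                        ],
                    }
                    for locus_name, allele_list in placements
                ]
                for strain, placements in self._strains.items()
            },
        }
        return cfg

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def from_config(cls, cfg: Mapping) -> "Registry":
        model = _model_from_config(cfg)
        loci = {}
        meta = {}
        for name, spec in cfg.get("loci", {}).items():
            loci[name] = Locus(
                name=name, chromosome=str(spec["chromosome"]),
                arm=spec["arm"], d=float(spec["d"]),
            )
            extra = {k: v for k, v in spec.items()
                     if k not in ("chromosome", "arm", "d")}
            if extra:
                meta[name] = extra
        strains = {}
        for strain, placements in cfg.get("strains", {}).items():
            entries = []
            for p in placements or []:
                entries.append(
                    (p["locus"],
                     [_allele_from_config(a, model) for a in p.get("alleles", [])])
                )
            strains[strain] = entries
        return cls(model, loci, strains, meta)

    @classmethod
    def load(cls, path) -> "Registry":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


def default_registry() -> Registry:
    """The canonical registry transcribed from the study's strain table."""
    text = resources.files("spoksim.data").joinpath(
        "default_registry.yaml").read_text()
    return Registry.from_config(yaml.safe_load(text))


def genotype_of(strain_name: str, registry: Optional[Registry] = None
                ) -> StrainGenotype:
    """Look up a strain's transcribed genotype in a registry (default: canonical)."""
    registry = registry or default_registry()
    return registry.genotype_of(strain_name)


# ---------------------------------------------------------------------------
# Psk phenotype labels

# (kill-capable homolog set, block arm or None) -> Psk label
_PSK_TABLE = {
    (frozenset({"Spok2", "Spok3", "Spok4"}), ("3", "L")): "Psk-1",
    (frozenset({"Spok2", "Spok3", "Spok4"}), ("5", "L")): "Psk-7",
    (frozenset({"Spok2", "Spok3"}), ("5", "R")): "Psk-2",
    (frozenset({"Spok3", "Spok4"}), ("3", "L")): "Psk-5",
    (frozenset({"Spok2", "Spok4"}), ("5", "L")): "Psk-8",
    (frozenset({"Spok2", "Spok3"}), ("4", "R")): "Psk-P1",
    (frozenset({"Spok2", "Spok3", "Spok4"}), ("4", "R")): "Psk-P1",
    (frozenset({"Spok2"}), None): "Psk-S",
    (frozenset({"Spok1"}), None): "Psk-C1",
    (frozenset(), None): "naive",
}

_STANDARD_SITES = {"spok2_site", "spok1_site", "spokpsi1_site", "papks1"}


def psk_type_of(g: StrainGenotype) -> str:
    """Spore-killer phenotype label from kill-capable *Spok* content + block arm.

    Unmapped combinations return an ``unclassified:`` description rather than
    raising; novel genotypes are expected when editing the registry.
    """
    kill_set = g.kill_capable_homologs()
    block_pos = None
    for locus, alleles in g.alleles.items():
        if locus.name in _STANDARD_SITES:
            continue
        if any(a.homolog in ("Spok3", "Spok4") for a in alleles):
            block_pos = (locus.chromosome, locus.arm)
    key = (kill_set, block_pos)
    if key in _PSK_TABLE:
        return _PSK_TABLE[key]
    if not kill_set:
        return "naive"
    desc = "+".join(sorted(kill_set)) + (
        f"@{block_pos[0]}{block_pos[1]}" if block_pos else "")
    return f"unclassified:{desc}"


def knockin(g: StrainGenotype, allele: SpokAllele, locus: Locus,
            name: Optional[str] = None) -> StrainGenotype:
    """Insert a single-copy allele at ``locus`` (e.g. the PaPKS1 site)."""
    alleles = dict(g.alleles)
    alleles[locus] = alleles.get(locus, ()) + (allele,)
    return StrainGenotype(name=name or f"{g.name}+{allele.label}@{locus.name}",
                          alleles=alleles, markers=dict(g.markers))


def knockout(g: StrainGenotype, homolog: str, name: Optional[str] = None
             ) -> StrainGenotype:
    """Delete every allele of ``homolog`` from the genotype."""
    alleles = {
        loc: tuple(a for a in al if a.homolog != homolog)
        for loc, al in g.alleles.items()
    }
    return StrainGenotype(name=name or f"{g.name}-d{homolog}",
                          alleles=alleles, markers=dict(g.markers))
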